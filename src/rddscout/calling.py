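"""RDD calling: genotype comparison, coverage thresholds and binomial rescue.

For every specimen, the DNA and RNA genotype at each sequenced site is
compared.  Concordant sites (same genotype in both assays) calibrate three
per-specimen coverage thresholds:

* ``c_dna_aa`` -- mean reference DNA read count over concordant homozygous-
  reference (AA) sites;
* ``c_rna_ab`` / ``c_rna_bb`` -- mean variant RNA read count over concordant
  heterozygous (AB) / homozygous-variant (BB) sites.

A discordant site (DNA AA, RNA AB or BB) is a *high-coverage* RDD when its
DNA reference reads strictly exceed ``c_dna_aa`` and its RNA variant reads
strictly exceed the class-matched RNA threshold.

Low-coverage sites are *rescued* with a pooled binomial argument.  Under the
assumption that a candidate site is edited in every specimen, the cohort-wide
editing ratio is ``r = e / t`` (edited / total RNA reads summed over all
specimens).  For one specimen with ``x`` reference DNA reads and ``y`` edited
RNA reads, the chance that low coverage alone explains the DNA evidence is
``(1-r)**x`` and the chance of the RNA evidence arising by error is ``r**y``.
The site is rescued when both are below ``alpha`` (default 0.05) and
``y > 3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import BASES, CALL_COLUMNS, COUNT_COLS

logger = logging.getLogger(__name__)

# genotype class codes used in the vectorized path
NOCALL, AA, AB, BB = 0, 1, 2, 3
GENOTYPE_NAMES = {NOCALL: "NoCall", AA: "AA", AB: "AB", BB: "BB"}

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class CoverageThresholds:
    """Per-specimen concordant-site coverage thresholds."""

    specimen: str
    c_dna_aa: float
    c_rna_ab: float
    c_rna_bb: float

    def rna_threshold(self, genotype: int) -> float:
        if genotype == AB:
            return self.c_rna_ab
        if genotype == BB:
            return self.c_rna_bb
        raise ValueError("RNA threshold defined only for AB/BB")


@dataclass
class RescueParams:
    """Rescue-rule constants: significance level and minimum edited reads.

    ``min_edited=4`` encodes the rule "y > 3"."""

    alpha: float = 0.05
    min_edited: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_edited < 1:
            raise ValueError("min_edited must be >= 1")


def call_genotype(
    counts, ref: str, min_depth: int = 2, hom_fraction: float = 0.9
) -> tuple[str, str | None]:
    """Classify one allele-count record against the reference base.

    Returns ``(genotype, variant_base)`` where genotype is one of
    ``NoCall/AA/AB/BB``.  ``variant_base`` is the most frequent non-reference
    base (ties broken alphabetically) for AB/BB, else None.  A frequency-based
    stand-in for a full genotype-likelihood caller.
    """
    if ref not in BASES:
        raise ValueError(f"ref must be one of {BASES}")
    vec = np.array([int(counts.get(f"n{b}", counts.get(b, 0))) for b in BASES])
    cls, var_idx = _genotype_vectorized(
        vec[None, :], np.array([_BASE_IDX[ref]]), min_depth, hom_fraction
    )
    variant = BASES[var_idx[0]] if cls[0] in (AB, BB) else None
    return GENOTYPE_NAMES[int(cls[0])], variant


def _genotype_vectorized(
    counts: np.ndarray, ref_idx: np.ndarray, min_depth: int, hom_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized genotype classification.

    ``counts`` is (n, 4); returns (class codes, variant base index).  The
    variant base is the most frequent non-reference base, ties broken
    alphabetically (lowest base index wins via argmax on the first maximum).
    """
    n = counts.shape[0]
    depth = counts.sum(axis=1)
    rows = np.arange(n)
    ref_count = counts[rows, ref_idx]
    nonref = counts.copy()
    nonref[rows, ref_idx] = -1  # ref base never selected as variant
    var_idx = nonref.argmax(axis=1)
    var_count = counts[rows, var_idx]

    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = np.where(depth > 0, ref_count / np.maximum(depth, 1), 0.0)
        var_frac = np.where(depth > 0, var_count / np.maximum(depth, 1), 0.0)

    cls = np.full(n, AB, dtype=np.int8)
    cls[ref_frac >= hom_fraction] = AA
    cls[(var_frac >= hom_fraction) & (cls != AA)] = BB
    cls[depth < min_depth] = NOCALL
    return cls, var_idx


def compute_thresholds(
    dna_cls: np.ndarray,
    rna_cls: np.ndarray,
    dna_ref_count: np.ndarray,
    dna_var_idx: np.ndarray,
    rna_counts: np.ndarray,
    rna_var_idx: np.ndarray,
    specimen: str = "",
) -> CoverageThresholds:
    """Compute concordant-site thresholds for one specimen.

    Concordance means identical genotype class in DNA and RNA; for AB/BB the
    variant base must also agree.  Empty categories yield a threshold of 0
    with a logged warning; no concordant sites at all is an error.
    """
    rows = np.arange(len(dna_cls))
    same_var = dna_var_idx == rna_var_idx
    conc_aa = (dna_cls == AA) & (rna_cls == AA)
    conc_ab = (dna_cls == AB) & (rna_cls == AB) & same_var
    conc_bb = (dna_cls == BB) & (rna_cls == BB) & same_var
    if not (conc_aa.any() or conc_ab.any() or conc_bb.any()):
        raise ValueError(f"specimen {specimen!r}: no concordant sites; "
                         "coverage thresholds are undefined")

    def _mean(mask: np.ndarray, values: np.ndarray, label: str) -> float:
        if not mask.any():
            logger.warning(
                "specimen %s: no concordant %s sites; threshold set to 0",
                specimen, label,
            )
            return 0.0
        return float(values[mask].mean())

    rna_var_count = rna_counts[rows, rna_var_idx]
    return CoverageThresholds(
        specimen=specimen,
        c_dna_aa=_mean(conc_aa, dna_ref_count, "AA"),
        c_rna_ab=_mean(conc_ab, rna_var_count, "AB"),
        c_rna_bb=_mean(conc_bb, rna_var_count, "BB"),
    )


def call_high_coverage(
    dna_counts, rna_counts, ref: str, th: CoverageThresholds,
    min_depth: int = 2, hom_fraction: float = 0.9,
) -> dict | None:
    """Evaluate one discordant site for a high-coverage call (scalar API)."""
    dna_cls, _ = call_genotype(dna_counts, ref, min_depth, hom_fraction)
    rna_cls, variant = call_genotype(rna_counts, ref, min_depth, hom_fraction)
    if dna_cls != "AA" or rna_cls not in ("AB", "BB"):
        return None
    get = lambda c, b: int(c.get(f"n{b}", c.get(b, 0)))  # noqa: E731
    x = get(dna_counts, ref)
    y = get(rna_counts, variant)
    rna_th = th.c_rna_ab if rna_cls == "AB" else th.c_rna_bb
    if x > th.c_dna_aa and y > rna_th:
        return {
            "ref": ref, "alt": variant, "x_dna_ref": x, "y_rna_alt": y,
            "rna_depth": sum(get(rna_counts, b) for b in BASES),
            "status": "high_coverage",
        }
    return None


def pooled_editing_ratio(rna_counts_at_site: np.ndarray, ref_idx: int,
                         alt_idx: int | None = None) -> tuple[float, int, int]:
    """Cohort-pooled editing ratio r = e / t at one site.

    ``rna_counts_at_site`` is (n_specimens, 4).  The edited base defaults to
    the most frequent pooled non-reference base (ties alphabetical).  Returns
    ``(r, alt_idx, t)``; ``t == 0`` marks an unevaluable site (r reported 0).
    """
    pooled = rna_counts_at_site.sum(axis=0)
    if alt_idx is None:
        nonref = pooled.copy()
        nonref[ref_idx] = -1
        alt_idx = int(nonref.argmax())
    t = int(pooled.sum())
    if t == 0:
        return 0.0, alt_idx, 0
    e = int(pooled[alt_idx])
    return e / t, alt_idx, t


def rescue_test(x: int, y: int, r: float, params: RescueParams | None = None) -> bool:
    """Decide whether a low-coverage site is rescued.

    Accepts iff ``(1-r)**x < alpha`` and ``r**y < alpha`` and
    ``y >= min_edited`` (default: y > 3).  The edge ``0**0`` is 1, so with
    ``r=0`` no site is ever rescued and with ``r=1`` an ``x=0`` site fails
    the DNA criterion.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    p = params or RescueParams()
    if y < p.min_edited:
        return False
    return (1.0 - r) ** x < p.alpha and r ** y < p.alpha


def call_rdds(
    counts: pd.DataFrame,
    genome: dict[str, str],
    params: RescueParams | None = None,
    min_depth: int = 2,
    hom_fraction: float = 0.9,
    per_specimen_thresholds: bool = True,
    enable_rescue: bool = True,
    thresholds: dict[str, CoverageThresholds] | None = None,
) -> pd.DataFrame:
    """Call RDDs for a cohort allele-count table.

    Returns a calls DataFrame (see :data:`rddscout.io_model.CALL_COLUMNS`)
    with per-call ``status`` of ``high_coverage`` or ``rescued``.  Calling is
    deterministic given inputs.

    With ``per_specimen_thresholds=False`` a single cohort-wide threshold set
    (computed over all specimens' concordant sites) is used instead.  An
    explicit ``thresholds`` mapping (specimen -> CoverageThresholds)
    overrides computation entirely -- used by the down-sampling evaluation,
    which applies the full-depth read-depth criteria to thinned data.
    """
    params = params or RescueParams()
    prep = _prepare(counts, genome, min_depth, hom_fraction)
    if prep is None:
        return _empty_calls()
    (wide, ref_idx, dna, rna, dna_cls, dna_var, rna_cls, rna_var,
     dna_ref_count, rna_var_count, rna_depth) = prep
    rows = np.arange(len(wide))

    specimens = wide["specimen"].to_numpy()
    if thresholds is not None:
        missing = set(pd.unique(specimens)) - set(thresholds)
        if missing:
            raise ValueError(f"no thresholds supplied for specimens {missing}")
    elif per_specimen_thresholds:
        thresholds = {}
        for sp in pd.unique(specimens):
            m = specimens == sp
            thresholds[sp] = compute_thresholds(
                dna_cls[m], rna_cls[m], dna_ref_count[m], dna_var[m],
                rna[m], rna_var[m], specimen=sp,
            )
    else:
        global_th = compute_thresholds(
            dna_cls, rna_cls, dna_ref_count, dna_var, rna, rna_var,
            specimen="<cohort>",
        )
        thresholds = {sp: global_th for sp in pd.unique(specimens)}

    th_dna = np.array([thresholds[s].c_dna_aa for s in specimens])
    th_ab = np.array([thresholds[s].c_rna_ab for s in specimens])
    th_bb = np.array([thresholds[s].c_rna_bb for s in specimens])
    th_rna = np.where(rna_cls == AB, th_ab, th_bb)

    discordant = (dna_cls == AA) & np.isin(rna_cls, (AB, BB))
    hc_mask = discordant & (dna_ref_count > th_dna) & (rna_var_count > th_rna)

    calls = [
        pd.DataFrame(
            {
                "specimen": specimens[hc_mask],
                "chrom": wide["chrom"].to_numpy()[hc_mask],
                "pos": wide["pos"].to_numpy()[hc_mask],
                "ref": np.array(BASES)[ref_idx[hc_mask]],
                "alt": np.array(BASES)[rna_var[hc_mask]],
                "x_dna_ref": dna_ref_count[hc_mask],
                "y_rna_alt": rna_var_count[hc_mask],
                "rna_depth": rna_depth[hc_mask],
                "status": "high_coverage",
            }
        )
    ]

    if enable_rescue:
        calls.append(
            _rescue_calls(
                wide, rna, ref_idx, dna_cls, dna_ref_count, rna_depth,
                hc_mask, params,
            )
        )

    out = pd.concat(calls, ignore_index=True)
    out = out.sort_values(["specimen", "chrom", "pos"]).reset_index(drop=True)
    return out.astype({"pos": np.int64, "x_dna_ref": np.int64,
                       "y_rna_alt": np.int64, "rna_depth": np.int64})


def _prepare(counts, genome, min_depth, hom_fraction):
    """Pair assays, resolve reference bases and genotype both assays."""
    wide = _pair_assays(counts)
    if wide.empty:
        return None
    ref_idx = _reference_indices(wide, genome)
    keep = ref_idx >= 0  # sites with N/unknown reference are skipped
    if not keep.all():
        logger.warning("skipping %d site rows with ambiguous reference base",
                       int((~keep).sum()))
        wide = wide.loc[keep].reset_index(drop=True)
        ref_idx = ref_idx[keep]
    dna = wide[[f"dna_n{b}" for b in BASES]].to_numpy(np.int64)
    rna = wide[[f"rna_n{b}" for b in BASES]].to_numpy(np.int64)
    rows = np.arange(len(wide))
    dna_cls, dna_var = _genotype_vectorized(dna, ref_idx, min_depth, hom_fraction)
    rna_cls, rna_var = _genotype_vectorized(rna, ref_idx, min_depth, hom_fraction)
    return (wide, ref_idx, dna, rna, dna_cls, dna_var, rna_cls, rna_var,
            dna[rows, ref_idx], rna[rows, rna_var], rna.sum(axis=1))


def cohort_thresholds(
    counts: pd.DataFrame,
    genome: dict[str, str],
    min_depth: int = 2,
    hom_fraction: float = 0.9,
) -> dict[str, CoverageThresholds]:
    """Per-specimen concordant-site thresholds for a cohort count table."""
    prep = _prepare(counts, genome, min_depth, hom_fraction)
    if prep is None:
        raise ValueError("no paired DNA/RNA records; thresholds undefined")
    (wide, _, _, rna, dna_cls, dna_var, rna_cls, rna_var,
     dna_ref_count, _, _) = prep
    specimens = wide["specimen"].to_numpy()
    out = {}
    for sp in pd.unique(specimens):
        m = specimens == sp
        out[sp] = compute_thresholds(
            dna_cls[m], rna_cls[m], dna_ref_count[m], dna_var[m],
            rna[m], rna_var[m], specimen=sp,
        )
    return out


def _rescue_calls(
    wide: pd.DataFrame,
    rna: np.ndarray,
    ref_idx: np.ndarray,
    dna_cls: np.ndarray,
    dna_ref_count: np.ndarray,
    rna_depth: np.ndarray,
    hc_mask: np.ndarray,
    params: RescueParams,
) -> pd.DataFrame:
    """Pooled-ratio rescue of low-coverage sites.

    A (site, specimen) pair is evaluated only when the specimen's DNA is AA
    and the pair is not already a high-coverage call.  The edited base and
    pooled ratio are shared per site across specimens.
    """
    # pooled RNA counts per site over all specimens
    site_keys = wide[["chrom", "pos"]]
    grouped = pd.DataFrame(rna, columns=list(BASES))
    grouped[["chrom", "pos"]] = site_keys
    pooled = grouped.groupby(["chrom", "pos"], sort=False)[list(BASES)].sum()

    site_index = pd.MultiIndex.from_frame(site_keys)
    pooled_rows = pooled.loc[site_index].to_numpy(np.int64)

    # site-level reference must be constant; take it per row
    nonref = pooled_rows.copy()
    rows = np.arange(len(wide))
    nonref[rows, ref_idx] = -1
    alt_idx = nonref.argmax(axis=1)
    t = pooled_rows.sum(axis=1)
    e = pooled_rows[rows, alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(t > 0, e / np.maximum(t, 1), 0.0)

    y = rna[rows, alt_idx]
    x = dna_ref_count

    cand = (dna_cls == AA) & ~hc_mask & (t > 0) & (y >= params.min_edited)
    with np.errstate(invalid="ignore"):
        p_dna = (1.0 - r) ** x
        p_rna = r.astype(float) ** y
    accepted = cand & (p_dna < params.alpha) & (p_rna < params.alpha)

    return pd.DataFrame(
        {
            "specimen": wide["specimen"].to_numpy()[accepted],
            "chrom": wide["chrom"].to_numpy()[accepted],
            "pos": wide["pos"].to_numpy()[accepted],
            "ref": np.array(BASES)[ref_idx[accepted]],
            "alt": np.array(BASES)[alt_idx[accepted]],
            "x_dna_ref": x[accepted],
            "y_rna_alt": y[accepted],
            "rna_depth": rna_depth[accepted],
            "status": "rescued",
        }
    )


def _pair_assays(counts: pd.DataFrame) -> pd.DataFrame:
    """Inner-join DNA and RNA rows per (specimen, chrom, pos)."""
    dna = counts[counts["assay"] == "DNA"].rename(
        columns={c: f"dna_{c}" for c in COUNT_COLS}
    )
    rna = counts[counts["assay"] == "RNA"].rename(
        columns={c: f"rna_{c}" for c in COUNT_COLS}
    )
    keys = ["specimen", "chrom", "pos"]
    wide = dna.drop(columns="assay").merge(
        rna.drop(columns="assay"), on=keys, how="inner"
    )
    return wide.reset_index(drop=True)


def _reference_indices(wide: pd.DataFrame, genome: dict[str, str]) -> np.ndarray:
    """Map each row's (chrom, pos) to a base index in BASES; -1 for N/other."""
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    refs = np.empty(len(wide), dtype=np.int64)
    chroms = wide["chrom"].to_numpy()
    poss = wide["pos"].to_numpy(np.int64)
    for chrom in pd.unique(chroms):
        contig = genome.get(chrom)
        if contig is None:
            raise KeyError(f"contig {chrom!r} missing from reference")
        seq = np.frombuffer(contig.encode("ascii"), dtype=np.uint8)
        m = chroms == chrom
        p = poss[m]
        if (p < 1).any() or (p > len(seq)).any():
            raise ValueError(f"position outside contig {chrom!r}")
        refs[m] = lut[seq[p - 1]]
    return refs


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in zip(
            CALL_COLUMNS,
            [object, object, np.int64, object, object, np.int64, np.int64,
             np.int64, object],
        )}
    )
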