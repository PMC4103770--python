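"""Seeded synthetic cohorts: toy genome, annotations, paired DNA/RNA allele
counts with planted edits, SNPs and sequencing error, and expression with a
miRNA-target-editing effect.

The generator emulates the structure of a low-coverage paired DNA/RNA tumor
cohort: shallow (~4X) DNA against deeper (~30X) RNA, editing concentrated in
Alu-like repeats with a strong canonical (A>G|T>C) class bias, part of the
edits laid down in clusters, germline SNPs segregating under Hardy-Weinberg,
uniform per-base sequencing error, and negative-binomial expression whose
mean is multiplied by ``2**delta`` in specimens edited at a miRNA target
site of the gene.  Alu-like intervals are divergent copies of one consensus
so that repeat copies genuinely cross-align, exercising the paralog filter;
the decoy genome is built from mutated host segments.

Everything is generated from a single integer seed; identical seeds yield
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import COMPLEMENT, substitution_class
from .io_model import (
    AnnotationSet,
    BASES,
    ExpressionTable,
    GeneModel,
    IntervalTrack,
)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the emulated study: a ~20 kb two-contig genome, six
    specimens, DNA ~4X / RNA ~30X Poisson depths, 300 planted edits (85% in
    Alu-like repeats, 97% canonical class inside Alu), 100 SNPs, 0.2% base
    error, Beta(2,1) per-site editing levels and a log2-scale miRNA-target
    expression effect of 1.
    """

    # genome geometry
    n_contigs: int = 2
    contig_length: int = 10_000
    # repeats
    n_alu_per_contig: int = 10
    alu_length: int = 300
    alu_divergence: float = 0.08
    n_other_repeats_per_contig: int = 3
    other_repeat_length: int = 400
    other_repeat_divergence: float = 0.15
    # genes
    n_genes_per_contig: int = 3
    n_ncrna_per_contig: int = 1
    # edits
    n_edits: int = 300
    alu_bias: float = 0.85
    canonical_bias_alu: float = 0.97
    canonical_bias_other: float = 0.55
    cluster_fraction: float = 0.4
    beta_a: float = 2.0
    beta_b: float = 1.0
    edit_penetrance: float = 1.0
    n_mirt_edits: int = 4
    mirt_edit_penetrance: float = 0.5
    # SNPs
    n_snps: int = 100
    # sequencing
    dna_depth: float = 4.0
    rna_depth: float = 30.0
    error_rate: float = 0.002
    read_length: int = 75
    # expression
    expr_mean_log: float = math.log(300.0)
    expr_mean_sd: float = 1.0
    nb_size: float = 10.0
    specimen_scale_sd: float = 0.3
    mirt_effect_delta: float = 1.0
    # decoy
    n_decoy_segments: int = 4
    decoy_segment_length: int = 500
    decoy_divergence: float = 0.20
    # cohort
    n_specimens: int = 6

    def specimen_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_specimens)]


@dataclass
class SyntheticTruth:
    """Planted ground truth.

    ``edits``: one row per edit site (chrom, pos, ref, alt, sub_class,
    stratum, beta, in_cluster, in_mirna_target, target_gene).
    ``edit_specimens``: one row per (edit site, edited specimen).
    ``snps``: one row per SNP (chrom, pos, ref, alt, af).
    ``snp_genotypes``: alt-allele copy number per (snp, specimen).
    ``mirt_genes``: genes with a planted miRNA-target edit and the specimens
    carrying it.
    """

    edits: pd.DataFrame
    edit_specimens: pd.DataFrame
    snps: pd.DataFrame
    snp_genotypes: pd.DataFrame
    mirt_genes: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticCohort:
    config: SimConfig
    genome: dict[str, str]
    decoy: dict[str, str]
    annotation: AnnotationSet
    truth: SyntheticTruth
    counts: pd.DataFrame
    expression: ExpressionTable
    dbsnp_mask: set[tuple[str, int]]


# ---------------------------------------------------------------------------
# Reference and annotations
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    # shift by 1..3 guarantees a different base
    out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def make_reference(
    config: SimConfig, seed: int
) -> tuple[dict[str, str], dict[str, str], AnnotationSet]:
    """Build the toy genome, decoy genome and annotation set.

    Deterministic for a fixed (config, seed).  Genes are laid out on a fixed
    grid (alternating strands, three coding exons, UTRs, two 20 bp miRNA
    target sites in each 3'UTR); Alu-like and other repeat copies are
    written into intronic and intergenic space as divergent copies of shared
    consensus sequences.
    """
    rng = np.random.default_rng(seed)
    L = config.contig_length
    gene_span = 2200
    slot = 2800
    need = 500 + (config.n_genes_per_contig - 1) * slot + gene_span
    need += 500 * config.n_ncrna_per_contig + 1000
    if need > L:
        raise ValueError("gene geometry does not fit the contig length")

    alu_consensus = _random_seq(rng, config.alu_length)
    other_consensus = _random_seq(rng, config.other_repeat_length)

    genome: dict[str, str] = {}
    ann = AnnotationSet()
    occupied: dict[str, list[tuple[int, int]]] = {}

    for ci in range(config.n_contigs):
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, L)
        occ: list[tuple[int, int]] = []

        # genes on a fixed grid
        for gi in range(config.n_genes_per_contig):
            s = 500 + gi * slot + 1  # 1-based gene start
            strand = "+" if (gi + ci) % 2 == 0 else "-"
            gene_id = f"G{ci + 1}_{gi + 1}"
            exons = [
                (s, s + 249),
                (s + 850, s + 1099),
                (s + 1700, s + 2199),
            ]
            model = GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=s + 100,
                cds_end=s + 1848,
                biotype="coding",
            )
            ann.gene_models.append(model)
            occ.extend(exons)
            # two 20 bp miRNA target sites inside the 3'UTR
            if strand == "+":
                utr3 = (s + 1849, s + 2199)
                t1 = (utr3[0] + 30, utr3[0] + 49)
                t2 = (utr3[0] + 120, utr3[0] + 139)
            else:
                utr3 = (s, s + 99)
                t1 = (utr3[0] + 10, utr3[0] + 29)
                t2 = (utr3[0] + 55, utr3[0] + 74)
            for ti, (ts, te) in enumerate((t1, t2)):
                ann.mirna_targets.add(
                    chrom, ts, te, (f"mir-{ci+1}{gi+1}{ti+1}", gene_id)
                )
            # conserved elements: CDS blocks
            ann.conserved.add(chrom, s + 100, s + 249)
            ann.conserved.add(chrom, s + 850, s + 1099)
            ann.conserved.add(chrom, s + 1700, s + 1848)

        for ni in range(config.n_ncrna_per_contig):
            s = L - 1400 + ni * 500 + 1
            gene_id = f"NC{ci + 1}_{ni + 1}"
            exons = [(s, s + 399)]
            ann.gene_models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t1",
                    chrom=chrom,
                    strand="+",
                    exons=exons,
                    biotype="ncRNA",
                )
            )
            occ.extend(exons)

        # repeats dropped into free space (introns and intergenic gaps)
        def place_repeat(length: int) -> int | None:
            for _ in range(200):
                start = int(rng.integers(1, L - length))
                cand = (start, start + length - 1)
                if all(e < cand[0] or s > cand[1] for s, e in occ):
                    occ.append(cand)
                    return start
            return None

        for _ in range(config.n_alu_per_contig):
            start = place_repeat(config.alu_length)
            if start is None:
                continue
            copy = _mutate(rng, alu_consensus, config.alu_divergence)
            seq[start - 1 : start - 1 + config.alu_length] = copy
            ann.alu.add(chrom, start, start + config.alu_length - 1)

        for _ in range(config.n_other_repeats_per_contig):
            start = place_repeat(config.other_repeat_length)
            if start is None:
                continue
            copy = _mutate(rng, other_consensus, config.other_repeat_divergence)
            seq[start - 1 : start - 1 + config.other_repeat_length] = copy
            ann.non_alu_repeat.add(
                chrom, start, start + config.other_repeat_length - 1
            )

        genome[chrom] = _to_str(seq)
        occupied[chrom] = occ

    # darned-like track: random positions inside Alu intervals
    alu_positions = _track_positions(ann.alu)
    if alu_positions:
        n_darned = min(50, len(alu_positions))
        idx = rng.choice(len(alu_positions), size=n_darned, replace=False)
        for i in sorted(idx):
            chrom, pos = alu_positions[i]
            ann.darned_like.add(chrom, pos, pos)

    decoy = _make_decoy(rng, genome, config)
    return genome, decoy, ann


def _make_decoy(rng: np.random.Generator, genome: dict[str, str],
                config: SimConfig) -> dict[str, str]:
    """Decoy genome: mutated host segments plus random sequence."""
    pieces: list[str] = []
    chroms = sorted(genome)
    for _ in range(config.n_decoy_segments):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        contig = genome[chrom]
        start = int(rng.integers(0, len(contig) - config.decoy_segment_length))
        seg = np.array(
            [_BASE_IDX[b] for b in contig[start : start + config.decoy_segment_length]],
            dtype=np.int8,
        )
        pieces.append(_to_str(_mutate(rng, seg, config.decoy_divergence)))
    pieces.append(_to_str(_random_seq(rng, 1000)))
    return {"decoy1": "".join(pieces)}


def _track_positions(track: IntervalTrack) -> list[tuple[str, int]]:
    out = []
    for chrom, start, end, _ in track.intervals():
        out.extend((chrom, p) for p in range(start, end + 1))
    return out


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------


def plant_truth(
    genome: dict[str, str],
    annotation: AnnotationSet,
    config: SimConfig,
    seed: int,
) -> SyntheticTruth:
    """Plant edit sites, SNPs and miRNA-target edits.

    Edits follow the configured stratum bias (fraction inside Alu), class
    bias (canonical A>G|T>C fraction, higher inside Alu) and cluster
    fraction (edits laid down in runs that satisfy the 50 bp / 3-in-100 bp
    rule).  SNP genotypes are Hardy-Weinberg draws per specimen.  Edit and
    SNP positions are disjoint.
    """
    rng = np.random.default_rng(seed)
    specimens = config.specimen_names()
    used: set[tuple[str, int]] = set()

    alu_pos = _track_positions(annotation.alu)
    all_pos = [
        (chrom, p)
        for chrom in sorted(genome)
        for p in range(1, len(genome[chrom]) + 1)
    ]
    alu_set = set(alu_pos)
    non_alu_pos = [x for x in all_pos if x not in alu_set]

    def ref_base(chrom: str, pos: int) -> str:
        return genome[chrom][pos - 1]

    def draw_alt(ref: str, canonical: bool) -> str | None:
        if canonical:
            if ref == "A":
                return "G"
            if ref == "T":
                return "C"
            return None
        choices = [b for b in BASES if b != ref]
        rng.shuffle(choices)
        for alt in choices:
            if substitution_class(ref, alt) != "A>G|T>C":
                return alt
        return None

    def sample_site(pool: list[tuple[str, int]], canonical: bool,
                    max_tries: int = 500) -> tuple[str, int, str, str] | None:
        for _ in range(max_tries):
            chrom, pos = pool[int(rng.integers(0, len(pool)))]
            if (chrom, pos) in used:
                continue
            ref = ref_base(chrom, pos)
            if ref not in BASES:
                continue
            alt = draw_alt(ref, canonical)
            if alt is None:
                continue
            return chrom, pos, ref, alt
        return None

    edits: list[dict] = []

    def add_edit(chrom: str, pos: int, ref: str, alt: str, *,
                 in_cluster: bool, penetrance: float) -> None:
        used.add((chrom, pos))
        beta = float(rng.beta(config.beta_a, config.beta_b))
        beta = min(max(beta, 0.02), 1.0)
        mir_hits = annotation.mirna_targets.overlapping(chrom, pos)
        target_gene = mir_hits[0][2][1] if mir_hits else None
        edits.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "sub_class": substitution_class(ref, alt),
                "stratum": "Alu" if (chrom, pos) in alu_set else (
                    "non-Alu repeat"
                    if annotation.non_alu_repeat.contains(chrom, pos)
                    else "non-repeat"
                ),
                "beta": beta,
                "in_cluster": in_cluster,
                "in_mirna_target": bool(mir_hits),
                "target_gene": target_gene,
                "penetrance": penetrance,
            }
        )

    # explicit miRNA-target edits (canonical class, partial penetrance)
    target_ivs = annotation.mirna_targets.intervals()
    rng.shuffle(target_ivs)
    planted_mirt = 0
    for chrom, ts, te, _ in target_ivs:
        if planted_mirt >= config.n_mirt_edits:
            break
        cand = [
            p for p in range(ts, te + 1)
            if (chrom, p) not in used and ref_base(chrom, p) in ("A", "T")
        ]
        if not cand:
            continue
        pos = int(cand[int(rng.integers(0, len(cand)))])
        ref = ref_base(chrom, pos)
        add_edit(chrom, pos, ref, "G" if ref == "A" else "C",
                 in_cluster=False, penetrance=config.mirt_edit_penetrance)
        planted_mirt += 1

    n_regular = config.n_edits - planted_mirt
    n_alu = int(round(n_regular * config.alu_bias))
    n_other = n_regular - n_alu

    # clustered edits: runs of 3-5 sites with 10-40 bp gaps inside one Alu
    n_clustered_target = int(round(n_alu * config.cluster_fraction))
    n_clustered = 0
    alu_ivs = [iv for iv in annotation.alu.intervals()]
    while n_clustered < n_clustered_target and alu_ivs:
        chrom, s, e, _ = alu_ivs[int(rng.integers(0, len(alu_ivs)))]
        size = int(rng.integers(3, 6))
        pos = int(rng.integers(s, max(s + 1, e - 160)))
        members = []
        for _ in range(size):
            if pos > e or (chrom, pos) in used:
                break
            ref = ref_base(chrom, pos)
            canonical = rng.random() < config.canonical_bias_alu
            # walk to the next usable base within a short gap
            hop = 0
            while (ref not in ("A", "T") and canonical) or (chrom, pos) in used:
                pos += 1
                hop += 1
                if pos > e or hop > 30:
                    break
                ref = ref_base(chrom, pos)
            if pos > e or (chrom, pos) in used:
                break
            alt = draw_alt(ref, canonical)
            if alt is None:
                pos += int(rng.integers(5, 20))
                continue
            members.append((chrom, pos, ref, alt))
            pos += int(rng.integers(10, 41))
        if len(members) >= 3:
            for chrom_, pos_, ref_, alt_ in members:
                add_edit(chrom_, pos_, ref_, alt_, in_cluster=True,
                         penetrance=config.edit_penetrance)
                n_clustered += 1

    # remaining Alu edits, singly placed
    while n_clustered + sum(
        1 for e_ in edits if e_["stratum"] == "Alu" and not e_["in_cluster"]
    ) < n_alu:
        canonical = rng.random() < config.canonical_bias_alu
        site = sample_site(alu_pos, canonical)
        if site is None:
            break
        add_edit(*site, in_cluster=False, penetrance=config.edit_penetrance)

    # non-Alu edits
    placed_other = 0
    while placed_other < n_other:
        canonical = rng.random() < config.canonical_bias_other
        site = sample_site(non_alu_pos, canonical)
        if site is None:
            break
        add_edit(*site, in_cluster=False, penetrance=config.edit_penetrance)
        placed_other += 1

    edit_columns = [
        "chrom", "pos", "ref", "alt", "sub_class", "stratum", "beta",
        "in_cluster", "in_mirna_target", "target_gene", "penetrance",
    ]
    edits_df = (
        pd.DataFrame(edits, columns=edit_columns)
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )

    # per-specimen edited status
    rows = []
    for _, e_ in edits_df.iterrows():
        edited = [
            sp for sp in specimens if rng.random() < e_["penetrance"]
        ]
        if not edited:
            edited = [specimens[int(rng.integers(0, len(specimens)))]]
        for sp in edited:
            rows.append(
                {
                    "chrom": e_["chrom"],
                    "pos": int(e_["pos"]),
                    "specimen": sp,
                    "beta": float(e_["beta"]),
                }
            )
    edit_specimens = pd.DataFrame(
        rows, columns=["chrom", "pos", "specimen", "beta"]
    )

    # SNPs (Hardy-Weinberg genotypes per specimen)
    snp_rows, geno_rows = [], []
    tries = 0
    while len(snp_rows) < config.n_snps and tries < 50 * config.n_snps:
        tries += 1
        chrom, pos = all_pos[int(rng.integers(0, len(all_pos)))]
        if (chrom, pos) in used:
            continue
        ref = ref_base(chrom, pos)
        if ref not in BASES:
            continue
        alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
        af = float(rng.uniform(0.05, 0.5))
        used.add((chrom, pos))
        snp_rows.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "af": af}
        )
        for sp in specimens:
            copies = int(rng.binomial(2, af))
            geno_rows.append(
                {"chrom": chrom, "pos": pos, "specimen": sp, "alt_copies": copies}
            )
    snps_df = (
        pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt", "af"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    snp_genotypes = pd.DataFrame(
        geno_rows, columns=["chrom", "pos", "specimen", "alt_copies"]
    )

    # mirT gene truth for the expression simulation
    mirt = edits_df[edits_df["in_mirna_target"] & edits_df["target_gene"].notna()]
    mg_rows = []
    for _, e_ in mirt.iterrows():
        edited = edit_specimens[
            (edit_specimens["chrom"] == e_["chrom"])
            & (edit_specimens["pos"] == e_["pos"])
        ]["specimen"].tolist()
        for sp in edited:
            mg_rows.append({"gene_id": e_["target_gene"], "specimen": sp})
    mirt_genes = pd.DataFrame(mg_rows, columns=["gene_id", "specimen"]).drop_duplicates()

    return SyntheticTruth(
        edits=edits_df,
        edit_specimens=edit_specimens,
        snps=snps_df,
        snp_genotypes=snp_genotypes,
        mirt_genes=mirt_genes,
    )


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def _multinomial_rows(rng: np.random.Generator, n: np.ndarray,
                      p: np.ndarray) -> np.ndarray:
    """Row-wise multinomial draws via sequential binomial splitting."""
    n = n.astype(np.int64)
    out = np.zeros_like(p, dtype=np.int64)
    remaining = n.copy()
    cum = np.ones(len(n))
    for j in range(p.shape[1] - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            pj = np.where(cum > 0, p[:, j] / cum, 0.0)
        pj = np.clip(pj, 0.0, 1.0)
        out[:, j] = rng.binomial(remaining, pj)
        remaining -= out[:, j]
        cum -= p[:, j]
    out[:, -1] = remaining
    return out


def simulate_counts(
    genome: dict[str, str],
    truth: SyntheticTruth,
    config: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Simulate paired DNA/RNA allele counts for every genomic position.

    DNA read depths are Poisson(``dna_depth``); reads draw from the
    specimen's genotype with per-base error ``error_rate``.  RNA depths are
    Poisson(``rna_depth``); at edit sites of edited specimens the edited
    base replaces the reference with probability beta, elsewhere RNA mirrors
    the DNA genotype.  Returns the long-format allele-count table.
    """
    rng = np.random.default_rng(seed)
    specimens = config.specimen_names()
    e = config.error_rate

    chroms = sorted(genome)
    pos_arrays = {c: np.arange(1, len(genome[c]) + 1) for c in chroms}
    ref_idx = {
        c: np.array([_BASE_IDX.get(b, 0) for b in genome[c]], dtype=np.int64)
        for c in chroms
    }

    # site-indexed lookups from truth
    snp_geno = {
        (r.chrom, r.pos, r.specimen): (r.alt_copies)
        for r in truth.snp_genotypes.itertuples(index=False)
    }
    snp_alt = {
        (r.chrom, r.pos): _BASE_IDX[r.alt]
        for r in truth.snps.itertuples(index=False)
    }
    edit_beta = {
        (r.chrom, r.pos, r.specimen): r.beta
        for r in truth.edit_specimens.itertuples(index=False)
    }
    edit_alt = {
        (r.chrom, r.pos): _BASE_IDX[r.alt]
        for r in truth.edits.itertuples(index=False)
    }

    frames = []
    for sp in specimens:
        for chrom in chroms:
            n = len(genome[chrom])
            ridx = ref_idx[chrom]
            rows = np.arange(n)

            # true DNA base distribution (n x 4)
            p_dna = np.zeros((n, 4))
            p_dna[rows, ridx] = 1.0
            for (c, pos), aidx in snp_alt.items():
                if c != chrom:
                    continue
                copies = snp_geno.get((c, pos, sp), 0)
                i = pos - 1
                if copies == 1:
                    p_dna[i, :] = 0.0
                    p_dna[i, ridx[i]] = 0.5
                    p_dna[i, aidx] = 0.5
                elif copies == 2:
                    p_dna[i, :] = 0.0
                    p_dna[i, aidx] = 1.0

            # RNA mirrors DNA, plus editing
            p_rna = p_dna.copy()
            for (c, pos), aidx in edit_alt.items():
                if c != chrom:
                    continue
                beta = edit_beta.get((c, pos, sp))
                if beta is None:
                    continue
                i = pos - 1
                p_rna[i, :] = 0.0
                p_rna[i, ridx[i]] = 1.0 - beta
                p_rna[i, aidx] = p_rna[i, aidx] + beta

            for assay, p_true, depth in (
                ("DNA", p_dna, config.dna_depth),
                ("RNA", p_rna, config.rna_depth),
            ):
                p_obs = p_true * (1.0 - e) + (1.0 - p_true) * (e / 3.0)
                p_obs /= p_obs.sum(axis=1, keepdims=True)
                depths = rng.poisson(depth, size=n)
                counts = _multinomial_rows(rng, depths, p_obs)
                frames.append(
                    pd.DataFrame(
                        {
                            "specimen": sp,
                            "chrom": chrom,
                            "pos": pos_arrays[chrom],
                            "assay": assay,
                            "nA": counts[:, 0],
                            "nC": counts[:, 1],
                            "nG": counts[:, 2],
                            "nT": counts[:, 3],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    truth: SyntheticTruth,
    gene_models: list[GeneModel],
    config: SimConfig,
    seed: int,
    mirt_status: pd.DataFrame | None = None,
) -> ExpressionTable:
    """Negative-binomial expression with a miRNA-target-editing effect.

    ``mu[g, i] = mean_g * s_i * 2**(delta * edited(g, i))`` with log-normal
    specimen scaling factors ``s_i`` (these exercise normalization) and
    gene-level NB dispersion ``nb_size``.  ``edited(g, i)`` comes from the
    planted mirT-gene truth (or an explicit ``mirt_status`` frame with
    columns gene_id, specimen).
    """
    rng = np.random.default_rng(seed)
    specimens = config.specimen_names()
    genes = [m.gene_id for m in gene_models]
    status = mirt_status if mirt_status is not None else truth.mirt_genes
    edited_pairs = (
        set(zip(status["gene_id"], status["specimen"]))
        if status is not None and len(status)
        else set()
    )

    mean_g = np.exp(rng.normal(config.expr_mean_log, config.expr_mean_sd,
                               size=len(genes)))
    s_i = np.exp(rng.normal(0.0, config.specimen_scale_sd, size=len(specimens)))

    mu = np.outer(mean_g, s_i)
    for gi, g in enumerate(genes):
        for si, sp in enumerate(specimens):
            if (g, sp) in edited_pairs:
                mu[gi, si] *= 2.0 ** config.mirt_effect_delta

    size = config.nb_size
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    frame = pd.DataFrame(counts, index=genes, columns=specimens)
    lengths = pd.Series(
        {m.gene_id: sum(e - s + 1 for s, e in m.exons) for m in gene_models}
    )
    return ExpressionTable(counts=frame, gene_lengths=lengths)


# ---------------------------------------------------------------------------
# One-call cohort builder
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig | None = None, seed: int = 0
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort from one seed.

    Sub-seeds for the reference, truth, counts and expression stages are
    drawn from a seed sequence so the stages are independently reproducible.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_ref, s_truth, s_counts, s_expr = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    genome, decoy, annotation = make_reference(config, s_ref)
    truth = plant_truth(genome, annotation, config, s_truth)
    counts = simulate_counts(genome, truth, config, s_counts)
    expression = simulate_expression(truth, annotation.gene_models, config, s_expr)
    dbsnp_mask = {(r.chrom, int(r.pos)) for r in truth.snps.itertuples(index=False)}
    return SyntheticCohort(
        config=config,
        genome=genome,
        decoy=decoy,
        annotation=annotation,
        truth=truth,
        counts=counts,
        expression=expression,
        dbsnp_mask=dbsnp_mask,
    )


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)


def simulate_mirt_cohort(
    n_genes_per_category: int = 20,
    n_specimens: int = 8,
    delta: float = 1.0,
    seed: int = 0,
    nb_size: float = 10.0,
) -> tuple[pd.DataFrame, list[GeneModel], ExpressionTable]:
    """Focused cohort for the miRNA-target expression association.

    Builds ``n_genes_per_category`` genes carrying miRNA-target edits (their
    expression multiplied by ``2**delta`` in edited specimens) and the same
    number of control genes carrying coding-region edits (no effect), each
    edited in a random subset of 2..n-2 specimens.  Returns an annotated-call
    frame (only the columns the grouping step consumes), the gene models and
    the expression table, so the association is exercised through the same
    code path as a full run.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        n_specimens=n_specimens, mirt_effect_delta=delta, nb_size=nb_size
    )
    specimens = config.specimen_names()

    models: list[GeneModel] = []
    call_rows: list[dict] = []
    status_rows: list[dict] = []
    pos = 1000
    for cat_i, category in enumerate(("mirT", "crRDD")):
        for gi in range(n_genes_per_category):
            gene_id = f"{category}{gi + 1}"
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t1",
                    chrom="chrS",
                    strand="+",
                    exons=[(pos, pos + 1999)],
                    cds_start=pos + 100,
                    cds_end=pos + 1599,
                    biotype="coding",
                )
            )
            n_with = int(rng.integers(2, n_specimens - 1))
            with_specs = list(
                rng.choice(specimens, size=n_with, replace=False)
            )
            for sp in with_specs:
                if category == "mirT":
                    call_rows.append(
                        {
                            "specimen": sp,
                            "chrom": "chrS",
                            "pos": pos + 1800,
                            "ref": "A",
                            "alt": "G",
                            "feature": "UTR3",
                            "gene_id": gene_id,
                            "in_mirna_target": True,
                            "in_mirna_target_gene": gene_id,
                        }
                    )
                    status_rows.append({"gene_id": gene_id, "specimen": sp})
                else:
                    call_rows.append(
                        {
                            "specimen": sp,
                            "chrom": "chrS",
                            "pos": pos + 500,
                            "ref": "A",
                            "alt": "G",
                            "feature": "CDS",
                            "gene_id": gene_id,
                            "in_mirna_target": False,
                            "in_mirna_target_gene": "",
                        }
                    )
            pos += 3000

    truth = SyntheticTruth(
        edits=pd.DataFrame(),
        edit_specimens=pd.DataFrame(),
        snps=pd.DataFrame(),
        snp_genotypes=pd.DataFrame(),
        mirt_genes=pd.DataFrame(status_rows, columns=["gene_id", "specimen"]),
    )
    expr_seed = int(rng.integers(0, 2**31))
    expression = simulate_expression(
        truth, models, config, expr_seed, mirt_status=truth.mirt_genes
    )
    calls = pd.DataFrame(call_rows)
    return calls, models, expression
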