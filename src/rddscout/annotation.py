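"""Annotation of RDD calls.

Because RNA sequencing here is non-strand-specific, the 12 ordered base
substitutions collapse into 6 strand-ambiguous classes (A>G|T>C being the
canonical deamination signature).  Sites are stratified into Alu repeats,
non-Alu repeats and non-repeat regions; assigned a genic feature with
precedence CDS > UTR > ncRNA > intron > intergenic; tested for clustering
(consecutive gaps <= 50 bp, or >= 3 sites inside a 100 bp window); and
marked recurrent when the same position + class is called in >= 2 specimens.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_model import AnnotationSet, GeneModel, IntervalTrack

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical order of the six strand-ambiguous substitution classes.
SUBSTITUTION_CLASSES = (
    "A>G|T>C",
    "C>T|G>A",
    "A>C|T>G",
    "A>T|T>A",
    "C>A|G>T",
    "C>G|G>C",
)

CANONICAL_CLASS = "A>G|T>C"

STRATA = ("Alu", "non-Alu repeat", "non-repeat")

GENIC_FEATURES = ("CDS", "UTR5", "UTR3", "ncRNA", "intron", "intergenic")
_FEATURE_RANK = {f: i for i, f in enumerate(GENIC_FEATURES)}


def substitution_class(ref: str, alt: str) -> str:
    """Collapse an ordered substitution into its strand-ambiguous class."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"bases must be one of {tuple(COMPLEMENT)}")
    if ref in ("A", "C"):
        fwd = (ref, alt)
    else:
        fwd = (COMPLEMENT[ref], COMPLEMENT[alt])
    label = f"{fwd[0]}>{fwd[1]}|{COMPLEMENT[fwd[0]]}>{COMPLEMENT[fwd[1]]}"
    assert label in SUBSTITUTION_CLASSES
    return label


def region_stratum(chrom: str, pos: int, annotation: AnnotationSet) -> str:
    """Alu / non-Alu repeat / non-repeat, with Alu taking precedence."""
    if annotation.alu.contains(chrom, pos):
        return "Alu"
    if annotation.non_alu_repeat.contains(chrom, pos):
        return "non-Alu repeat"
    return "non-repeat"


def genic_feature(
    chrom: str, pos: int, gene_models: Sequence[GeneModel]
) -> tuple[str, str | None]:
    """Assign the highest-precedence genic feature over all transcripts.

    Precedence: CDS > UTR5/UTR3 > ncRNA exon > intron > intergenic.  Ties
    between transcripts at equal precedence go to the first transcript in
    file order.  Returns ``(feature, gene_id)`` with gene_id None for
    intergenic sites.
    """
    best: tuple[int, str, str | None] = (_FEATURE_RANK["intergenic"], "intergenic", None)
    for m in gene_models:
        if m.chrom != chrom or not (m.start <= pos <= m.end):
            continue
        feat = _feature_in_transcript(pos, m)
        rank = _FEATURE_RANK[feat]
        if rank < best[0]:
            best = (rank, feat, m.gene_id)
    return best[1], best[2]


def _feature_in_transcript(pos: int, m: GeneModel) -> str:
    exonic = any(s <= pos <= e for s, e in m.exons)
    if not exonic:
        return "intron"
    if m.biotype != "coding":
        return "ncRNA"
    if m.cds_start <= pos <= m.cds_end:
        return "CDS"
    upstream = pos < m.cds_start
    if m.strand == "+":
        return "UTR5" if upstream else "UTR3"
    return "UTR3" if upstream else "UTR5"


def coding_consequence(
    chrom: str, pos: int, ref: str, alt: str, model: GeneModel,
    genome: Mapping[str, str],
) -> dict:
    """Codon-level consequence of an edit inside a CDS.

    The codon is rebuilt on the coding strand (reference-strand alleles are
    complemented for minus-strand genes), the edited base substituted and
    both codons translated.  Returns a dict with ``consequence`` in
    {synonymous, missense, stop_gain, stop_loss, unknown}, plus ref/alt
    amino acids.  A CDS whose spliced length is not divisible by 3 yields
    ``unknown``.
    """
    if model.biotype != "coding":
        raise ValueError("consequence requires a coding transcript")
    cds_blocks = [
        (max(s, model.cds_start), min(e, model.cds_end))
        for s, e in model.exons
        if e >= model.cds_start and s <= model.cds_end
    ]
    cds_seq = "".join(genome[chrom][s - 1 : e] for s, e in cds_blocks)
    if len(cds_seq) % 3 != 0:
        return {"consequence": "unknown", "aa_ref": None, "aa_alt": None}

    offset = 0
    cds_index = None
    for s, e in cds_blocks:
        if s <= pos <= e:
            cds_index = offset + (pos - s)
            break
        offset += e - s + 1
    if cds_index is None:
        raise ValueError("position not inside the CDS of this transcript")

    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        cds_index = len(cds_seq) - 1 - cds_index
        ref_c, alt_c = COMPLEMENT[ref], COMPLEMENT[alt]
    else:
        ref_c, alt_c = ref, alt

    if cds_seq[cds_index] != ref_c:
        return {"consequence": "unknown", "aa_ref": None, "aa_alt": None}

    codon_i = cds_index // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    within = cds_index % 3
    alt_codon = codon[:within] + alt_c + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        consequence = "synonymous"
    elif aa_alt == "*":
        consequence = "stop_gain"
    elif aa_ref == "*":
        consequence = "stop_loss"
    else:
        consequence = "missense"
    return {"consequence": consequence, "aa_ref": aa_ref, "aa_alt": aa_alt}


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------


def find_clusters(
    positions: Sequence[int], d1: int = 50, w: int = 100, m: int = 3
) -> list[list[int]]:
    """Maximal clusters of positions on one chromosome (one specimen).

    Two rules mark sites: consecutive sites at distance <= ``d1`` link a
    pair; any window of ``w`` consecutive bases containing >= ``m`` sites
    links all sites in the window.  Clusters are the connected components of
    the union of both relations; unmarked sites are not clustered.
    """
    pos = sorted(set(int(p) for p in positions))
    n = len(pos)
    parent = list(range(n))
    linked = [False] * n

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        linked[i] = linked[j] = True
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n - 1):
        if pos[i + 1] - pos[i] <= d1:
            union(i, i + 1)

    # windows of length w: positions within [p_i, p_i + w - 1]
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and pos[j + 1] - pos[i] <= w - 1:
            j += 1
        if j - i + 1 >= m:
            for k in range(i, j):
                union(k, k + 1)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        if linked[i]:
            comps.setdefault(find(i), []).append(pos[i])
    return [sorted(v) for v in sorted(comps.values())]


def flag_clustered(calls: pd.DataFrame, d1: int = 50, w: int = 100, m: int = 3
                   ) -> pd.Series:
    """Per-call boolean: does the call belong to a cluster?

    Clustering is evaluated per (specimen, chromosome) over that specimen's
    call positions.
    """
    flags = pd.Series(False, index=calls.index)
    for (_, _), grp in calls.groupby(["specimen", "chrom"]):
        clustered: set[int] = set()
        for cluster in find_clusters(grp["pos"].tolist(), d1, w, m):
            clustered.update(cluster)
        flags.loc[grp.index] = grp["pos"].astype(int).isin(clustered).to_numpy()
    return flags


# ---------------------------------------------------------------------------
# Recurrence and track overlap
# ---------------------------------------------------------------------------


def recurrence(calls: pd.DataFrame) -> pd.DataFrame:
    """Add per-call recurrence count and ``recurrent`` flag.

    Keyed on (chrom, pos, substitution class), so the same edit reported on
    either strand in different specimens counts as recurrent.  The count is
    the number of distinct specimens sharing the key.
    """
    out = calls.copy()
    if "sub_class" not in out.columns:
        out["sub_class"] = [
            substitution_class(r, a) for r, a in zip(out["ref"], out["alt"])
        ]
    key = ["chrom", "pos", "sub_class"]
    counts = out.groupby(key)["specimen"].nunique().rename("recurrence")
    out = out.merge(counts, on=key, how="left")
    out["recurrence"] = out["recurrence"].astype(int)
    out["recurrent"] = out["recurrence"] >= 2
    out.index = calls.index
    return out


def overlap_annotate(
    calls: pd.DataFrame, track: IntervalTrack, column: str,
    carry_ids: bool = False,
) -> pd.DataFrame:
    """Flag calls falling inside a track (closed-interval membership).

    With ``carry_ids=True`` (miRNA target track), two extra columns carry
    semicolon-joined miRNA and target-gene identifiers from the payloads of
    all overlapped intervals.
    """
    out = calls.copy()
    flags = []
    mirna_ids = []
    gene_ids = []
    for chrom, pos in zip(out["chrom"], out["pos"].astype(int)):
        hits = track.overlapping(chrom, pos)
        flags.append(bool(hits))
        if carry_ids:
            mids, gids = [], []
            for _, _, data in hits:
                if isinstance(data, tuple) and len(data) == 2:
                    mids.append(data[0])
                    gids.append(data[1])
                elif data is not None:
                    gids.append(str(data))
            mirna_ids.append(";".join(dict.fromkeys(mids)))
            gene_ids.append(";".join(dict.fromkeys(gids)))
    out[column] = pd.Series(flags, index=out.index, dtype=bool)
    if carry_ids:
        out[column + "_mirna"] = pd.Series(mirna_ids, index=out.index)
        out[column + "_gene"] = pd.Series(gene_ids, index=out.index)
    return out


def annotate_calls(
    calls: pd.DataFrame,
    annotation: AnnotationSet,
    d1: int = 50,
    w: int = 100,
    m: int = 3,
) -> pd.DataFrame:
    """Full annotation pass: class, stratum, genic feature, clusters,
    recurrence and interval-track overlaps."""
    out = calls.copy()
    out["sub_class"] = [
        substitution_class(r, a) for r, a in zip(out["ref"], out["alt"])
    ]
    out["stratum"] = [
        region_stratum(c, int(p), annotation)
        for c, p in zip(out["chrom"], out["pos"])
    ]
    feats = [
        genic_feature(c, int(p), annotation.gene_models)
        for c, p in zip(out["chrom"], out["pos"])
    ]
    out["feature"] = [f for f, _ in feats]
    out["gene_id"] = [g for _, g in feats]
    out["clustered"] = flag_clustered(out, d1, w, m)
    out = recurrence(out)
    out = overlap_annotate(out, annotation.conserved, "in_conserved")
    out = overlap_annotate(out, annotation.darned_like, "in_darned")
    out = overlap_annotate(
        out, annotation.mirna_targets, "in_mirna_target", carry_ids=True
    )
    return out
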