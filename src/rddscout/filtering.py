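"""Five-stage false-positive filter cascade for candidate RDDs.

The stages, in the order they are reported (results are order-invariant
because every stage sets an independent flag):

1. known variants -- positions present in a dbSNP-like or COSMIC-like mask;
2. DNA support -- the edited base seen in *any* DNA read of *any* specimen;
3. splice proximity -- intronic positions within ``k`` (default 8) bases of
   an exon boundary, where splice-spanning reads mismap;
4. murine contamination -- the 61 bp flank with the edited base substituted
   aligns better to a decoy (mouse-like) genome than the unedited flank, the
   hit covers the site and exceeds 90% identity;
5. paralogs -- the substituted flank (61 and 101 bp, with *all* candidate
   RDDs in the window substituted) aligns to some other host-genome locus at
   least as well as to its own locus.

A call is retained iff every flag is False.  The alignment-based stages
operate per unique (chrom, pos, alt) and accept an optional cache dict so
that repeated pipeline runs over the same genome (e.g. down-sampling
evaluations) do not redo identical alignments.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import LocalAligner, default_aligner
from .io_model import BASES, GeneModel

logger = logging.getLogger(__name__)

FLAG_COLUMNS = (
    "flag_known_variant",
    "flag_dna_support_any_specimen",
    "flag_splice_proximal",
    "flag_contamination_hit",
    "flag_paralog_hit",
)


# ---------------------------------------------------------------------------
# Stage 1: known variants
# ---------------------------------------------------------------------------


def filter_known_variants(
    calls: pd.DataFrame,
    dbsnp_mask: set[tuple[str, int]] | None = None,
    cosmic_mask: set[tuple[str, int]] | None = None,
) -> pd.Series:
    """Flag calls whose (chrom, pos) is in either mask (alt-agnostic)."""
    mask = (dbsnp_mask or set()) | (cosmic_mask or set())
    keys = list(zip(calls["chrom"], calls["pos"].astype(int)))
    return pd.Series([k in mask for k in keys], index=calls.index, dtype=bool)


# ---------------------------------------------------------------------------
# Stage 2: DNA support in any specimen
# ---------------------------------------------------------------------------


def filter_dna_support(calls: pd.DataFrame, counts: pd.DataFrame) -> pd.Series:
    """Flag calls with >= 1 DNA read of the call's alt base in any specimen."""
    dna = counts[counts["assay"] == "DNA"]
    pooled = dna.groupby(["chrom", "pos"])[[f"n{b}" for b in BASES]].sum()
    flags = np.zeros(len(calls), dtype=bool)
    for i, (chrom, pos, alt) in enumerate(
        zip(calls["chrom"], calls["pos"].astype(int), calls["alt"])
    ):
        try:
            row = pooled.loc[(chrom, pos)]
        except KeyError:
            continue
        flags[i] = int(row[f"n{alt}"]) >= 1
    return pd.Series(flags, index=calls.index)


# ---------------------------------------------------------------------------
# Stage 3: splice proximity
# ---------------------------------------------------------------------------


def _splice_flank_trees(models: Sequence[GeneModel], k: int) -> dict[str, IntervalTree]:
    """Intronic bases within k of an exon boundary, as closed intervals."""
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for s, e in m.introns:
            left_end = min(s + k - 1, e)
            right_start = max(e - k + 1, s)
            tree.addi(s, left_end + 1)
            tree.addi(right_start, e + 1)
    return trees


def filter_splice_proximity(
    calls: pd.DataFrame, gene_models: Sequence[GeneModel], k: int = 8
) -> pd.Series:
    """Flag intronic calls within ``k`` bases of an exon boundary.

    The filter is intronic-only: exonic bases adjacent to a junction are
    never flagged.  A site is tested against the introns of every transcript.
    """
    trees = _splice_flank_trees(gene_models, k)
    flags = [
        chrom in trees and bool(trees[chrom].overlaps_point(int(pos)))
        for chrom, pos in zip(calls["chrom"], calls["pos"])
    ]
    return pd.Series(flags, index=calls.index, dtype=bool)


# ---------------------------------------------------------------------------
# Flank construction
# ---------------------------------------------------------------------------


def build_substituted_flank(
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    alt: str,
    width: int = 61,
    substitutions: Mapping[int, str] | None = None,
) -> tuple[str, int, int]:
    """Genomic flank of ``width`` centered on ``pos`` with edits substituted.

    Returns ``(sequence, center_index, window_start)`` where ``center_index``
    is the 0-based offset of ``pos`` within the sequence and ``window_start``
    the 1-based genomic start.  The center base is always replaced by
    ``alt``; any additional candidate positions in ``substitutions`` that
    fall inside the window are substituted too (used by the paralog check).
    Windows are truncated (with a log note) near contig ends.
    """
    if width % 2 == 0:
        raise ValueError("width must be odd")
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} missing from FASTA")
    contig = genome[chrom]
    half = (width - 1) // 2
    wstart = pos - half
    wend = pos + half
    if wstart < 1 or wend > len(contig):
        logger.debug("flank at %s:%d truncated at contig end", chrom, pos)
        wstart = max(wstart, 1)
        wend = min(wend, len(contig))
    seq = list(contig[wstart - 1 : wend])
    seq[pos - wstart] = alt
    if substitutions:
        for p, a in substitutions.items():
            if wstart <= p <= wend and p != pos:
                seq[p - wstart] = a
    return "".join(seq), pos - wstart, wstart


def _site_alt_map(calls: pd.DataFrame) -> dict[str, dict[int, str]]:
    """Per-chromosome candidate position -> edited base.

    When specimens disagree on the edited base at a position, the most
    frequent alt wins, ties broken alphabetically.
    """
    out: dict[str, dict[int, str]] = {}
    grouped = (
        calls.groupby(["chrom", "pos", "alt"]).size().reset_index(name="n")
    )
    grouped = grouped.sort_values(
        ["chrom", "pos", "n", "alt"], ascending=[True, True, False, True]
    )
    first = grouped.drop_duplicates(["chrom", "pos"])
    for chrom, pos, alt in zip(first["chrom"], first["pos"], first["alt"]):
        out.setdefault(chrom, {})[int(pos)] = alt
    return out


# ---------------------------------------------------------------------------
# Stage 4: contamination (decoy genome)
# ---------------------------------------------------------------------------


def filter_contamination(
    calls: pd.DataFrame,
    genome: Mapping[str, str],
    decoy: Mapping[str, str] | None,
    aligner: LocalAligner | None = None,
    width: int = 61,
    min_identity: float = 0.90,
    cache: dict | None = None,
) -> pd.Series:
    """Flag calls better explained by a decoy (e.g. mouse) genome.

    A call is flagged when the substituted flank's best decoy hit scores
    strictly higher than the unsubstituted flank's best decoy hit, the hit
    covers the edited position, and identity exceeds ``min_identity``.
    With no decoy supplied the stage is skipped (all False) with a warning.
    """
    if decoy is None or not decoy:
        logger.warning("no decoy genome supplied; contamination stage skipped")
        return pd.Series(False, index=calls.index)
    aligner = aligner or default_aligner()
    cache = cache if cache is not None else {}
    decisions: dict[tuple, bool] = {}
    uniq = calls.drop_duplicates(["chrom", "pos", "alt"])
    for chrom, pos, alt in zip(uniq["chrom"], uniq["pos"].astype(int), uniq["alt"]):
        key = ("con", chrom, pos, alt, width)
        if key not in cache:
            cache[key] = _contamination_hit(
                genome, decoy, aligner, chrom, pos, alt, width, min_identity
            )
        decisions[(chrom, pos, alt)] = cache[key]
    return pd.Series(
        [
            decisions[(c, int(p), a)]
            for c, p, a in zip(calls["chrom"], calls["pos"], calls["alt"])
        ],
        index=calls.index,
        dtype=bool,
    )


def _contamination_hit(genome, decoy, aligner, chrom, pos, alt, width,
                       min_identity) -> bool:
    sub, center, _ = build_substituted_flank(genome, chrom, pos, alt, width)
    orig = list(sub)
    orig[center] = genome[chrom][pos - 1]
    orig = "".join(orig)
    sub_score = max(aligner.score(sub, t) for t in decoy.values())
    orig_score = max(aligner.score(orig, t) for t in decoy.values())
    if sub_score <= orig_score:
        return False
    best = aligner.best_hit(sub, dict(decoy))
    if best is None:
        return False
    covers = best.query_start <= center < best.query_end
    return covers and best.identity > min_identity


# ---------------------------------------------------------------------------
# Stage 5: paralogs (host genome)
# ---------------------------------------------------------------------------


def filter_paralog(
    calls: pd.DataFrame,
    genome: Mapping[str, str],
    aligner: LocalAligner | None = None,
    widths: Sequence[int] = (61, 101),
    cache: dict | None = None,
) -> pd.Series:
    """Flag calls whose substituted flank aligns elsewhere at least as well.

    For each width the flank (with every candidate RDD position in the
    window substituted) is aligned to the host genome with the origin window
    masked out; the call is flagged when any such off-origin alignment scores
    >= the flank's alignment to its own (unsubstituted) origin window, for
    either width.
    """
    aligner = aligner or default_aligner()
    cache = cache if cache is not None else {}
    alt_map = _site_alt_map(calls)
    decisions: dict[tuple, bool] = {}
    uniq = calls.drop_duplicates(["chrom", "pos", "alt"])
    for chrom, pos, alt in zip(uniq["chrom"], uniq["pos"].astype(int), uniq["alt"]):
        flagged = False
        for width in widths:
            sub, center, wstart = build_substituted_flank(
                genome, chrom, pos, alt, width, substitutions=alt_map.get(chrom)
            )
            # window substitution pattern is part of the cache identity
            subs_sig = tuple(
                (p - pos, a)
                for p, a in sorted(alt_map.get(chrom, {}).items())
                if wstart <= p < wstart + len(sub)
            )
            key = ("par", chrom, pos, alt, width, subs_sig)
            if key not in cache:
                cache[key] = _paralog_hit(
                    genome, aligner, chrom, sub, wstart, len(sub)
                )
            if cache[key]:
                flagged = True
                break
        decisions[(chrom, pos, alt)] = flagged
    return pd.Series(
        [
            decisions[(c, int(p), a)]
            for c, p, a in zip(calls["chrom"], calls["pos"], calls["alt"])
        ],
        index=calls.index,
        dtype=bool,
    )


def _paralog_hit(genome, aligner, chrom, sub_flank, wstart, wlen) -> bool:
    origin_window = genome[chrom][wstart - 1 : wstart - 1 + wlen]
    origin_score = aligner.score(sub_flank, origin_window)
    best_off = 0.0
    for name, contig in genome.items():
        if name == chrom:
            masked = (
                contig[: wstart - 1] + "N" * wlen + contig[wstart - 1 + wlen :]
            )
            target = masked
        else:
            target = contig
        best_off = max(best_off, aligner.score(sub_flank, target))
        if best_off >= origin_score:
            return True
    return False


# ---------------------------------------------------------------------------
# Cascade driver
# ---------------------------------------------------------------------------


def apply_filters(
    calls: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    genome: Mapping[str, str] | None = None,
    decoy: Mapping[str, str] | None = None,
    dbsnp_mask: set[tuple[str, int]] | None = None,
    cosmic_mask: set[tuple[str, int]] | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    splice_flank: int = 8,
    flank_widths: Sequence[int] = (61, 101),
    contamination_width: int = 61,
    min_identity: float = 0.90,
    aligner: LocalAligner | None = None,
    cache: dict | None = None,
) -> pd.DataFrame:
    """Run all five stages and return calls with flag columns + ``retained``.

    Stages whose inputs are absent are skipped (flag False everywhere) with
    a warning, mirroring a run without that resource.
    """
    out = calls.copy()
    n = len(out)
    false = pd.Series(False, index=out.index)
    if n == 0:
        for col in FLAG_COLUMNS:
            out[col] = pd.Series(dtype=bool)
        out["retained"] = pd.Series(dtype=bool)
        return out

    out["flag_known_variant"] = (
        filter_known_variants(out, dbsnp_mask, cosmic_mask)
        if (dbsnp_mask or cosmic_mask)
        else false
    )
    out["flag_dna_support_any_specimen"] = (
        filter_dna_support(out, counts) if counts is not None else false
    )
    if gene_models:
        out["flag_splice_proximal"] = filter_splice_proximity(
            out, gene_models, splice_flank
        )
    else:
        logger.warning("no gene models; splice-proximity stage skipped")
        out["flag_splice_proximal"] = false
    if genome is not None:
        out["flag_contamination_hit"] = filter_contamination(
            out, genome, decoy, aligner, contamination_width, min_identity, cache
        )
        out["flag_paralog_hit"] = filter_paralog(
            out, genome, aligner, flank_widths, cache
        )
    else:
        logger.warning("no genome FASTA; alignment stages skipped")
        out["flag_contamination_hit"] = false
        out["flag_paralog_hit"] = false

    out["retained"] = ~out[list(FLAG_COLUMNS)].any(axis=1)
    return out


def retained(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls surviving every filter stage."""
    if "retained" not in calls.columns:
        raise ValueError("run apply_filters first")
    return calls[calls["retained"]].reset_index(drop=True)
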