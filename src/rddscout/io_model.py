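"""Data model, coordinate conventions and readers/writers.

All public coordinates are 1-based and intervals are fully closed.  BED input
(0-based, half-open) is converted on read and back on write, so a BED record
``(chrom, s, e)`` covers the 1-based positions ``s+1 .. e``.

The central tabular containers are plain :class:`pandas.DataFrame` objects
with fixed schemas:

* allele counts -- columns ``specimen, chrom, pos, assay, nA, nC, nG, nT``
  with one row per (specimen, site, assay) and ``assay`` in {``DNA``,
  ``RNA``};
* RDD calls -- columns ``specimen, chrom, pos, ref, alt, x_dna_ref,
  y_rna_alt, rna_depth, status`` plus whatever flag/annotation columns later
  stages add.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COUNT_COLS = ("nA", "nC", "nG", "nT")
ASSAYS = ("DNA", "RNA")

#: Fixed column order for RDD call tables (round-trips through read/write).
CALL_COLUMNS = (
    "specimen",
    "chrom",
    "pos",
    "ref",
    "alt",
    "x_dna_ref",
    "y_rna_alt",
    "rna_depth",
    "status",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicSite:
    """A single 1-based genomic position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class AlleleCountRecord:
    """Per-(specimen, site, assay) counts of the four bases."""

    specimen: str
    site: GenomicSite
    assay: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")
        if any(self.counts.get(b, 0) < 0 for b in BASES):
            raise ValueError("counts must be non-negative")

    @property
    def depth(self) -> int:
        return sum(int(self.counts.get(b, 0)) for b in BASES)


@dataclass
class GeneModel:
    """A transcript model: exon blocks, CDS span, strand and biotype.

    Coordinates are 1-based closed.  ``exons`` are sorted, non-overlapping
    ``(start, end)`` blocks.  For ``biotype == "ncRNA"`` the CDS span is
    ``None``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e:
                raise ValueError("exon blocks must be non-overlapping")
        if any(s > e for s, e in self.exons):
            raise ValueError("exon start must be <= end")
        if self.biotype == "coding":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError("coding transcript requires a CDS span")
            if not (self.start <= self.cds_start <= self.cds_end <= self.end):
                raise ValueError("CDS must lie within the exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e + 1, s2 - 1)
            for (_, e), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e > 1
        ]


class IntervalTrack:
    """A named collection of 1-based closed genomic intervals.

    Intervals may carry an arbitrary data payload (used by the miRNA-target
    track for miRNA / target-gene identifiers).  Queries are point-overlap
    (`contains`, `overlapping`); `merged_length` reports the number of
    distinct covered bases.
    """

    def __init__(
        self,
        name: str,
        intervals: Iterable[tuple[str, int, int]] | None = None,
        data: Iterable[object] | None = None,
    ) -> None:
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        intervals = list(intervals or [])
        payload = list(data) if data is not None else [None] * len(intervals)
        if len(payload) != len(intervals):
            raise ValueError("data must match intervals in length")
        for (chrom, start, end), d in zip(intervals, payload):
            self.add(chrom, start, end, d)

    def add(self, chrom: str, start: int, end: int, data: object = None) -> None:
        if start > end:
            raise FormatError(f"interval start > end: {chrom}:{start}-{end}")
        # closed interval [start, end] -> half-open tree interval [start, end+1)
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, data)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def overlapping(self, chrom: str, pos: int) -> list[tuple[int, int, object]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree[pos], key=lambda iv: (iv.begin, iv.end))
        return [(iv.begin, iv.end - 1, iv.data) for iv in hits]

    def intervals(self) -> list[tuple[str, int, int, object]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end - 1, iv.data))
        return out

    def merged_length(self) -> int:
        total = 0
        for tree in self._trees.values():
            merged = IntervalTree(tree)
            merged.merge_overlaps(strict=False)
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalTrack({self.name!r}, n={len(self)})"


@dataclass
class AnnotationSet:
    """Named interval tracks plus gene models used by annotation stages."""

    alu: IntervalTrack = field(default_factory=lambda: IntervalTrack("alu"))
    non_alu_repeat: IntervalTrack = field(
        default_factory=lambda: IntervalTrack("non_alu_repeat")
    )
    conserved: IntervalTrack = field(default_factory=lambda: IntervalTrack("conserved"))
    darned_like: IntervalTrack = field(
        default_factory=lambda: IntervalTrack("darned_like")
    )
    mirna_targets: IntervalTrack = field(
        default_factory=lambda: IntervalTrack("mirna_targets")
    )
    gene_models: list[GeneModel] = field(default_factory=list)


@dataclass
class ExpressionTable:
    """Gene x specimen raw counts with optional size factors and lengths."""

    counts: pd.DataFrame
    size_factors: pd.Series | None = None
    gene_lengths: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("expression counts must be non-negative")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


# ---------------------------------------------------------------------------
# Allele-count tables
# ---------------------------------------------------------------------------

_COUNT_HEADER = ["specimen", "chrom", "pos", "assay"] + list(COUNT_COLS)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a TSV allele-count table.

    Expects header columns ``specimen chrom pos assay nA nC nG nT``.
    Malformed rows raise :class:`FormatError` / :class:`ValueError` naming the
    offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "specimen": str})
    missing = [c for c in _COUNT_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for i, assay in enumerate(df["assay"]):
        if assay not in ASSAYS:
            raise FormatError(f"{path} line {i + 2}: bad assay {assay!r}")
    for col in COUNT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise ValueError(f"{path} line {line}: non-numeric {col}")
        if (vals < 0).any():
            line = int(vals.index[vals < 0][0]) + 2
            raise ValueError(f"{path} line {line}: negative count in {col}")
        df[col] = vals.astype(np.int64)
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 2
        raise ValueError(f"{path} line {line}: pos must be >= 1")
    return df[_COUNT_HEADER]


def write_allele_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[_COUNT_HEADER].to_csv(path, sep="\t", index=False)


def counts_as_records(df: pd.DataFrame) -> list[AlleleCountRecord]:
    """Materialize table rows as :class:`AlleleCountRecord` objects."""
    return [
        AlleleCountRecord(
            specimen=row.specimen,
            site=GenomicSite(row.chrom, int(row.pos)),
            assay=row.assay,
            counts={b: int(getattr(row, f"n{b}")) for b in BASES},
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Intervals (BED) and gene models (BED12)
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path, name: str) -> IntervalTrack:
    """Read a BED file into an :class:`IntervalTrack` (1-based closed).

    Columns beyond the third are optional; when a 4th (name) column of the
    form ``mirna_id|gene_id`` is present it is attached as interval payload
    ``(mirna_id, gene_id)``, otherwise the raw name string is attached.
    """
    track = IntervalTrack(name)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise FormatError(f"{path} line {lineno}: start > end")
            if start == end:  # zero-length BED record covers no base
                continue
            data: object = None
            if len(fields) >= 4:
                nm = fields[3]
                data = tuple(nm.split("|", 1)) if "|" in nm else nm
            track.add(chrom, start + 1, end, data)
    return track


def write_intervals(track: IntervalTrack, path: str | Path) -> None:
    """Write a track back to BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, data in track.intervals():
            fields = [chrom, str(start - 1), str(end)]
            if data is not None:
                fields.append("|".join(data) if isinstance(data, tuple) else str(data))
            fh.write("\t".join(fields) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models.

    The BED name field encodes ``gene_id:transcript_id``; a transcript with
    ``thickStart == thickEnd`` is treated as non-coding (``biotype ncRNA``).
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path} line {lineno}: BED12 requires 12 columns")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            nblocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(starts) != nblocks:
                raise FormatError(f"{path} line {lineno}: block count mismatch")
            exons = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            gene_id, _, tx_id = name.partition(":")
            coding = thick_end > thick_start
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx_id or gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start + 1 if coding else None,
                    cds_end=thick_end if coding else None,
                    biotype="coding" if coding else "ncRNA",
                )
            )
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start0 = m.start - 1
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            starts = ",".join(str(s - 1 - start0) for s, _ in m.exons)
            thick = (
                (m.cds_start - 1, m.cds_end) if m.biotype == "coding" else (start0, start0)
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom,
                        start0,
                        m.end,
                        f"{m.gene_id}:{m.transcript_id}",
                        0,
                        m.strand,
                        thick[0],
                        thick[1],
                        "0,0,0",
                        len(m.exons),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Variant masks (VCF subset or 2-column position list)
# ---------------------------------------------------------------------------


def read_variant_mask(
    path: str | Path, cdna_info_key: str = "MOLTYPE", cdna_value: str = "cDNA"
) -> set[tuple[str, int]]:
    """Read a known-variant mask from a minimal VCF or a 2-column list.

    VCF records whose INFO column carries ``MOLTYPE=cDNA`` (key/value
    configurable) are *excluded* from the mask: such entries describe
    transcript-derived variation and would mask genuine editing sites.
    Only ``(chrom, pos)`` is retained; masking is alt-agnostic.
    """
    mask: set[tuple[str, int]] = set()
    flag = f"{cdna_info_key}={cdna_value}"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:  # simple chrom<TAB>pos list
                chrom, pos = fields
            elif len(fields) >= 8:  # VCF body line
                chrom, pos = fields[0], fields[1]
                info = fields[7]
                if flag in info.split(";"):
                    continue
            elif len(fields) >= 5:  # headerless VCF-like without INFO
                chrom, pos = fields[0], fields[1]
            else:
                raise FormatError(f"{path} line {lineno}: unreadable mask line")
            try:
                mask.add((chrom, int(pos)))
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: bad position") from exc
    return mask


# ---------------------------------------------------------------------------
# RDD call tables
# ---------------------------------------------------------------------------


def write_rdd_table(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls with a deterministic column order (core columns first)."""
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    calls[cols].to_csv(path, sep="\t", index=False)


def read_rdd_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "specimen": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing call columns {missing}")
    return df


# ---------------------------------------------------------------------------
# FASTA and expression matrices
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (kilobase-scale) FASTA into a dict of uppercase sequences."""
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def counts_from_bam(
    bam_path: str | Path,
    specimen: str,
    assay: str,
    min_pos: int = 1,
    max_pos: int | None = None,
) -> pd.DataFrame:
    """Optional adapter: pileup a coordinate-sorted, indexed BAM into the
    allele-count table schema.

    The core pipeline consumes count tables; this helper exists for users
    who start from alignments.  Requires :mod:`pysam`.  Positions are
    reported 1-based; rows with zero coverage are omitted.
    """
    import pysam  # local import: BAM support is optional

    if assay not in ASSAYS:
        raise ValueError(f"assay must be one of {ASSAYS}")
    rows = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for chrom in bam.references:
            length = bam.get_reference_length(chrom)
            stop = min(max_pos or length, length)
            cov = bam.count_coverage(
                chrom, start=min_pos - 1, stop=stop, quality_threshold=0
            )
            arr = np.array(cov)  # 4 x n in A, C, G, T order
            depth = arr.sum(axis=0)
            for i in np.nonzero(depth)[0]:
                rows.append(
                    {
                        "specimen": specimen,
                        "chrom": chrom,
                        "pos": min_pos + int(i),
                        "assay": assay,
                        "nA": int(arr[0, i]),
                        "nC": int(arr[1, i]),
                        "nG": int(arr[2, i]),
                        "nT": int(arr[3, i]),
                    }
                )
    return pd.DataFrame(rows, columns=_COUNT_HEADER)


def read_expression(
    path: str | Path, lengths_path: str | Path | None = None
) -> ExpressionTable:
    """Read a gene x specimen count matrix (TSV, genes as the index)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0]
    return ExpressionTable(counts=counts, gene_lengths=lengths)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")
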