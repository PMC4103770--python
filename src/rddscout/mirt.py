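"""Association between miRNA-target-site editing and transcript expression.

Edits inside predicted miRNA target regions (mirT RDDs) may let a transcript
escape miRNA-mediated repression.  For every protein-coding gene with mirT
RDDs the cohort is split into specimens *with* and *without* such an edit and
the (median-of-ratios normalized) expression of the two groups is compared as
``logFC = log2((mean_with + pseudocount) / (mean_without + pseudocount))``.
Genes with coding-region RDDs (crRDDs) and no mirT RDDs serve as the negative
control; genes carrying both kinds are removed.  To limit expression-driven
detection bias only genes with approximate RNA coverage > 10X are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_model import ExpressionTable, GeneModel


@dataclass
class GeneComparison:
    """Per-gene with/without-edit expression comparison."""

    gene_id: str
    category: str  # 'mirT' or 'crRDD'
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    log_fc: float
    p_value: float | None  # Welch t-test; None unless >= 3 per group


# ---------------------------------------------------------------------------
# Normalization (median-of-ratios)
# ---------------------------------------------------------------------------


def normalize_counts(table: ExpressionTable) -> ExpressionTable:
    """Median-of-ratios size-factor normalization of a count matrix.

    The size factor of a specimen is the median, over genes expressed in
    every specimen, of the ratio between its count and the gene's geometric
    mean across specimens.  Normalized values are counts divided by the size
    factor, so scaling one specimen's counts by ``c`` leaves its normalized
    values unchanged.
    """
    counts = table.counts
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in all specimens; "
                         "size factors are undefined")
    log_counts = np.log(counts.loc[usable].astype(float))
    log_geomean = log_counts.mean(axis=1)
    log_ratios = log_counts.sub(log_geomean, axis=0)
    size_factors = np.exp(log_ratios.median(axis=0))
    normalized = counts.div(size_factors, axis=1)
    return ExpressionTable(
        counts=counts,
        size_factors=size_factors,
        gene_lengths=table.gene_lengths,
        normalized=normalized,
    )


def gene_coverage(total_reads: float, read_length: float,
                  transcript_length: float) -> float:
    """Approximate fold-coverage = reads x read length / transcript length."""
    if transcript_length <= 0:
        raise ValueError("transcript length must be positive")
    return total_reads * read_length / transcript_length


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def assign_groups(
    calls: pd.DataFrame, gene_models: list[GeneModel]
) -> pd.DataFrame:
    """Build the per-gene, per-specimen edit-status matrix C(i, k).

    Input calls must be annotated (``in_mirna_target`` with carried target
    gene ids, and ``feature``/``gene_id`` for coding-region RDDs).  Only
    protein-coding genes are evaluated; genes with both mirT RDDs and
    coding-region RDDs are removed.  Returns a tidy frame with columns
    ``gene_id, category, specimen`` listing which specimens carry a
    qualifying RDD for the gene (``category`` in {mirT, crRDD}).
    """
    coding_genes = {m.gene_id for m in gene_models if m.biotype == "coding"}

    mirt_pairs: set[tuple[str, str]] = set()
    if "in_mirna_target" in calls.columns:
        hit = calls[calls["in_mirna_target"]]
        for specimen, genes in zip(hit["specimen"],
                                   hit.get("in_mirna_target_gene", "")):
            for g in str(genes).split(";"):
                if g and g in coding_genes:
                    mirt_pairs.add((g, specimen))

    cr_pairs: set[tuple[str, str]] = set()
    cds = calls[(calls.get("feature") == "CDS")]
    for specimen, g in zip(cds["specimen"], cds["gene_id"]):
        if g and g in coding_genes:
            cr_pairs.add((g, specimen))

    mirt_genes = {g for g, _ in mirt_pairs}
    cr_genes = {g for g, _ in cr_pairs}
    dual = mirt_genes & cr_genes  # dual-status genes leave both analyses

    rows = [
        {"gene_id": g, "category": "mirT", "specimen": s}
        for g, s in sorted(mirt_pairs)
        if g not in dual
    ] + [
        {"gene_id": g, "category": "crRDD", "specimen": s}
        for g, s in sorted(cr_pairs)
        if g not in dual
    ]
    return pd.DataFrame(rows, columns=["gene_id", "category", "specimen"])


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------


def compare_expression(
    groups: pd.DataFrame,
    expression: ExpressionTable,
    read_length: float = 75.0,
    min_coverage: float = 10.0,
    pseudocount: float = 1.0,
    min_group_for_test: int = 3,
) -> list[GeneComparison]:
    """Compare normalized expression with vs without a qualifying RDD.

    Genes are kept when their approximate coverage exceeds ``min_coverage``
    (strict) and both groups are non-empty; the Welch t-test is reported only
    when both groups have at least ``min_group_for_test`` specimens.
    """
    if expression.normalized is None:
        expression = normalize_counts(expression)
    norm = expression.normalized
    specimens = list(norm.columns)
    out: list[GeneComparison] = []
    for (gene, category), grp in groups.groupby(["gene_id", "category"]):
        if gene not in norm.index:
            continue
        if expression.gene_lengths is not None and gene in expression.gene_lengths.index:
            cov = gene_coverage(
                float(expression.counts.loc[gene].sum()),
                read_length,
                float(expression.gene_lengths.loc[gene]),
            )
            if not cov > min_coverage:
                continue
        with_specs = [s for s in specimens if s in set(grp["specimen"])]
        without_specs = [s for s in specimens if s not in set(grp["specimen"])]
        if not with_specs or not without_specs:
            continue
        vals_with = norm.loc[gene, with_specs].astype(float)
        vals_without = norm.loc[gene, without_specs].astype(float)
        mean_with = float(vals_with.mean())
        mean_without = float(vals_without.mean())
        log_fc = float(
            np.log2((mean_with + pseudocount) / (mean_without + pseudocount))
        )
        p_value = None
        if (
            len(vals_with) >= min_group_for_test
            and len(vals_without) >= min_group_for_test
        ):
            if np.allclose(vals_with.var(ddof=1) + vals_without.var(ddof=1), 0):
                p_value = 1.0 if mean_with == mean_without else 0.0
            else:
                p_value = float(
                    stats.ttest_ind(vals_with, vals_without, equal_var=False).pvalue
                )
        out.append(
            GeneComparison(
                gene_id=gene,
                category=category,
                n_with=len(vals_with),
                n_without=len(vals_without),
                mean_with=mean_with,
                mean_without=mean_without,
                log_fc=log_fc,
                p_value=p_value,
            )
        )
    return out


def proportion_table(
    comparisons: list[GeneComparison],
    cutoffs: tuple[float, ...] = (0.0, 0.5, 1.0),
) -> pd.DataFrame:
    """Up/down-regulated gene counts per logFC cutoff and RDD category.

    'Up at cutoff c' means logFC > c; 'down' means logFC < -c.  Ties at a
    cutoff (including logFC exactly 0) count as not-up.  Fractions are of
    the category total.
    """
    rows = []
    frame = pd.DataFrame(
        {
            "category": [c.category for c in comparisons],
            "log_fc": [c.log_fc for c in comparisons],
        }
    )
    for category, grp in frame.groupby("category"):
        total = len(grp)
        for cut in cutoffs:
            up = int((grp["log_fc"] > cut).sum())
            down = int((grp["log_fc"] < -cut).sum())
            rows.append(
                {
                    "category": category,
                    "cutoff": cut,
                    "n_genes": total,
                    "n_up": up,
                    "n_down": down,
                    "frac_up": up / total if total else float("nan"),
                    "frac_down": down / total if total else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["category", "cutoff", "n_genes", "n_up", "n_down",
                 "frac_up", "frac_down"],
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, 2x2)
# ---------------------------------------------------------------------------


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    The p-value sums, over the hypergeometric support with the observed
    margins, every table probability not exceeding the observed one (with a
    small relative guard against floating-point ties).  Returns
    ``(odds_ratio, p)``; the odds ratio is ``(a*d)/(b*c)`` (inf when
    ``b*c == 0``).  Any zero margin gives p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        odds = np.inf if b * c == 0 else (a * d) / (b * c)
        return float(odds), 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    logpmf = (
        _log_comb(col1, support)
        + _log_comb(n - col1, row1 - support)
        - _log_comb(n, row1)
    )
    pmf = np.exp(logpmf)
    observed = pmf[support == a][0]
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(odds), p


def _log_comb(n: np.ndarray | int, k: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def up_proportion_test(
    comparisons: list[GeneComparison], cutoff: float = 0.0
) -> dict:
    """Compare the up-regulated proportion between mirT and crRDD genes.

    Builds the 2x2 table (up vs not-up at ``cutoff``) across the two
    categories and applies the two-sided Fisher exact test.
    """
    tab = {}
    frame = pd.DataFrame(
        {
            "category": [c.category for c in comparisons],
            "up": [c.log_fc > cutoff for c in comparisons],
        }
    )
    for category in ("mirT", "crRDD"):
        grp = frame[frame["category"] == category]
        tab[category] = (int(grp["up"].sum()), int((~grp["up"]).sum()))
    (a, b), (c, d) = tab["mirT"], tab["crRDD"]
    odds, p = fisher_exact_2x2(a, b, c, d)
    return {
        "mirT_up": a, "mirT_not_up": b,
        "crRDD_up": c, "crRDD_not_up": d,
        "mirT_frac_up": a / (a + b) if a + b else float("nan"),
        "crRDD_frac_up": c / (c + d) if c + d else float("nan"),
        "odds_ratio": odds,
        "p_value": p,
    }
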