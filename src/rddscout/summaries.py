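"""Cohort summary tables for annotated RDD calls.

Includes the Alu-stratum FDR estimate: since nearly all genuine editing in
Alu repeats is the canonical A>G|T>C deamination class, the fraction of
non-canonical calls inside Alu elements bounds the false-discovery rate of
the whole prediction, assuming every non-canonical Alu call is a false
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import CANONICAL_CLASS, STRATA, SUBSTITUTION_CLASSES
from .io_model import IntervalTrack


@dataclass
class FdrEstimate:
    """Alu-based FDR: 1 minus the canonical-class fraction in a stratum."""

    stratum: str
    n_calls: int
    fraction_canonical: float
    fdr: float

    @property
    def fdr_percent(self) -> float:
        """FDR as a percent rounded to one decimal (reporting convention)."""
        return round(self.fdr * 100.0, 1)


def class_distribution(calls: pd.DataFrame, by_specimen: bool = False
                       ) -> pd.DataFrame:
    """Cross-tabulate calls by substitution class and region stratum.

    Returns a tidy frame with columns ``stratum, sub_class, count, fraction``
    (fractions within each stratum margin; they sum to 1 per stratum).  With
    ``by_specimen=True`` an extra ``specimen`` level is included.  A pooled
    margin over all strata is appended under stratum ``all``.
    """
    if calls.empty:
        return pd.DataFrame(columns=["stratum", "sub_class", "count", "fraction"])
    req = ["sub_class", "stratum"]
    if any(c not in calls.columns for c in req):
        raise ValueError("calls must be annotated with sub_class and stratum")
    keys = (["specimen"] if by_specimen else []) + ["stratum"]

    parts = []
    grouped = calls.groupby(keys + ["sub_class"], observed=True).size()
    counts = grouped.reset_index(name="count")
    parts.append(counts)
    pooled = (
        calls.groupby((["specimen"] if by_specimen else []) + ["sub_class"],
                      observed=True)
        .size()
        .reset_index(name="count")
    )
    pooled["stratum"] = "all"
    parts.append(pooled[counts.columns])
    out = pd.concat(parts, ignore_index=True)
    margin_keys = [k for k in keys if k != "stratum"] + ["stratum"]
    out["fraction"] = out["count"] / out.groupby(margin_keys)["count"].transform("sum")
    cat = pd.CategoricalDtype(list(SUBSTITUTION_CLASSES), ordered=True)
    out["sub_class"] = out["sub_class"].astype(cat)
    strat_cat = pd.CategoricalDtype(list(STRATA) + ["all"], ordered=True)
    out["stratum"] = out["stratum"].astype(strat_cat)
    return out.sort_values(margin_keys + ["sub_class"]).reset_index(drop=True)


def estimate_fdr_alu(dist: pd.DataFrame, stratum: str = "Alu") -> FdrEstimate:
    """Alu-based FDR from a class distribution table.

    ``fdr = 1 - fraction(A>G|T>C in the Alu stratum)``.  An empty Alu margin
    is undefined and raises.
    """
    sub = dist[dist["stratum"] == stratum]
    total = int(sub["count"].sum())
    if total == 0:
        raise ValueError(f"no calls in stratum {stratum!r}; FDR undefined")
    canon = int(sub.loc[sub["sub_class"] == CANONICAL_CLASS, "count"].sum())
    frac = canon / total
    return FdrEstimate(
        stratum=stratum, n_calls=total, fraction_canonical=frac, fdr=1.0 - frac
    )


def density_per_mb(calls: pd.DataFrame, track: IntervalTrack) -> float:
    """Calls inside the track per megabase of (merged) track length."""
    length = track.merged_length()
    if length == 0:
        raise ValueError("track has zero length")
    inside = sum(
        track.contains(c, int(p)) for c, p in zip(calls["chrom"], calls["pos"])
    )
    return inside / (length / 1e6)


def recurrence_histogram(calls: pd.DataFrame) -> dict:
    """Distribution of distinct site keys by number of sharing specimens.

    Returns ``{"histogram": {k: n_sites}, "n_sites": total distinct keys,
    "unique_fraction": share seen in exactly one specimen,
    "clustered_fraction": share of calls flagged clustered (when present)}``.
    """
    if "recurrence" not in calls.columns:
        raise ValueError("calls must carry recurrence annotation")
    sites = calls.drop_duplicates(["chrom", "pos", "sub_class"])
    hist = (
        sites.groupby("recurrence").size().sort_index().to_dict()
    )
    n_sites = int(len(sites))
    unique_fraction = hist.get(1, 0) / n_sites if n_sites else float("nan")
    out = {
        "histogram": {int(k): int(v) for k, v in hist.items()},
        "n_sites": n_sites,
        "unique_fraction": unique_fraction,
    }
    if "clustered" in calls.columns and len(calls):
        out["clustered_fraction"] = float(calls["clustered"].mean())
    return out


def track_overlap_fraction(calls: pd.DataFrame, column: str,
                           sub_class: str | None = None) -> float:
    """Fraction of calls carrying a membership flag (optionally one class)."""
    sub = calls if sub_class is None else calls[calls["sub_class"] == sub_class]
    if sub.empty:
        return float("nan")
    return float(sub[column].mean())


def summarize(calls: pd.DataFrame) -> dict:
    """One-stop cohort summary used by the CLI report."""
    dist = class_distribution(calls)
    out: dict = {"n_calls": int(len(calls))}
    if calls.empty:
        return out
    out["class_distribution"] = dist
    try:
        fdr = estimate_fdr_alu(dist)
        out["alu_fdr_percent"] = fdr.fdr_percent
        out["alu_fraction_canonical"] = fdr.fraction_canonical
    except ValueError:
        out["alu_fdr_percent"] = None
    out["n_rescued"] = int((calls["status"] == "rescued").sum())
    out["n_high_coverage"] = int((calls["status"] == "high_coverage").sum())
    if "recurrence" in calls.columns:
        out.update(recurrence_histogram(calls))
    return out
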