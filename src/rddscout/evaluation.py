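"""Down-sampling recovery evaluation and truth-based metrics.

The down-sampling experiment asks how many of the RDDs found at full depth
would still be detected after discarding a fraction of the reads, and how
much of that detection is owed to the low-coverage rescue rather than to the
plain high-coverage rule.  Thinning operates at count level: each base count
is replaced by a binomial draw with the keep probability, which matches
per-read subsampling in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import substitution_class
from .io_model import COUNT_COLS

#: Call keys used throughout recovery/truth comparisons.
RECOVERY_KEY = ("specimen", "chrom", "pos", "sub_class")
SITE_KEY = ("chrom", "pos", "sub_class")


@dataclass
class RecoveryReport:
    keep_fraction: float
    n_full_high_coverage: int
    detected_fraction: float
    rescued_share_of_detected: float
    n_novel: int
    n_thinned: int = 0

    @property
    def novel_rate(self) -> float:
        """Novel keys as a fraction of all thinned-run call keys."""
        return self.n_novel / self.n_thinned if self.n_thinned else 0.0


def downsample_counts(
    counts: pd.DataFrame, keep_fraction: float, seed: int
) -> pd.DataFrame:
    """Binomial thinning of every base count (reproducible under seed)."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    out = counts.copy()
    if keep_fraction == 1.0:
        return out
    rng = np.random.default_rng(seed)
    for col in COUNT_COLS:
        out[col] = rng.binomial(out[col].to_numpy(np.int64), keep_fraction)
    return out


def _keyed(calls: pd.DataFrame, key=RECOVERY_KEY) -> pd.DataFrame:
    out = calls.copy()
    if "sub_class" not in out.columns:
        out["sub_class"] = [
            substitution_class(r, a) for r, a in zip(out["ref"], out["alt"])
        ]
    return out


def recovery_metrics(
    full_calls: pd.DataFrame,
    thinned_calls: pd.DataFrame,
    keep_fraction: float = float("nan"),
) -> RecoveryReport:
    """Compare thinned-data calls against the full-depth call set.

    Detection is measured over the full run's *high-coverage* call keys
    (specimen, chrom, pos, class); the rescued share is the fraction of
    those detections that the thinned run could only make via rescue.
    Novel keys are thinned calls absent from the full call set entirely.
    """
    if full_calls.empty:
        raise ValueError("full call set is empty; recovery undefined")
    full = _keyed(full_calls)
    thin = _keyed(thinned_calls)
    key = list(RECOVERY_KEY)

    full_keys = set(map(tuple, full[key].itertuples(index=False)))
    full_hc = full[full["status"] == "high_coverage"]
    hc_keys = set(map(tuple, full_hc[key].itertuples(index=False)))

    thin_records = {
        tuple(k): status
        for *k, status in thin[key + ["status"]].itertuples(index=False)
    }
    thin_keys = set(thin_records)

    detected = hc_keys & thin_keys
    detected_fraction = len(detected) / len(hc_keys) if hc_keys else float("nan")
    rescued = sum(1 for k in detected if thin_records[k] == "rescued")
    rescued_share = rescued / len(detected) if detected else float("nan")
    novel = len(thin_keys - full_keys)
    return RecoveryReport(
        keep_fraction=keep_fraction,
        n_full_high_coverage=len(hc_keys),
        detected_fraction=detected_fraction,
        rescued_share_of_detected=rescued_share,
        n_novel=novel,
        n_thinned=len(thin_keys),
    )


def precision_recall(
    calls: pd.DataFrame,
    truth_sites: pd.DataFrame,
    min_beta: float | None = None,
) -> dict:
    """Precision/recall of called sites against planted truth.

    Both sides are keyed by (chrom, pos, substitution class).  ``truth_sites``
    needs columns chrom, pos, ref, alt (plus optional ``beta`` and
    ``stratum``); with ``min_beta`` the recall denominator is restricted to
    edits with site-level editing >= that value.  Precision over an empty
    call set is reported as NaN.
    """
    calls = _keyed(calls)
    truth = _keyed(truth_sites)
    key = list(SITE_KEY)
    call_keys = set(map(tuple, calls.drop_duplicates(key)[key].itertuples(index=False)))
    truth_all = truth
    if min_beta is not None and "beta" in truth.columns:
        truth = truth[truth["beta"] >= min_beta]
    truth_keys = set(map(tuple, truth[key].itertuples(index=False)))
    truth_keys_all = set(map(tuple, truth_all[key].itertuples(index=False)))

    tp = len(call_keys & truth_keys_all)
    precision = tp / len(call_keys) if call_keys else float("nan")
    recall = (
        len(call_keys & truth_keys) / len(truth_keys) if truth_keys else float("nan")
    )
    out = {
        "n_called_sites": len(call_keys),
        "n_truth_sites": len(truth_keys),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
    if "stratum" in truth_all.columns:
        per = {}
        for stratum, grp in truth_all.groupby("stratum"):
            keys = set(map(tuple, grp[key].itertuples(index=False)))
            per[stratum] = (
                len(call_keys & keys) / len(keys) if keys else float("nan")
            )
        out["recall_by_stratum"] = per
    return out


def truth_fdr(calls: pd.DataFrame, truth_sites: pd.DataFrame) -> float:
    """Observed false-discovery proportion of called sites vs planted truth."""
    pr = precision_recall(calls, truth_sites)
    return 1.0 - pr["precision"] if pr["n_called_sites"] else float("nan")
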