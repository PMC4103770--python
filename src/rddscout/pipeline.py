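"""End-to-end orchestration of the RDD discovery workflow.

``run_pipeline`` wires the stages (call -> filter -> annotate -> summarize
[-> mirT expression]) over in-memory inputs and records per-stage candidate
counts; the CLI and the evaluation helpers are thin layers over it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import annotation as ann_mod
from . import calling, evaluation, filtering, mirt, summaries
from .calling import RescueParams
from .io_model import AnnotationSet, ExpressionTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls_raw: pd.DataFrame
    calls_filtered: pd.DataFrame  # all candidates with flag columns
    calls: pd.DataFrame  # retained + annotated
    summary: dict
    stage_counts: dict[str, int]
    comparisons: list = field(default_factory=list)
    proportions: pd.DataFrame | None = None
    mirt_test: dict | None = None


def run_pipeline(
    counts: pd.DataFrame,
    genome: dict[str, str],
    annotation: AnnotationSet,
    dbsnp_mask: set | None = None,
    cosmic_mask: set | None = None,
    decoy: dict[str, str] | None = None,
    expression: ExpressionTable | None = None,
    params: RescueParams | None = None,
    splice_flank: int = 8,
    read_length: float = 75.0,
    min_coverage: float = 10.0,
    per_specimen_thresholds: bool = True,
    enable_rescue: bool = True,
    thresholds: dict | None = None,
    filter_cache: dict | None = None,
) -> PipelineResult:
    """Run calling, filtering, annotation and summaries (and, when an
    expression table is given, the miRNA-target expression association)."""
    stage_counts: dict[str, int] = {}

    calls_raw = calling.call_rdds(
        counts,
        genome,
        params=params,
        per_specimen_thresholds=per_specimen_thresholds,
        enable_rescue=enable_rescue,
        thresholds=thresholds,
    )
    stage_counts["called"] = len(calls_raw)
    logger.info("calling: %d candidate RDDs", len(calls_raw))

    flagged = filtering.apply_filters(
        calls_raw,
        counts=counts,
        genome=genome,
        decoy=decoy,
        dbsnp_mask=dbsnp_mask,
        cosmic_mask=cosmic_mask,
        gene_models=annotation.gene_models,
        splice_flank=splice_flank,
        cache=filter_cache,
    )
    surviving = flagged.copy()
    for col in filtering.FLAG_COLUMNS:
        surviving = surviving[~surviving[col]]
        stage = col.removeprefix("flag_")
        stage_counts[f"after_{stage}"] = len(surviving)
        logger.info("filter %s: %d candidates remain", stage, len(surviving))

    kept = filtering.retained(flagged)
    annotated = ann_mod.annotate_calls(kept, annotation) if len(kept) else kept
    stage_counts["final"] = len(annotated)

    summary = summaries.summarize(annotated) if len(annotated) else {"n_calls": 0}

    result = PipelineResult(
        calls_raw=calls_raw,
        calls_filtered=flagged,
        calls=annotated,
        summary=summary,
        stage_counts=stage_counts,
    )

    if expression is not None and len(annotated):
        normalized = mirt.normalize_counts(expression)
        groups = mirt.assign_groups(annotated, annotation.gene_models)
        comparisons = mirt.compare_expression(
            groups, normalized, read_length=read_length, min_coverage=min_coverage
        )
        result.comparisons = comparisons
        if comparisons:
            result.proportions = mirt.proportion_table(comparisons)
            cats = {c.category for c in comparisons}
            if {"mirT", "crRDD"} <= cats:
                result.mirt_test = mirt.up_proportion_test(comparisons)
    return result


def downsample_evaluation(
    counts: pd.DataFrame,
    genome: dict[str, str],
    annotation: AnnotationSet,
    keep_fractions: tuple[float, ...] = (0.7, 0.5, 0.3),
    seed: int = 0,
    filter_cache: dict | None = None,
    **pipeline_kwargs,
) -> tuple[list[evaluation.RecoveryReport], PipelineResult]:
    """Full-depth run plus one thinned run per keep fraction.

    The thinned runs re-apply the *full-depth* read-depth criteria (the
    per-specimen concordant-site thresholds are computed once on the full
    data), mirroring a down-sampling experiment that asks how much of the
    original call set survives with fewer reads.  A shared filter cache
    avoids re-aligning flanks for sites already judged in the full-depth run
    (those decisions depend only on the genome and the candidate windows,
    not on depth).
    """
    cache = filter_cache if filter_cache is not None else {}
    full_thresholds = calling.cohort_thresholds(counts, genome)
    full = run_pipeline(counts, genome, annotation, filter_cache=cache,
                        thresholds=full_thresholds, **pipeline_kwargs)
    reports = []
    for i, keep in enumerate(keep_fractions):
        thinned = evaluation.downsample_counts(counts, keep, seed=seed + 1000 * (i + 1))
        res = run_pipeline(thinned, genome, annotation, filter_cache=cache,
                           thresholds=full_thresholds, **pipeline_kwargs)
        reports.append(
            evaluation.recovery_metrics(full.calls, res.calls, keep_fraction=keep)
        )
    return reports, full
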