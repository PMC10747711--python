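"""Alignment scoring: midpoint and onset protocols, timing-error
tolerance tables, and per-phone error rates.

Midpoint protocol
    A prediction matches a ground-truth segment when the truth segment's
    temporal midpoint lies within the predicted segment
    (``pred.start <= truth.midpoint <= pred.end``); a *hit* additionally
    requires equal labels.  Hits over the number of truth segments is the
    recall-like proportion, hits over the number of predictions the
    precision-like one, and their harmonic mean the headline score.  The
    nested comparison of every truth segment with every prediction is kept
    as-is — one truth segment may hit several predictions and vice versa —
    with a one-to-one variant available behind ``unique_matching=True``.

Onset protocol
    A predicted segment start within a tolerance (default 20 ms) of a
    ground-truth segment start is a match; matched pairs with equal labels
    are correct.  Matching is greedy one-to-one by increasing time
    difference, the standard convention for boundary F1.

For every hit the absolute onset and offset timing errors
``dt_start = |t_start_truth - t_start_pred|`` and
``dt_end = |t_end_truth - t_end_pred|`` are recorded; the tolerance table
reports the fraction of hits with error strictly below each threshold
(defaults 20/40/60 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from phonealign.types import LabeledSegment

__all__ = [
    "EvalReport",
    "ToleranceTable",
    "harmonic_mean",
    "midpoint_evaluate",
    "onset_evaluate",
    "per_phone_error_rates",
    "tolerance_table",
]

DEFAULT_THRESHOLDS = (0.02, 0.04, 0.06)


@dataclass(frozen=True)
class EvalReport:
    """Midpoint-protocol scores for one (truth, prediction) pair of lists."""

    hits: int
    n_truth: int
    n_pred: int
    precision_like: float
    recall_like: float
    harmonic_mean: float
    dt_start: tuple[float, ...]
    dt_end: tuple[float, ...]
    match_fraction: float  # midpoint matches ignoring labels, over n_truth


@dataclass(frozen=True)
class ToleranceTable:
    """Fractions of timing errors strictly below each threshold."""

    thresholds: tuple[float, ...]
    fractions_start: tuple[float, ...]
    fractions_end: tuple[float, ...]


def harmonic_mean(a: float, b: float) -> float:
    """``2 / (1/a + 1/b)``; defined as 0 when either argument is 0."""
    if a < 0 or b < 0:
        raise ValueError("harmonic mean arguments must be non-negative")
    if a == 0.0 or b == 0.0:
        return 0.0
    return 2.0 / (1.0 / a + 1.0 / b)


def midpoint_evaluate(
    truth: Sequence[LabeledSegment],
    pred: Sequence[LabeledSegment],
    unique_matching: bool = False,
) -> EvalReport:
    """Score a predicted alignment with the midpoint protocol.

    With ``unique_matching=True`` each truth segment and each prediction
    participates in at most one hit (first eligible pair in scan order);
    the default reproduces the plain nested-loop counting.
    """
    if not truth or not pred:
        raise ValueError("truth and prediction lists must be non-empty")
    hits = 0
    matches_any_label = 0
    dt_start: list[float] = []
    dt_end: list[float] = []
    used_preds: set[int] = set()
    for tseg in truth:
        mid = tseg.midpoint
        truth_matched = False
        truth_hit = False
        for j, pseg in enumerate(pred):
            if not (pseg.start <= mid <= pseg.end):
                continue
            truth_matched = True
            if tseg.label != pseg.label:
                continue
            if unique_matching and (truth_hit or j in used_preds):
                continue
            hits += 1
            truth_hit = True
            used_preds.add(j)
            dt_start.append(abs(tseg.start - pseg.start))
            dt_end.append(abs(tseg.end - pseg.end))
        if truth_matched:
            matches_any_label += 1
    recall_like = hits / len(truth)
    precision_like = hits / len(pred)
    return EvalReport(
        hits=hits,
        n_truth=len(truth),
        n_pred=len(pred),
        precision_like=precision_like,
        recall_like=recall_like,
        harmonic_mean=harmonic_mean(recall_like, precision_like),
        dt_start=tuple(dt_start),
        dt_end=tuple(dt_end),
        match_fraction=matches_any_label / len(truth),
    )


def onset_evaluate(
    truth: Sequence[LabeledSegment],
    pred: Sequence[LabeledSegment],
    tolerance: float = 0.02,
) -> tuple[float, float, float]:
    """Boundary-onset precision, recall and F1 at the given tolerance.

    Candidate (truth, pred) pairs whose segment starts differ by at most
    ``tolerance`` are matched greedily by increasing time difference, one
    to one; a matched pair is correct when the labels agree.
    """
    if not truth or not pred:
        raise ValueError("truth and prediction lists must be non-empty")
    candidates = sorted(
        (
            (abs(t.start - p.start), ti, pi)
            for ti, t in enumerate(truth)
            for pi, p in enumerate(pred)
            if abs(t.start - p.start) <= tolerance
        ),
    )
    used_t: set[int] = set()
    used_p: set[int] = set()
    correct = 0
    for _, ti, pi in candidates:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        if truth[ti].label == pred[pi].label:
            correct += 1
    precision = correct / len(pred)
    recall = correct / len(truth)
    return precision, recall, harmonic_mean(precision, recall)


def tolerance_table(
    report: EvalReport, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> ToleranceTable:
    """Fractions of hit timing errors strictly below each threshold."""
    if not report.dt_start:
        raise ValueError("report contains no hits")
    n = len(report.dt_start)
    return ToleranceTable(
        thresholds=tuple(thresholds),
        fractions_start=tuple(
            sum(d < th for d in report.dt_start) / n for th in thresholds
        ),
        fractions_end=tuple(
            sum(d < th for d in report.dt_end) / n for th in thresholds
        ),
    )


def per_phone_error_rates(
    truth: Sequence[LabeledSegment], pred: Sequence[LabeledSegment]
) -> dict[str, float]:
    """Per-phone error rate: fraction of that phone's truth segments with
    no midpoint-protocol hit.  Phones absent from the truth are omitted."""
    totals: dict[str, int] = {}
    hit_counts: dict[str, int] = {}
    for tseg in truth:
        totals[tseg.label] = totals.get(tseg.label, 0) + 1
        mid = tseg.midpoint
        hit = any(
            p.start <= mid <= p.end and p.label == tseg.label for p in pred
        )
        if hit:
            hit_counts[tseg.label] = hit_counts.get(tseg.label, 0) + 1
    return {
        phone: 1.0 - hit_counts.get(phone, 0) / n for phone, n in totals.items()
    }
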