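"""Truth-set evaluation of variant call sets and QUAL/DP cutoff optimization.

Given a call set and a table of orthogonally validated variants, this
module classifies every truth entry as TP/FP/TN/FN under a (QUAL, DP)
cutoff pair, derives recall, accuracy, F score and validation rate, and
searches the cutoff grid exhaustively for the pair(s) maximizing F.

Terminology note: in this toolkit "accuracy" is TP/(TP+FP) — the
quantity usually called precision.  The name follows the field usage the
toolkit reproduces; the two are the same number.

A metric with a zero denominator is *undefined* and encoded as ``None``,
never silently 0; undefined F scores are excluded from grid maximization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_io import TruthEntry, VariantKey, VariantRecord

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CutoffCombo",
    "GridResult",
    "confusion_counts",
    "compute_metrics",
    "validation_rate",
    "grid_search",
    "apply_filter",
    "qual_concordance",
    "format_pct",
    "DEFAULT_QUAL_RANGE",
    "DEFAULT_DP_RANGE",
]

#: Default exhaustive grid: QUAL 15..35 and DP 3..15, step 1, inclusive.
DEFAULT_QUAL_RANGE = range(15, 36)
DEFAULT_DP_RANGE = range(3, 16)


class DegenerateGridError(ValueError):
    """No cutoff combination yields a defined F score."""


class AmbiguousCallError(ValueError):
    """A truth key matches more than one call record."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Recall, accuracy (= precision), F score and validation rate.

    ``None`` marks an undefined value (zero denominator).
    """

    recall: Optional[float]
    accuracy: Optional[float]
    f_score: Optional[float]
    validate_rate: Optional[float]


@dataclass(frozen=True, order=True)
class CutoffCombo:
    qual_min: int
    dp_min: int

    def __post_init__(self) -> None:
        if self.qual_min < 0 or self.dp_min < 0:
            raise ValueError("cutoffs must be non-negative")


@dataclass
class GridResult:
    """Exhaustive grid evaluation: one row per cutoff combination.

    ``best_combos`` holds *all* combinations attaining the maximum
    defined F score (ties are reported, not broken).
    """

    rows: list[tuple[CutoffCombo, ConfusionCounts, MetricSet]]
    best_combos: list[CutoffCombo] = field(default_factory=list)

    @property
    def best_f_score(self) -> float:
        best = self.best_combos[0]
        for combo, _, m in self.rows:
            if combo == best:
                assert m.f_score is not None
                return m.f_score
        raise RuntimeError("best combo missing from grid rows")

    def to_dataframe(self) -> pd.DataFrame:
        best = set(self.best_combos)
        recs = []
        for combo, c, m in self.rows:
            recs.append(
                {
                    "qual_min": combo.qual_min,
                    "dp_min": combo.dp_min,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "recall": m.recall,
                    "accuracy": m.accuracy,
                    "f_score": m.f_score,
                    "best_flag": int(combo in best),
                }
            )
        return pd.DataFrame.from_records(recs)


def _index_calls(calls: Iterable[VariantRecord]) -> dict[VariantKey, VariantRecord]:
    index: dict[VariantKey, VariantRecord] = {}
    for rec in calls:
        if rec.key in index:
            raise AmbiguousCallError(f"variant key {rec.key} appears more than once")
        index[rec.key] = rec
    return index


def _predicted(rec: Optional[VariantRecord], cutoff: CutoffCombo) -> bool:
    if rec is None:
        return False
    if rec.qual < cutoff.qual_min:
        return False
    if cutoff.dp_min > 0:
        # records without a DP annotation cannot satisfy a positive depth cutoff
        return rec.dp is not None and rec.dp >= cutoff.dp_min
    return True


def confusion_counts(
    calls: Sequence[VariantRecord],
    truth: Sequence[TruthEntry],
    cutoff: CutoffCombo,
) -> ConfusionCounts:
    """Classify every truth entry under a cutoff pair.

    A truth variant is *predicted* when it is present in the call set and
    passes ``qual >= qual_min`` and ``dp >= dp_min`` (inclusive cutoffs).
    Truth entries absent from the call set count as FN when validated and
    TN when failed; the counts always sum to ``len(truth)``.
    """
    index = _index_calls(calls)
    tp = fp = tn = fn = 0
    for entry in truth:
        pred = _predicted(index.get(entry.key), cutoff)
        if entry.validated:
            if pred:
                tp += 1
            else:
                fn += 1
        else:
            if pred:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Derive recall, accuracy, F and validation rate from confusion counts.

    recall = TP/(TP+FN); accuracy = TP/(TP+FP);
    F = 2*accuracy*recall/(accuracy+recall) = 2*TP/(2*TP+FP+FN);
    validate_rate = (TP+FN)/total — the fraction of evaluated variants
    that are experimentally true, independent of any cutoff.
    """
    return MetricSet(
        recall=_ratio(c.tp, c.tp + c.fn),
        accuracy=_ratio(c.tp, c.tp + c.fp),
        f_score=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        validate_rate=_ratio(c.tp + c.fn, c.total),
    )


def validation_rate(n_validated: int, n_total: int) -> float:
    """Fraction of candidates confirmed by the orthogonal assay."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_validated <= n_total:
        raise ValueError("need 0 <= n_validated <= n_total")
    return n_validated / n_total


def grid_search(
    calls: Sequence[VariantRecord],
    truth: Sequence[TruthEntry],
    qual_range: Iterable[int] = DEFAULT_QUAL_RANGE,
    dp_range: Iterable[int] = DEFAULT_DP_RANGE,
) -> GridResult:
    """Evaluate every (qual_min, dp_min) combination exhaustively.

    Returns the full per-combination table and all combinations attaining
    the maximum defined F score.  Raises DegenerateGridError when no
    combination yields a defined F score.
    """
    qual_vals = list(qual_range)
    dp_vals = list(dp_range)
    if not qual_vals or not dp_vals:
        raise ValueError("cutoff ranges must be non-empty")
    rows: list[tuple[CutoffCombo, ConfusionCounts, MetricSet]] = []
    for q in qual_vals:
        for d in dp_vals:
            combo = CutoffCombo(qual_min=q, dp_min=d)
            c = confusion_counts(calls, truth, combo)
            rows.append((combo, c, compute_metrics(c)))
    defined = [(combo, m.f_score) for combo, _, m in rows if m.f_score is not None]
    if not defined:
        raise DegenerateGridError(
            "grid is degenerate: no cutoff combination yields a defined F score"
        )
    best_f = max(f for _, f in defined)
    best = [combo for combo, f in defined if f == best_f]
    return GridResult(rows=rows, best_combos=best)


def apply_filter(
    calls: Sequence[VariantRecord],
    qual_min: float = 0.0,
    dp_min: int = 3,
    dp_max: float = 10_000,
) -> list[VariantRecord]:
    """Retain records with qual >= qual_min and dp_min <= dp <= dp_max.

    Defaults reproduce the classic varFilter depth bounds (at least 3 and
    at most 10,000 reads).  Records without a DP annotation are removed
    whenever a depth bound is active.  Input order is preserved.
    """
    if dp_min > dp_max:
        raise ValueError("dp_min must not exceed dp_max")
    depth_active = dp_min > 0 or dp_max < math.inf
    kept = []
    for rec in calls:
        if rec.qual < qual_min:
            continue
        if depth_active:
            if rec.dp is None or not dp_min <= rec.dp <= dp_max:
                continue
        kept.append(rec)
    return kept


def qual_concordance(
    set_a: Sequence[VariantRecord], set_b: Sequence[VariantRecord]
) -> tuple[float, float, int]:
    """Compare QUAL scores of two call sets matched on variant key.

    Returns ``(pearson_r, frac_a_higher, n_matched)`` where
    ``frac_a_higher`` is the fraction of matched pairs with strictly
    higher QUAL in ``set_a``.  Raises on <2 matched pairs or when either
    matched QUAL vector has zero variance.
    """
    index_b = _index_calls(set_b)
    pairs = [(a.qual, index_b[a.key].qual) for a in set_a if a.key in index_b]
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 matched pairs, got {len(pairs)}")
    qa = np.array([p[0] for p in pairs], dtype=float)
    qb = np.array([p[1] for p in pairs], dtype=float)
    if qa.std() == 0 or qb.std() == 0:
        raise ValueError("QUAL variance is zero in a matched set")
    r = float(np.corrcoef(qa, qb)[0, 1])
    frac = float(np.mean(qa > qb))
    return r, frac, len(pairs)


def format_pct(x: Optional[float]) -> str:
    """Render a proportion as a percentage with 2 decimals, round-half-up."""
    if x is None:
        return "NA"
    q = (Decimal(repr(x)) * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{q}%"
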