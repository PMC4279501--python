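"""Scoring predicted gears against reference labels.

The reference (in the original study, frame-by-frame video analysis) is
given as gear intervals over time; predictions are per-cycle.  Each
cycle receives the reference gear whose interval overlaps it most, then
predictions are scored with a 5×5 confusion matrix (reference rows,
predicted columns), overall and per-gear accuracies, and a breakdown of
errors into start-up, transition-phase and other — transitions between
gears being where misclassification concentrates.  The two inferential
statistics used to compare training regimes and relate accuracy to
transition counts (paired t-test, Pearson correlation) are included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError
from .gears import GEARS, gear_index
from .io import LabelInterval
from .preprocess import CycleSegment

#: sentinel reference label for cycles not covered by any interval
UNLABELED = None


def align_labels(intervals: Sequence[LabelInterval],
                 segments: Sequence[CycleSegment]) -> list[str | None]:
    """Assign each cycle the reference gear with the largest time overlap.

    Ties go to the earlier interval; cycles with zero overlap receive
    ``None`` (UNLABELED) and are excluded from scoring downstream.
    """
    labels: list[str | None] = []
    for seg in segments:
        best_gear, best_overlap = None, 0.0
        for iv in intervals:
            overlap = min(seg.end, iv.end) - max(seg.start, iv.start)
            if overlap > best_overlap + 1e-12:
                best_gear, best_overlap = iv.gear, overlap
        labels.append(best_gear)
    return labels


@dataclass
class ConfusionMatrix:
    """5×5 reference-by-predicted cycle counts in canonical gear order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(GEARS), len(GEARS)):
            raise ValidationError(f"counts must be 5x5, got {c.shape}")
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = c.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalized percentages; NaN rows where a gear never occurs."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(GEARS),
                            columns=list(GEARS))

    def format_table(self) -> str:
        """Text table with 'n (pct%)' cells, reference rows."""
        pct = self.row_percentages()
        header = "ref\\pred" + "".join(f"{g:>12}" for g in GEARS)
        lines = [header]
        for i, g in enumerate(GEARS):
            cells = []
            for j in range(len(GEARS)):
                if np.isnan(pct[i, j]):
                    cells.append(f"{self.counts[i, j]} (-)")
                else:
                    cells.append(f"{self.counts[i, j]} ({pct[i, j]:.0f}%)")
            lines.append(f"{g:<8}" + "".join(f"{c:>12}" for c in cells))
        return "\n".join(lines)


def confusion_matrix(predictions: Sequence[str],
                     references: Sequence[str]) -> ConfusionMatrix:
    """Count reference-vs-predicted gears over aligned cycle sequences."""
    if len(predictions) != len(references):
        raise ValidationError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(references)} references"
        )
    counts = np.zeros((len(GEARS), len(GEARS)), dtype=int)
    for p, r in zip(predictions, references):
        counts[gear_index(r), gear_index(p)] += 1
    return ConfusionMatrix(counts)


def accuracy_summary(cm: ConfusionMatrix) -> dict:
    """Overall and per-gear percent correct (diagonal over row sum).

    Gears that never occur in the reference are reported as ``None``.
    Raises for an empty matrix.
    """
    if cm.total == 0:
        raise DegenerateInputError("cannot summarize an empty confusion matrix")
    diag = np.diag(cm.counts)
    row_sums = cm.counts.sum(axis=1)
    per_gear = {
        g: (100.0 * diag[i] / row_sums[i]) if row_sums[i] > 0 else None
        for i, g in enumerate(GEARS)
    }
    return {
        "overall_pct": 100.0 * diag.sum() / cm.total,
        "per_gear_pct": per_gear,
        "n_cycles": cm.total,
    }


@dataclass(frozen=True)
class ErrorBreakdown:
    """Misclassifications split into start-up / transition / other.

    Categories are assigned with precedence startup > transition, so
    the three counts sum to the total number of errors.
    """

    n_startup_errors: int
    n_transition_errors: int
    n_other_errors: int

    @property
    def total_errors(self) -> int:
        return (self.n_startup_errors + self.n_transition_errors
                + self.n_other_errors)

    def _frac(self, n: int) -> float:
        return n / self.total_errors if self.total_errors else 0.0

    @property
    def startup_fraction(self) -> float:
        return self._frac(self.n_startup_errors)

    @property
    def transition_fraction(self) -> float:
        return self._frac(self.n_transition_errors)

    @property
    def other_fraction(self) -> float:
        return self._frac(self.n_other_errors)


def error_breakdown(predictions: Sequence[str], references: Sequence[str],
                    k: int = 3, w: int = 1) -> ErrorBreakdown:
    """Categorize misclassified cycles.

    A misclassified cycle at index ``j`` is a *startup* error if
    ``j < k`` (first k cycles of the recording), else a *transition*
    error if it lies within ``w`` cycles of a reference gear change —
    with the change starting at cycle ``c``, the window is
    ``c - w <= j <= c + w - 1``, i.e. the last ``w`` cycles of the old
    gear and the first ``w`` of the new — else an *other* error.
    """
    if len(predictions) != len(references):
        raise ValidationError("predictions and references differ in length")
    changes = [i for i in range(1, len(references))
               if references[i] != references[i - 1]]
    n_start = n_trans = n_other = 0
    for j, (p, r) in enumerate(zip(predictions, references)):
        if p == r:
            continue
        if j < k:
            n_start += 1
        elif any(c - w <= j <= c + w - 1 for c in changes):
            n_trans += 1
        else:
            n_other += 1
    return ErrorBreakdown(n_start, n_trans, n_other)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Classical paired-sample t-test on the differences b − a.

    Returns the t statistic, degrees of freedom n−1 and the two-sided
    p-value from the t distribution.  If every difference is zero the
    result is (0, n−1, 1); identical nonzero differences make the
    statistic undefined and raise :class:`DegenerateInputError`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise DegenerateInputError("paired t-test needs n >= 2")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TTestResult(0.0, n - 1, 1.0)
        raise DegenerateInputError(
            "all paired differences are identical and nonzero; "
            "t statistic undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D and equal length")
    if x.size < 3:
        raise DegenerateInputError("pearson_r needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("pearson_r undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_report(predictions: Sequence[str],
                    references: Sequence[str | None],
                    k: int = 3, w: int = 1) -> dict:
    """Full evaluation of aligned per-cycle predictions.

    Cycles with ``None`` reference are excluded from scoring.  Returns a
    JSON-serializable dict with the confusion matrix (counts and row
    percentages), accuracy summary and error breakdown.
    """
    pairs = [(p, r) for p, r in zip(predictions, references) if r is not None]
    preds = [p for p, _ in pairs]
    refs = [r for _, r in pairs]
    cm = confusion_matrix(preds, refs)
    report: dict = {
        "n_scored_cycles": len(pairs),
        "n_unlabeled_cycles": len(predictions) - len(pairs),
        "confusion_counts": cm.counts.tolist(),
        "gear_order": list(GEARS),
    }
    pct = cm.row_percentages()
    report["confusion_row_pct"] = [
        [None if np.isnan(v) else float(v) for v in row] for row in pct
    ]
    if pairs:
        report["accuracy"] = accuracy_summary(cm)
        bd = error_breakdown(preds, refs, k=k, w=w)
        report["error_breakdown"] = {
            "n_startup_errors": bd.n_startup_errors,
            "n_transition_errors": bd.n_transition_errors,
            "n_other_errors": bd.n_other_errors,
            "startup_fraction": bd.startup_fraction,
            "transition_fraction": bd.transition_fraction,
            "other_fraction": bd.other_fraction,
            "startup_window_cycles": k,
            "transition_window_cycles": w,
        }
    return report
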