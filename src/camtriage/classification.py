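"""Threshold classification, ROC curves, operating points and time savings.

Convention (inverted from the usual ML orientation): the *positive* class is
the non-target recording, because correctly discarding an empty video is the
success being counted.  A recording is discarded when its D value is strictly
below the threshold; ties are kept for inspection, which is conservative
toward not losing target footage.

* TP-rate = discarded non-target / all non-target (the workload saved),
* FP-rate = discarded target / all target (the footage lost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabeledRecording",
    "ClassificationMatrix",
    "RocCurve",
    "OperatingPoint",
    "classify",
    "confusion",
    "rates",
    "roc_curve",
    "auc",
    "threshold_for_fp",
    "time_savings",
]

LABELS = ("target", "non-target")
CONDITIONS = ("dry", "wet", "unknown")


@dataclass(frozen=True)
class LabeledRecording:
    """One recording: its D value(s), manual label, condition and duration."""

    source_id: str
    d_values: dict
    label: str
    condition: str = "unknown"
    duration_s: float = 15.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for m, d in self.d_values.items():
            if d < 0:
                raise ValueError(f"negative D value {d} for method {m!r}")

    def d(self, method: str) -> float:
        try:
            return float(self.d_values[method])
        except KeyError:
            raise KeyError(
                f"recording {self.source_id!r} has no D value for method {method!r}"
            )


@dataclass(frozen=True)
class ClassificationMatrix:
    """Confusion counts with positive = non-target.

    tp: non-target discarded, fp: target discarded,
    fn: non-target kept,      tn: target kept.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_nontarget(self) -> int:
        return self.tp + self.fn

    @property
    def n_target(self) -> int:
        return self.fp + self.tn

    @property
    def n_discarded(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep: one (threshold, fp_rate, tp_rate) point per candidate
    threshold, ordered by increasing threshold."""

    thresholds: np.ndarray
    fp_rates: np.ndarray
    tp_rates: np.ndarray
    method: str
    condition: str = "all"

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.fp_rates, self.tp_rates))


@dataclass(frozen=True)
class OperatingPoint:
    """A chosen working threshold with its achieved rates and payoff."""

    threshold: float
    achieved_fp_rate: float
    achieved_tp_rate: float
    discarded_count: int
    time_savings_min: float
    method: str = ""


def classify(d_value: float, threshold: float) -> str:
    """Discard iff D < threshold (strict); a tie is kept for inspection."""
    return "discard" if d_value < threshold else "keep"


def confusion(
    recordings: Sequence[LabeledRecording], threshold: float, method: str
) -> ClassificationMatrix:
    """Confusion matrix at a threshold (positive class = non-target)."""
    tp = fp = fn = tn = 0
    for r in recordings:
        below = r.d(method) < threshold
        if r.label == "non-target":
            tp += below
            fn += not below
        else:
            fp += below
            tn += not below
    return ClassificationMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def rates(m: ClassificationMatrix) -> tuple[float, float]:
    """(tp_rate, fp_rate) = (tp/(tp+fn), fp/(fp+tn))."""
    if m.n_nontarget == 0 or m.n_target == 0:
        raise ValueError("rates undefined: one class is empty")
    return m.tp / m.n_nontarget, m.fp / m.n_target


def _candidate_thresholds(d: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct D values plus sentinels just
    below the minimum and above the maximum, so achieved rates are stable to
    infinitesimal threshold perturbation."""
    u = np.unique(d)
    lo = u[0] - 1.0
    hi = u[-1] + 1.0
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[lo], mids, [hi]])


def _check_both_classes(recordings: Sequence[LabeledRecording]) -> None:
    labels = {r.label for r in recordings}
    if labels != set(LABELS):
        raise ValueError(f"both classes required; got only {sorted(labels)}")


def roc_curve(
    recordings: Sequence[LabeledRecording], method: str, condition: str = "all"
) -> RocCurve:
    """Sweep the threshold over the full range of D values.

    Both rates are non-decreasing in the threshold; the sentinel endpoints
    give (0, 0) and (1, 1).
    """
    _check_both_classes(recordings)
    d = np.array([r.d(method) for r in recordings])
    is_pos = np.array([r.label == "non-target" for r in recordings])
    thr = _candidate_thresholds(d)
    # below[i, j] = recording j discarded at threshold i
    below = d[None, :] < thr[:, None]
    n_pos = int(is_pos.sum())
    n_neg = len(recordings) - n_pos
    tp_rates = below[:, is_pos].sum(axis=1) / n_pos
    fp_rates = below[:, ~is_pos].sum(axis=1) / n_neg
    return RocCurve(
        thresholds=thr,
        fp_rates=fp_rates,
        tp_rates=tp_rates,
        method=method,
        condition=condition,
    )


def auc(curve: RocCurve) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    return float(np.trapezoid(curve.tp_rates, curve.fp_rates))


def time_savings(m: ClassificationMatrix, duration_s: float = 15.0) -> float:
    """Minutes of footage not watched: every discarded recording, correctly
    or not, skips visual inspection."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return m.n_discarded * duration_s / 60.0


def threshold_for_fp(
    recordings: Sequence[LabeledRecording], method: str, tolerated_fp: float
) -> OperatingPoint:
    """Largest candidate threshold whose FP-rate stays within tolerance.

    Maximises discarding subject to fp_rate <= tolerated_fp: the cost
    asymmetry is losing target footage, so the tolerance is a hard cap, not a
    target to approach from above.  If no non-trivial threshold satisfies the
    cap, the below-minimum sentinel with rates (0, 0) is returned.
    """
    if not 0 <= tolerated_fp < 1:
        raise ValueError("tolerated_fp must be in [0, 1)")
    curve = roc_curve(recordings, method)
    ok = np.flatnonzero(curve.fp_rates <= tolerated_fp)
    i = int(ok[-1])  # fp_rates are non-decreasing, so the last ok index is maximal
    thr = float(curve.thresholds[i])
    m = confusion(recordings, thr, method)
    saved = sum(r.duration_s for r in recordings if r.d(method) < thr) / 60.0
    return OperatingPoint(
        threshold=thr,
        achieved_fp_rate=float(curve.fp_rates[i]),
        achieved_tp_rate=float(curve.tp_rates[i]),
        discarded_count=m.n_discarded,
        time_savings_min=saved,
        method=method,
    )


def subset_by_condition(
    recordings: Iterable[LabeledRecording], condition: str
) -> list[LabeledRecording]:
    """Filter recordings by condition; 'all' passes everything through."""
    if condition == "all":
        return list(recordings)
    return [r for r in recordings if r.condition == condition]
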