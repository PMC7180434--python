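"""Binary-classification metrics for vessel-vs-other tissue recognition.

The positive class is the blood-vessel group (artery + vein); everything
else (skin, fat, muscle, lung, pleural cavity) is the negative "other"
group. Performance is summarised by the F-measure, the harmonic mean of
positive predictive value (precision) and sensitivity (recall):

    F = 2 * PPV * sensitivity / (PPV + sensitivity)

Degenerate counts (0/0 denominators) yield ``None`` — explicitly undefined
— rather than a coerced 0 or 1, so threshold sweeps cannot silently prefer
a vacuous operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import DomainError

__all__ = [
    "VESSEL",
    "OTHER",
    "ConfusionMatrix",
    "Metrics",
    "confusion",
    "metrics",
    "f_measure",
    "invert_f_measure",
    "sweep_table",
]

VESSEL = "vessel"
OTHER = "other"
_LABELS = {VESSEL, OTHER}


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with vessel as the positive class.

    TP: vessel recognised as vessel; FP: other recognised as vessel;
    TN: other recognised as other; FN: vessel recognised as other.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one item")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Derived metrics; a ``None`` field means its denominator was zero."""

    ppv: Optional[float]
    sensitivity: Optional[float]
    accuracy: float
    f_measure: Optional[float]

    def as_dict(self) -> dict:
        return {
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
        }


def _validate_labels(labels: Sequence[str], name: str) -> None:
    bad = set(labels) - _LABELS
    if bad:
        raise DomainError(f"unknown {name} label(s) {sorted(bad)}; expected {sorted(_LABELS)}")


def confusion(labels_true: Sequence[str], labels_pred: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix from true/predicted 'vessel'/'other' labels."""
    if len(labels_true) != len(labels_pred):
        raise DomainError(
            f"label lengths differ: {len(labels_true)} true vs {len(labels_pred)} predicted"
        )
    _validate_labels(labels_true, "true")
    _validate_labels(labels_pred, "predicted")
    tp = fp = tn = fn = 0
    for t, p in zip(labels_true, labels_pred):
        if t == VESSEL:
            if p == VESSEL:
                tp += 1
            else:
                fn += 1
        else:
            if p == VESSEL:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


def f_measure(ppv: float, sensitivity: float) -> Optional[float]:
    """Harmonic mean of precision and recall; None when both are zero."""
    if ppv + sensitivity == 0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def metrics(cm: ConfusionMatrix) -> Metrics:
    """PPV, sensitivity, accuracy and F-measure from a confusion matrix."""
    ppv = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    acc = (cm.tp + cm.tn) / cm.total
    f = f_measure(ppv, sens) if (ppv is not None and sens is not None) else None
    return Metrics(ppv, sens, acc, f)


def invert_f_measure(
    f: float,
    *,
    ppv: Optional[float] = None,
    sensitivity: Optional[float] = None,
) -> float:
    """Recover the missing metric from an F-measure and its partner.

    Solving F = 2ps/(p+s) for the unknown gives known*F / (2*known - F);
    the pair is infeasible when 2*known <= F (the harmonic mean can never
    exceed twice the smaller operand).
    """
    if not (0.0 < f <= 1.0):
        raise DomainError(f"F-measure {f} outside (0, 1]")
    if (ppv is None) == (sensitivity is None):
        raise DomainError("provide exactly one of ppv= or sensitivity=")
    known = ppv if ppv is not None else sensitivity
    denom = 2.0 * known - f
    if denom <= 0:
        raise DomainError(
            f"infeasible pair: F = {f} cannot arise with a partner metric of {known}"
        )
    return known * f / denom


def sweep_table(
    scores: Iterable[float],
    labels_true: Sequence[str],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Metrics at every decision threshold in ``grid``.

    A sample is predicted vessel when its score is strictly above the
    threshold. Returns one row per threshold with the confusion counts and
    derived metrics (NaN where undefined).
    """
    if len(grid) == 0:
        raise DomainError("threshold grid is empty")
    scores = list(scores)
    rows = []
    for t in grid:
        pred = [VESSEL if s > t else OTHER for s in scores]
        cm = confusion(labels_true, pred)
        m = metrics(cm)
        rows.append(
            {
                "threshold": t,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "ppv": m.ppv,
                "sensitivity": m.sensitivity,
                "accuracy": m.accuracy,
                "f_measure": m.f_measure,
            }
        )
    return pd.DataFrame(rows)
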