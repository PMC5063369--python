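"""Confusion counts and derived diagnostic metrics.

All metrics are kept as exact rationals (`fractions.Fraction`) internally;
rounding happens only in the display layer, half-up to one decimal percent.
A metric whose denominator is empty (e.g. PPV with no predicted positives)
is UNDEFINED, represented as ``None`` and rendered as an em dash — it is a
value, not an error, and propagates through reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "confusion",
    "metrics_from_counts",
    "format_percent",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion tallies; ``tp`` counts predicted-positive & label-positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be nonnegative")
        if sum(counts) == 0:
            raise ValueError("confusion counts must total > 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions, labels) -> ConfusionCounts:
    """Tally a binary prediction vector against the reference labels."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {lab.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(np.sum(pred & lab)),
        fp=int(np.sum(pred & ~lab)),
        tn=int(np.sum(~pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy, Se, Sp, PPV, NPV and Youden's J, as exact rationals.

    ``youden_j = sensitivity + specificity - 1`` exactly; it is UNDEFINED
    (None) whenever either addend is.
    """

    counts: ConfusionCounts
    accuracy: Fraction
    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None

    @property
    def youden_j(self) -> Fraction | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1

    def display_row(self) -> dict[str, str]:
        """Counts + percents in the standard report column order."""
        c = self.counts
        return {
            "accuracy": _cell(c.tp + c.tn, c.total, self.accuracy),
            "sensitivity": _cell(c.tp, c.tp + c.fn, self.sensitivity),
            "specificity": _cell(c.tn, c.tn + c.fp, self.specificity),
            "ppv": _cell(c.tp, c.tp + c.fp, self.ppv),
            "npv": _cell(c.tn, c.tn + c.fn, self.npv),
        }


def _frac(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def metrics_from_counts(c: ConfusionCounts) -> DiagnosticMetrics:
    """Derive all diagnostic metrics from a confusion table, exactly."""
    return DiagnosticMetrics(
        counts=c,
        accuracy=Fraction(c.tp + c.tn, c.total),
        sensitivity=_frac(c.tp, c.tp + c.fn),
        specificity=_frac(c.tn, c.tn + c.fp),
        ppv=_frac(c.tp, c.tp + c.fp),
        npv=_frac(c.tn, c.tn + c.fn),
    )


def format_percent(value: Fraction | float | None, decimals: int = 1) -> str:
    """Render a proportion as a percent, half-up at ``decimals`` places.

    UNDEFINED (None) renders as an em dash.
    """
    if value is None:
        return "—"
    if isinstance(value, Fraction):
        d = Decimal(value.numerator * 100) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value) * 100))
    q = Decimal(1).scaleb(-decimals)
    return f"{d.quantize(q, rounding=ROUND_HALF_UP)}%"


def _cell(num: int, den: int, value: Fraction | None) -> str:
    if value is None:
        return "—"
    return f"{num}/{den}({format_percent(value)})"
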