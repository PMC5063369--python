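"""Single-parameter optimal cutoffs and ROC analysis.

The decision orientation is fixed throughout the package: a node is called
positive when the parameter is ``>= cutoff``.  Candidate cutoffs are the
observed values, the midpoints between adjacent observed values snapped to
the measurement grid, plus one grid step above the maximum (the "call
everything negative" candidate), so the scan is exhaustive: the decision
function can only change at observed values.

Two optimality criteria are supported: raw accuracy, and Youden's index
J = sensitivity + specificity - 1.  When several cutoffs tie, the largest
cutoff wins — the most conservative choice, calling the fewest positives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._grid import DIAMETER_RES, SUV_RES, snap
from .cohort import Cohort
from .metrics import ConfusionCounts, DiagnosticMetrics, metrics_from_counts

__all__ = [
    "Criterion",
    "CutoffResult",
    "CutoffScan",
    "RocResult",
    "scan_cutoffs",
    "roc_curve",
    "parameter_resolution",
]


class Criterion(enum.Enum):
    ACCURACY = "accuracy"
    YOUDEN = "youden"


def parameter_resolution(parameter: str) -> float:
    return SUV_RES if parameter == "nsuv" else DIAMETER_RES


@dataclass(frozen=True)
class CutoffResult:
    """The optimal cutoff for one parameter under one criterion."""

    parameter: str
    cutoff: float
    criterion: Criterion
    accuracy: Fraction
    youden_j: Fraction | None
    n_correct: int
    n_total: int
    metrics: DiagnosticMetrics


@dataclass(frozen=True)
class CutoffScan:
    """Best cutoff plus the full audit table of every candidate."""

    best: CutoffResult
    table: pd.DataFrame


def candidate_cutoffs(values: np.ndarray, res: float) -> np.ndarray:
    """Observed values, grid-snapped midpoints, and one step past the max."""
    obs = np.unique(snap(values, res))
    mids = snap((obs[:-1] + obs[1:]) / 2.0, res) if obs.size > 1 else np.empty(0)
    top = snap(obs[-1] + res, res)
    return np.unique(np.concatenate([obs, mids, [top]]))


def _extract(cohort: Cohort, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    v = cohort.values(parameter)
    if np.isnan(v).any():
        raise ValueError(f"parameter {parameter!r} is missing for some records")
    labels = cohort.labels
    if labels.all() or not labels.any():
        raise ValueError("cohort must contain both classes")
    return v, labels


def scan_cutoffs(
    cohort: Cohort, parameter: str, criterion: Criterion = Criterion.ACCURACY
) -> CutoffScan:
    """Exhaustive cutoff scan for one parameter.

    Returns the maximizing cutoff under ``criterion`` (largest cutoff on
    ties) together with the full scan table for audit.
    """
    res = parameter_resolution(parameter)
    v, labels = _extract(cohort, parameter)
    cands = candidate_cutoffs(v, res)

    pos = np.sort(v[labels])
    neg = np.sort(v[~labels])
    n_pos, n_neg = pos.size, neg.size
    # "value >= cutoff" counts via searchsorted on each class
    tp = n_pos - np.searchsorted(pos, cands, side="left")
    fp = n_neg - np.searchsorted(neg, cands, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    acc = (tp + tn) / (n_pos + n_neg)
    j = tp / n_pos + tn / n_neg - 1.0

    table = pd.DataFrame(
        {
            "cutoff": cands,
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "accuracy": acc,
            "youden_j": j,
        }
    )

    score = acc if criterion is Criterion.ACCURACY else j
    # ties -> largest cutoff: candidates ascend, take the last argmax
    i = int(np.flatnonzero(score >= score.max() - 1e-12)[-1])
    counts = ConfusionCounts(tp=int(tp[i]), fp=int(fp[i]), tn=int(tn[i]), fn=int(fn[i]))
    m = metrics_from_counts(counts)
    best = CutoffResult(
        parameter=parameter,
        cutoff=float(cands[i]),
        criterion=criterion,
        accuracy=m.accuracy,
        youden_j=m.youden_j,
        n_correct=counts.tp + counts.tn,
        n_total=counts.total,
        metrics=m,
    )
    return CutoffScan(best=best, table=table)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with trapezoidal AUC and bootstrap 95% CI."""

    parameter: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]


def _empirical_auc(values: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, _ = _sk_roc_curve(labels, values)
    return float(np.trapezoid(tpr, fpr))


def roc_curve(
    cohort: Cohort,
    parameter: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC over all distinct thresholds, AUC by trapezoid.

    The 95% CI on the AUC is a stratified bootstrap (resampling positives
    and negatives separately, ``n_boot`` replicates, percentile interval).
    """
    v, labels = _extract(cohort, parameter)
    fpr, tpr, thr = _sk_roc_curve(labels, v)
    auc = float(np.trapezoid(tpr, fpr))

    rng = np.random.default_rng(seed)
    pos = v[labels]
    neg = v[~labels]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        bv = np.concatenate([bp, bn])
        bl = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        reps[b] = _empirical_auc(bv, bl)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return RocResult(
        parameter=parameter,
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_ci95=(float(lo), float(hi)),
    )
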