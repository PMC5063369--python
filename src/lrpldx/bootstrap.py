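"""Bootstrap comparison of two decision rules' accuracy.

Each replicate draws ``n_cases_per_replicate`` nodes with replacement and
evaluates *both* rules on the same draw (a paired design, so the
difference distribution is free of between-draw variance).  The summary
is the median (or mean) of the replicate accuracies with a percentile
95% CI; in MEAN mode a paired t-test over the replicate accuracy pairs is
added.  The t-test treats the replicate accuracies as independent
observations — they are resamples of one cohort, not independent samples,
so its p-value is a descriptive index rather than a calibrated error
rate; the CI overlap of the two replicate distributions is the primary
comparison.

The sampling unit is the node by default; ``cluster_by_patient=True``
resamples whole patients instead, respecting within-patient correlation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .rules import RuleSpec, apply_rule

__all__ = [
    "SummaryMode",
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_accuracy_compare",
]


class SummaryMode(enum.Enum):
    MEDIAN = "median"
    MEAN = "mean"


@dataclass(frozen=True)
class BootstrapConfig:
    n_cases_per_replicate: int = 100
    n_replicates: int = 100
    seed: int = 0
    summary: SummaryMode = SummaryMode.MEDIAN
    cluster_by_patient: bool = False

    def __post_init__(self) -> None:
        if self.n_cases_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    acc_a: np.ndarray = field(repr=False)
    acc_b: np.ndarray = field(repr=False)
    summary_mode: SummaryMode
    summary_a: float
    summary_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    ci_overlap: bool
    overlap_extent: float
    t_statistic: float | None
    p_value: float | None

    def replicate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(1, self.acc_a.size + 1),
                "accuracy_a": self.acc_a,
                "accuracy_b": self.acc_b,
                "difference": self.acc_a - self.acc_b,
            }
        )


def _percentile_ci(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_accuracy_compare(
    cohort: Cohort,
    rule_a: RuleSpec,
    rule_b: RuleSpec,
    config: BootstrapConfig = BootstrapConfig(),
) -> BootstrapResult:
    """Paired bootstrap of the accuracies of two rules on one cohort.

    Replicates that happen to contain a single class are kept (accuracy
    is still defined).  With identical rules every paired difference is
    exactly zero and the t statistic is UNDEFINED (None).
    """
    labels = cohort.labels
    correct_a = apply_rule(rule_a, cohort) == labels
    correct_b = apply_rule(rule_b, cohort) == labels

    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    b = config.n_replicates
    m = config.n_cases_per_replicate

    if config.cluster_by_patient:
        patients = np.array([r.patient_id for r in cohort.records])
        uniq = np.unique(patients)
        groups = {p: np.flatnonzero(patients == p) for p in uniq}
        acc_a = np.empty(b)
        acc_b = np.empty(b)
        for i in range(b):
            idx_parts = []
            while sum(len(p) for p in idx_parts) < m:
                idx_parts.append(groups[rng.choice(uniq)])
            idx = np.concatenate(idx_parts)[:m]
            acc_a[i] = correct_a[idx].mean()
            acc_b[i] = correct_b[idx].mean()
    else:
        draws = rng.integers(0, n, size=(b, m))
        acc_a = correct_a[draws].mean(axis=1)
        acc_b = correct_b[draws].mean(axis=1)

    if config.summary is SummaryMode.MEDIAN:
        sa, sb = float(np.median(acc_a)), float(np.median(acc_b))
        t_stat = p_val = None
    else:
        sa, sb = float(np.mean(acc_a)), float(np.mean(acc_b))
        diffs = acc_a - acc_b
        if np.allclose(diffs, diffs[0]) and np.std(diffs) == 0:
            t_stat = p_val = None  # zero-variance differences: t UNDEFINED
        else:
            t = stats.ttest_rel(acc_a, acc_b)
            t_stat, p_val = float(t.statistic), float(t.pvalue)

    ci_a = _percentile_ci(acc_a)
    ci_b = _percentile_ci(acc_b)
    extent = min(ci_a[1], ci_b[1]) - max(ci_a[0], ci_b[0])
    return BootstrapResult(
        acc_a=acc_a,
        acc_b=acc_b,
        summary_mode=config.summary,
        summary_a=sa,
        summary_b=sb,
        ci_a=ci_a,
        ci_b=ci_b,
        ci_overlap=extent >= 0,
        overlap_extent=float(extent),
        t_statistic=t_stat,
        p_value=p_val,
    )
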