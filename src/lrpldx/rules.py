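"""Combined multi-threshold decision rules and their exhaustive search.

Three rule templates are supported, all MIAD-first (a node with
MIAD >= c_miad is always called positive; the secondary clauses only act
on the remaining nodes):

* ``AND_RULE``:    positive iff miad >= c1  or (maad >= c2 and macd >= c3)
* ``OR_RULE``:     positive iff miad >= c1  or (maad >= c2 or  macd >= c3)
* ``STAGE2_RULE``: positive iff miad >= c1  or  nsuv >= c4
                   or (macd >= c3 and maad >= c2)

The search ("brute force attack" in the clinical literature that coined
the workflow: an exhaustive key search over every candidate cutoff
combination) enumerates all cutoff vectors on the measurement grid
spanned by the observed values, plus a degenerate +inf sentinel per
secondary parameter that disables its clause — so the single-MIAD-cutoff
baseline is always inside the search space and the optimum can never fall
below it.

The enumeration is exact but does not loop over rules one by one: because
a node's prediction under the diameter clause is a 2-D survival indicator
(maad >= c2 and macd >= c3), correct-count surfaces over the whole
(c2, c3) grid are obtained from 2-D suffix-sums of class histograms, and
the SUV threshold adds one outer sweep.  The result is identical to the
naive quadruple loop (a standing test asserts this on small cohorts).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

from ._grid import DIAMETER_RES, SUV_RES, snap
from .cohort import Cohort
from .cutoffs import Criterion, CutoffResult, scan_cutoffs
from .metrics import DiagnosticMetrics, confusion, metrics_from_counts

__all__ = [
    "RuleTemplate",
    "error_accounting",
    "RuleSpec",
    "SearchResult",
    "BaselineComparison",
    "apply_rule",
    "apply_rule_to_arrays",
    "brute_force_search",
    "compare_to_baseline",
]

INF = math.inf


class RuleTemplate(enum.Enum):
    AND_RULE = "and"
    OR_RULE = "or"
    STAGE2_RULE = "stage2"


@dataclass(frozen=True)
class RuleSpec:
    """A parameterized decision rule: template + cutoff vector.

    A cutoff of +inf disables its clause (degenerate sentinel).  Finite
    cutoffs are snapped to the measurement grid (0.1 mm / 0.01 SUV).
    """

    template: RuleTemplate
    c_miad: float
    c_maad: float = INF
    c_macd: float = INF
    c_nsuv: float = INF

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_miad", snap(self.c_miad, DIAMETER_RES))
        object.__setattr__(self, "c_maad", snap(self.c_maad, DIAMETER_RES))
        object.__setattr__(self, "c_macd", snap(self.c_macd, DIAMETER_RES))
        object.__setattr__(self, "c_nsuv", snap(self.c_nsuv, SUV_RES))
        if self.template is not RuleTemplate.STAGE2_RULE and np.isfinite(self.c_nsuv):
            raise ValueError("c_nsuv only applies to STAGE2_RULE")

    def as_dict(self) -> dict:
        return {
            "template": self.template.value,
            "c_miad": self.c_miad,
            "c_maad": self.c_maad,
            "c_macd": self.c_macd,
            "c_nsuv": self.c_nsuv,
        }


def apply_rule_to_arrays(
    rule: RuleSpec,
    miad: np.ndarray,
    maad: np.ndarray,
    macd: np.ndarray,
    nsuv: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate a rule on raw measurement arrays (pure, order-preserving)."""
    primary = miad >= rule.c_miad
    if rule.template is RuleTemplate.AND_RULE:
        secondary = (maad >= rule.c_maad) & (macd >= rule.c_macd)
    elif rule.template is RuleTemplate.OR_RULE:
        secondary = (maad >= rule.c_maad) | (macd >= rule.c_macd)
    else:
        if nsuv is None:
            raise ValueError("STAGE2_RULE requires the SUV channel")
        secondary = (nsuv >= rule.c_nsuv) | (
            (macd >= rule.c_macd) & (maad >= rule.c_maad)
        )
    return primary | secondary


def apply_rule(rule: RuleSpec, cohort: Cohort) -> np.ndarray:
    """Binary prediction vector of ``rule`` over the cohort, in order."""
    nsuv = None
    if rule.template is RuleTemplate.STAGE2_RULE:
        nsuv = cohort.values("nsuv")
        if np.isnan(nsuv).any():
            raise ValueError(
                "STAGE2_RULE needs an SUVmean for every node; "
                "this looks like a stage I cohort"
            )
    return apply_rule_to_arrays(
        rule,
        miad=cohort.values("miad"),
        maad=cohort.values("maad"),
        macd=cohort.values("macd"),
        nsuv=nsuv,
    )


@dataclass(frozen=True)
class SearchResult:
    """Best rule found by the exhaustive search, with error accounting."""

    best_rule: RuleSpec
    metrics: DiagnosticMetrics
    baseline: CutoffResult
    corrected_fn: int
    introduced_errors: int
    error_reduction_rate: Fraction
    n_rules_evaluated: int
    audit: Optional[pd.DataFrame] = None
    ledger: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


@dataclass(frozen=True)
class BaselineComparison:
    """Per-node error accounting of the combined rule vs the baseline."""

    baseline_errors: int
    rule_errors: int
    corrected: int
    corrected_fn: int
    corrected_fp: int
    introduced_errors: int
    net_corrected: int
    error_reduction_rate: Fraction
    ledger: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _suffix2d(ia: np.ndarray, ic: np.ndarray, na: int, nc: int) -> np.ndarray:
    """S[j,k] = number of points with ia >= j and ic >= k (shape na+1 x nc+1).

    Index na / nc is the +inf sentinel slot, which no point occupies.
    """
    m = np.bincount(ia * (nc + 1) + ic, minlength=(na + 1) * (nc + 1))
    m = m.reshape(na + 1, nc + 1)
    return m[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]


def _pick_best_2d(key: np.ndarray) -> tuple[int, int]:
    """Argmax of an integer key; ties -> largest macd index, then maad index.

    ``key`` has shape (n_maad, n_macd).
    """
    best = key.max()
    jj, kk = np.nonzero(key == best)
    order = np.lexsort((jj, kk))
    i = order[-1]
    return int(jj[i]), int(kk[i])


def _grids(cohort: Cohort, template: RuleTemplate):
    ga = np.append(np.unique(cohort.values("maad")), INF)
    gc = np.append(np.unique(cohort.values("macd")), INF)
    if template is RuleTemplate.STAGE2_RULE:
        nv = cohort.values("nsuv")
        if np.isnan(nv).any():
            raise ValueError("STAGE2_RULE search requires the SUV channel")
        gn = np.append(np.unique(nv), INF)
    else:
        gn = np.array([INF])
    return ga, gc, gn


def brute_force_search(
    cohort: Cohort,
    template: RuleTemplate,
    c_miad: float | None = None,
    scan_miad: bool = False,
    baseline: CutoffResult | None = None,
    audit_limit: int = 200_000,
) -> SearchResult:
    """Exhaustive search over the cutoff grid of a rule template.

    The MIAD cutoff is fixed first (default: the cohort's accuracy-optimal
    single cutoff), mirroring the sequential protocol of the analysis;
    with ``scan_miad=True`` it is swept over its own grid instead.
    Secondary cutoffs are enumerated over all observed values plus the
    +inf sentinel.  The optimum maximizes accuracy; ties are resolved by
    higher specificity, then the lexicographically largest cutoff vector
    in the order (MIAD, NSUV, MACD, MAAD) — the most conservative rule.

    The full audit table of evaluated rules is retained when the search
    space has at most ``audit_limit`` combinations (set 0 to disable).
    """
    labels = cohort.labels
    if labels.all() or not labels.any():
        raise ValueError("cohort must contain both classes")

    if baseline is None:
        baseline = scan_cutoffs(cohort, "miad", Criterion.ACCURACY).best
    if c_miad is None:
        c_miad = baseline.cutoff
    c_miad = snap(c_miad, DIAMETER_RES)

    miad = cohort.values("miad")
    maad = cohort.values("maad")
    macd = cohort.values("macd")
    nsuv = (
        cohort.values("nsuv") if template is RuleTemplate.STAGE2_RULE else None
    )
    ga, gc, gn = _grids(cohort, template)
    na, nc = ga.size - 1, gc.size - 1

    if scan_miad:
        gm = np.unique(miad)
        gm = np.append(gm, snap(gm[-1] + DIAMETER_RES, DIAMETER_RES))
    else:
        if not np.isfinite(c_miad):
            raise ValueError("fixed MIAD cutoff must be finite")
        gm = np.array([c_miad])

    n_rules = gm.size * (na + 1) * (nc + 1) * gn.size
    keep_audit = 0 < n_rules <= audit_limit
    audit_rows: list[pd.DataFrame] = []

    # grid indices of each node (values are exact grid members)
    ia_all = np.searchsorted(ga[:-1], maad)
    ic_all = np.searchsorted(gc[:-1], macd)

    n_total = labels.size
    best: tuple[int, int, tuple[float, float, float, float]] | None = None
    # iterate MIAD cutoffs descending so exact ties keep the largest c_miad
    for cm in gm[::-1]:
        fixed_pos = miad >= cm
        sub = ~fixed_pos
        fixed_correct = int(np.sum(fixed_pos & labels))
        sub_pos = sub & labels
        sub_neg = sub & ~labels

        if template is RuleTemplate.STAGE2_RULE:
            order_n = gn[::-1]  # descending: sentinel first, ties keep larger c_nsuv
        else:
            order_n = gn  # single +inf entry
        for cn in order_n:
            if template is RuleTemplate.STAGE2_RULE:
                s_mask = nsuv >= cn
                pos_s = int(np.sum(sub_pos & s_mask))
                p_sel = sub_pos & ~s_mask
                n_sel = sub_neg & ~s_mask
            else:
                pos_s = 0
                p_sel = sub_pos
                n_sel = sub_neg

            sp = _suffix2d(ia_all[p_sel], ic_all[p_sel], na, nc)
            sn = _suffix2d(ia_all[n_sel], ic_all[n_sel], na, nc)
            n_neg_sel = int(n_sel.sum())
            if template is RuleTemplate.OR_RULE:
                # D = (maad>=c2) | (macd>=c3): inclusion-exclusion on suffix counts
                dp = sp[:, :1] + sp[:1, :] - sp
                dn = sn[:, :1] + sn[:1, :] - sn
            else:
                dp, dn = sp, sn
            correct = fixed_correct + pos_s + dp + (n_neg_sel - dn)
            tn = n_neg_sel - dn

            key = correct * np.int64(n_total + 1) + tn
            j, k = _pick_best_2d(key)
            cand = (
                int(correct[j, k]),
                int(tn[j, k]),
                (float(cm), float(cn), float(gc[k]), float(ga[j])),
            )
            # strict improvement on (correct, tn); exact ties keep the
            # earlier candidate, which has the larger (c_miad, c_nsuv)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand

            if keep_audit:
                jj, kk = np.meshgrid(
                    np.arange(na + 1), np.arange(nc + 1), indexing="ij"
                )
                audit_rows.append(
                    pd.DataFrame(
                        {
                            "c_miad": float(cm),
                            "c_nsuv": float(cn),
                            "c_macd": gc[kk.ravel()],
                            "c_maad": ga[jj.ravel()],
                            "n_correct": correct.ravel(),
                            "accuracy": correct.ravel() / n_total,
                            "tn": tn.ravel(),
                        }
                    )
                )

    assert best is not None
    _, _, (bm, bn, bc, bad) = best
    kwargs = {"c_miad": bm, "c_maad": bad, "c_macd": bc}
    if template is RuleTemplate.STAGE2_RULE:
        kwargs["c_nsuv"] = bn
    best_rule = RuleSpec(template=template, **kwargs)

    rule_pred = apply_rule(best_rule, cohort)
    m = metrics_from_counts(confusion(rule_pred, labels))
    base_pred = miad >= baseline.cutoff

    ledger = pd.DataFrame(
        {
            "node_id": [r.node_id for r in cohort.records],
            "label": labels.astype(int),
            "baseline_pred": base_pred.astype(int),
            "rule_pred": rule_pred.astype(int),
        }
    )
    base_wrong = base_pred != labels
    rule_wrong = rule_pred != labels
    corrected_fn = int(np.sum(base_wrong & ~rule_wrong & labels))
    introduced = int(np.sum(~base_wrong & rule_wrong))
    base_err = int(base_wrong.sum())
    net = base_err - int(rule_wrong.sum())
    rate = Fraction(net, base_err) if base_err else Fraction(0)

    audit = pd.concat(audit_rows, ignore_index=True) if keep_audit else None
    return SearchResult(
        best_rule=best_rule,
        metrics=m,
        baseline=baseline,
        corrected_fn=corrected_fn,
        introduced_errors=introduced,
        error_reduction_rate=rate,
        n_rules_evaluated=int(n_rules),
        audit=audit,
        ledger=ledger,
    )


def compare_to_baseline(result: SearchResult) -> BaselineComparison:
    """Error-accounting report: which baseline errors the rule fixed.

    ``error_reduction_rate`` is the *net* number of corrected errors
    (fixed minus newly introduced) over the baseline error count.
    """
    led = result.ledger
    return error_accounting(
        led["label"].to_numpy(bool),
        led["baseline_pred"].to_numpy(bool),
        led["rule_pred"].to_numpy(bool),
        node_ids=led["node_id"].tolist(),
    )


def error_accounting(
    labels, baseline_pred, rule_pred, node_ids=None
) -> BaselineComparison:
    """Per-node error ledger of a rule against a baseline prediction."""
    lab = np.asarray(labels, bool)
    bp = np.asarray(baseline_pred, bool)
    rp = np.asarray(rule_pred, bool)
    if node_ids is None:
        node_ids = [str(i + 1) for i in range(lab.size)]
    led = pd.DataFrame(
        {
            "node_id": node_ids,
            "label": lab.astype(int),
            "baseline_pred": bp.astype(int),
            "rule_pred": rp.astype(int),
        }
    )
    base_wrong = bp != lab
    rule_wrong = rp != lab
    led["baseline_wrong"] = base_wrong.astype(int)
    led["rule_wrong"] = rule_wrong.astype(int)
    led["status"] = np.select(
        [
            base_wrong & ~rule_wrong & lab,
            base_wrong & ~rule_wrong & ~lab,
            ~base_wrong & rule_wrong,
        ],
        ["rescued_false_negative", "rescued_false_positive", "newly_wrong"],
        default="unchanged",
    )
    base_err = int(base_wrong.sum())
    rule_err = int(rule_wrong.sum())
    corrected = int(np.sum(base_wrong & ~rule_wrong))
    corrected_fn = int(np.sum(base_wrong & ~rule_wrong & lab))
    corrected_fp = corrected - corrected_fn
    introduced = int(np.sum(~base_wrong & rule_wrong))
    net = base_err - rule_err
    return BaselineComparison(
        baseline_errors=base_err,
        rule_errors=rule_err,
        corrected=corrected,
        corrected_fn=corrected_fn,
        corrected_fp=corrected_fp,
        introduced_errors=introduced,
        net_corrected=net,
        error_reduction_rate=Fraction(net, base_err) if base_err else Fraction(0),
        ledger=led,
    )
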