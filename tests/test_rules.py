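from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lrpldx.cohort import Stage
from lrpldx.cutoffs import scan_cutoffs
from lrpldx.rules import (
    RuleSpec,
    RuleTemplate,
    apply_rule,
    apply_rule_to_arrays,
    brute_force_search,
    compare_to_baseline,
    error_accounting,
)

from conftest import PLANTED_STAGE2, make_cohort, naive_rule_search, random_cohort


class TestApplyRule:
    def test_stage2_clauses(self):
        rule = PLANTED_STAGE2  # MIAD 6.1 / MAAD 8.0 / MACD 25.0 / NSUV 2.6
        rows = [
            (6.2, 7.0, 10.0, 0.5, None),   # primary clause fires
            (5.0, 5.0, 10.0, 2.6, None),   # SUV clause fires at the boundary
            (5.0, 7.9, 25.0, 1.0, None),   # AND clause needs both diameters
            (5.0, 8.0, 25.0, 1.0, None),   # both diameters at the boundary
            (5.0, 8.0, 24.9, 1.0, None),   # MACD just below
        ]
        miad, maad, macd, nsuv, _ = map(np.array, zip(*rows))
        pred = apply_rule_to_arrays(rule, miad, maad, macd, nsuv=nsuv)
        assert pred.tolist() == [True, True, False, True, False]

    def test_or_rule_positive_set_contains_and_rule_set(self):
        rng = np.random.default_rng(6)
        cohort = random_cohort(rng, 50)
        kw = dict(c_miad=6.0, c_maad=8.0, c_macd=15.0)
        and_pred = apply_rule(RuleSpec(template=RuleTemplate.AND_RULE, **kw), cohort)
        or_pred = apply_rule(RuleSpec(template=RuleTemplate.OR_RULE, **kw), cohort)
        assert (or_pred | and_pred == or_pred).all()

    @given(
        delta=st.sampled_from(["c_miad", "c_maad", "c_macd", "c_nsuv"]),
        step=st.integers(1, 30),
    )
    def test_raising_any_cutoff_never_adds_positives(self, delta, step):
        cohort = random_cohort(np.random.default_rng(12), 40)
        base = dict(c_miad=5.0, c_maad=8.0, c_macd=15.0, c_nsuv=2.0)
        lo = RuleSpec(template=RuleTemplate.STAGE2_RULE, **base)
        raised = dict(base)
        raised[delta] = base[delta] + step * (0.01 if delta == "c_nsuv" else 0.1)
        hi = RuleSpec(template=RuleTemplate.STAGE2_RULE, **raised)
        p_lo = apply_rule(lo, cohort)
        p_hi = apply_rule(hi, cohort)
        assert not (p_hi & ~p_lo).any()

    def test_stage2_rule_needs_suv_channel(self):
        cohort = make_cohort([(5, 6, 7, None, True), (4, 5, 6, None, False)])
        with pytest.raises(ValueError, match="stage I"):
            apply_rule(PLANTED_STAGE2, cohort)

    def test_cutoffs_snapped_and_nsuv_guarded(self):
        r = RuleSpec(template=RuleTemplate.STAGE2_RULE, c_miad=6.1499, c_nsuv=2.604)
        assert (r.c_miad, r.c_nsuv) == (6.1, 2.6)
        with pytest.raises(ValueError):
            RuleSpec(template=RuleTemplate.AND_RULE, c_miad=6.0, c_nsuv=2.6)


class TestBruteForceSearch:
    def test_sentinel_rule_reduces_to_miad_baseline(self, stage2_cohort):
        """+inf secondary cutoffs disable every clause except MIAD's."""
        base = scan_cutoffs(stage2_cohort, "miad").best
        for template in RuleTemplate:
            rule = RuleSpec(template=template, c_miad=base.cutoff)
            pred = apply_rule(rule, stage2_cohort)
            assert (pred == (stage2_cohort.values("miad") >= base.cutoff)).all()
            acc = Fraction(int((pred == stage2_cohort.labels).sum()), len(stage2_cohort))
            assert acc == base.accuracy

    def test_search_never_below_baseline(self):
        rng = np.random.default_rng(2)
        for trial in range(4):
            cohort = random_cohort(rng, 35)
            for template in RuleTemplate:
                res = brute_force_search(cohort, template)
                assert res.metrics.accuracy >= res.baseline.accuracy

    @pytest.mark.parametrize("template", list(RuleTemplate))
    def test_matches_naive_quadruple_loop(self, template):
        rng = np.random.default_rng(77)
        cohort = random_cohort(rng, 18)
        res = brute_force_search(cohort, template, scan_miad=True)
        naive = naive_rule_search(cohort, template)
        c = res.metrics.counts
        r = res.best_rule
        assert (c.tp + c.tn, c.tn, r.c_miad, r.c_nsuv, r.c_macd, r.c_maad) == naive

    def test_audit_table_contains_every_rule(self):
        cohort = random_cohort(np.random.default_rng(5), 12)
        res = brute_force_search(cohort, RuleTemplate.AND_RULE, scan_miad=True)
        assert res.audit is not None
        assert len(res.audit) == res.n_rules_evaluated
        # the reported optimum is the audit-table maximum
        assert res.audit["n_correct"].max() == res.metrics.counts.tp + res.metrics.counts.tn

    def test_recovers_planted_stage2_rule(self, planted_stage2_cohort):
        cohort, _ = planted_stage2_cohort
        res = brute_force_search(cohort, RuleTemplate.STAGE2_RULE, scan_miad=True, audit_limit=0)
        r = res.best_rule
        assert abs(r.c_miad - 6.1) <= 0.1 + 1e-9
        assert abs(r.c_maad - 8.0) <= 0.1 + 1e-9
        assert abs(r.c_macd - 25.0) <= 0.1 + 1e-9
        assert abs(r.c_nsuv - 2.6) <= 0.01 + 1e-9

    def test_fixed_miad_respected(self, stage2_cohort):
        res = brute_force_search(stage2_cohort, RuleTemplate.STAGE2_RULE, c_miad=6.1)
        assert res.best_rule.c_miad == 6.1

    def test_single_class_rejected(self):
        cohort = make_cohort([(5, 6, 7, 1.0, True)] * 4, stage=Stage.STAGE_II)
        with pytest.raises(ValueError):
            brute_force_search(cohort, RuleTemplate.AND_RULE)


class TestErrorAccounting:
    def test_published_stage2_error_reduction(self):
        # 45 baseline errors, 6 false negatives rescued, none introduced
        labels = np.r_[np.ones(45, bool), np.zeros(20, bool)]
        base_pred = np.r_[np.zeros(45, bool), np.zeros(20, bool)]  # 45 FN
        rule_pred = base_pred.copy()
        rule_pred[:6] = True
        acc = error_accounting(labels, base_pred, rule_pred)
        assert acc.baseline_errors == 45
        assert acc.corrected_fn == 6
        assert acc.introduced_errors == 0
        assert acc.error_reduction_rate == Fraction(6, 45)
        from lrpldx.metrics import format_percent

        assert format_percent(acc.error_reduction_rate) == "13.3%"

    def test_published_stage1_error_reduction(self):
        labels = np.r_[np.ones(73, bool), np.zeros(27, bool)]
        base_pred = np.r_[np.zeros(73, bool), np.zeros(27, bool)]
        rule_pred = base_pred.copy()
        rule_pred[:3] = True
        acc = error_accounting(labels, base_pred, rule_pred)
        assert acc.error_reduction_rate == Fraction(3, 73)
        from lrpldx.metrics import format_percent

        assert format_percent(acc.error_reduction_rate) == "4.1%"

    def test_identical_predictions_rate_zero(self):
        labels = np.array([1, 0, 1, 0], bool)
        pred = np.array([1, 0, 0, 0], bool)
        acc = error_accounting(labels, pred, pred)
        assert acc.error_reduction_rate == 0
        assert (acc.ledger["status"] == "unchanged").all()

    def test_ledger_statuses_partition_cohort(self, planted_stage2_cohort):
        cohort, _ = planted_stage2_cohort
        res = brute_force_search(
            cohort, RuleTemplate.STAGE2_RULE, c_miad=6.1, audit_limit=0
        )
        cmp_ = compare_to_baseline(res)
        assert len(cmp_.ledger) == len(cohort)
        assert cmp_.net_corrected == cmp_.baseline_errors - cmp_.rule_errors
        assert cmp_.corrected - cmp_.introduced_errors == cmp_.net_corrected
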