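import numpy as np
import pytest
from scipy import stats

from lrpldx.cohort import Stage
from lrpldx.cutoffs import Criterion, roc_curve, scan_cutoffs
from lrpldx.rules import RuleSpec, RuleTemplate
from lrpldx.synthetic import GeneratorConfig, generate_cohort

from conftest import make_cohort, random_cohort


def mann_whitney_auc(values, labels):
    """AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    pos = values[labels]
    neg = values[~labels]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (pos.size * neg.size)


class TestScanCutoffs:
    def test_recovers_planted_miad_threshold(self):
        rule = RuleSpec(template=RuleTemplate.AND_RULE, c_miad=6.1)
        cohort, _ = generate_cohort(
            GeneratorConfig(n_nodes=400, seed=9, planted_rule=rule)
        )
        for crit in Criterion:
            best = scan_cutoffs(cohort, "miad", crit).best
            assert best.accuracy == 1
            assert abs(best.cutoff - 6.1) <= 0.1 + 1e-9

    def test_perfect_separation_tie_break_takes_largest_cutoff(self):
        # positives all >= 8, negatives all <= 5: any cutoff in (5, 8] is
        # perfect; the scan must return the largest candidate, 8.0
        rows = [(8.0, 9, 10, None, True), (8.5, 9, 10, None, True)] + [
            (4.0, 5, 6, None, False),
            (5.0, 6, 7, None, False),
        ]
        best = scan_cutoffs(make_cohort(rows), "miad").best
        assert best.accuracy == 1
        assert best.cutoff == 8.0

    def test_matches_exhaustive_enumeration_on_small_cohort(self):
        rng = np.random.default_rng(17)
        cohort = random_cohort(rng, 30)
        values = cohort.values("miad")
        labels = cohort.labels
        best_acc = 0.0
        for c in np.unique(values):
            acc = float(np.mean((values >= c) == labels))
            best_acc = max(best_acc, acc)
        # "call everything negative" is also in the scan's candidate set
        best_acc = max(best_acc, float(np.mean(~labels)))
        assert float(scan_cutoffs(cohort, "miad").best.accuracy) == pytest.approx(
            best_acc
        )

    def test_accuracy_never_below_majority_class(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            cohort = random_cohort(rng, 40)
            prev = float(cohort.labels.mean())
            best = scan_cutoffs(cohort, "macd").best
            assert float(best.accuracy) >= max(prev, 1 - prev) - 1e-12

    def test_scan_invariant_to_record_order(self, stage2_cohort):
        shuffled = stage2_cohort.subset(
            np.random.default_rng(4).permutation(len(stage2_cohort))
        )
        a = scan_cutoffs(stage2_cohort, "nsuv").best
        b = scan_cutoffs(shuffled, "nsuv").best
        assert (a.cutoff, a.accuracy) == (b.cutoff, b.accuracy)

    def test_youden_optimum_matches_roc_vertex_sweep(self, stage2_cohort):
        """The J-optimal cutoff attains max(tpr - fpr) over ROC vertices."""
        best = scan_cutoffs(stage2_cohort, "miad", Criterion.YOUDEN).best
        r = roc_curve(stage2_cohort, "miad", n_boot=10, seed=0)
        assert float(best.youden_j) == pytest.approx(float(np.max(r.tpr - r.fpr)))

    def test_single_class_cohort_rejected(self):
        cohort = make_cohort([(5, 6, 7, None, True)] * 4)
        with pytest.raises(ValueError):
            scan_cutoffs(cohort, "miad")


class TestRoc:
    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(31)
        for trial in range(10):
            cohort = random_cohort(rng, 60)
            for p in ("miad", "nsuv"):
                r = roc_curve(cohort, p, n_boot=10, seed=trial)
                expected = mann_whitney_auc(cohort.values(p), cohort.labels)
                assert r.auc == pytest.approx(expected, abs=1e-12)

    def test_perfect_separation_auc_one(self):
        rows = [(8 + i / 10, 9, 10, None, True) for i in range(5)] + [
            (4 + i / 10, 6, 7, None, False) for i in range(5)
        ]
        r = roc_curve(make_cohort(rows), "miad", n_boot=10, seed=0)
        assert r.auc == 1.0

    def test_permuted_labels_auc_near_half(self, stage1_cohort):
        """A label permutation destroys the association: each permuted AUC
        sits within 4 sd of 1/2 and the mean over permutations converges."""
        from dataclasses import replace
        from lrpldx.cohort import Cohort

        rng = np.random.default_rng(2)
        labels = stage1_cohort.labels
        n_pos = int(labels.sum())
        n_neg = labels.size - n_pos
        # Mann-Whitney null sd of AUC
        sd = np.sqrt((labels.size + 1) / (12 * n_pos * n_neg))
        aucs = []
        for _ in range(10):
            perm = rng.permutation(labels)
            shuffled = Cohort(
                tuple(
                    replace(r, label=bool(l))
                    for r, l in zip(stage1_cohort.records, perm)
                ),
                stage=Stage.STAGE_I,
            )
            auc = roc_curve(shuffled, "miad", n_boot=10, seed=0).auc
            assert abs(auc - 0.5) < 4 * sd
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_curve_monotone_and_ci_brackets_auc(self, stage2_cohort):
        r = roc_curve(stage2_cohort, "miad", n_boot=200, seed=1)
        assert (np.diff(r.fpr) >= 0).all()
        assert (np.diff(r.tpr) >= 0).all()
        lo, hi = r.auc_ci95
        assert lo <= r.auc <= hi
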