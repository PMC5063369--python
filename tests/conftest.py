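import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lrpldx.cohort import Cohort, NodeRecord, Stage
from lrpldx.rules import INF, RuleSpec, RuleTemplate
from lrpldx.synthetic import GeneratorConfig, generate_cohort, make_stage2_subset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_cohort(rows, stage=Stage.STAGE_I):
    """Build a cohort from (miad, maad, macd, nsuv, label) tuples."""
    recs = []
    for i, (mi, ma, mc, su, lab) in enumerate(rows, start=1):
        recs.append(
            NodeRecord(
                node_id=f"N{i}",
                patient_id=f"P{i}",
                miad=mi,
                maad=ma,
                macd=mc,
                nsuv=su,
                label=bool(lab),
            )
        )
    return Cohort(tuple(recs), stage=stage)


def random_cohort(rng, n, stage=Stage.STAGE_II):
    """Small random cohort with arbitrary labels (both classes guaranteed)."""
    maad = np.round(rng.uniform(3, 20, n), 1)
    miad = np.round(maad * rng.uniform(0.3, 1.0, n), 1)
    miad = np.maximum(np.minimum(miad, maad), 0.1)
    macd = np.round(rng.uniform(4, 35, n), 1)
    nsuv = np.round(rng.uniform(0, 6, n), 2)
    labels = rng.random(n) < 0.5
    labels[0], labels[1] = True, False
    return make_cohort(zip(miad, maad, macd, nsuv, labels), stage=stage)


PLANTED_STAGE2 = RuleSpec(
    template=RuleTemplate.STAGE2_RULE, c_miad=6.1, c_maad=8.0, c_macd=25.0, c_nsuv=2.6
)


@pytest.fixture(scope="session")
def stage1_cohort():
    cohort, _ = generate_cohort(GeneratorConfig(seed=11))
    return cohort


@pytest.fixture(scope="session")
def stage2_cohort(stage1_cohort):
    return make_stage2_subset(stage1_cohort, 410, seed=12)


@pytest.fixture(scope="session")
def planted_stage2_cohort():
    cohort, sidecar = generate_cohort(
        GeneratorConfig(
            n_nodes=663,
            seed=1,
            planted_rule=PLANTED_STAGE2,
            label_noise_rate=0.02,
            stage=Stage.STAGE_II,
        )
    )
    return cohort, sidecar


@pytest.fixture(scope="session")
def separable_cohort():
    """Labels exactly MIAD >= 6.1, no noise, and a clear (>= 0.5 mm)
    margin around the boundary: linearly separable on MIAD."""
    rule = RuleSpec(template=RuleTemplate.AND_RULE, c_miad=6.1)
    cohort, _ = generate_cohort(
        GeneratorConfig(
            n_nodes=400,
            seed=5,
            planted_rule=rule,
            boundary_fraction=0.0,
            stage=Stage.STAGE_II,
        )
    )
    keep = [i for i, r in enumerate(cohort.records) if abs(r.miad - 6.1) > 0.45]
    return cohort.subset(keep[:240])


def naive_rule_search(cohort, template, miad_grid=None):
    """Independent oracle: quadruple loop over observed-value cutoffs.

    Returns (n_correct, tn, c_miad, c_nsuv, c_macd, c_maad) of the best
    rule under the same tie-break order, evaluated with plain comparisons.
    """
    labels = cohort.labels
    miad = cohort.values("miad")
    maad = cohort.values("maad")
    macd = cohort.values("macd")
    nsuv = cohort.values("nsuv")
    if miad_grid is None:
        gm = sorted(np.unique(miad))
        gm = gm + [round(gm[-1] + 0.1, 1)]
    else:
        gm = list(miad_grid)
    ga = list(np.unique(maad)) + [INF]
    gc = list(np.unique(macd)) + [INF]
    gn = list(np.unique(nsuv)) + [INF] if template is RuleTemplate.STAGE2_RULE else [INF]
    best = None
    for cm in gm:
        primary = miad >= cm
        for cn in gn:
            suv_hit = nsuv >= cn if template is RuleTemplate.STAGE2_RULE else False
            for cc in gc:
                for ca in ga:
                    if template is RuleTemplate.OR_RULE:
                        sec = (maad >= ca) | (macd >= cc)
                    else:
                        sec = (maad >= ca) & (macd >= cc)
                    pred = primary | sec | suv_hit
                    ok = pred == labels
                    key = (
                        int(ok.sum()),
                        int((ok & ~labels).sum()),
                        cm,
                        cn,
                        cc,
                        ca,
                    )
                    if best is None or key > best:
                        best = key
    return best
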