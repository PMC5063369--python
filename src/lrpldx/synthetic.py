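"""Synthetic node cohorts with the statistical structure the analysis assumes.

The generator emulates a two-class cohort of retropharyngeal nodes:

* the three diameters are class-conditional correlated lognormals, with
  MIAD <= MAAD guaranteed by construction — MAAD is sampled together with a
  log eccentricity ratio (clipped at 0, so the ratio lies in (0, 1]) and
  MIAD is their product;
* the SUVmean channel is a class-conditional lognormal among measured
  nodes, with a point mass at exactly 0 for the subset of negative nodes
  that were read as qualitatively negative on PET and never measured
  (their SUVmean is imputed to 0, and the imputation is recorded in the
  ground-truth sidecar);
* labels come either from class-conditional sampling (realistic overlap)
  or from a planted decision rule applied to the measurements plus an
  optional label-noise rate (for exact parameter-recovery tests).

Default calibration targets the neighbourhood of the published optima:
an optimal MIAD cutoff near 6 mm with accuracy in the high 80s%, MAAD
near 8–10 mm, MACD near 16 mm, SUVmean near 1.8, at ~50.8% prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from ._grid import DIAMETER_RES, SUV_RES, snap
from .cohort import Cohort, NodeRecord, Stage

if TYPE_CHECKING:  # pragma: no cover
    from .rules import RuleSpec

__all__ = [
    "DiameterClassModel",
    "SuvClassModel",
    "GeneratorConfig",
    "generate_cohort",
    "make_stage2_subset",
]


@dataclass(frozen=True)
class DiameterClassModel:
    """Mean vector and covariance of (log MIAD, log MAAD, log MACD), mm."""

    mean: tuple[float, float, float]
    cov: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, float)
        if c.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc


@dataclass(frozen=True)
class SuvClassModel:
    """Location/scale of log SUVmean among measured nodes."""

    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")


def _corr_to_cov(sds: tuple[float, float, float], corr: np.ndarray) -> tuple:
    s = np.asarray(sds)
    return tuple(map(tuple, corr * np.outer(s, s)))


_DIAM_CORR = np.array(
    [
        [1.00, 0.85, 0.50],
        [0.85, 1.00, 0.60],
        [0.50, 0.60, 1.00],
    ]
)

# class-conditional defaults: (log-mm means for MIAD, MAAD, MACD)
_NEG_DIAMETERS = DiameterClassModel(
    mean=(float(np.log(4.3)), float(np.log(6.6)), float(np.log(12.0))),
    cov=_corr_to_cov((0.28, 0.33, 0.45), _DIAM_CORR),
)
_POS_DIAMETERS = DiameterClassModel(
    mean=(float(np.log(8.5)), float(np.log(13.0)), float(np.log(20.0))),
    cov=_corr_to_cov((0.28, 0.33, 0.45), _DIAM_CORR),
)
_NEG_SUV = SuvClassModel(log_mean=float(np.log(1.3)), log_sd=0.45)
_POS_SUV = SuvClassModel(log_mean=float(np.log(3.0)), log_sd=0.50)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``qualitative_negative_fraction`` is the probability that a *negative*
    node has no measured SUV (qualitative PET read only); such nodes get
    SUVmean imputed to exactly 0.  With a ``planted_rule`` the labels are
    a deterministic function of the measurements (flipped independently
    with probability ``label_noise_rate``).  In planted mode a fraction
    ``boundary_fraction`` of the nodes are "equivocal": one active
    threshold of the rule is chosen at random and the node is placed
    within ``boundary_window_steps`` grid steps of it, with the other
    parameters set so that this threshold alone decides the node.  This
    puts observed values on both sides of every planted cutoff — the
    design condition for a recovery study, since candidate cutoffs are
    observed values — while the remaining nodes come from the
    prevalence-weighted mixture of the two class models.
    """

    n_nodes: int = 663
    prevalence: float = 0.508
    seed: int = 0
    diameters_negative: DiameterClassModel = _NEG_DIAMETERS
    diameters_positive: DiameterClassModel = _POS_DIAMETERS
    suv_negative: SuvClassModel = _NEG_SUV
    suv_positive: SuvClassModel = _POS_SUV
    qualitative_negative_fraction: float = 0.6
    planted_rule: Optional["RuleSpec"] = None
    label_noise_rate: float = 0.0
    boundary_fraction: float = 0.4
    boundary_window_steps: int = 5
    stage: Stage = Stage.STAGE_I
    cohort_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.qualitative_negative_fraction <= 1.0):
            raise ValueError("qualitative_negative_fraction must lie in [0, 1]")
        if not (0.0 <= self.label_noise_rate < 1.0):
            raise ValueError("label_noise_rate must lie in [0, 1)")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")


def _sample_diameters(
    rng: np.random.Generator, model: DiameterClassModel, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (miad, maad, macd) with miad <= maad by construction.

    The configured MVN on (log miad, log maad, log macd) is re-expressed as
    (log maad, log macd, d = log miad - log maad); d is clipped at 0 so the
    eccentricity ratio exp(d) lies in (0, 1].
    """
    mu = np.asarray(model.mean)
    sigma = np.asarray(model.cov)
    a = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, -1.0, 0.0]])
    y = rng.multivariate_normal(a @ mu, a @ sigma @ a.T, size=n, method="cholesky")
    log_maad, log_macd, d = y[:, 0], y[:, 1], np.minimum(y[:, 2], 0.0)
    maad = np.exp(log_maad)
    macd = np.exp(log_macd)
    miad = maad * np.exp(d)
    return miad, maad, macd


def _boundary_nodes(
    rng: np.random.Generator, rule: "RuleSpec", n: int, window_steps: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Equivocal nodes straddling one active threshold of a planted rule.

    For each node one finite cutoff of the rule is picked at random; the
    node's value on that parameter is uniform within ``window_steps`` grid
    steps of the cutoff, and the remaining parameters are set so that the
    picked clause alone decides the node (other clauses off; for an AND
    clause the partner condition is switched on).
    """
    from .rules import RuleTemplate

    is_stage2 = rule.template is RuleTemplate.STAGE2_RULE
    is_or = rule.template is RuleTemplate.OR_RULE
    active = [("miad", rule.c_miad)]
    if np.isfinite(rule.c_maad):
        active.append(("maad", rule.c_maad))
    if np.isfinite(rule.c_macd):
        active.append(("macd", rule.c_macd))
    if is_stage2 and np.isfinite(rule.c_nsuv):
        active.append(("nsuv", rule.c_nsuv))

    w_d = window_steps * DIAMETER_RES
    w_s = window_steps * SUV_RES

    def low(c: float, lo: float, hi: float, fallback: tuple[float, float]) -> float:
        return rng.uniform(lo * c, hi * c) if np.isfinite(c) else rng.uniform(*fallback)

    miad = np.empty(n)
    maad = np.empty(n)
    macd = np.empty(n)
    nsuv = np.empty(n)
    picks = rng.integers(0, len(active), size=n)
    for i in range(n):
        name, cut = active[picks[i]]
        # defaults: every clause off
        mi = low(rule.c_miad, 0.35, 0.85, (3.0, 5.0))
        su = low(rule.c_nsuv, 0.05, 0.85, (0.2, 1.5)) if is_stage2 else rng.uniform(0.2, 1.5)
        if name == "miad":
            mi = cut + rng.uniform(-w_d, w_d)
            ma = (
                rng.uniform(mi, 0.95 * rule.c_maad)
                if is_or and np.isfinite(rule.c_maad) and 0.95 * rule.c_maad > mi
                else mi * rng.uniform(1.02, 1.9)
            )
            mc = low(rule.c_macd, 0.3, 0.8, (8.0, 20.0))
        elif name == "maad":
            ma = cut + rng.uniform(-w_d, w_d)
            if is_or:
                mc = low(rule.c_macd, 0.3, 0.8, (5.0, 12.0))
            else:  # AND partner on
                mc = (
                    rule.c_macd * rng.uniform(1.02, 1.3)
                    if np.isfinite(rule.c_macd)
                    else ma * rng.uniform(1.0, 1.6)
                )
            mi = min(mi, 0.9 * ma)
        elif name == "macd":
            mc = cut + rng.uniform(-w_d, w_d)
            if is_or:
                ma = low(rule.c_maad, 0.4, 0.85, (4.0, 7.0))
            else:
                ma = (
                    rule.c_maad * rng.uniform(1.02, 1.3)
                    if np.isfinite(rule.c_maad)
                    else rng.uniform(6.0, 14.0)
                )
            mi = min(mi, 0.9 * ma)
        else:  # nsuv
            su = max(cut + rng.uniform(-w_s, w_s), 0.0)
            ma = mi * rng.uniform(1.02, 1.9)
            mc = low(rule.c_macd, 0.3, 0.8, (8.0, 20.0))
        miad[i], maad[i], macd[i], nsuv[i] = mi, ma, mc, su
    maad = np.maximum(maad, miad)
    return miad, maad, macd, nsuv


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus a ground-truth sidecar.

    The sidecar records, per node, the mixture class it was drawn from,
    the final (possibly noise-flipped) label, whether the SUV channel was
    zero-imputed, and the pre-imputation SUV draw.  Deterministic given
    the config (bit-identical cohorts for identical configs).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes

    component = rng.random(n) < cfg.prevalence  # latent mixture class
    miad = np.empty(n)
    maad = np.empty(n)
    macd = np.empty(n)
    suv_raw = np.empty(n)
    for is_pos, dm, sm in (
        (True, cfg.diameters_positive, cfg.suv_positive),
        (False, cfg.diameters_negative, cfg.suv_negative),
    ):
        idx = np.flatnonzero(component == is_pos)
        if idx.size == 0:
            continue
        mi, ma, mc = _sample_diameters(rng, dm, idx.size)
        miad[idx], maad[idx], macd[idx] = mi, ma, mc
        suv_raw[idx] = np.exp(rng.normal(sm.log_mean, sm.log_sd, size=idx.size))

    is_boundary = np.zeros(n, bool)
    if cfg.planted_rule is not None and cfg.boundary_fraction > 0:
        is_boundary = rng.random(n) < cfg.boundary_fraction
        k = int(is_boundary.sum())
        if k:
            bm, ba, bc, bs = _boundary_nodes(
                rng, cfg.planted_rule, k, cfg.boundary_window_steps
            )
            miad[is_boundary] = bm
            maad[is_boundary] = ba
            macd[is_boundary] = bc
            suv_raw[is_boundary] = bs

    miad = np.maximum(snap(miad, DIAMETER_RES), DIAMETER_RES)
    maad = np.maximum(snap(maad, DIAMETER_RES), miad)
    macd = np.maximum(snap(macd, DIAMETER_RES), DIAMETER_RES)
    suv_raw = np.maximum(snap(suv_raw, SUV_RES), SUV_RES)

    if cfg.planted_rule is not None:
        from .rules import apply_rule_to_arrays

        rule_label = apply_rule_to_arrays(
            cfg.planted_rule, miad=miad, maad=maad, macd=macd, nsuv=suv_raw
        )
        flips = rng.random(n) < cfg.label_noise_rate
        labels = rule_label ^ flips
    else:
        rule_label = np.zeros(n, bool)
        flips = np.zeros(n, bool)
        labels = component.copy()

    # qualitative-negative PET reads: negative nodes without a measured SUV
    qual_neg = (~labels) & (rng.random(n) < cfg.qualitative_negative_fraction)
    nsuv = np.where(qual_neg, 0.0, suv_raw)

    records = []
    width = len(str(n))
    for i in range(n):
        records.append(
            NodeRecord(
                node_id=f"N{i + 1:0{width}d}",
                patient_id=f"P{i // 2 + 1:0{width}d}",
                miad=float(miad[i]),
                maad=float(maad[i]),
                macd=float(macd[i]),
                nsuv=None if qual_neg[i] else float(nsuv[i]),
                nsuv_qualitative_negative=bool(qual_neg[i]),
                label=bool(labels[i]),
                cohort_tag=cfg.cohort_tag,
            )
        )
    cohort = Cohort(tuple(records), stage=cfg.stage)

    sidecar = pd.DataFrame(
        {
            "node_id": [r.node_id for r in records],
            "mixture_class": component.astype(int),
            "planted_rule_label": rule_label.astype(int),
            "label_flipped": flips.astype(int),
            "label": labels.astype(int),
            "suv_raw": suv_raw,
            "suv_imputed_zero": qual_neg.astype(int),
            "boundary_design": is_boundary.astype(int),
        }
    )
    return cohort, sidecar


def make_stage2_subset(cohort: Cohort, n: int, seed: int) -> Cohort:
    """Reproducible subsample with the SUV channel defined for every node.

    Emulates the restriction of the full cohort to the nodes that carry
    PET data (measured SUVmean, or qualitative-negative imputed 0).
    Record order of the parent is preserved.
    """
    eligible = [
        i
        for i, r in enumerate(cohort.records)
        if r.nsuv is not None or r.nsuv_qualitative_negative
    ]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} nodes but only {len(eligible)} carry an SUV channel"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(eligible), size=n, replace=False))
    sub = Cohort(
        tuple(cohort.records[eligible[i]] for i in chosen), stage=Stage.STAGE_II
    )
    return sub
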