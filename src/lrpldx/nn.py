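"""Shallow feed-forward classification of nodal parameters.

The classifier mirrors the classical MATLAB-style setup for tabular
two-class problems: one hidden layer of tanh units, a linear output unit,
0/1 targets, and mean-squared-error minimization — here fitted with
scikit-learn's ``MLPRegressor``.  The cohort is split roughly in half
into train and test sets (no validation set, no early stopping beyond the
iteration cap); inputs are z-scored using training-split statistics only,
and the linear output is thresholded at 0.5.

Every nonempty subset of the stage's parameters is evaluated as an input
combination: 7 combinations for the three diameters, 15 once the SUVmean
is added.  By default all combinations share a single train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .cohort import Cohort, Stage
from .metrics import DiagnosticMetrics, confusion, metrics_from_counts

__all__ = [
    "NNConfig",
    "FittedNN",
    "ComboEvaluation",
    "split_half",
    "train_nn",
    "evaluate_all_combos",
    "combos_for_stage",
    "combo_code",
]

#: compact combination codes used in report tables
_CODE = {"miad": "A1", "maad": "A2", "macd": "C", "nsuv": "N"}

# combination orders as laid out in the report tables: the full set first,
# then decreasing subset size, singletons last
_STAGE1_COMBOS: tuple[tuple[str, ...], ...] = (
    ("miad", "maad", "macd"),
    ("miad", "maad"),
    ("miad", "macd"),
    ("maad", "macd"),
    ("miad",),
    ("maad",),
    ("macd",),
)
_STAGE2_COMBOS: tuple[tuple[str, ...], ...] = (
    ("miad", "maad", "macd", "nsuv"),
    ("miad", "maad", "macd"),
    ("miad", "maad", "nsuv"),
    ("miad", "macd", "nsuv"),
    ("maad", "macd", "nsuv"),
    ("miad", "maad"),
    ("miad", "macd"),
    ("miad", "nsuv"),
    ("macd", "nsuv"),
    ("maad", "macd"),
    ("maad", "nsuv"),
    ("miad",),
    ("maad",),
    ("macd",),
    ("nsuv",),
)


def combos_for_stage(stage: Stage) -> tuple[tuple[str, ...], ...]:
    return _STAGE1_COMBOS if stage is Stage.STAGE_I else _STAGE2_COMBOS


def combo_code(combo: Sequence[str]) -> str:
    return "".join(_CODE[p] for p in combo)


@dataclass(frozen=True)
class NNConfig:
    hidden_units: int = 5
    input_combo: tuple[str, ...] = ("miad", "maad", "macd")
    train_fraction: float = 0.5
    seed: int = 0
    max_iterations: int = 500
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.input_combo:
            raise ValueError("input_combo must be nonempty")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.hidden_units < 1:
            raise ValueError("at least one hidden unit is required")


@dataclass(frozen=True)
class FittedNN:
    config: NNConfig
    model: MLPRegressor = field(repr=False)
    scaler: StandardScaler = field(repr=False)
    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)
    training_log: dict

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """Raw linear outputs for a feature matrix in original units."""
        return self.model.predict(self.scaler.transform(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.decision_values(x) >= self.config.decision_threshold


@dataclass(frozen=True)
class ComboEvaluation:
    combo: tuple[str, ...]
    code: str
    metrics: DiagnosticMetrics
    n_train: int
    n_test: int


def split_half(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition: round(train_fraction*n) training rows."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _features(cohort: Cohort, combo: Sequence[str]) -> np.ndarray:
    cols = [cohort.values(p) for p in combo]
    x = np.column_stack(cols)
    if np.isnan(x).any():
        raise ValueError(f"combination {tuple(combo)} has missing measurements")
    return x


def train_nn(
    cohort: Cohort,
    config: NNConfig,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> FittedNN:
    """Fit the one-hidden-layer network on a random half of the cohort.

    If the drawn training half happens to contain a single class (the
    split is not stratified, matching the original protocol), the split
    is redrawn with the next seed and a warning is issued.
    """
    y = cohort.labels.astype(float)
    x = _features(cohort, config.input_combo)

    seed = config.seed
    if split is None:
        for attempt in range(32):
            train_idx, test_idx = split_half(len(y), config.train_fraction, seed + attempt)
            if np.unique(y[train_idx]).size == 2:
                if attempt:
                    warnings.warn(
                        f"single-class training split with seed {seed}; "
                        f"redrew with seed {seed + attempt}",
                        stacklevel=2,
                    )
                break
        else:
            raise ValueError("could not draw a two-class training split")
    else:
        train_idx, test_idx = split
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("provided training split contains a single class")

    scaler = StandardScaler().fit(x[train_idx])
    xt = scaler.transform(x[train_idx])
    model = MLPRegressor(
        hidden_layer_sizes=(config.hidden_units,),
        activation="tanh",
        solver="lbfgs",
        max_iter=config.max_iterations,
        random_state=np.random.RandomState(config.seed % (2**32)),
        tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", category=UserWarning)
        model.fit(xt, y[train_idx])
    resid = model.predict(xt) - y[train_idx]
    log = {
        "final_train_mse": float(np.mean(resid**2)),
        "n_iterations": int(model.n_iter_),
        "loss_curve": [float(v) for v in getattr(model, "loss_curve_", [])],
    }
    return FittedNN(
        config=config,
        model=model,
        scaler=scaler,
        train_idx=train_idx,
        test_idx=test_idx,
        training_log=log,
    )


def evaluate_combo(cohort: Cohort, config: NNConfig, split=None) -> ComboEvaluation:
    fitted = train_nn(cohort, config, split=split)
    x = _features(cohort, config.input_combo)
    pred = fitted.predict(x[fitted.test_idx])
    lab = cohort.labels[fitted.test_idx]
    return ComboEvaluation(
        combo=tuple(config.input_combo),
        code=combo_code(config.input_combo),
        metrics=metrics_from_counts(confusion(pred, lab)),
        n_train=fitted.train_idx.size,
        n_test=fitted.test_idx.size,
    )


def evaluate_all_combos(
    cohort: Cohort,
    stage: Stage,
    base_config: NNConfig = NNConfig(),
    shared_split: bool = True,
) -> list[ComboEvaluation]:
    """Evaluate every parameter combination of the stage (7 or 15 rows).

    By default a single train/test split is shared across combinations;
    with ``shared_split=False`` each combination redraws its own split
    from a seed offset by its table position.
    """
    out = []
    split = None
    if shared_split:
        y = cohort.labels
        for attempt in range(32):
            split = split_half(len(y), base_config.train_fraction, base_config.seed + attempt)
            if np.unique(y[split[0]]).size == 2:
                break
        else:
            raise ValueError("could not draw a two-class training split")
    for i, combo in enumerate(combos_for_stage(stage)):
        cfg = replace(
            base_config,
            input_combo=combo,
            seed=base_config.seed if shared_split else base_config.seed + 1000 * (i + 1),
        )
        out.append(evaluate_combo(cohort, cfg, split=split))
    return out
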