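"""Presence-background SDM algorithms behind one fit/predict contract.

Five algorithm families are exposed, mirroring common SDM practice, each with
fixed "default" hyperparameters pinned here so runs are reproducible:

``GLM``
    Logistic regression with linear + quadratic terms per predictor
    (unpenalised).
``GAM``
    Logistic additive model: cubic regression-spline basis per predictor with
    a small basis dimension, fitted as a ridge-penalised logistic regression.
``GBM``
    Gradient-boosted classification trees (2500 trees, depth 7, learning rate
    0.001 — the conventional boosted-SDM defaults).
``RF``
    Random forest with 500 trees; class-probability output.
``MAXENT``
    Maxent-style penalised presence/background logistic regression on linear,
    quadratic and hinge transformations of the predictors (the "maxnet"
    formulation), i.e. an L1-regularised GLM on an expanded feature set — not
    the Java application.

All algorithms consume a feature table (rows = presence and background
points) and produce a scorer mapping feature vectors to [0, 1].
Cross-validation follows the 5-fold × 5-background-replicate scheme: each
replicate draws a fresh uniform background sample, presences and background
are split into stratified folds, one model is fitted per (replicate, fold) —
25 runs per configuration cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import SplineTransformer

from ._seeds import derive_seed
from .errors import DegenerateDataError, GridError, ParameterError
from .predictor_prep import extract_features
from .raster import EnvStack, Raster

__all__ = [
    "ALGORITHMS",
    "DEFAULT_HYPERPARAMETERS",
    "ModelSpec",
    "FittedModel",
    "CVPlan",
    "CVRun",
    "make_background",
    "fit_model",
    "predict_surface",
    "cross_validate",
]

ALGORITHMS = ("GLM", "GAM", "GBM", "RF", "MAXENT")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "GLM": {"max_iter": 1000},
    "GAM": {"n_knots": 4, "degree": 3, "C": 1.0, "max_iter": 1000},
    "GBM": {"n_estimators": 2500, "learning_rate": 0.001, "max_depth": 7},
    "RF": {"n_estimators": 500},
    "MAXENT": {"n_hinge": 5, "reg_multiplier": 1.0, "max_iter": 2000},
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus (default-filled) hyperparameters and seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(self.hyperparameters)
        return params


@dataclass
class FittedModel:
    """A fitted scorer over feature vectors; predictions lie in [0, 1]."""

    spec: ModelSpec
    feature_names: list[str]
    _predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    replicate: int | None = None
    fold: int | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ParameterError(
                f"expected (n, {len(self.feature_names)}) feature matrix"
            )
        return np.clip(self._predict(X), 0.0, 1.0)


@dataclass(frozen=True)
class CVPlan:
    """5-fold × 5-background-replicate cross-validation plan."""

    k_folds: int = 5
    n_background_replicates: int = 5
    background_size: int = 1000
    seed: int = 0


@dataclass
class CVRun:
    """One of the 25 cross-validation runs of a configuration cell."""

    model: FittedModel
    replicate: int
    fold: int
    test_scores: np.ndarray
    test_labels: np.ndarray
    train_index: np.ndarray
    test_index: np.ndarray


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def make_background(stack: EnvStack, n_bg: int, seed: int = 0) -> np.ndarray:
    """Uniform random background points over valid (non-nodata) cells."""
    if n_bg < 1:
        raise ParameterError("n_bg must be >= 1")
    mask = stack.joint_valid_mask
    cells = np.argwhere(mask)
    if n_bg > len(cells) * 100:
        raise ParameterError("background size far exceeds available cells")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cells), size=n_bg)
    rows, cols = cells[idx, 0], cells[idx, 1]
    spec = stack.spec
    u = rng.random(n_bg)
    v = rng.random(n_bg)
    x = spec.origin_x + (cols + u) * spec.cell_size
    y = spec.origin_y + (spec.n_rows - rows - 1 + v) * spec.cell_size
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _standardiser(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd <= 0] = 1.0
    return lambda A: (A - mean) / sd


def _maxent_expansion(X01: np.ndarray, n_hinge: int) -> np.ndarray:
    """Linear + quadratic + forward/reverse hinge features on [0,1] inputs."""
    feats = [X01, X01**2]
    knots = np.linspace(0.0, 1.0, n_hinge + 2)[1:-1]
    for t in knots:
        feats.append(np.clip((X01 - t) / (1.0 - t), 0.0, None))
        feats.append(np.clip((t - X01) / t, 0.0, None))
    return np.hstack(feats)


def fit_model(spec: ModelSpec, features: pd.DataFrame) -> FittedModel:
    """Fit one SDM on a feature table with a binary ``label`` column.

    Requires both classes and at least two presence rows.  Returns a
    :class:`FittedModel` whose ``predict`` maps raw feature vectors (same
    column order as the table, minus ``label``) to scores in [0, 1].
    """
    if "label" not in features.columns:
        raise ParameterError("feature table needs a 'label' column")
    feature_names = [c for c in features.columns if c != "label"]
    X = features[feature_names].to_numpy(dtype=float)
    y = features["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training data contains a single class")
    if int((y == 1).sum()) < 2:
        raise DegenerateDataError("need at least two presence rows")

    params = spec.resolved()
    alg = spec.algorithm
    # 0.5-prevalence weighting: presences and background contribute equal
    # total weight, so predicted probabilities are not deflated by the
    # presence:background ratio (the biomod2-style default)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    sample_weight = np.where(y == 1, len(y) / (2.0 * n1), len(y) / (2.0 * n0))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        if alg == "GLM":
            scale = _standardiser(X)
            transform = lambda A: np.hstack([scale(A), scale(A) ** 2])
            est = LogisticRegression(
                C=np.inf, max_iter=params["max_iter"], random_state=spec.seed
            )
        elif alg == "GAM":
            scale = _standardiser(X)
            spline = SplineTransformer(
                n_knots=params["n_knots"],
                degree=params["degree"],
                knots="uniform",
                include_bias=False,
            )
            spline.fit(scale(X))
            transform = lambda A: spline.transform(scale(A))
            est = LogisticRegression(
                C=params["C"],
                max_iter=params["max_iter"],
                random_state=spec.seed,
            )
        elif alg == "GBM":
            transform = lambda A: A
            est = GradientBoostingClassifier(
                n_estimators=params["n_estimators"],
                learning_rate=params["learning_rate"],
                max_depth=params["max_depth"],
                random_state=spec.seed,
            )
        elif alg == "RF":
            transform = lambda A: A
            est = RandomForestClassifier(
                n_estimators=params["n_estimators"],
                random_state=spec.seed,
                n_jobs=1,
            )
        else:  # MAXENT
            lo = X.min(axis=0)
            span = X.max(axis=0) - lo
            span[span <= 0] = 1.0
            n_hinge = params["n_hinge"]
            transform = lambda A: _maxent_expansion(
                np.clip((A - lo) / span, 0.0, 1.0), n_hinge
            )
            est = LogisticRegression(
                l1_ratio=1,
                C=1.0 / params["reg_multiplier"],
                solver="liblinear",
                max_iter=params["max_iter"],
                random_state=spec.seed,
            )
        if alg == "MAXENT":
            # maxnet keeps the raw presence/background contrast; its output
            # is a relative suitability index, not a calibrated probability
            est.fit(transform(X), y)
        else:
            est.fit(transform(X), y, sample_weight=sample_weight)

    pos_col = int(np.argwhere(est.classes_ == 1)[0, 0])

    def _predict(A: np.ndarray) -> np.ndarray:
        return est.predict_proba(transform(A))[:, pos_col]

    return FittedModel(spec=spec, feature_names=feature_names, _predict=_predict)


def predict_surface(model: FittedModel, stack: EnvStack) -> Raster:
    """Score every valid cell of a stack; nodata propagates."""
    missing = [n for n in model.feature_names if n not in stack.names]
    if missing:
        raise GridError(f"stack is missing model layers: {missing}")
    sub = stack.subset(model.feature_names)
    mask = sub.joint_valid_mask
    X = sub.table(mask)
    values = np.full(stack.spec.shape, np.nan)
    values[mask] = model.predict(X)
    return Raster(stack.spec, values)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _class_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled k-fold test-index lists for one class."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [test for _, test in kf.split(np.arange(n))]


def cross_validate(
    spec: ModelSpec,
    presence_points: np.ndarray,
    stack: EnvStack,
    plan: CVPlan = CVPlan(),
) -> list[CVRun]:
    """Run the full 5-fold × 5-background-replicate scheme (25 fits).

    Presences and background are split into folds separately (so every fold
    holds both classes); each background replicate draws a fresh uniform
    background sample of ``plan.background_size`` points.  Held-out scores
    and labels of every run are returned alongside the fitted model.
    """
    presence_points = np.asarray(presence_points, dtype=float)
    n_pres = len(presence_points)
    if n_pres < plan.k_folds:
        raise DegenerateDataError(
            f"need at least k_folds={plan.k_folds} presences, got {n_pres}"
        )
    runs: list[CVRun] = []
    for rep in range(plan.n_background_replicates):
        bg = make_background(
            stack, plan.background_size, seed=derive_seed(plan.seed, "background", rep)
        )
        pts = np.vstack([presence_points, bg])
        labels = np.concatenate(
            [np.ones(n_pres, dtype=int), np.zeros(len(bg), dtype=int)]
        )
        feats = extract_features(stack, pts, labels=labels)
        X_all = feats  # index preserves position in pts
        pres_idx = X_all.index[X_all["label"] == 1].to_numpy()
        bg_idx = X_all.index[X_all["label"] == 0].to_numpy()
        pres_folds = _class_folds(
            len(pres_idx), plan.k_folds, derive_seed(plan.seed, "pfold", rep)
        )
        bg_folds = _class_folds(
            len(bg_idx), plan.k_folds, derive_seed(plan.seed, "bfold", rep)
        )
        for fold in range(plan.k_folds):
            test = np.concatenate(
                [pres_idx[pres_folds[fold]], bg_idx[bg_folds[fold]]]
            )
            test_mask = X_all.index.isin(test)
            train_df = X_all[~test_mask]
            test_df = X_all[test_mask]
            model = fit_model(
                ModelSpec(
                    spec.algorithm,
                    spec.hyperparameters,
                    seed=derive_seed(spec.seed, rep, fold),
                ),
                train_df,
            )
            model.replicate, model.fold = rep, fold
            scores = model.predict(
                test_df[model.feature_names].to_numpy(dtype=float)
            )
            runs.append(
                CVRun(
                    model=model,
                    replicate=rep,
                    fold=fold,
                    test_scores=scores,
                    test_labels=test_df["label"].to_numpy(),
                    train_index=train_df.index.to_numpy(),
                    test_index=test_df.index.to_numpy(),
                )
            )
    return runs
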