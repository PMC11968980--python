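"""Regression models of chromatin contact frequency from GReX features.

Two routes are provided:

1. A baseline suite — ordinary linear regression plus four non-linear
   regressors (polynomial, random forest, support vector, gradient
   boosting), each grid-searched on an 80/20 train-validation split with R²
   as the selection metric.
2. Fully-connected feed-forward networks trained by mini-batch gradient
   descent on the mean-squared-error loss with optional L1/L2 penalties,
   dropout and max-norm weight constraints. The implementation covers the
   named weight-initialization schemes (normal, Kaiming uniform/normal,
   Xavier normal, uniform, zeros), activations (ReLU, hard sigmoid,
   softsign, tanh, linear) and optimizers (SGD, Adagrad, Adam, NAdam), and
   a 5-fold cross-validated grid search over (architecture, training
   config) candidates.

Three named presets capture the optimal published architectures: a
whole-blood GReX model (2×120 hard sigmoid, Kaiming-uniform hidden /
Kaiming-normal output init, NAdam lr 0.01, 90 epochs, batch 110), a
cerebellum GReX model (2×90 softsign, Xavier-normal / uniform init,
Adagrad lr 0.3, 50 epochs, batch 80), and a K562 nuclear run-on model
(2×150 ReLU, normal / zeros init, Adagrad lr 0.2, 90 epochs, batch 160).

Features are z-scored with statistics fitted on the training data only and
stored with the model, so cross-tissue application reuses the training
tissue's scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR

from .contact_pairs import PairDataset

ACTIVATIONS = ("relu", "hard_sigmoid", "softsign", "tanh", "linear")
INITS = ("normal", "kaiming_uniform", "kaiming_normal", "xavier_normal", "uniform", "zeros")
OPTIMIZERS = ("sgd", "adagrad", "adam", "nadam")


@dataclass(frozen=True)
class NNArchitecture:
    """Specification of a fully-connected contact-frequency network."""

    n_inputs: int = 2
    hidden_layers: int = 2
    hidden_neurons: int = 90
    activation: str = "softsign"
    hidden_init: str = "xavier_normal"
    output_init: str = "uniform"
    dropout: float = 0.0
    weight_constraint: Optional[float] = None  # max-norm bound on incoming weights
    l1: float = 0.0
    l2: float = 0.0

    def __post_init__(self) -> None:
        if self.n_inputs <= 0 or self.hidden_layers <= 0 or self.hidden_neurons <= 0:
            raise ValueError("layer counts and sizes must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.hidden_init not in INITS or self.output_init not in INITS:
            raise ValueError("unknown initialization scheme")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("l1/l2 must be nonnegative")

    @property
    def n_parameters(self) -> int:
        sizes = [self.n_inputs] + [self.hidden_neurons] * self.hidden_layers + [1]
        return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adagrad"
    learning_rate: float = 0.3
    epochs: int = 50
    batch_size: int = 80
    cv_folds: int = 5
    selection_metric: str = "r2"  # "r2" | "rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.selection_metric not in ("r2", "rmse"):
            raise ValueError("selection_metric must be 'r2' or 'rmse'")


PRESETS: Dict[str, Tuple[NNArchitecture, TrainConfig]] = {
    "whole_blood": (
        NNArchitecture(2, 2, 120, "hard_sigmoid", "kaiming_uniform", "kaiming_normal"),
        TrainConfig("nadam", 0.01, 90, 110),
    ),
    "cerebellum": (
        NNArchitecture(2, 2, 90, "softsign", "xavier_normal", "uniform"),
        TrainConfig("adagrad", 0.3, 50, 80),
    ),
    "k562_run_on": (
        NNArchitecture(2, 2, 150, "relu", "normal", "zeros"),
        TrainConfig("adagrad", 0.2, 90, 160),
    ),
}


@dataclass
class PredictionVector:
    """Observed/predicted outcome pair for R² evaluation."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed and predicted must have equal length")

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def mean_observed(self) -> float:
        return float(self.observed.mean())


def evaluate_r2(p: Union[PredictionVector, Tuple[np.ndarray, np.ndarray]]) -> float:
    """Coefficient of determination 1 − Σ(ŷ−y)² / Σ(y−ȳ)² (may be negative)."""
    if not isinstance(p, PredictionVector):
        p = PredictionVector(*p)
    if p.n < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(((p.observed - p.mean_observed) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in observed outcome; R² undefined")
    ss_res = float(((p.predicted - p.observed) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def mse(p: PredictionVector) -> float:
    return float(((p.observed - p.predicted) ** 2).mean())


# ---------------------------------------------------------------------------
# Activations / initializers / optimizers


def _activation(name: str):
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0),
                lambda z, a: (z > 0).astype(float))
    if name == "hard_sigmoid":
        # max(0, min(1, 0.2 z + 0.5))
        return (lambda z: np.clip(0.2 * z + 0.5, 0.0, 1.0),
                lambda z, a: np.where((z > -2.5) & (z < 2.5), 0.2, 0.0))
    if name == "softsign":
        return (lambda z: z / (1.0 + np.abs(z)),
                lambda z, a: 1.0 / (1.0 + np.abs(z)) ** 2)
    if name == "tanh":
        return (np.tanh, lambda z, a: 1.0 - a**2)
    if name == "linear":
        return (lambda z: z, lambda z, a: np.ones_like(z))
    raise ValueError(name)


def _init_weights(name: str, fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    shape = (fan_in, fan_out)
    if name == "normal":
        return rng.normal(0.0, 0.05, shape)
    if name == "kaiming_uniform":
        bound = np.sqrt(6.0 / fan_in)
        return rng.uniform(-bound, bound, shape)
    if name == "kaiming_normal":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
    if name == "xavier_normal":
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), shape)
    if name == "uniform":
        return rng.uniform(-0.05, 0.05, shape)
    if name == "zeros":
        return np.zeros(shape)
    raise ValueError(name)


class _Optimizer:
    """Per-parameter adaptive update rules."""

    def __init__(self, name: str, lr: float, params: List[np.ndarray]):
        self.name = name
        self.lr = lr
        self.t = 0
        self.state = [
            {"g2": np.zeros_like(p), "m": np.zeros_like(p), "v": np.zeros_like(p)}
            for p in params
        ]

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, st in zip(params, grads, self.state):
            if self.name == "sgd":
                p -= self.lr * g
            elif self.name == "adagrad":
                st["g2"] += g * g
                p -= self.lr * g / (np.sqrt(st["g2"]) + 1e-10)
            elif self.name == "adam":
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / (1 - b1**self.t)
                vhat = st["v"] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            elif self.name == "nadam":
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / (1 - b1 ** (self.t + 1))
                vhat = st["v"] / (1 - b2**self.t)
                nesterov = b1 * mhat + (1 - b1) * g / (1 - b1 ** (self.t + 1))
                p -= self.lr * nesterov / (np.sqrt(vhat) + eps)
            else:
                raise ValueError(self.name)


# ---------------------------------------------------------------------------
# The network


@dataclass
class TrainedModel:
    """A trained contact-frequency network with its feature scaling."""

    architecture: NNArchitecture
    config: TrainConfig
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    fold_scores: List[float] = field(default_factory=list)
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.architecture.n_inputs

    def predict(self, X: Union[np.ndarray, PairDataset]) -> np.ndarray:
        if isinstance(X, PairDataset):
            X = X.features(with_distance=self.architecture.n_inputs == 3)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        Z = (X - self.feature_mean) / self.feature_std
        act, _ = _activation(self.architecture.activation)
        a = Z
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = act(a @ W + b)
        out = a @ self.weights[-1] + self.biases[-1]
        return out.ravel()


def _forward_backward(Xb, yb, weights, biases, act, dact, arch, rng):
    """One mini-batch pass; returns (grads_W, grads_b, batch_loss)."""
    n = Xb.shape[0]
    a = Xb
    acts = [a]
    zs = []
    masks = []
    for li, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W + b
        zs.append(z)
        if li < len(weights) - 1:
            a = act(z)
            if arch.dropout > 0.0:
                keep = 1.0 - arch.dropout
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
        else:
            a = z
        acts.append(a)
    pred = acts[-1].ravel()
    err = pred - yb
    loss = float((err**2).mean())
    delta = (2.0 / n) * err[:, None]
    gW: List[np.ndarray] = [None] * len(weights)  # type: ignore[list-item]
    gb: List[np.ndarray] = [None] * len(weights)  # type: ignore[list-item]
    for li in range(len(weights) - 1, -1, -1):
        gW[li] = acts[li].T @ delta
        gb[li] = delta.sum(axis=0)
        gW[li] += arch.l1 * np.sign(weights[li]) + 2.0 * arch.l2 * weights[li]
        if li > 0:
            delta = delta @ weights[li].T
            if masks[li - 1] is not None:
                delta = delta * masks[li - 1]
            delta = delta * dact(zs[li - 1], act(zs[li - 1]))
    return gW, gb, loss


def train_nn(
    train: Union[PairDataset, Tuple[np.ndarray, np.ndarray]],
    arch: NNArchitecture,
    cfg: TrainConfig,
    provenance: Optional[Dict[str, object]] = None,
) -> TrainedModel:
    """Train a network by mini-batch gradient descent on the MSE loss.

    Loss = MSE + l1·Σ|w| + l2·Σw² over weight matrices (biases unpenalized).
    Features are z-scored with training-set statistics stored on the model.
    Fully deterministic given ``cfg.seed``. Non-finite loss aborts with
    diagnostics.
    """
    if isinstance(train, PairDataset):
        X = train.features(with_distance=arch.n_inputs == 3)
        y = train.contact
    else:
        X, y = train
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != arch.n_inputs:
        raise ValueError(f"architecture expects {arch.n_inputs} inputs, data has {X.shape[1]}")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Z = (X - mean) / std

    rng = np.random.default_rng(cfg.seed)
    sizes = [arch.n_inputs] + [arch.hidden_neurons] * arch.hidden_layers + [1]
    weights = [
        _init_weights(arch.hidden_init if i < len(sizes) - 2 else arch.output_init,
                      sizes[i], sizes[i + 1], rng)
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    act, dact = _activation(arch.activation)
    params = weights + biases
    opt = _Optimizer(cfg.optimizer, cfg.learning_rate, params)

    n = Z.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            gW, gb, loss = _forward_backward(Z[idx], y[idx], weights, biases,
                                             act, dact, arch, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch offset {start} "
                    f"(lr={cfg.learning_rate}, optimizer={cfg.optimizer})"
                )
            opt.step(params, gW + gb)
            if arch.weight_constraint is not None:
                for W in weights:
                    norms = np.linalg.norm(W, axis=0, keepdims=True)
                    factor = np.minimum(1.0, arch.weight_constraint / np.maximum(norms, 1e-12))
                    W *= factor
    return TrainedModel(arch, cfg, weights, biases, mean, std,
                        provenance=dict(provenance or {}))


def cross_validate_nn(
    data: Union[PairDataset, Tuple[np.ndarray, np.ndarray]],
    arch: NNArchitecture,
    cfg: TrainConfig,
) -> List[float]:
    """K-fold CV scores (R² or RMSE per ``cfg.selection_metric``)."""
    if isinstance(data, PairDataset):
        X = data.features(with_distance=arch.n_inputs == 3)
        y = data.contact
    else:
        X, y = data
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cfg.cv_folds)
    scores = []
    for k in range(cfg.cv_folds):
        te = folds[k]
        tr = np.concatenate([folds[j] for j in range(cfg.cv_folds) if j != k])
        model = train_nn((X[tr], y[tr]), arch, cfg)
        pred = model.predict(X[te])
        pv = PredictionVector(y[te], pred)
        scores.append(evaluate_r2(pv) if cfg.selection_metric == "r2"
                      else float(np.sqrt(mse(pv))))
    return scores


def nn_grid_search(
    train: Union[PairDataset, Tuple[np.ndarray, np.ndarray]],
    space: Sequence[Tuple[NNArchitecture, TrainConfig]],
    folds: int = 5,
) -> Tuple[pd.DataFrame, Tuple[NNArchitecture, TrainConfig]]:
    """Rank candidate (architecture, config) pairs by mean CV score.

    R² is maximized, RMSE minimized; ties break toward fewer parameters,
    then lower candidate index. Candidates whose training produces a
    non-finite loss are marked failed and excluded from the ranking.
    """
    if not space:
        raise ValueError("search space is empty")
    rows = []
    for idx, (arch, cfg) in enumerate(space):
        cfg = replace(cfg, cv_folds=folds)
        try:
            scores = cross_validate_nn(train, arch, cfg)
            rows.append({"candidate": idx, "mean_score": float(np.mean(scores)),
                         "n_parameters": arch.n_parameters, "failed": False,
                         "fold_scores": scores})
        except FloatingPointError as exc:
            warnings.warn(f"candidate {idx} failed: {exc}")
            rows.append({"candidate": idx, "mean_score": np.nan,
                         "n_parameters": arch.n_parameters, "failed": True,
                         "fold_scores": []})
    results = pd.DataFrame(rows)
    ok = results[~results["failed"]].copy()
    if ok.empty:
        raise RuntimeError("all grid-search candidates failed")
    metric = space[0][1].selection_metric
    ascending = metric == "rmse"
    ok = ok.sort_values(["mean_score", "n_parameters", "candidate"],
                        ascending=[ascending, True, True])
    best_idx = int(ok.iloc[0]["candidate"])
    ranked = pd.concat([ok, results[results["failed"]]]).reset_index(drop=True)
    return ranked, space[best_idx]


# ---------------------------------------------------------------------------
# Baseline suite

DEFAULT_GRIDS: Dict[str, List] = {
    "polynomial": list(range(1, 11)),        # degree 1..10
    "random_forest": list(range(10, 101, 10)),  # 10..100 trees
    "svr": [round(0.1 * k, 1) for k in range(1, 11)],  # epsilon 0.1..1
    "gradient_boosting": list(range(10, 301, 40)),  # 10..290 boosting stages
}

_SVR_MAX_ROWS = 4000  # kernel SVR is quadratic in n; fit on a subsample


def fit_baseline_suite(
    train: Union[PairDataset, Tuple[np.ndarray, np.ndarray]],
    val_fraction: float = 0.2,
    grids: Optional[Dict[str, List]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid-search the linear + four non-linear baselines.

    Returns a table (model_name, best_hyperparameter, validation_r2). The
    split is 80/20 train-validation; R² selects the best hyperparameter per
    family. SVR is fit on a row subsample when the training portion exceeds
    a few thousand rows, since kernel fits scale quadratically.
    """
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    for name, grid in grids.items():
        if not grid:
            raise ValueError(f"empty grid for {name}")
    if isinstance(train, PairDataset):
        X = train.features()
        y = train.contact
    else:
        X, y = train
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_tr = int(np.floor(n * (1.0 - val_fraction)))
    tr, va = perm[:n_tr], perm[n_tr:]
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    def val_r2(model, Xt=Xtr, yt=ytr):
        model.fit(Xt, yt)
        return evaluate_r2(PredictionVector(yva, model.predict(Xva)))

    rows = [("linear", None, val_r2(LinearRegression()))]

    best = max(grids["polynomial"],
               key=lambda d: val_r2(make_pipeline(PolynomialFeatures(d), LinearRegression())))
    rows.append(("polynomial", best,
                 val_r2(make_pipeline(PolynomialFeatures(best), LinearRegression()))))

    def rf(k):
        return RandomForestRegressor(n_estimators=k, random_state=seed, n_jobs=1)

    best = max(grids["random_forest"], key=lambda k: val_r2(rf(k)))
    rows.append(("random_forest", best, val_r2(rf(best))))

    if len(tr) > _SVR_MAX_ROWS:
        sub = rng.choice(len(tr), _SVR_MAX_ROWS, replace=False)
        Xs, ys = Xtr[sub], ytr[sub]
    else:
        Xs, ys = Xtr, ytr

    def svr(eps):
        return make_pipeline(StandardScaler(), SVR(epsilon=eps))

    best = max(grids["svr"], key=lambda e: val_r2(svr(e), Xs, ys))
    rows.append(("svr", best, val_r2(svr(best), Xs, ys)))

    def gbr(k):
        return GradientBoostingRegressor(n_estimators=k, random_state=seed)

    best = max(grids["gradient_boosting"], key=lambda k: val_r2(gbr(k)))
    rows.append(("gradient_boosting", best, val_r2(gbr(best))))

    return pd.DataFrame(rows, columns=["model_name", "best_hyperparameter", "validation_r2"])
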