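"""Feed-forward network and classical baselines for pseudo-IC50 prediction.

The network is a fully connected conic MLP (default two hidden layers of
200 and 100 units) with ReLU hidden activations, inverted dropout after
each hidden layer, and either a linear output trained under mean squared
error (regression on log-IC50) or a sigmoid output trained under mean
binary cross-entropy (classification of potent responses).  Optimizers:
Adam (regression default), RMSprop (classification default) or plain SGD.
All randomness — weight initialization, dropout masks, mini-batch order —
flows through one seeded generator, so a fixed seed gives bit-identical
training histories.

Baselines (KNN, random forest, SVM, gradient boosting) stand on
scikit-learn estimators configured with the tuned settings used for the
reference comparison, behind the same predict contract.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "DNNRegressor",
    "DNNClassifier",
    "parameter_count",
    "BASELINE_DEFAULTS",
    "BaselineConfig",
    "make_baseline",
    "train_baseline",
    "predict_scores",
    "grid_search_cv",
    "default_grids",
    "save_dnn",
    "load_dnn",
]


def parameter_count(input_dim: int, hidden_units: Sequence[int], output_dim: int = 1) -> int:
    """Total weights + biases of a dense network with the given layer widths."""
    widths = [input_dim, *hidden_units, output_dim]
    if any(w < 1 for w in widths):
        raise ValueError("all layer widths must be >= 1")
    return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the feed-forward network."""

    input_dim: int
    hidden_units: tuple[int, ...] = (200, 100)
    dropout_rate: float = 0.5
    output_activation: str = "linear"  # "linear" (regression) | "sigmoid" (classification)

    def __post_init__(self):
        if self.input_dim < 1 or any(h < 1 for h in self.hidden_units):
            raise ValueError("all layer widths must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.output_activation not in ("linear", "sigmoid"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.input_dim, self.hidden_units)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults follow the tuned regression/classification setups."""

    task: str = "regression"
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 128
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")
        if self.optimizer not in ("adam", "rmsprop", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def for_regression(cls, **overrides) -> "TrainingConfig":
        base = dict(task="regression", optimizer="adam", learning_rate=1e-5, batch_size=128, epochs=200)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def for_classification(cls, **overrides) -> "TrainingConfig":
        base = dict(task="classification", optimizer="rmsprop", learning_rate=1e-3, batch_size=32, epochs=500)
        base.update(overrides)
        return cls(**base)


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Optimizer:
    def __init__(self, kind: str, lr: float):
        self.kind, self.lr = kind, lr
        self.state: dict[int, tuple] = {}
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.kind == "sgd":
                p -= self.lr * g
            elif self.kind == "rmsprop":
                cache = self.state.get(i, np.zeros_like(p))
                cache = 0.9 * cache + 0.1 * g * g
                self.state[i] = cache
                p -= self.lr * g / (np.sqrt(cache) + 1e-8)
            else:  # adam
                m, v = self.state.get(i, (np.zeros_like(p), np.zeros_like(p)))
                m = 0.9 * m + 0.1 * g
                v = 0.999 * v + 0.001 * g * g
                self.state[i] = (m, v)
                mhat = m / (1 - 0.9**self.t)
                vhat = v / (1 - 0.999**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class _BaseDNN(BaseEstimator):
    """Shared fit/forward machinery; subclasses fix output activation and loss."""

    _output_activation = "linear"

    def __init__(
        self,
        hidden_units: Sequence[int] = (200, 100),
        dropout_rate: float = 0.5,
        optimizer: str = "adam",
        learning_rate: float = 1e-5,
        batch_size: int = 128,
        epochs: int = 200,
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    # -- core ---------------------------------------------------------------

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> None:
        widths = [input_dim, *list(self.hidden_units), 1]
        self.weights_ = [_glorot_uniform(rng, a, b) for a, b in zip(widths[:-1], widths[1:])]
        self.biases_ = [np.zeros(b) for b in widths[1:]]

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; dropout only when a generator is supplied (training)."""
        acts, masks = [X], []
        a = X
        n_hidden = len(self.weights_) - 1
        for layer in range(n_hidden):
            z = a @ self.weights_[layer] + self.biases_[layer]
            a = np.maximum(z, 0.0)
            if rng is not None and self.dropout_rate > 0:
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(a.shape) < keep) / keep  # inverted dropout
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        z_out = (a @ self.weights_[-1] + self.biases_[-1]).ravel()
        if self._output_activation == "sigmoid":
            from scipy.special import expit

            out = expit(z_out)
        else:
            out = z_out
        return out, acts, masks

    def _loss_and_delta(self, pred: np.ndarray, y: np.ndarray):
        raise NotImplementedError

    def _fit_core(self, X: np.ndarray, y: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        spec = NetworkSpec(
            input_dim=X.shape[1],
            hidden_units=tuple(self.hidden_units),
            dropout_rate=self.dropout_rate,
            output_activation=self._output_activation,
        )
        cfg = TrainingConfig(
            task="regression" if self._output_activation == "linear" else "classification",
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)
        opt = _Optimizer(cfg.optimizer, cfg.learning_rate)
        n = X.shape[0]
        history = []
        # overflow during a diverging run is caught by the finite-loss check
        with np.errstate(over="ignore", invalid="ignore"):
            self._run_epochs(X, y, cfg, rng, opt, n, history)
        self.loss_curve_ = history
        self.n_features_in_ = X.shape[1]
        self.spec_ = spec
        self.config_ = cfg

    def _run_epochs(self, X, y, cfg, rng, opt, n, history) -> None:
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                pred, acts, masks = self._forward(xb, rng=rng)
                loss, delta = self._loss_and_delta(pred, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch offset {start}; "
                        "lower the learning rate or rescale the inputs"
                    )
                epoch_loss += loss * len(idx)
                seen += len(idx)
                self._backward(delta, acts, masks, opt)
            history.append(epoch_loss / seen)

    def _backward(self, delta: np.ndarray, acts, masks, opt: _Optimizer) -> None:
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.biases_)
        d = delta[:, None]  # (B, 1) at the output
        grads_w[-1] = acts[-1].T @ d
        grads_b[-1] = d.sum(axis=0)
        da = d @ self.weights_[-1].T
        for layer in range(len(self.weights_) - 2, -1, -1):
            a = acts[layer + 1]
            if masks[layer] is not None:
                da = da * masks[layer]
            dz = da * (a > 0)
            grads_w[layer] = acts[layer].T @ dz
            grads_b[layer] = dz.sum(axis=0)
            if layer > 0:
                da = dz @ self.weights_[layer].T
        opt.step(self.weights_ + self.biases_, grads_w + grads_b)

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        out, _, _ = self._forward(X, rng=None)
        return out


class DNNRegressor(RegressorMixin, _BaseDNN):
    """MLP regressor of log-IC50 under mean squared error."""

    _output_activation = "linear"

    def fit(self, X, y):
        self._fit_core(X, y)
        return self

    def predict(self, X):
        return self._raw_predict(X)

    def _loss_and_delta(self, pred, y):
        err = pred - y
        return float(np.mean(err**2)), 2.0 * err / len(y)


class DNNClassifier(ClassifierMixin, _BaseDNN):
    """MLP classifier of potent (low-IC50) responses under mean binary cross-entropy."""

    _output_activation = "sigmoid"

    def __init__(
        self,
        hidden_units: Sequence[int] = (200, 100),
        dropout_rate: float = 0.5,
        optimizer: str = "rmsprop",
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 500,
        seed: int = 0,
    ):
        super().__init__(hidden_units, dropout_rate, optimizer, learning_rate, batch_size, epochs, seed)

    def fit(self, X, y):
        y = np.asarray(y).ravel()
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("classification labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        self._fit_core(X, y.astype(float))
        return self

    def predict_proba(self, X):
        p = self._raw_predict(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self._raw_predict(X) >= 0.5).astype(int)

    def _loss_and_delta(self, pred, y):
        p = np.clip(pred, 1e-12, 1 - 1e-12)
        loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return loss, (pred - y) / len(y)  # sigmoid + BCE simplification


# -- classical baselines -----------------------------------------------------

BASELINE_DEFAULTS: dict[tuple[str, str], dict] = {
    ("knn", "regression"): {"n_neighbors": 6, "weights": "uniform", "algorithm": "auto"},
    ("knn", "classification"): {"n_neighbors": 5, "weights": "uniform", "algorithm": "auto"},
    ("rf", "regression"): {"n_estimators": 200, "min_samples_leaf": 50},
    ("rf", "classification"): {"n_estimators": 100, "min_samples_leaf": 10},
    ("svm", "regression"): {"kernel": "rbf", "C": 10.0, "gamma": 0.01},
    ("svm", "classification"): {"kernel": "rbf", "C": 1.0, "gamma": 0.1},
    ("gbm", "regression"): {
        "n_estimators": 500,
        "min_samples_split": 1000,
        "learning_rate": 0.01,
        "min_samples_leaf": 60,
    },
    ("gbm", "classification"): {
        "n_estimators": 200,
        "min_samples_split": 600,
        "learning_rate": 0.01,
        "min_samples_leaf": 60,
    },
}

_BASELINE_CLASSES = {
    ("knn", "regression"): KNeighborsRegressor,
    ("knn", "classification"): KNeighborsClassifier,
    ("rf", "regression"): RandomForestRegressor,
    ("rf", "classification"): RandomForestClassifier,
    ("svm", "regression"): SVR,
    ("svm", "classification"): SVC,
    ("gbm", "regression"): GradientBoostingRegressor,
    ("gbm", "classification"): GradientBoostingClassifier,
}


@dataclass(frozen=True)
class BaselineConfig:
    family: str
    task: str = "regression"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if (self.family, self.task) not in _BASELINE_CLASSES:
            raise ValueError(f"unsupported baseline {self.family!r}/{self.task!r}")


def make_baseline(family: str, task: str = "regression", seed: int = 0, **overrides) -> BaseEstimator:
    """Instantiate a baseline estimator with the tuned default settings."""
    cfg = BaselineConfig(family, task, overrides, seed)
    params = dict(BASELINE_DEFAULTS[(family, task)])
    params.update(overrides)
    cls = _BASELINE_CLASSES[(family, task)]
    if family in ("rf", "gbm"):
        params.setdefault("random_state", seed)
    if family == "svm" and task == "classification":
        params.setdefault("random_state", seed)
    return cls(**params)


def train_baseline(config: BaselineConfig, X: np.ndarray, y: np.ndarray) -> BaseEstimator:
    model = make_baseline(config.family, config.task, seed=config.seed, **dict(config.hyperparameters))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if config.family == "knn":
        k = model.get_params()["n_neighbors"]
        if k > X.shape[0]:
            raise ValueError(f"k={k} exceeds the {X.shape[0]} training samples")
    model.fit(X, y)
    return model


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Uniform predict contract: regression values, or a positive-class score in [0, 1].

    Margin classifiers without calibrated probabilities are mapped through a
    logistic squashing of the decision function.
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        from scipy.special import expit

        return expit(np.asarray(model.decision_function(X), dtype=float).ravel())
    return np.asarray(model.predict(X), dtype=float).ravel()


# -- grid search -------------------------------------------------------------

def default_grids(task: str = "regression") -> dict[str, list]:
    """Hyperparameter grids around the tuned optimum; level counts 5,5,3,3,5,5."""
    center_lr = [1e-5, 1e-4, 1e-3]
    return {
        "epochs": [50, 100, 200, 350, 500],
        "batch_size": [32, 64, 128, 256, 512],
        "learning_rate": center_lr,
        "dropout_rate": [0.2, 0.35, 0.5],
        "hidden1": [50, 100, 200, 300, 400],
        "hidden2": [25, 50, 100, 150, 200],
    }


def grid_size(grids: Mapping[str, Sequence]) -> int:
    out = 1
    for v in grids.values():
        out *= len(v)
    return out


def _make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks."""
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(block) for block in np.array_split(perm, folds)]


def grid_search_cv(
    model_factory,
    grids: Mapping[str, Sequence],
    folds: int,
    X: np.ndarray,
    y: np.ndarray,
    task: str = "regression",
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive k-fold CV over the Cartesian product of ``grids``.

    ``model_factory(**params)`` must return an unfitted estimator.  Returns
    the winning parameter dict (min mean validation MSE for regression, max
    mean validation accuracy for classification; ties resolved to the first
    configuration in product order) and the full CV table.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    for k, v in grids.items():
        if len(v) == 0:
            raise ValueError(f"grid for {k!r} is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    fold_idx = _make_folds(n, folds, seed)
    keys = list(grids.keys())
    records = []
    best_params, best_score = None, None
    for combo in itertools.product(*(grids[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = []
        for val in fold_idx:
            mask = np.ones(n, dtype=bool)
            mask[val] = False
            model = model_factory(**params)
            model.fit(X[mask], y[mask])
            pred = model.predict(X[val])
            if task == "regression":
                scores.append(float(np.mean((pred - y[val]) ** 2)))
            else:
                scores.append(float(np.mean(pred == y[val])))
        mean_score = float(np.mean(scores))
        records.append({**params, "mean_score": mean_score})
        better = (
            best_score is None
            or (task == "regression" and mean_score < best_score)
            or (task != "regression" and mean_score > best_score)
        )
        if better:
            best_params, best_score = params, mean_score
    return best_params, pd.DataFrame.from_records(records)


# -- persistence -------------------------------------------------------------

def save_dnn(model: _BaseDNN, directory: str | Path) -> None:
    """Write a fitted network as JSON spec + NPZ parameter archive."""
    check_is_fitted(model, "weights_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = {
        "kind": "classifier" if isinstance(model, DNNClassifier) else "regressor",
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "loss_curve": model.loss_curve_,
    }
    spec["params"]["hidden_units"] = list(spec["params"]["hidden_units"])
    (directory / "spec.json").write_text(json.dumps(spec, indent=1))
    arrays = {f"W{i}": w for i, w in enumerate(model.weights_)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases_)})
    np.savez(directory / "parameters.npz", **arrays)


def load_dnn(directory: str | Path) -> _BaseDNN:
    directory = Path(directory)
    spec = json.loads((directory / "spec.json").read_text())
    cls = DNNClassifier if spec["kind"] == "classifier" else DNNRegressor
    params = dict(spec["params"])
    params["hidden_units"] = tuple(params["hidden_units"])
    model = cls(**params)
    with np.load(directory / "parameters.npz") as arc:
        n_layers = sum(1 for k in arc.files if k.startswith("W"))
        model.weights_ = [arc[f"W{i}"] for i in range(n_layers)]
        model.biases_ = [arc[f"b{i}"] for i in range(n_layers)]
    model.n_features_in_ = spec["n_features_in"]
    model.loss_curve_ = spec["loss_curve"]
    if spec["kind"] == "classifier":
        model.classes_ = np.array([0, 1])
    return model
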