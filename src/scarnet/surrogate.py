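"""Feed-forward neural surrogate for the contraction model.

The network maps the 25 Min-Max-scaled patient/wound parameters to the
365-day RSA course: two hidden layers of 100 rectified-linear units and a
sigmoid output layer (the RSA is bounded in (0, 1), so the sigmoid is the
natural output unit).  Training minimizes the mean squared error with a
choice of eight first-order optimizers (Adamax by default, initial
learning rate 0.015 decayed by 0.99 per epoch, mini-batches of 64) and
early stopping: training halts once 30 consecutive epochs fail to improve
the monitored loss by more than 1e-5, and the best weights seen are
restored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import ScalerParams, SplitData
from .errors import ConfigurationError, TrainingError
from .optimizers import OPTIMIZERS, make_optimizer

logger = logging.getLogger(__name__)

__all__ = ["NetworkConfig", "TrainingConfig", "SurrogateModel",
           "EarlyStopping", "build_network", "train", "train_with_cv",
           "lr_range_test", "predict"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture: 25 -> 100 -> 100 -> 365, ReLU hidden, sigmoid output."""

    layer_sizes: Tuple[int, ...] = (25, 100, 100, 365)

    def __post_init__(self):
        object.__setattr__(self, "layer_sizes", tuple(self.layer_sizes))
        if len(self.layer_sizes) != 4:
            raise ConfigurationError(
                "the surrogate uses exactly two hidden layers")
        if any(s < 1 for s in self.layer_sizes):
            raise ConfigurationError("layer sizes must be positive")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def n_parameters(self) -> int:
        return sum((a + 1) * b for a, b in
                   zip(self.layer_sizes[:-1], self.layer_sizes[1:]))


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol (loss is always the mean squared error)."""

    optimizer: str = "adamax"
    learning_rate: float = 0.015
    lr_decay: float = 0.99          # multiplicative, once per epoch
    batch_size: int = 64
    patience: int = 30              # early-stopping epochs without improvement
    min_delta: float = 1e-5         # loss change below this is 'no improvement'
    max_epochs: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.min_delta < 0:
            raise ConfigurationError("min_delta must be >= 0")
        if self.optimizer.lower() not in OPTIMIZERS:
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


class EarlyStopping:
    """Improvement bookkeeping: stop after ``patience`` epochs in which the
    monitored loss fails to drop by more than ``min_delta`` below the best."""

    def __init__(self, patience: int = 30, min_delta: float = 1e-5):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0
        self._epoch = -1

    def update(self, loss: float) -> bool:
        """Record one epoch's monitored loss; True means stop now."""
        self._epoch += 1
        if self.best - loss > self.min_delta:
            self.best = loss
            self.best_epoch = self._epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


@dataclass
class SurrogateModel:
    """Weights + architecture + the input scaler fitted with the corpus."""

    weights: List[np.ndarray]           # per layer, shape (fan_in, fan_out)
    biases: List[np.ndarray]
    config: NetworkConfig
    scaler: Optional[ScalerParams] = None
    feature_names: Optional[Tuple[str, ...]] = None
    history: Dict[str, list] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights)
                   + sum(b.size for b in self.biases))

    # ---------------------------- forward pass ----------------------------
    def forward(self, X_scaled: np.ndarray,
                return_hidden: bool = False):
        """Batched forward pass on already-scaled inputs."""
        X_scaled = np.atleast_2d(np.asarray(X_scaled, float))
        if X_scaled.shape[1] != self.config.n_inputs:
            raise ConfigurationError(
                f"expected {self.config.n_inputs} input features, "
                f"got {X_scaled.shape[1]}")
        h1 = np.maximum(X_scaled @ self.weights[0] + self.biases[0], 0.0)
        h2 = np.maximum(h1 @ self.weights[1] + self.biases[1], 0.0)
        logits = h2 @ self.weights[2] + self.biases[2]
        out = _sigmoid(logits)
        if return_hidden:
            return out, (X_scaled, h1, h2)
        return out

    def copy_weights(self) -> Tuple[List[np.ndarray], List[np.ndarray]]:
        return ([w.copy() for w in self.weights],
                [b.copy() for b in self.biases])

    def set_weights(self, weights, biases) -> None:
        self.weights = [w.copy() for w in weights]
        self.biases = [b.copy() for b in biases]

    # ---------------------------- persistence -----------------------------
    def save(self, path) -> None:
        meta = {
            "layer_sizes": list(self.config.layer_sizes),
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
        }
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        if self.scaler is not None:
            arrays["scaler_min"] = self.scaler.data_min
            arrays["scaler_max"] = self.scaler.data_max
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = [data[f"W{i}"] for i in range(3)]
            biases = [data[f"b{i}"] for i in range(3)]
            scaler = None
            if "scaler_min" in data:
                scaler = ScalerParams(data_min=data["scaler_min"],
                                      data_max=data["scaler_max"])
        return cls(weights=weights, biases=biases,
                   config=NetworkConfig(tuple(meta["layer_sizes"])),
                   scaler=scaler,
                   feature_names=tuple(meta["feature_names"])
                   if meta.get("feature_names") else None,
                   history=meta.get("history", {}))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_network(config: Optional[NetworkConfig] = None, seed: int = 0,
                  scaler: Optional[ScalerParams] = None,
                  feature_names: Optional[Sequence[str]] = None) -> SurrogateModel:
    """Glorot-uniform initialized, untrained surrogate (deterministic per seed)."""
    config = config or NetworkConfig()
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(config.layer_sizes[:-1], config.layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return SurrogateModel(weights=weights, biases=biases, config=config,
                          scaler=scaler,
                          feature_names=tuple(feature_names) if feature_names else None)


def _mse(model: SurrogateModel, X: np.ndarray, Y: np.ndarray) -> float:
    pred = model.forward(X)
    return float(np.mean((pred - Y) ** 2))


def _backprop(model: SurrogateModel, Xb: np.ndarray, Yb: np.ndarray):
    """Gradients of the batch MSE w.r.t. all weights and biases."""
    out, (x0, h1, h2) = model.forward(Xb, return_hidden=True)
    B = Xb.shape[0]
    # dL/dlogits for MSE + sigmoid output
    delta = 2.0 * (out - Yb) / (B * Yb.shape[1]) * out * (1.0 - out)
    gW2 = h2.T @ delta
    gb2 = delta.sum(axis=0)
    d2 = (delta @ model.weights[2].T) * (h2 > 0)
    gW1 = h1.T @ d2
    gb1 = d2.sum(axis=0)
    d1 = (d2 @ model.weights[1].T) * (h1 > 0)
    gW0 = x0.T @ d1
    gb0 = d1.sum(axis=0)
    return [gW0, gW1, gW2], [gb0, gb1, gb2]


def train(model: SurrogateModel, X_train: np.ndarray, Y_train: np.ndarray,
          X_val: Optional[np.ndarray] = None,
          Y_val: Optional[np.ndarray] = None,
          config: Optional[TrainingConfig] = None,
          verbose: bool = False) -> SurrogateModel:
    """Mini-batch training with per-epoch learning-rate decay and early
    stopping on the validation MSE (training MSE if no validation set).

    The model is modified in place and returned; ``model.history`` holds the
    per-epoch loss curves and the epoch whose weights were restored.
    """
    config = config or TrainingConfig()
    X_train = np.asarray(X_train, float)
    Y_train = np.asarray(Y_train, float)
    has_val = X_val is not None and Y_val is not None

    opt = make_optimizer(config.optimizer, config.learning_rate)
    stopper = EarlyStopping(config.patience, config.min_delta)
    rng = np.random.default_rng(config.seed)
    params = model.weights + model.biases

    history: Dict[str, list] = {"train_loss": [], "val_loss": []} if has_val \
        else {"train_loss": []}
    best_weights = model.copy_weights()

    n = X_train.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            gw, gb = _backprop(model, X_train[idx], Y_train[idx])
            opt.update(params, gw + gb)

        train_loss = _mse(model, X_train, Y_train)
        history["train_loss"].append(train_loss)
        if has_val:
            monitored = _mse(model, X_val, Y_val)
            history["val_loss"].append(monitored)
        else:
            monitored = train_loss
        if not np.isfinite(monitored):
            raise TrainingError(
                f"training diverged (non-finite loss) at epoch {epoch}",
                epoch=epoch)
        if verbose and epoch % 25 == 0:
            logger.info("epoch %d: monitored MSE %.3e", epoch, monitored)

        stop = stopper.update(monitored)
        if stopper.best_epoch == epoch:
            best_weights = model.copy_weights()
        if stop:
            break
        opt.lr *= config.lr_decay

    model.set_weights(*best_weights)
    model.history = history
    model.history["best_epoch"] = [stopper.best_epoch]
    return model


def train_with_cv(split: SplitData, net_config: Optional[NetworkConfig] = None,
                  train_config: Optional[TrainingConfig] = None,
                  feature_names: Optional[Sequence[str]] = None,
                  verbose: bool = False):
    """Train one model per cross-validation fold plus a final model on the
    full training split; returns (fold_models, final_model)."""
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainingConfig()
    fold_models = []
    for k, (fit_idx, val_idx) in enumerate(split.folds):
        m = build_network(net_config, seed=train_config.seed + k + 1,
                          scaler=split.scaler, feature_names=feature_names)
        train(m, split.X_train[fit_idx], split.Y_train[fit_idx],
              split.X_train[val_idx], split.Y_train[val_idx],
              config=train_config, verbose=verbose)
        fold_models.append(m)
    final = build_network(net_config, seed=train_config.seed,
                          scaler=split.scaler, feature_names=feature_names)
    train(final, split.X_train, split.Y_train, config=train_config,
          verbose=verbose)
    return fold_models, final


def lr_range_test(optimizer_names: Sequence[str], lr_grid: Sequence[float],
                  X: np.ndarray, Y: np.ndarray, epochs: int = 150,
                  batch_size: int = 64, seed: int = 0,
                  smooth_window: int = 5,
                  net_config: Optional[NetworkConfig] = None) -> pd.DataFrame:
    """Learning-rate range test: train a fresh network for every
    (optimizer, learning rate) cell and record the smoothed final loss.

    Divergence is recorded (loss = inf, diverged = True), never raised, so
    the sweep always completes.  The returned frame is sorted by loss.
    """
    if len(lr_grid) == 0 or len(optimizer_names) == 0:
        raise ConfigurationError("need at least one optimizer and one learning rate")
    rows = []
    for name in optimizer_names:
        for lr in lr_grid:
            cfg = TrainingConfig(optimizer=name, learning_rate=float(lr),
                                 lr_decay=1.0, batch_size=batch_size,
                                 patience=epochs + 1, min_delta=0.0,
                                 max_epochs=epochs, seed=seed)
            m = build_network(net_config, seed=seed)
            try:
                train(m, X, Y, config=cfg)
                losses = np.asarray(m.history["train_loss"], float)
                w = min(smooth_window, len(losses))
                loss = float(np.mean(losses[-w:]))
                diverged = not np.isfinite(loss)
            except TrainingError:
                loss, diverged = np.inf, True
            rows.append({"optimizer": name, "lr": float(lr),
                         "loss": loss, "diverged": diverged})
    return pd.DataFrame(rows).sort_values("loss").reset_index(drop=True)


def predict(model: SurrogateModel, raw_inputs: np.ndarray) -> np.ndarray:
    """RSA predictions (n x 365) from raw (unscaled) parameter vectors.

    Inputs outside the scaler's fitted range are allowed (the network
    extrapolates) but logged as a warning.
    """
    X = np.atleast_2d(np.asarray(raw_inputs, float))
    if model.scaler is not None:
        Xs = model.scaler.transform(X)
        if np.any(Xs < -1e-9) or np.any(Xs > 1 + 1e-9):
            warnings.warn(
                "inputs outside the scaler's fitted range; the surrogate "
                "extrapolates", stacklevel=2)
    else:
        Xs = X
    return model.forward(Xs)
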