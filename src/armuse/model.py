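"""CNN + Dense binary classifier for 2-s accelerometry windows.

The network takes a (60, C, 1) window — 60 time samples at 30 Hz by C
acceleration channels (3 for a single arm, 6 for both) — and outputs the
probability that the movement is functional.  Architecture:

* feature extraction: two 3×3 "same" convolution blocks (16 then 32
  filters), each followed by batch normalisation, ReLU and 20% dropout;
* feature aggregation: flatten, then two dense layers of 64 ReLU units
  with L2 kernel penalty (λ = 1e-3) and 30% dropout each;
* classification: a single sigmoid unit.

Training uses Adam (initial learning rate 1e-3), binary cross-entropy,
batch size 64, for up to 700 epochs, with the learning rate cut by a
factor of 0.1 whenever the validation loss is flat for 10 epochs, and
early stopping (patience 20 on validation accuracy) that restores the
best-validation-epoch weights.

:class:`FunctionalUseCNN` wraps all of this in a scikit-learn estimator
(``fit`` / ``predict`` / ``predict_proba``), so it composes with sklearn
model selection; the module-level :func:`train` / :func:`predict_proba` /
:func:`classify` functions are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _net

WINDOW_T = 60
SUPPORTED_CHANNELS = (3, 6)


class SingleClassError(ValueError):
    """Training data contains one class only.

    Severely imbalanced subjects can lose their minority windows to a
    split; rebalance the training set (see :mod:`armuse.imbalance`)
    or use a stratified split.
    """


@dataclass
class ArchitectureSpec:
    """Declarative layer list; the analytic parameter count reads this."""

    input_shape: tuple
    layers: list = field(default_factory=list)
    padding: str = "same"

    def add(self, kind: str, **kw):
        self.layers.append({"kind": kind, **kw})


def build_architecture(input_shape: tuple, l2: float = 1e-3) -> ArchitectureSpec:
    """Describe the fixed two-conv / two-dense architecture for one shape.

    ``input_shape`` must be (60, C, 1) with C in {3, 6}; anything else is
    rejected.  The returned spec records every layer with the sizes needed
    to count parameters analytically.
    """
    if len(input_shape) != 3 or input_shape[0] != WINDOW_T \
            or input_shape[1] not in SUPPORTED_CHANNELS or input_shape[2] != 1:
        raise ValueError(
            f"unsupported input shape {input_shape}; expected (60, C, 1), C in {SUPPORTED_CHANNELS}")
    T, C, _ = input_shape
    spec = ArchitectureSpec(input_shape=input_shape)
    c_in = 1
    for filters in (16, 32):
        spec.add("conv2d", filters=filters, kernel=(3, 3), c_in=c_in,
                 padding="same")
        spec.add("batchnorm", features=filters)
        spec.add("relu")
        spec.add("dropout", rate=0.20)
        c_in = filters
    flat = T * C * c_in
    spec.add("flatten", units=flat)
    n_in = flat
    for units in (64, 64):
        spec.add("dense", units=units, n_in=n_in, l2=l2, activation="relu")
        spec.add("dropout", rate=0.30)
        n_in = units
    spec.add("dense", units=1, n_in=n_in, l2=0.0, activation="sigmoid")
    return spec


def count_parameters(spec: ArchitectureSpec, include_non_trainable: bool = False) -> int:
    """Analytic parameter count of a spec, layer by layer.

    Convolution: kh·kw·c_in·filters + filters.  Batch norm: 2·features
    trainable (γ, β) plus 2·features non-trainable running statistics.
    Dense: n_in·units + units.
    """
    trainable = 0
    non_trainable = 0
    for layer in spec.layers:
        kind = layer["kind"]
        if kind == "conv2d":
            kh, kw = layer["kernel"]
            trainable += kh * kw * layer["c_in"] * layer["filters"] + layer["filters"]
        elif kind == "batchnorm":
            trainable += 2 * layer["features"]
            non_trainable += 2 * layer["features"]
        elif kind == "dense":
            trainable += layer["n_in"] * layer["units"] + layer["units"]
    return trainable + (non_trainable if include_non_trainable else 0)


@dataclass
class TrainConfig:
    """Training schedule: Adam 1e-3, batch 64, ≤700 epochs, plateau ×0.1
    after 10 flat validation-loss epochs, early stop patience 20 on
    validation accuracy with best-weight restore."""

    batch_size: int = 64
    max_epochs: int = 700
    lr: float = 1e-3
    lr_factor: float = 0.1
    lr_patience: int = 10
    stop_patience: int = 20
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")
        if not self.lr_patience < self.stop_patience:
            raise ValueError("lr_patience must be smaller than stop_patience")


@dataclass
class TrainedModel:
    """A fitted classifier plus its spec and per-epoch history."""

    estimator: "FunctionalUseCNN"
    spec: ArchitectureSpec
    history: dict
    epochs_run: int


class FunctionalUseCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator around the NumPy CNN.

    Parameters mirror :class:`TrainConfig`; ``fit`` accepts windows of
    shape (N, 60, C) or (N, 60, C, 1) already scaled with the robust
    scaler fitted on the same training split.  Validation data for the
    callbacks is passed to ``fit`` directly; without it a stratified
    ``validation_fraction`` tail split of the training data is used.

    Fitted attributes: ``classes_``, ``spec_``, ``history_``,
    ``epochs_run_``, ``n_parameters_``.
    """

    def __init__(self, batch_size=64, max_epochs=700, lr=1e-3, lr_factor=0.1,
                 lr_patience=10, stop_patience=20, min_delta=1e-4,
                 validation_fraction=0.2, l2=1e-3, seed=0):
        self.l2 = l2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.lr = lr
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, validation_data=None):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise SingleClassError(
                "training data contains a single class; rebalance it "
                "(armuse.imbalance) or stratify the split")
        yb = (y == self.classes_.max()).astype(np.float64)

        if validation_data is not None:
            Xv = self._check_X(validation_data[0])
            yv = (np.asarray(validation_data[1]) == self.classes_.max()).astype(np.float64)
            Xt, yt = X, yb
        else:
            Xt, yt, Xv, yv = self._holdout_split(X, yb)

        cfg = TrainConfig(batch_size=self.batch_size, max_epochs=self.max_epochs,
                          lr=self.lr, lr_factor=self.lr_factor,
                          lr_patience=self.lr_patience,
                          stop_patience=self.stop_patience,
                          min_delta=self.min_delta, seed=self.seed)
        self.spec_ = build_architecture(X.shape[1:], l2=self.l2)
        self.n_parameters_ = count_parameters(self.spec_)
        rng = np.random.default_rng(self.seed)
        self._net = _build_net(self.spec_, rng)
        self.history_ = _train_loop(self._net, Xt, yt, Xv, yv, cfg, rng)
        self.epochs_run_ = len(self.history_["loss"])
        return self

    def _holdout_split(self, X, yb):
        rng = np.random.default_rng(self.seed)
        idx = rng.permutation(len(X))
        n_val = max(1, int(round(self.validation_fraction * len(X))))
        val, tr = idx[:n_val], idx[n_val:]
        if len(np.unique(yb[tr])) < 2:  # keep both classes in training
            raise SingleClassError("holdout split left a single-class training set")
        return X[tr], yb[tr], X[val], yb[val]

    # ------------------------------------------------------------ inference
    def predict_proba(self, X):
        """(N, 2) probabilities, columns ordered as ``classes_``."""
        p = self._proba_functional(X)
        return np.column_stack([1.0 - p, p])

    def _proba_functional(self, X, batch=512):
        check_is_fitted(self, "history_")
        X = self._check_X(X)
        if X.shape[1:] != tuple(self.spec_.input_shape):
            raise ValueError(
                f"window shape {X.shape[1:]} does not match model input "
                f"{self.spec_.input_shape}")
        out = np.empty(len(X))
        for i in range(0, len(X), batch):
            logits = self._net.forward(X[i:i + batch], training=False)
            out[i:i + batch] = _net.sigmoid(logits).ravel()
        return out

    def predict(self, X, threshold=0.5):
        p = self._proba_functional(X)
        hi, lo = self.classes_.max(), self.classes_.min()
        return np.where(p >= threshold, hi, lo)

    @staticmethod
    def _check_X(X):
        X = np.asarray(X, dtype=_net.DTYPE)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4 or X.shape[1] != WINDOW_T or X.shape[2] not in SUPPORTED_CHANNELS:
            raise ValueError("expected windows of shape (N, 60, C[, 1]), C in {3, 6}")
        return X


def _build_net(spec: ArchitectureSpec, rng) -> _net.Sequential:
    layers = []
    for layer in spec.layers:
        kind = layer["kind"]
        if kind == "conv2d":
            layers.append(_net.Conv2DSame(layer["c_in"], layer["filters"], rng))
        elif kind == "batchnorm":
            layers.append(_net.BatchNorm(layer["features"]))
        elif kind == "relu":
            layers.append(_net.ReLU())
        elif kind == "dropout":
            layers.append(_net.Dropout(layer["rate"], rng))
        elif kind == "flatten":
            layers.append(_net.Flatten())
        elif kind == "dense":
            layers.append(_net.Dense(layer["n_in"], layer["units"], rng,
                                     l2=layer["l2"]))
            if layer["activation"] == "relu":
                layers.append(_net.ReLU())
    return _net.Sequential(layers)


def _evaluate(net, X, y, batch=512):
    """Mean BCE loss (incl. L2 penalty) and accuracy in inference mode."""
    losses, correct = 0.0, 0
    for i in range(0, len(X), batch):
        logits = net.forward(X[i:i + batch], training=False)
        loss, _, p = _net.bce_with_logits(logits, y[i:i + batch])
        losses += loss * len(p)
        correct += int(np.sum((p >= 0.5) == (y[i:i + batch] >= 0.5)))
    n = len(X)
    return losses / n + net.l2_penalty(), correct / n


def _train_loop(net, Xt, yt, Xv, yv, cfg: TrainConfig, rng) -> dict:
    """Mini-batch Adam with plateau LR drops and early stopping.

    Follows the usual Keras callback semantics: ReduceLROnPlateau watches
    the validation loss (patience ``lr_patience``, factor ``lr_factor``),
    EarlyStopping watches the validation accuracy (patience
    ``stop_patience``) and restores the best-epoch weights; the best epoch
    therefore has the maximum validation accuracy of the whole history.
    """
    opt = _net.Adam(net.params, lr=cfg.lr)
    hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
            "lr": []}
    best_val_acc = -np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    wait_stop = 0
    plateau_best = np.inf
    wait_lr = 0
    n = len(Xt)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            logits = net.forward(Xt[b], training=True)
            loss, grad, p = _net.bce_with_logits(logits, yt[b])
            net.backward(grad)
            opt.step()
            ep_loss += loss * len(b)
            ep_correct += int(np.sum((p >= 0.5) == (yt[b] >= 0.5)))
        train_loss = ep_loss / n + net.l2_penalty()
        val_loss, val_acc = _evaluate(net, Xv, yv)
        hist["loss"].append(train_loss)
        hist["accuracy"].append(ep_correct / n)
        hist["val_loss"].append(val_loss)
        hist["val_accuracy"].append(val_acc)
        hist["lr"].append(opt.lr)

        # ReduceLROnPlateau on validation loss
        if val_loss < plateau_best - cfg.min_delta:
            plateau_best = val_loss
            wait_lr = 0
        else:
            wait_lr += 1
            if wait_lr >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                wait_lr = 0

        # EarlyStopping on validation accuracy, restore best weights
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_weights = net.get_weights()
            best_epoch = epoch
            wait_stop = 0
        else:
            wait_stop += 1
            if wait_stop >= cfg.stop_patience:
                break
    net.set_weights(best_weights)
    hist["best_epoch"] = best_epoch
    hist["best_val_accuracy"] = best_val_acc
    return hist


# ----------------------------------------------------------- thin wrappers

def train(X_train, y_train, X_val, y_val, config: TrainConfig | None = None) -> TrainedModel:
    """Train the window classifier on one split; see :class:`FunctionalUseCNN`."""
    config = config or TrainConfig()
    est = FunctionalUseCNN(batch_size=config.batch_size,
                           max_epochs=config.max_epochs, lr=config.lr,
                           lr_factor=config.lr_factor,
                           lr_patience=config.lr_patience,
                           stop_patience=config.stop_patience,
                           min_delta=config.min_delta, seed=config.seed)
    est.fit(X_train, y_train, validation_data=(X_val, y_val))
    return TrainedModel(estimator=est, spec=est.spec_, history=est.history_,
                        epochs_run=est.epochs_run_)


def predict_proba(model, windows) -> np.ndarray:
    """Probability that each window is functional, in [0, 1]."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    return est._proba_functional(windows)


def classify(p, threshold: float = 0.5) -> np.ndarray:
    """Threshold functional probabilities: p ≥ threshold → 1 (functional)."""
    return (np.asarray(p) >= threshold).astype(np.int64)
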