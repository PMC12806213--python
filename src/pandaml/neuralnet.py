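"""Feedforward neural networks for tabular omics classification.

A NumPy multilayer perceptron with explicit forward/backward passes:
softmax cross-entropy classifiers (optionally L1/L2-penalized), a
grid-based hyperparameter search over the axes hidden layers, layer size,
learning rate, activation, regularization (+strength) and batch size, and a
symmetric autoencoder for low-dimensional feature compression (latent
dimension 2-10 by convention, selected by downstream validation accuracy).

Inputs are z-score standardized with training-set statistics; optimization
is mini-batch Adam by default (plain SGD available); everything is
deterministic given the config seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnConfig",
    "AnnModel",
    "TrainingHistory",
    "Autoencoder",
    "train_ann",
    "predict_proba",
    "predict_labels",
    "hyperparameter_search",
    "default_search_grid",
    "train_autoencoder",
    "select_latent_dim",
]


@dataclass(frozen=True)
class AnnConfig:
    """Architecture and training hyperparameters for one MLP fit."""

    hidden_layers: int = 1
    layer_size: int = 30
    learning_rate: float = 1e-3
    activation: str = "relu"          # relu | tanh | sigmoid
    regularization: str = "none"      # none | l1 | l2
    regularization_strength: float = 0.0
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    optimizer: str = "adam"           # adam | sgd

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.hidden_layers < 0 or self.layer_size < 1 or self.batch_size < 1:
            raise ValueError("invalid architecture parameters")
        if self.learning_rate <= 0 or self.regularization_strength < 0:
            raise ValueError("invalid optimization parameters")
        if self.activation not in ("relu", "tanh", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.regularization not in ("none", "l1", "l2"):
            raise ValueError(f"unknown regularization {self.regularization!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(asdict(self)).rename_axis("epoch")


@dataclass
class AnnModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    class_levels: list
    config: AnnConfig


@dataclass
class Autoencoder:
    enc_weights: list[np.ndarray]
    enc_biases: list[np.ndarray]
    dec_weights: list[np.ndarray]
    dec_biases: list[np.ndarray]
    latent_dim: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    activation: str
    loss_history: list[float] = field(default_factory=list)

    def encode(self, X) -> np.ndarray:
        H = (np.atleast_2d(X) - self.x_mean) / self.x_sd
        n_layers = len(self.enc_weights)
        for i, (W, b) in enumerate(zip(self.enc_weights, self.enc_biases)):
            H = H @ W + b
            if i < n_layers - 1:  # latent layer stays linear
                H = _ACT[self.activation][0](H)
        return H

    def decode(self, Z) -> np.ndarray:
        H = np.atleast_2d(Z)
        n_layers = len(self.dec_weights)
        for i, (W, b) in enumerate(zip(self.dec_weights, self.dec_biases)):
            H = H @ W + b
            if i < n_layers - 1:  # output layer stays linear
                H = _ACT[self.activation][0](H)
        return H * self.x_sd + self.x_mean

    def reconstruction_mse(self, X) -> float:
        X = np.atleast_2d(X)
        return float(np.mean((self.decode(self.encode(X)) - X) ** 2))


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z):
    return (z > 0).astype(float)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACT = {
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "sigmoid": (_sigmoid, lambda z: _sigmoid(z) * (1.0 - _sigmoid(z))),
}


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(sizes, activation, rng):
    """He initialization for relu, Xavier otherwise; biases zero."""
    Ws, bs = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = (np.sqrt(2.0 / fan_in) if activation == "relu"
                 else np.sqrt(1.0 / fan_in))
        Ws.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    return Ws, bs


def _penalty(Ws, reg, strength):
    if reg == "none" or strength == 0.0:
        return 0.0
    if reg == "l2":
        return strength * sum(float((W ** 2).sum()) for W in Ws)
    return strength * sum(float(np.abs(W).sum()) for W in Ws)


def _penalty_grad(W, reg, strength):
    if reg == "none" or strength == 0.0:
        return 0.0
    if reg == "l2":
        return 2.0 * strength * W
    return strength * np.sign(W)


def loss_and_grads(Ws, bs, X, Y, activation, task="softmax",
                   reg="none", strength=0.0):
    """Loss plus analytic gradients for a standardized-input MLP.

    ``task='softmax'`` expects one-hot Y and returns mean cross-entropy;
    ``task='mse'`` expects a target matrix and returns mean squared error
    (averaged over all entries). Hidden layers use ``activation``; the
    output layer is softmax or linear respectively. Penalties apply to
    weight matrices only, never biases.
    """
    act, act_grad = _ACT[activation]
    n = X.shape[0]
    zs, hs = [], [X]
    H = X
    L = len(Ws)
    for i in range(L):
        Z = H @ Ws[i] + bs[i]
        zs.append(Z)
        H = act(Z) if i < L - 1 else Z
        hs.append(H)
    if task == "softmax":
        P = _softmax(H)
        data_loss = -float(np.sum(Y * np.log(np.clip(P, 1e-12, None)))) / n
        delta = (P - Y) / n
    else:
        diff = H - Y
        data_loss = float((diff ** 2).mean())
        delta = 2.0 * diff / diff.size
    loss = data_loss + _penalty(Ws, reg, strength)
    dWs = [None] * L
    dbs = [None] * L
    for i in range(L - 1, -1, -1):
        dWs[i] = hs[i].T @ delta + _penalty_grad(Ws[i], reg, strength)
        dbs[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ Ws[i].T) * act_grad(zs[i - 1])
    return loss, dWs, dbs


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Sgd:
    def __init__(self, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


def _standardize_fit(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_ann(X_train, y_train, X_val=None, y_val=None,
              config: AnnConfig = AnnConfig()):
    """Train a softmax MLP classifier; returns (AnnModel, TrainingHistory).

    With ``hidden_layers=0`` the network is multinomial logistic regression.
    Standardization parameters come from the training set only; the
    validation set is transformed with them, never refit.
    """
    from .plsda import dummy_code

    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    levels = sorted(set(y_train.tolist()))
    if len(levels) < 2:
        raise ValueError("training data must contain at least two classes")
    if y_val is not None:
        extra = set(np.asarray(y_val).tolist()) - set(levels)
        if extra:
            raise ValueError(f"validation classes absent from training: {sorted(extra)}")
    Y_train, _ = dummy_code(y_train, levels)
    mean, sd = _standardize_fit(X_train)
    Xs = (X_train - mean) / sd
    if X_val is not None:
        Xv = (np.asarray(X_val, dtype=float) - mean) / sd
        Y_val, _ = dummy_code(np.asarray(y_val), levels)

    sizes = ([X_train.shape[1]] + [config.layer_size] * config.hidden_layers
             + [len(levels)])
    rng = np.random.default_rng(config.seed)
    Ws, bs = _init_params(sizes, config.activation, rng)
    params = Ws + bs
    opt = (_Adam(params, config.learning_rate) if config.optimizer == "adam"
           else _Sgd(params, config.learning_rate))
    n = Xs.shape[0]
    batch = min(config.batch_size, n)
    history = TrainingHistory()
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            _, dWs, dbs = loss_and_grads(
                Ws, bs, Xs[idx], Y_train[idx], config.activation, "softmax",
                config.regularization, config.regularization_strength)
            opt.step(params, dWs + dbs)
        tr_loss, tr_acc = _eval_epoch(Ws, bs, Xs, Y_train, config.activation)
        history.train_loss.append(tr_loss)
        history.train_accuracy.append(tr_acc)
        if X_val is not None:
            v_loss, v_acc = _eval_epoch(Ws, bs, Xv, Y_val, config.activation)
            history.val_loss.append(v_loss)
            history.val_accuracy.append(v_acc)
    model = AnnModel(weights=Ws, biases=bs, x_mean=mean, x_sd=sd,
                     class_levels=levels, config=config)
    return model, history


def _eval_epoch(Ws, bs, Xs, Y, activation):
    """Plain cross-entropy (no penalty) and argmax accuracy."""
    H = Xs
    L = len(Ws)
    act = _ACT[activation][0]
    for i in range(L):
        H = H @ Ws[i] + bs[i]
        if i < L - 1:
            H = act(H)
    P = _softmax(H)
    loss = -float(np.sum(Y * np.log(np.clip(P, 1e-12, None)))) / Xs.shape[0]
    acc = float((P.argmax(axis=1) == Y.argmax(axis=1)).mean())
    return loss, acc


def predict_proba(model: AnnModel, X) -> np.ndarray:
    """Softmax class probabilities; rows sum to one."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.x_mean.shape[0]})")
    H = (X - model.x_mean) / model.x_sd
    act = _ACT[model.config.activation][0]
    L = len(model.weights)
    for i in range(L):
        H = H @ model.weights[i] + model.biases[i]
        if i < L - 1:
            H = act(H)
    return _softmax(H)


def predict_labels(model: AnnModel, X) -> list:
    P = predict_proba(model, X)
    return [model.class_levels[k] for k in P.argmax(axis=1)]


def default_search_grid(epochs: int = 100, seed: int = 0) -> list[AnnConfig]:
    """Full factorial grid over the optimized hyperparameter axes."""
    grid = []
    for (hl, ls, lr, act, reg, strength, bsz) in itertools.product(
            (1, 3, 5), (10, 30, 60), (1e-2, 1e-3), ("relu", "tanh"),
            ("none", "l2"), (1e-4, 1e-2), (16, 32)):
        if reg == "none" and strength != 1e-4:
            continue  # strength is meaningless without a penalty
        grid.append(AnnConfig(hidden_layers=hl, layer_size=ls, learning_rate=lr,
                              activation=act, regularization=reg,
                              regularization_strength=0.0 if reg == "none" else strength,
                              batch_size=bsz, epochs=epochs, seed=seed))
    return grid


def compact_search_grid(epochs: int = 100, seed: int = 0) -> list[AnnConfig]:
    """Small default grid for the benchmark harness (4 configurations)."""
    return [
        AnnConfig(hidden_layers=1, layer_size=30, learning_rate=1e-2,
                  epochs=epochs, seed=seed),
        AnnConfig(hidden_layers=1, layer_size=30, learning_rate=1e-3,
                  epochs=epochs, seed=seed),
        AnnConfig(hidden_layers=3, layer_size=30, learning_rate=1e-3,
                  epochs=epochs, seed=seed),
        AnnConfig(hidden_layers=1, layer_size=30, learning_rate=1e-3,
                  regularization="l2", regularization_strength=1e-4,
                  epochs=epochs, seed=seed),
    ]


def hyperparameter_search(X_train, y_train, X_val, y_val,
                          grid: list[AnnConfig], seed: int = 0):
    """Train one model per grid point; pick the best validation accuracy.

    Ties break by lower validation loss, then by grid order. Returns
    ``(best_config, best_model, search_table)`` where the table has one row
    per configuration with its final train/validation metrics.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    rows = []
    best = None
    for g, cfg in enumerate(grid):
        cfg_seeded = replace(cfg, seed=cfg.seed + seed)
        model, hist = train_ann(X_train, y_train, X_val, y_val, cfg_seeded)
        row = asdict(cfg_seeded)
        row.update(train_accuracy=hist.train_accuracy[-1],
                   train_loss=hist.train_loss[-1],
                   val_accuracy=hist.val_accuracy[-1],
                   val_loss=hist.val_loss[-1])
        rows.append(row)
        key = (-row["val_accuracy"], row["val_loss"], g)
        if best is None or key < best[0]:
            best = (key, cfg_seeded, model, hist)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


def train_autoencoder(X, latent_dim: int, config: AnnConfig = AnnConfig()):
    """Train a symmetric autoencoder on mean-squared reconstruction error.

    The encoder stacks ``config.hidden_layers`` nonlinear layers then a
    linear latent layer; the decoder mirrors it. ``hidden_layers=0`` gives
    a purely linear autoencoder (a PCA-like subspace fit).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if latent_dim >= p:
        raise ValueError(f"latent_dim {latent_dim} >= feature count {p}: "
                         "no compression")
    if not 2 <= latent_dim <= 10:
        logger.warning("latent_dim %d outside the conventional 2-10 range",
                       latent_dim)
    mean, sd = _standardize_fit(X)
    Xs = (X - mean) / sd
    hidden = [config.layer_size] * config.hidden_layers
    sizes = [p] + hidden + [latent_dim] + hidden[::-1] + [p]
    rng = np.random.default_rng(config.seed)
    Ws, bs = _init_params(sizes, config.activation, rng)
    params = Ws + bs
    opt = (_Adam(params, config.learning_rate) if config.optimizer == "adam"
           else _Sgd(params, config.learning_rate))
    batch = min(config.batch_size, n)
    act = _ACT[config.activation][0]
    n_enc = len(hidden) + 1
    loss_history = []
    linear_layers = {n_enc - 1, len(Ws) - 1}  # latent and output stay linear

    def forward_all(H):
        for i in range(len(Ws)):
            H = H @ Ws[i] + bs[i]
            if i not in linear_layers:
                H = act(H)
        return H

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            _, dWs, dbs = _ae_grads(Ws, bs, Xs[idx], config.activation,
                                    linear_layers, config.regularization,
                                    config.regularization_strength)
            opt.step(params, dWs + dbs)
        loss_history.append(float(((forward_all(Xs) - Xs) ** 2).mean()))
    return Autoencoder(enc_weights=Ws[:n_enc], enc_biases=bs[:n_enc],
                       dec_weights=Ws[n_enc:], dec_biases=bs[n_enc:],
                       latent_dim=latent_dim, x_mean=mean, x_sd=sd,
                       activation=config.activation, loss_history=loss_history)


def _ae_grads(Ws, bs, X, activation, linear_layers, reg, strength):
    act, act_grad = _ACT[activation]
    zs, hs = [], [X]
    H = X
    for i in range(len(Ws)):
        Z = H @ Ws[i] + bs[i]
        zs.append(Z)
        H = Z if i in linear_layers else act(Z)
        hs.append(H)
    diff = H - X
    loss = float((diff ** 2).mean()) + _penalty(Ws, reg, strength)
    delta = 2.0 * diff / diff.size
    dWs = [None] * len(Ws)
    dbs = [None] * len(Ws)
    for i in range(len(Ws) - 1, -1, -1):
        dWs[i] = hs[i].T @ delta + _penalty_grad(Ws[i], reg, strength)
        dbs[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ Ws[i].T
            if (i - 1) not in linear_layers:
                delta = delta * act_grad(zs[i - 1])
    return loss, dWs, dbs


def select_latent_dim(X_train, y_train, X_val, y_val, dims=range(2, 11),
                      config: AnnConfig = AnnConfig()):
    """Pick the autoencoder latent dimension by downstream validation accuracy.

    For each candidate dimension: fit the autoencoder on the training set,
    encode train/validation, train the downstream classifier, and record
    validation accuracy. Returns ``(best_dim, table)``; ties prefer the
    smaller dimension.
    """
    dims = sorted(set(int(d) for d in dims))
    if not dims:
        raise ValueError("dims is empty")
    rows = []
    best = None
    for d in dims:
        ae = train_autoencoder(np.asarray(X_train, float), d, config)
        Zt = ae.encode(X_train)
        Zv = ae.encode(X_val)
        _, hist = train_ann(Zt, y_train, Zv, y_val, config)
        acc = hist.val_accuracy[-1]
        rows.append({"latent_dim": d, "val_accuracy": acc,
                     "val_loss": hist.val_loss[-1],
                     "reconstruction_mse": ae.reconstruction_mse(X_train)})
        if best is None or acc > best[1]:
            best = (d, acc)
    return best[0], pd.DataFrame(rows)
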