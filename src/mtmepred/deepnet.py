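"""Fixed-architecture feed-forward network for genomic/phenomic prediction.

The architecture is deliberately not tunable: three fully connected hidden
layers, each with round(2/3 · n_inputs) units (half-up rounding, minimum 1),
dropout of 30% after every hidden layer during training, and a linear output
layer with one unit per trait. Only the training hyperparameters
(activation, optimizer, epochs, batch size, loss, loss weight) vary, which
is what the grid search explores.

The network is a small self-contained NumPy implementation: seeded Glorot
initialisation, inverted dropout, minibatch backpropagation with Adam or
momentum SGD, and mean-squared-error or mean-absolute-error losses. All
randomness (weight init, shuffling, dropout masks) flows from the config
seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

ACTIVATIONS = ("relu", "tanh", "sigmoid")
OPTIMIZERS = ("adam", "sgd")
LOSSES = ("mean_squared_error", "mean_absolute_error")
METRICS = ("mse", "mae")

DROPOUT_RATE = 0.30
N_HIDDEN_LAYERS = 3

# optimizer step sizes (fixed defaults, not part of the hyperparameter grid)
ADAM_LR, ADAM_BETA1, ADAM_BETA2, ADAM_EPS = 1e-3, 0.9, 0.999, 1e-8
SGD_LR, SGD_MOMENTUM = 1e-2, 0.9


@dataclass(frozen=True)
class ModelConfig:
    """One hyperparameter combination for network training."""

    activation: str = "tanh"
    optimizer: str = "adam"
    epochs: int = 100
    batch_size: int = 32
    loss: str = "mean_squared_error"
    metric: str = "mse"
    loss_weight: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.loss_weight <= 0:
            raise ValueError("loss_weight must be positive")

    def label(self) -> str:
        return (
            f"{self.activation}|{self.optimizer}|e{self.epochs}|b{self.batch_size}"
            f"|{self.loss}|{self.metric}|w{self.loss_weight}"
        )


def _hidden_width(n_inputs: int) -> int:
    # two-thirds rule with half-up rounding, clamped at 1
    return max(1, int(np.floor(2.0 * n_inputs / 3.0 + 0.5)))


@dataclass(frozen=True)
class NetworkSpec:
    """Immutable architecture: widths follow the two-thirds rule, dropout 0.30."""

    n_inputs: int
    n_outputs: int
    hidden_sizes: tuple[int, int, int] = None  # type: ignore[assignment]
    dropout_rate: float = DROPOUT_RATE

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be positive")
        h = _hidden_width(self.n_inputs)
        expected = (h,) * N_HIDDEN_LAYERS
        if self.hidden_sizes is None:
            object.__setattr__(self, "hidden_sizes", expected)
        elif tuple(self.hidden_sizes) != expected:
            raise ValueError(
                f"hidden layer widths are fixed at {expected} for {self.n_inputs} "
                "inputs and cannot be modified"
            )
        if self.dropout_rate != DROPOUT_RATE:
            raise ValueError(f"dropout rate is fixed at {DROPOUT_RATE} and cannot be modified")


def build_network(n_inputs: int, n_outputs: int) -> NetworkSpec:
    """Architecture for a given input/output dimensionality."""
    return NetworkSpec(n_inputs=n_inputs, n_outputs=n_outputs)


# ---------------------------------------------------------------------------
# forward / backward machinery
# ---------------------------------------------------------------------------


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))  # sigmoid


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a * a
    return a * (1.0 - a)


def _init_params(spec: NetworkSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    sizes = [spec.n_inputs, *spec.hidden_sizes, spec.n_outputs]
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def _forward(
    params, spec: NetworkSpec, config: ModelConfig, X: np.ndarray,
    rng: np.random.Generator | None,
):
    """Forward pass; dropout masks drawn from rng when training (rng given)."""
    caches = []
    a = X
    keep = 1.0 - spec.dropout_rate
    for i, (W, b) in enumerate(params):
        z = a @ W + b
        if i < len(params) - 1:
            h = _act(config.activation, z)
            if rng is not None:
                mask = (rng.random(h.shape) < keep) / keep  # inverted dropout
                h_out = h * mask
            else:
                mask = None
                h_out = h
            caches.append((a, z, h, mask))
            a = h_out
        else:
            caches.append((a, z, None, None))
            a = z  # linear output
    return a, caches


def _loss_and_grad(config: ModelConfig, yhat: np.ndarray, y: np.ndarray):
    err = yhat - y
    n = err.size
    if config.loss == "mean_squared_error":
        loss = float(np.mean(err * err))
        grad = 2.0 * err / n
    else:
        loss = float(np.mean(np.abs(err)))
        grad = np.sign(err) / n
    return config.loss_weight * loss, config.loss_weight * grad


def _backward(params, caches, config: ModelConfig, grad_out: np.ndarray):
    grads = [None] * len(params)
    delta = grad_out
    for i in range(len(params) - 1, -1, -1):
        a_in, z, h, mask = caches[i]
        if i < len(params) - 1:
            if mask is not None:
                delta = delta * mask
            delta = delta * _act_grad(config.activation, z, h)
        W, _ = params[i]
        grads[i] = (a_in.T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = delta @ W.T
    return grads


class _Optimizer:
    def __init__(self, config: ModelConfig, params):
        self.kind = config.optimizer
        self.t = 0
        self.state = [
            (np.zeros_like(W), np.zeros_like(b), np.zeros_like(W), np.zeros_like(b))
            for W, b in params
        ]

    def step(self, params, grads):
        self.t += 1
        new_params = []
        for (W, b), (gW, gb), (mW, mb, vW, vb) in zip(params, grads, self.state):
            if self.kind == "adam":
                mW[:] = ADAM_BETA1 * mW + (1 - ADAM_BETA1) * gW
                mb[:] = ADAM_BETA1 * mb + (1 - ADAM_BETA1) * gb
                vW[:] = ADAM_BETA2 * vW + (1 - ADAM_BETA2) * gW * gW
                vb[:] = ADAM_BETA2 * vb + (1 - ADAM_BETA2) * gb * gb
                corr1 = 1 - ADAM_BETA1**self.t
                corr2 = 1 - ADAM_BETA2**self.t
                W = W - ADAM_LR * (mW / corr1) / (np.sqrt(vW / corr2) + ADAM_EPS)
                b = b - ADAM_LR * (mb / corr1) / (np.sqrt(vb / corr2) + ADAM_EPS)
            else:  # momentum SGD
                mW[:] = SGD_MOMENTUM * mW + gW
                mb[:] = SGD_MOMENTUM * mb + gb
                W = W - SGD_LR * mW
                b = b - SGD_LR * mb
            new_params.append((W, b))
        return new_params


@dataclass
class _Scaler:
    mean: np.ndarray
    scale: np.ndarray  # std with zeros replaced by 1 (constant columns map to 0)

    @classmethod
    def fit(cls, A: np.ndarray) -> "_Scaler":
        mean = A.mean(axis=0)
        scale = A.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, A: np.ndarray) -> np.ndarray:
        return (A - self.mean) / self.scale

    def inverse(self, A: np.ndarray) -> np.ndarray:
        return A * self.scale + self.mean


@dataclass
class TrainedNetwork:
    """A fitted network with its scalers and full training history."""

    spec: NetworkSpec
    config: ModelConfig
    params: list
    x_scaler: _Scaler
    y_scaler: _Scaler
    training_history: list[float]


def fit_network(X: np.ndarray, Y: np.ndarray, config: ModelConfig) -> TrainedNetwork:
    """Train the fixed architecture on a covariate matrix and response(s).

    X columns and Y columns are standardised with training statistics; the
    network is trained for exactly ``config.epochs`` epochs of shuffled
    minibatches. Raises on a non-finite loss.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("X and Y must be free of missing values")

    spec = build_network(X.shape[1], Y.shape[1])
    rng = np.random.default_rng(config.seed)
    params = _init_params(spec, rng)
    opt = _Optimizer(config, params)

    x_scaler = _Scaler.fit(X)
    y_scaler = _Scaler.fit(Y)
    Xs = x_scaler.transform(X)
    Ys = y_scaler.transform(Y)

    n = Xs.shape[0]
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            yhat, caches = _forward(params, spec, config, Xs[idx], rng)
            loss, grad = _loss_and_grad(config, yhat, Ys[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss became non-finite at epoch {epoch + 1}; "
                    "consider a lower learning rate or different optimizer"
                )
            grads = _backward(params, caches, config, grad)
            params = opt.step(params, grads)
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))

    return TrainedNetwork(spec, config, params, x_scaler, y_scaler, history)


def train(ds, config: ModelConfig) -> TrainedNetwork:
    """Train on a :class:`~mtmepred.prepare.PreparedDataset`."""
    return fit_network(ds.X, ds.Y, config)


def predict(tn: TrainedNetwork, X_new: np.ndarray) -> np.ndarray:
    """Deterministic predictions in original trait units (dropout disabled)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != tn.spec.n_inputs:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; network expects {tn.spec.n_inputs}"
        )
    yhat, _ = _forward(tn.params, tn.spec, tn.config, tn.x_scaler.transform(X_new), None)
    return tn.y_scaler.inverse(yhat)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_network(tn: TrainedNetwork, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (W, b) in enumerate(tn.params):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path / "weights.npz", **arrays)
    (path / "scalers.yaml").write_text(
        yaml.safe_dump(
            {
                "x_mean": tn.x_scaler.mean.tolist(),
                "x_scale": tn.x_scaler.scale.tolist(),
                "y_mean": tn.y_scaler.mean.tolist(),
                "y_scale": tn.y_scaler.scale.tolist(),
            }
        )
    )
    (path / "config.yaml").write_text(
        yaml.safe_dump(
            {
                "config": vars(tn.config) if not hasattr(tn.config, "__dataclass_fields__")
                else {f: getattr(tn.config, f) for f in tn.config.__dataclass_fields__},
                "spec": {"n_inputs": tn.spec.n_inputs, "n_outputs": tn.spec.n_outputs},
                "history": tn.training_history,
            }
        )
    )


def load_network(path: str | Path) -> TrainedNetwork:
    path = Path(path)
    meta = yaml.safe_load((path / "config.yaml").read_text())
    config = ModelConfig(**meta["config"])
    spec = build_network(meta["spec"]["n_inputs"], meta["spec"]["n_outputs"])
    with np.load(path / "weights.npz") as z:
        n_layers = len([k for k in z.files if k.startswith("W")])
        params = [(z[f"W{i}"].copy(), z[f"b{i}"].copy()) for i in range(n_layers)]
    sc = yaml.safe_load((path / "scalers.yaml").read_text())
    x_scaler = _Scaler(np.asarray(sc["x_mean"]), np.asarray(sc["x_scale"]))
    y_scaler = _Scaler(np.asarray(sc["y_mean"]), np.asarray(sc["y_scale"]))
    return TrainedNetwork(spec, config, params, x_scaler, y_scaler, meta["history"])
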