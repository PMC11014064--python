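"""Dense classifier head over moment descriptors.

Architecture (fixed block layout, configurable widths, default
100/165/245/120): four fully connected hidden blocks, each
``linear -> batch norm -> activation -> dropout`` with an exponential
linear unit in the first block and rectified linear units in the rest,
followed by a softmax output layer.  Training minimizes categorical
cross-entropy with Adam (default learning rate 1e-3) on shuffled
minibatches; all randomness (initialization, shuffling, dropout) flows
from a single integer seed, so train + predict is bit-reproducible.

Implemented directly on numpy arrays: forward, backward, batch-norm
running statistics and the optimizer are all in this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelConfig", "TrainedModel", "Prediction", "softmax",
           "build_model", "train", "predict", "save_model", "load_model"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class ModelConfig:
    input_dim: int
    n_classes: int
    hidden_widths: tuple[int, ...] = (100, 165, 245, 120)
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if self.n_classes < 2:
            raise ValueError("classification needs at least 2 classes")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))


@dataclass
class Prediction:
    probabilities: np.ndarray
    labels: np.ndarray


@dataclass
class TrainedModel:
    config: ModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    bn_gamma: list[np.ndarray]
    bn_beta: list[np.ndarray]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]
    log: list[dict] = field(default_factory=list)

    @property
    def n_hidden(self) -> int:
        return len(self.config.hidden_widths)


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max subtraction."""
    s = np.asarray(scores, dtype=float)
    s = s - np.max(s, axis=-1, keepdims=True)
    e = np.exp(s)
    return e / np.sum(e, axis=-1, keepdims=True)


def build_model(config: ModelConfig) -> TrainedModel:
    """Seeded He-style initialization of all layers; BN stats at identity."""
    rng = np.random.default_rng(config.seed)
    dims = (config.input_dim, *config.hidden_widths, config.n_classes)
    W, b = [], []
    for din, dout in zip(dims[:-1], dims[1:]):
        W.append(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
        b.append(np.zeros(dout))
    gamma = [np.ones(w) for w in config.hidden_widths]
    beta = [np.zeros(w) for w in config.hidden_widths]
    mean = [np.zeros(w) for w in config.hidden_widths]
    var = [np.ones(w) for w in config.hidden_widths]
    return TrainedModel(config, W, b, gamma, beta, mean, var)


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        # expm1 only on the negative branch to avoid spurious overflow
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    return np.maximum(z, 0.0)


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(z > 0, 1.0, np.exp(z))
    return (z > 0).astype(float)


def _layer_kind(i: int) -> str:
    return "elu" if i == 0 else "relu"


def _forward(model: TrainedModel, X: np.ndarray, training: bool,
             rng: np.random.Generator | None):
    cfg = model.config
    cache = []
    h = X
    for i in range(model.n_hidden):
        z = h @ model.weights[i] + model.biases[i]
        if training:
            mu = z.mean(axis=0)
            varb = z.var(axis=0)
            model.bn_mean[i] = _BN_MOMENTUM * model.bn_mean[i] + (1 - _BN_MOMENTUM) * mu
            model.bn_var[i] = _BN_MOMENTUM * model.bn_var[i] + (1 - _BN_MOMENTUM) * varb
        else:
            mu, varb = model.bn_mean[i], model.bn_var[i]
        inv_std = 1.0 / np.sqrt(varb + _BN_EPS)
        xhat = (z - mu) * inv_std
        a_in = model.bn_gamma[i] * xhat + model.bn_beta[i]
        kind = _layer_kind(i)
        act = _act(a_in, kind)
        if training and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            mask = (rng.random(act.shape) < keep) / keep
            out = act * mask
        else:
            mask = None
            out = act
        cache.append((h, xhat, inv_std, a_in, mask, kind))
        h = out
    logits = h @ model.weights[-1] + model.biases[-1]
    probs = softmax(logits)
    return probs, h, cache


def _backward(model: TrainedModel, probs, y_onehot, h_last, cache):
    B = probs.shape[0]
    grads_W = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    grads_g = [None] * model.n_hidden
    grads_be = [None] * model.n_hidden
    dlogits = (probs - y_onehot) / B
    grads_W[-1] = h_last.T @ dlogits
    grads_b[-1] = dlogits.sum(axis=0)
    dh = dlogits @ model.weights[-1].T
    for i in range(model.n_hidden - 1, -1, -1):
        h_in, xhat, inv_std, a_in, mask, kind = cache[i]
        if mask is not None:
            dh = dh * mask
        da = dh * _act_grad(a_in, kind)
        grads_g[i] = (da * xhat).sum(axis=0)
        grads_be[i] = da.sum(axis=0)
        dxhat = da * model.bn_gamma[i]
        dz = (inv_std / B) * (
            B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        grads_W[i] = h_in.T @ dz
        grads_b[i] = dz.sum(axis=0)
        dh = dz @ model.weights[i].T
    return grads_W, grads_b, grads_g, grads_be


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(model: TrainedModel, features: np.ndarray, labels: np.ndarray,
          epochs: int, seed: int = 0, batch_size: int = 32,
          learning_rate: float = 1e-3) -> TrainedModel:
    """Minibatch Adam on categorical cross-entropy; mutates and returns model."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    cfg = model.config
    if X.ndim != 2 or X.shape[1] != cfg.input_dim:
        raise ValueError(f"features must be (n, {cfg.input_dim})")
    if y.min() < 0 or y.max() >= cfg.n_classes:
        raise ValueError("labels out of range")
    rng = np.random.default_rng(seed)
    params = (model.weights + model.biases + model.bn_gamma + model.bn_beta)
    opt = _Adam(params, learning_rate)
    onehot = np.eye(cfg.n_classes)[y]
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            probs, h_last, cache = _forward(model, X[sel], True, rng)
            gW, gb, gg, gbe = _backward(model, probs, onehot[sel], h_last, cache)
            opt.step(params, gW + gb + gg + gbe)
            p_true = np.clip(probs[np.arange(sel.size), y[sel]], 1e-12, None)
            total_loss += float(-np.log(p_true).sum())
            correct += int((probs.argmax(axis=1) == y[sel]).sum())
        model.log.append(
            {"epoch": epoch, "loss": total_loss / n, "accuracy": correct / n}
        )
    return model


def predict(model: TrainedModel, features: np.ndarray) -> Prediction:
    """Inference mode: BN uses running statistics, dropout disabled."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != {model.config.input_dim}"
        )
    probs, _, _ = _forward(model, X, False, None)
    return Prediction(probs, probs.argmax(axis=1))


def save_model(path, model: TrainedModel) -> None:
    arrays = {}
    for name, group in (
        ("W", model.weights), ("b", model.biases), ("g", model.bn_gamma),
        ("be", model.bn_beta), ("rm", model.bn_mean), ("rv", model.bn_var),
    ):
        for i, a in enumerate(group):
            arrays[f"{name}{i}"] = a
    cfg = model.config
    arrays["config"] = np.frombuffer(
        json.dumps(
            {
                "input_dim": cfg.input_dim,
                "n_classes": cfg.n_classes,
                "hidden_widths": list(cfg.hidden_widths),
                "dropout": cfg.dropout,
                "seed": cfg.seed,
            }
        ).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    data = np.load(path)
    cfg_d = json.loads(bytes(data["config"]).decode())
    cfg = ModelConfig(
        input_dim=cfg_d["input_dim"],
        n_classes=cfg_d["n_classes"],
        hidden_widths=tuple(cfg_d["hidden_widths"]),
        dropout=cfg_d["dropout"],
        seed=cfg_d["seed"],
    )
    nh = len(cfg.hidden_widths)
    get = lambda name, k: [data[f"{name}{i}"] for i in range(k)]
    return TrainedModel(
        cfg, get("W", nh + 1), get("b", nh + 1), get("g", nh),
        get("be", nh), get("rm", nh), get("rv", nh),
    )
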