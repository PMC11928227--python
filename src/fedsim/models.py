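"""Trainable classifiers behind a single local-training contract.

Every model is a pair (architecture, flat parameter vector). The architecture
maps a parameter vector plus a feature matrix to per-class decision scores and
knows how to backpropagate a score-space gradient to parameter space
analytically; no autodiff framework is involved. Three architectures are
provided:

* :class:`LinearArch` — linear scores ``XW + b``; with the logistic loss this
  is multinomial logistic regression, with the hinge loss a one-vs-rest
  linear SVM.
* :class:`MLPArch` — two linear layers with a ReLU between them (a small
  fully connected net).
* :class:`ConvArch` — one 1-D convolution over the feature axis, ReLU,
  global average pooling, and a dense output layer.

Loss reduction defaults to SUM for the linear models: a single full-batch
gradient step on pooled data is then exactly the sum of per-client steps,
which is what makes a centralized run at learning rate eta/N reproduce a
federated run at eta over N equal clients. Mean reduction is selectable and
breaks that factor-N relationship.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "LossSpec",
    "Architecture",
    "LinearArch",
    "MLPArch",
    "ConvArch",
    "init_params",
    "gradient",
    "local_step",
    "predict",
    "accuracy",
]


@dataclass(frozen=True)
class LossSpec:
    """Which loss to differentiate and how to reduce over samples."""

    name: Literal["logistic", "hinge", "cross_entropy"]
    reduction: Literal["sum", "mean"] = "sum"

    def __post_init__(self) -> None:
        if self.name not in ("logistic", "hinge", "cross_entropy"):
            raise ValueError(f"unknown loss {self.name!r}")
        if self.reduction not in ("sum", "mean"):
            raise ValueError(f"unknown reduction {self.reduction!r}")


@dataclass
class ModelParams:
    """Flat ordered vector of real coefficients plus its architecture."""

    theta: np.ndarray
    arch: "Architecture"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.theta.size != self.arch.n_params:
            raise ValueError(
                f"parameter vector has {self.theta.size} entries, "
                f"architecture expects {self.arch.n_params}"
            )

    def copy(self) -> "ModelParams":
        return ModelParams(self.theta.copy(), self.arch)

    @property
    def is_finite(self) -> bool:
        return bool(np.isfinite(self.theta).all())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = json.dumps(self.arch.descriptor())
        np.savetxt(path, self.theta, header=header)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        desc = json.loads(header)
        arch = _ARCH_REGISTRY[desc.pop("arch")](**desc)
        return cls(np.loadtxt(path), arch)


class Architecture:
    """Interface: score computation + analytic backprop for a flat vector."""

    n_params: int
    n_classes: int
    n_features: int

    def descriptor(self) -> dict:
        raise NotImplementedError

    def init(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def decision_function(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Return (n, C) class scores."""
        raise NotImplementedError

    def backward(self, theta: np.ndarray, X: np.ndarray, dscores: np.ndarray) -> np.ndarray:
        """Chain a (n, C) score-space gradient back to a flat parameter gradient."""
        raise NotImplementedError

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) features, got {X.shape}"
            )
        return X


@dataclass(frozen=True)
class LinearArch(Architecture):
    """Linear scores XW + b; layout [W (d*C, row-major), b (C)]."""

    n_features: int
    n_classes: int

    @property
    def n_params(self) -> int:
        return self.n_features * self.n_classes + self.n_classes

    def descriptor(self) -> dict:
        return {"arch": "linear", "n_features": self.n_features,
                "n_classes": self.n_classes}

    def init(self, rng: np.random.Generator) -> np.ndarray:
        W = rng.normal(scale=0.01, size=(self.n_features, self.n_classes))
        b = np.zeros(self.n_classes)
        return np.concatenate([W.ravel(), b])

    def _unpack(self, theta: np.ndarray):
        d, C = self.n_features, self.n_classes
        return theta[: d * C].reshape(d, C), theta[d * C :]

    def decision_function(self, theta, X):
        X = self._check_X(X)
        W, b = self._unpack(theta)
        return X @ W + b

    def backward(self, theta, X, dscores):
        X = self._check_X(X)
        dW = X.T @ dscores
        db = dscores.sum(axis=0)
        return np.concatenate([dW.ravel(), db])


@dataclass(frozen=True)
class MLPArch(Architecture):
    """Two linear layers with a ReLU between: X -> ReLU(XW1+b1) -> W2 + b2."""

    n_features: int
    n_classes: int
    hidden: int = 64

    @property
    def n_params(self) -> int:
        d, h, C = self.n_features, self.hidden, self.n_classes
        return d * h + h + h * C + C

    def descriptor(self) -> dict:
        return {"arch": "mlp", "n_features": self.n_features,
                "n_classes": self.n_classes, "hidden": self.hidden}

    def init(self, rng: np.random.Generator) -> np.ndarray:
        d, h, C = self.n_features, self.hidden, self.n_classes
        W1 = rng.normal(scale=np.sqrt(2.0 / d), size=(d, h))
        W2 = rng.normal(scale=np.sqrt(2.0 / h), size=(h, C))
        return np.concatenate([W1.ravel(), np.zeros(h), W2.ravel(), np.zeros(C)])

    def _unpack(self, theta):
        d, h, C = self.n_features, self.hidden, self.n_classes
        i = 0
        W1 = theta[i : i + d * h].reshape(d, h); i += d * h
        b1 = theta[i : i + h]; i += h
        W2 = theta[i : i + h * C].reshape(h, C); i += h * C
        b2 = theta[i : i + C]
        return W1, b1, W2, b2

    def _forward(self, theta, X):
        W1, b1, W2, b2 = self._unpack(theta)
        Z = X @ W1 + b1
        A = np.maximum(Z, 0.0)
        return Z, A, A @ W2 + b2

    def decision_function(self, theta, X):
        X = self._check_X(X)
        return self._forward(theta, X)[2]

    def backward(self, theta, X, dscores):
        X = self._check_X(X)
        W1, b1, W2, b2 = self._unpack(theta)
        Z, A, _ = self._forward(theta, X)
        dW2 = A.T @ dscores
        db2 = dscores.sum(axis=0)
        dA = dscores @ W2.T
        dZ = dA * (Z > 0)
        dW1 = X.T @ dZ
        db1 = dZ.sum(axis=0)
        return np.concatenate([dW1.ravel(), db1, dW2.ravel(), db2])


@dataclass(frozen=True)
class ConvArch(Architecture):
    """1-D convolution over the feature axis, ReLU, global average pool, dense.

    Tabular features are treated as a length-d signal; the model is only meant
    to be a deeper nonconvex architecture than the MLP, not an image CNN.
    Layout: [kernels (F*k), conv bias (F), W (F*C), b (C)].
    """

    n_features: int
    n_classes: int
    n_filters: int = 8
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.kernel > self.n_features:
            raise ValueError("kernel wider than the feature axis")

    @property
    def n_params(self) -> int:
        F, k, C = self.n_filters, self.kernel, self.n_classes
        return F * k + F + F * C + C

    def descriptor(self) -> dict:
        return {"arch": "conv", "n_features": self.n_features,
                "n_classes": self.n_classes, "n_filters": self.n_filters,
                "kernel": self.kernel}

    def init(self, rng: np.random.Generator) -> np.ndarray:
        F, k, C = self.n_filters, self.kernel, self.n_classes
        K = rng.normal(scale=np.sqrt(2.0 / k), size=(F, k))
        W = rng.normal(scale=np.sqrt(2.0 / F), size=(F, C))
        return np.concatenate([K.ravel(), np.zeros(F), W.ravel(), np.zeros(C)])

    def _unpack(self, theta):
        F, k, C = self.n_filters, self.kernel, self.n_classes
        i = 0
        K = theta[i : i + F * k].reshape(F, k); i += F * k
        bc = theta[i : i + F]; i += F
        W = theta[i : i + F * C].reshape(F, C); i += F * C
        b = theta[i : i + C]
        return K, bc, W, b

    def _windows(self, X):
        # (n, L, k) sliding windows along the feature axis, L = d - k + 1
        return np.lib.stride_tricks.sliding_window_view(X, self.kernel, axis=1)

    def _forward(self, theta, X):
        K, bc, W, b = self._unpack(theta)
        V = self._windows(X)                      # (n, L, k)
        Z = V @ K.T + bc                          # (n, L, F)
        A = np.maximum(Z, 0.0)
        G = A.mean(axis=1)                        # (n, F)
        return V, Z, G, G @ W + b

    def decision_function(self, theta, X):
        X = self._check_X(X)
        return self._forward(theta, X)[3]

    def backward(self, theta, X, dscores):
        X = self._check_X(X)
        K, bc, W, b = self._unpack(theta)
        V, Z, G, _ = self._forward(theta, X)
        L = Z.shape[1]
        dW = G.T @ dscores
        db = dscores.sum(axis=0)
        dG = dscores @ W.T                        # (n, F)
        dZ = (dG[:, None, :] / L) * (Z > 0)       # (n, L, F)
        dK = np.einsum("nlf,nlk->fk", dZ, V)
        dbc = dZ.sum(axis=(0, 1))
        return np.concatenate([dK.ravel(), dbc, dW.ravel(), db])


_ARCH_REGISTRY = {
    "linear": lambda **kw: LinearArch(**kw),
    "mlp": lambda **kw: MLPArch(**kw),
    "conv": lambda **kw: ConvArch(**kw),
}


# --------------------------------------------------------------------------
# losses: value and score-space gradient
# --------------------------------------------------------------------------

def _one_hot(y: np.ndarray, C: int) -> np.ndarray:
    Y = np.zeros((y.shape[0], C))
    Y[np.arange(y.shape[0]), y] = 1.0
    return Y


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_value(params: ModelParams, X: np.ndarray, y: np.ndarray, loss: LossSpec) -> float:
    """Scalar loss under the declared reduction (for monitoring and oracles)."""
    scores = params.arch.decision_function(params.theta, X)
    y = np.asarray(y, dtype=int)
    C = params.arch.n_classes
    if loss.name in ("logistic", "cross_entropy"):
        P = _softmax(scores)
        vals = -np.log(np.clip(P[np.arange(len(y)), y], 1e-300, None))
    else:  # one-vs-rest hinge
        T = 2.0 * _one_hot(y, C) - 1.0
        vals = np.maximum(0.0, 1.0 - T * scores).sum(axis=1)
    total = vals.sum()
    return float(total / len(y)) if loss.reduction == "mean" else float(total)


def _dscores(scores: np.ndarray, y: np.ndarray, loss: LossSpec) -> np.ndarray:
    C = scores.shape[1]
    if loss.name in ("logistic", "cross_entropy"):
        d = _softmax(scores) - _one_hot(y, C)
    else:
        T = 2.0 * _one_hot(y, C) - 1.0
        d = np.where(T * scores < 1.0, -T, 0.0)
    if loss.reduction == "mean":
        d = d / scores.shape[0]
    return d


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def init_params(arch: Architecture, seed: int) -> ModelParams:
    """Reproducible random initialization; all biases start at zero."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    return ModelParams(arch.init(rng), arch)


def gradient(params: ModelParams, X: np.ndarray, y: np.ndarray, loss: LossSpec) -> np.ndarray:
    """Exact analytic gradient of the loss, as a flat ModelParams-shaped vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if y.size and (y.min() < 0 or y.max() >= params.arch.n_classes):
        raise ValueError("labels outside the architecture's class range")
    scores = params.arch.decision_function(params.theta, X)
    return params.arch.backward(params.theta, X, _dscores(scores, y, loss))


def local_step(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    eta_l: float,
    loss: LossSpec,
    n_batches: int = 1,
    seed: int = 0,
) -> ModelParams:
    """One local epoch of (mini-batch) gradient descent.

    The data are shuffled once and split into ``n_batches`` near-equal shards;
    one gradient step is taken per shard in order. ``n_batches=1`` is a single
    full-batch step ``theta - eta_l * grad``.
    """
    if eta_l < 0:
        raise ValueError("eta_l must be nonnegative")
    n = np.asarray(X).shape[0]
    if n_batches < 1 or n_batches > n:
        raise ValueError(f"n_batches must be in 1..{n}, got {n_batches}")
    theta = params.theta.copy()
    if n_batches == 1:
        g = gradient(params, X, y, loss)
        return ModelParams(theta - eta_l * g, params.arch)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    order = rng.permutation(n)
    out = ModelParams(theta, params.arch)
    for batch in np.array_split(order, n_batches):
        g = gradient(out, X[batch], np.asarray(y)[batch], loss)
        out = ModelParams(out.theta - eta_l * g, params.arch)
    return out


def predict(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Argmax class decision."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot predict on an empty matrix")
    scores = params.arch.decision_function(params.theta, X)
    return scores.argmax(axis=1)


def accuracy(params: ModelParams, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of correct argmax decisions, in [0, 1]."""
    y = np.asarray(y, dtype=int)
    return float(np.mean(predict(params, X) == y))
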