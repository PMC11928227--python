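"""Federated PCA via exact covariance pooling, preceded by local z-normalization.

High-dimensional inputs (thousands of features, few hundred samples) defeat
every classifier in the raw feature space, so the pipeline reduces to the
top-k principal components first — computed federatedly: each client shares
only its sample count, per-feature sum, and scatter matrix (sufficient
statistics), from which the server assembles the pooled covariance exactly
and eigendecomposes it. Pooling sufficient statistics makes this federated
PCA *equal* to centralized PCA on the pooled matrix, which is the module's
defining contract (an iterative approximate subspace backend could be slotted
in behind the same API).

Per-client z-normalization before the PCA acts as a batch-effect correction:
an affine per-site distortion of the features (different measurement
technologies at different sites) is removed locally, each site's features
ending at mean 0 / variance 1, before any statistics are pooled. Population
(1/n) variance convention throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PCAProjection",
    "ClientMoments",
    "ZNormalizer",
    "local_znorm",
    "client_moments",
    "federated_pca",
    "project",
    "reduce_clients",
]

#: variance floor: features constant within a client map to 0 after z-norm
VAR_FLOOR = 1e-8


@dataclass
class ClientMoments:
    """Sufficient statistics one client shares: (s, sum x, sum x x^T)."""

    s: int
    feature_sum: np.ndarray   # (d,)
    scatter: np.ndarray       # (d, d), sum of outer products

    def __add__(self, other: "ClientMoments") -> "ClientMoments":
        return ClientMoments(
            self.s + other.s,
            self.feature_sum + other.feature_sum,
            self.scatter + other.scatter,
        )


@dataclass
class PCAProjection:
    """Top-k component matrix (orthonormal rows) plus the pooled mean."""

    k: int
    components: np.ndarray    # (k, d)
    mean: np.ndarray          # (d,)
    eigenvalues: np.ndarray   # (k,), nonincreasing
    client_sizes: list

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = json.dumps({"k": self.k, "d": int(self.mean.shape[0]),
                             "variance_convention": "population",
                             "client_sizes": list(self.client_sizes)})
        np.savetxt(path, np.vstack([self.mean[None, :], self.components]),
                   header=header)

    @classmethod
    def load(cls, path: str | Path) -> "PCAProjection":
        path = Path(path)
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("# ").strip())
        arr = np.loadtxt(path)
        mean, components = arr[0], arr[1:]
        return cls(k=meta["k"], components=components, mean=mean,
                   eigenvalues=np.full(meta["k"], np.nan),
                   client_sizes=meta["client_sizes"])


def local_znorm(X: np.ndarray) -> np.ndarray:
    """Standardize each feature to local mean 0, variance 1 (population 1/n).

    Features whose local variance falls below the floor (constant columns)
    are mapped to exactly 0 rather than blown up.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a nonempty (n, d) matrix")
    mu = X.mean(axis=0)
    var = X.var(axis=0)  # population convention
    out = X - mu
    dead = var < VAR_FLOOR
    sd = np.sqrt(np.where(dead, 1.0, var))
    out /= sd
    out[:, dead] = 0.0
    return out


def client_moments(X: np.ndarray) -> ClientMoments:
    """Exact sufficient statistics of one client's (already normalized) data."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("client data must be finite")
    return ClientMoments(s=X.shape[0], feature_sum=X.sum(axis=0),
                         scatter=X.T @ X)


def pooled_covariance(moments: list[ClientMoments]) -> tuple[np.ndarray, np.ndarray, int]:
    """(mean, covariance, S) of the pooled data, assembled from client moments."""
    total = moments[0]
    for m in moments[1:]:
        total = total + m
    S = total.s
    mu = total.feature_sum / S
    cov = total.scatter / S - np.outer(mu, mu)
    return mu, cov, S


def federated_pca(moments: list[ClientMoments], k: int) -> PCAProjection:
    """Top-k eigenvectors of the pooled covariance from client moments.

    Eigenvalues are returned in nonincreasing order; each component's sign is
    fixed so that its largest-magnitude entry is positive, making runs
    reproducible across platforms.
    """
    if not moments:
        raise ValueError("need at least one client's moments")
    d = moments[0].feature_sum.shape[0]
    if k > d:
        raise ValueError(f"k={k} exceeds feature dimension d={d}")
    S = sum(m.s for m in moments)
    if S <= k:
        raise ValueError(f"need more than k={k} pooled samples, got {S}")
    mu, cov, _ = pooled_covariance(moments)
    cov = (cov + cov.T) / 2.0  # enforce symmetry against round-off
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T  # (k, d)
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return PCAProjection(k=k, components=comps, mean=mu, eigenvalues=evals,
                         client_sizes=[m.s for m in moments])


@dataclass
class ZNormalizer:
    """Per-feature standardization fitted on one client's training shard.

    Test-time data from the same client reuses the training mean/SD, so the
    transform is a fixed local batch correction, not a per-matrix rescaling.
    """

    mean: np.ndarray
    sd: np.ndarray
    dead: np.ndarray  # boolean mask of (locally) constant features

    @classmethod
    def fit(cls, X: np.ndarray) -> "ZNormalizer":
        X = np.asarray(X, dtype=float)
        var = X.var(axis=0)
        dead = var < VAR_FLOOR
        return cls(mean=X.mean(axis=0),
                   sd=np.sqrt(np.where(dead, 1.0, var)), dead=dead)

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = (np.asarray(X, dtype=float) - self.mean) / self.sd
        out[:, self.dead] = 0.0
        return out


def reduce_clients(clients, k: int, znorm: bool = True):
    """Full federated dimensionality-reduction pipeline over ClientData shards.

    Each client (optionally) z-normalizes locally using its training-shard
    statistics, shares sufficient statistics, and receives back the pooled
    top-k projection, which it applies to its train and test shards. Returns
    the projected clients and the fitted projection.
    """
    from .partitioner import ClientData  # local import to avoid a cycle
    from .synthetic_data import Dataset

    normalizers = [ZNormalizer.fit(c.train.X) if znorm else None for c in clients]
    prepped = [
        nz.transform(c.train.X) if nz is not None else np.asarray(c.train.X, dtype=float)
        for nz, c in zip(normalizers, clients)
    ]
    proj = federated_pca([client_moments(Xp) for Xp in prepped], k)
    reduced = []
    for nz, c, Xp in zip(normalizers, clients, prepped):
        Xte = nz.transform(c.test.X) if nz is not None else np.asarray(c.test.X, dtype=float)
        reduced.append(ClientData(
            train=Dataset(project(Xp, proj), c.train.y, meta=dict(c.train.meta)),
            test=Dataset(project(Xte, proj), c.test.y, meta=dict(c.test.meta)),
        ))
    return reduced, proj


def project(X: np.ndarray, proj: PCAProjection) -> np.ndarray:
    """Center by the pooled mean and project onto the component rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != proj.mean.shape[0]:
        raise ValueError(
            f"data has {X.shape[1]} features, projection expects {proj.mean.shape[0]}"
        )
    return (X - proj.mean) @ proj.components.T
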