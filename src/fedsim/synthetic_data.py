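"""Synthetic tabular datasets with the statistical structure of the study inputs.

Three generator families cover the three kinds of real data the framework is
meant to emulate:

* :func:`make_blobs` — well-separated Gaussian clusters standing in for easy
  image-digit classification problems (two-class and four-class variants).
* :func:`make_expression` — high-dimensional, low-signal data resembling
  transcriptome profiles (thousands of genes, few informative directions),
  optionally contaminated with per-site batch effects via
  :func:`inject_batch_effect`.
* :func:`make_fingerprints` — sparse binary molecular-fingerprint-like
  features whose labels come from thresholding a continuous latent activation
  (a pIC50-style value) at 6.3.

Every generator is a pure function of its arguments: the only source of
randomness is the integer ``seed``, fed through a fresh
``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "BatchEffectSpec",
    "make_blobs",
    "make_expression",
    "make_fingerprints",
    "inject_batch_effect",
    "random_batch_effect",
    "binarize_activation",
]

#: pIC50 threshold above which a molecule counts as activating its target.
ACTIVATION_CUTOFF = 6.3


@dataclass
class Dataset:
    """A labeled feature matrix.

    Attributes
    ----------
    X : ndarray of shape (n_samples, n_features)
        Feature matrix (dense float array even for binary features).
    y : ndarray of shape (n_samples,)
        Integer class labels in ``0..C-1``.
    feature_kind : {"dense", "sparse-binary"}
        Whether features are continuous or 0/1 indicators.
    meta : dict
        Generator name, parameters, seed, and (after partitioning) the row
        indices of the parent dataset this shard was cut from.
    """

    X: np.ndarray
    y: np.ndarray
    feature_kind: Literal["dense", "sparse-binary"] = "dense"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} labels"
            )
        if self.feature_kind == "sparse-binary":
            vals = np.unique(self.X)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("sparse-binary features must contain only {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if self.y.size else 0

    def subset(self, rows: np.ndarray) -> "Dataset":
        """Row-subset view (copies data), recording original row ids in meta."""
        rows = np.asarray(rows, dtype=int)
        parent_rows = self.meta.get("rows")
        orig = rows if parent_rows is None else np.asarray(parent_rows)[rows]
        meta = {**self.meta, "rows": orig.tolist()}
        return Dataset(self.X[rows], self.y[rows], self.feature_kind, meta)

    # -- persistence: CSV with a "label" column + JSON sidecar -------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.X, columns=[f"f{j}" for j in range(self.n_features)])
        df["label"] = self.y
        df.to_csv(path, index=False)
        sidecar = {"feature_kind": self.feature_kind, "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path} has no 'label' column")
        y = df.pop("label").to_numpy(dtype=int)
        sidecar_path = path.with_suffix(".json")
        kind, meta = "dense", {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            kind = sidecar.get("feature_kind", "dense")
            meta = sidecar.get("meta", {})
        return cls(df.to_numpy(dtype=float), y, kind, meta)


@dataclass
class BatchEffectSpec:
    """Per-group affine distortion of features, emulating site/technology shifts.

    ``X'[i] = X[i] * scale[g(i)] + shift[g(i)]`` where ``g(i)`` is the group of
    sample ``i``. Groups typically coincide with clients, mimicking e.g. the
    microarray-versus-RNA-seq discrepancy between data-collection sites.
    """

    shift: np.ndarray  # (n_groups, d) additive, feature units
    scale: np.ndarray  # (n_groups, d) multiplicative, > 0
    groups: np.ndarray  # (n_samples,) group index per sample

    def __post_init__(self) -> None:
        self.shift = np.atleast_2d(np.asarray(self.shift, dtype=float))
        self.scale = np.atleast_2d(np.asarray(self.scale, dtype=float))
        self.groups = np.asarray(self.groups, dtype=int)
        if self.shift.shape != self.scale.shape:
            raise ValueError("shift and scale must have the same shape")
        if (self.scale <= 0).any():
            raise ValueError("scale must be strictly positive")
        n_groups = self.shift.shape[0]
        if self.groups.min() < 0 or self.groups.max() >= n_groups:
            raise ValueError("group assignment refers to an undefined group")


def _check_positive(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def make_blobs(n: int, d: int, C: int, separation: float, seed: int) -> Dataset:
    """Isotropic Gaussian clusters with class means on a scaled simplex.

    Parameters
    ----------
    n, d, C : int
        Samples, features, classes. ``n >= C >= 2``.
    separation : float
        Pairwise Euclidean distance between class means (unit within-class
        standard deviation, so ``separation`` is in within-class SD units).
    seed : int
        PRNG seed; identical arguments give bitwise-identical output.
    """
    _check_positive(n=n, d=d, C=C)
    if C < 2 or n < C:
        raise ValueError(f"need n >= C >= 2, got n={n}, C={C}")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))

    if d >= C:
        # regular simplex: scaled standard-basis vectors, pairwise distance
        # sqrt(2) before scaling
        means = np.zeros((C, d))
        means[np.arange(C), np.arange(C)] = separation / np.sqrt(2.0)
    else:
        raw = rng.normal(size=(C, d))
        dists = np.linalg.norm(raw[:, None] - raw[None, :], axis=-1)
        mean_dist = dists[np.triu_indices(C, 1)].mean()
        means = raw * (separation / mean_dist if mean_dist > 0 else 0.0)
    means -= means.mean(axis=0)

    # equal per-class counts (+-1), dealt round-robin then shuffled
    y = np.arange(n) % C
    rng.shuffle(y)
    X = means[y] + rng.normal(size=(n, d))
    meta = {"generator": "make_blobs", "n": n, "d": d, "C": C,
            "separation": separation, "seed": seed}
    return Dataset(X, y, "dense", meta)


def make_expression(
    n: int,
    d: int,
    k_informative: int,
    noise_sd: float,
    seed: int,
    latent_sd: float = 20.0,
    class_sep: float = 40.0,
    hetero: float = 1.8,
) -> Dataset:
    """High-dimensional expression-like data with a low-rank class signal.

    The binary label is carried by a rank-``k_informative`` latent factor
    embedded in a random orthonormal subspace of the ``d`` features; all
    remaining variance is independent per-feature noise whose scale varies
    across features as ``noise_sd * exp(hetero * N(0,1))`` — the roughly
    lognormal per-gene variance heterogeneity real expression matrices show.
    The latent factors have standard deviation ``latent_sd`` per dimension
    and carry a between-class mean displacement of total length
    ``class_sep``, so the signal subspace sits near the top of the pooled
    covariance spectrum and a top-k principal-component reduction isolates
    it. A raw-feature linear classifier instead has to estimate the class
    direction across all ``d`` features, where the heavy-tailed noise
    variances drown the estimate at small ``n``; classification in the raw
    feature domain therefore lands near chance while the same classifier on
    the reduced features recovers the signal.
    """
    _check_positive(n=n, d=d, k_informative=k_informative)
    if k_informative > d:
        raise ValueError(f"k_informative={k_informative} exceeds d={d}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    k = k_informative
    # orthonormal embedding of the latent subspace
    B = np.linalg.qr(rng.normal(size=(d, k)))[0]  # (d, k)
    y = np.arange(n) % 2
    rng.shuffle(y)
    direction = rng.normal(size=k)
    direction /= np.linalg.norm(direction)
    latent = latent_sd * rng.normal(size=(n, k))
    latent += np.where(y[:, None] == 1, 0.5, -0.5) * class_sep * direction
    feature_sd = noise_sd * np.exp(hetero * rng.normal(size=d))
    X = latent @ B.T + feature_sd * rng.normal(size=(n, d))
    meta = {"generator": "make_expression", "n": n, "d": d,
            "k_informative": k, "noise_sd": noise_sd, "latent_sd": latent_sd,
            "class_sep": class_sep, "hetero": hetero, "seed": seed}
    return Dataset(X, y, "dense", meta)


def make_fingerprints(
    n: int, d: int, density: float, class_imbalance: float, seed: int
) -> Dataset:
    """Sparse binary fingerprint-like features with imbalanced activity labels.

    Features are i.i.d. Bernoulli(``density``) bits. A continuous latent
    activation on the pIC50 scale is built from a random linear read-out of
    the bits plus noise, shifted so that the requested fraction of molecules
    exceeds the activation cutoff, then thresholded with
    :func:`binarize_activation`.
    """
    _check_positive(n=n, d=d)
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    if not 0 < class_imbalance < 1:
        raise ValueError("class_imbalance must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))

    X = (rng.random(size=(n, d)) < density).astype(float)
    w = rng.normal(size=d)
    latent = (X - density) @ w + 0.5 * np.sqrt(d * density * (1 - density)) * rng.normal(size=n)
    # place the cutoff at the empirical (1 - class_imbalance) quantile so the
    # positive fraction matches the request up to ties
    q = np.quantile(latent, 1.0 - class_imbalance)
    pic50 = ACTIVATION_CUTOFF + (latent - q)
    y = binarize_activation(pic50)
    meta = {"generator": "make_fingerprints", "n": n, "d": d,
            "density": density, "class_imbalance": class_imbalance, "seed": seed}
    return Dataset(X, y, "sparse-binary", meta)


def binarize_activation(pic50, cutoff: float = ACTIVATION_CUTOFF) -> np.ndarray:
    """Binarize continuous activation values: active iff strictly above cutoff.

    A compound counts as activating its target only when its pIC50 value is
    strictly greater than ``cutoff`` (default 6.3); a value exactly at the
    cutoff is inactive.
    """
    pic50 = np.asarray(pic50, dtype=float)
    if np.isnan(pic50).any():
        raise ValueError("activation values contain NaN")
    return (pic50 > cutoff).astype(int)


def random_batch_effect(
    ds: Dataset,
    groups: np.ndarray,
    shift_mag: float = 3.0,
    scale_sd: float = 0.5,
    seed: int = 0,
) -> BatchEffectSpec:
    """Draw a random per-group affine batch effect sized to the data.

    Shifts are ``shift_mag`` times each feature's marginal SD (so strong
    features get proportionally strong site offsets, as measurement-platform
    differences do) and scales are lognormal with log-SD ``scale_sd``.
    """
    groups = np.asarray(groups, dtype=int)
    n_groups = int(groups.max()) + 1
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    sd_j = ds.X.std(axis=0)
    shift = shift_mag * sd_j * rng.normal(size=(n_groups, ds.n_features))
    scale = np.exp(scale_sd * rng.normal(size=(n_groups, ds.n_features)))
    return BatchEffectSpec(shift=shift, scale=scale, groups=groups)


def inject_batch_effect(ds: Dataset, spec: BatchEffectSpec) -> Dataset:
    """Apply a per-group affine distortion ``x -> x * scale[g] + shift[g]``."""
    if spec.groups.shape[0] != ds.n_samples:
        raise ValueError(
            f"group assignment covers {spec.groups.shape[0]} samples, "
            f"dataset has {ds.n_samples}"
        )
    if spec.shift.shape[1] != ds.n_features:
        raise ValueError(
            f"effect vectors have {spec.shift.shape[1]} features, "
            f"dataset has {ds.n_features}"
        )
    X = ds.X * spec.scale[spec.groups] + spec.shift[spec.groups]
    meta = {**ds.meta, "batch_effect": True}
    return Dataset(X, ds.y.copy(), ds.feature_kind if ds.feature_kind == "dense" else "dense", meta)
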