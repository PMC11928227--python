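"""Client partitioning schemes: IID, sample imbalance, class imbalance, disjoint classes.

Four ways of distributing one dataset across ``N`` clients:

* ``iid`` — equal sizes, per-client class mix matching the global mix;
* ``si`` (sample imbalance) — linear ramp of client sizes, class mix IID;
* ``ci`` (class imbalance) — equal sizes, per-client class proportions
  sliding from mostly-negative to mostly-positive (binary) or drawn from a
  Dirichlet (multiclass);
* ``ci_aggressive`` — each client holds only a subset of the classes, with
  subsets not necessarily overlapping.

All schemes are exact partitions: shards are disjoint and their union is the
input dataset. Row provenance is tracked in ``Dataset.meta['rows']`` so
partition-of-unity can be verified by multiset equality of row ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .synthetic_data import Dataset

__all__ = [
    "PartitionSpec",
    "ClientData",
    "InfeasiblePartition",
    "split_iid",
    "split_sample_imbalance",
    "split_class_imbalance",
    "split_disjoint_classes",
    "train_test_split",
    "make_clients",
    "save_manifest",
]


class InfeasiblePartition(ValueError):
    """The requested client distribution cannot be realized on this dataset."""


@dataclass
class PartitionSpec:
    """Which distribution scheme to use and its shape parameters."""

    kind: Literal["iid", "si", "ci", "ci_aggressive"]
    N: int
    seed: int = 0
    ramp_ratio: float = 10.0            # si: largest/smallest client size
    fraction_range: tuple = (0.1, 0.9)  # ci: positive-class fraction lo -> hi
    classes_per_client: int = 0         # ci_aggressive: 0 means ceil(C/2)
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.kind not in ("iid", "si", "ci", "ci_aggressive"):
            raise ValueError(f"unknown partition kind {self.kind!r}")


@dataclass
class ClientData:
    """One client's local train/test shards."""

    train: Dataset
    test: Dataset

    @property
    def size(self) -> int:
        """Training-set sample count s^i reported to the server for weighting."""
        return self.train.n_samples


def _class_indices(ds: Dataset, rng: np.random.Generator) -> dict[int, np.ndarray]:
    out = {}
    for c in np.unique(ds.y):
        idx = np.flatnonzero(ds.y == c)
        rng.shuffle(idx)
        out[int(c)] = idx
    return out


def _largest_remainder(quotas: np.ndarray, total: int, start: int = 0) -> np.ndarray:
    """Integer apportionment of `total` by real-valued quotas (sum preserved).

    Ties in the fractional parts are broken round-robin starting at client
    ``start``, so repeated calls (one per class) can rotate the start and keep
    totals balanced when quotas are equal.
    """
    quotas = np.asarray(quotas, dtype=float)
    N = quotas.size
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = quotas - base
        rotated = (np.arange(N) - start) % N
        order = np.lexsort((rotated, -np.round(frac, 12)))
        base[order[:short]] += 1
    elif short < 0:
        frac = quotas - base
        order = np.argsort(frac, kind="stable")
        take = 0
        for j in order:
            if base[j] > 0:
                base[j] -= 1
                take += 1
                if take == -short:
                    break
    return base


def split_iid(ds: Dataset, N: int, seed: int) -> list[Dataset]:
    """Deal samples to N clients stratified by class; sizes differ by <= 1."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > ds.n_samples:
        raise ValueError(f"cannot split {ds.n_samples} samples over {N} clients")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    shards: list[list[np.ndarray]] = [[] for _ in range(N)]
    pointer = 0  # rotates across classes so totals stay within +-1
    for c, idx in _class_indices(ds, rng).items():
        base, rem = divmod(len(idx), N)
        counts = np.full(N, base)
        for j in range(rem):
            counts[(pointer + j) % N] += 1
        pointer = (pointer + rem) % N
        stops = np.cumsum(counts)
        start = 0
        for i, stop in enumerate(stops):
            shards[i].append(idx[start:stop])
            start = stop
    return [ds.subset(np.sort(np.concatenate(parts))) for parts in shards]


def split_sample_imbalance(ds: Dataset, N: int, ramp_ratio: float, seed: int) -> list[Dataset]:
    """Client sizes follow a linear ramp with largest/smallest ~= ramp_ratio."""
    if ramp_ratio < 1:
        raise ValueError("ramp_ratio must be >= 1")
    if N > ds.n_samples:
        raise ValueError(f"cannot split {ds.n_samples} samples over {N} clients")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    if N == 1:
        weights = np.ones(1)
    else:
        weights = 1.0 + (ramp_ratio - 1.0) * np.arange(N) / (N - 1)
    weights /= weights.sum()

    shards: list[list[np.ndarray]] = [[] for _ in range(N)]
    pointer = 0  # rotate tie-breaking across classes, starting at the smallest client
    for c, idx in _class_indices(ds, rng).items():
        counts = _largest_remainder(weights * len(idx), len(idx), start=pointer)
        pointer = (pointer + int(len(idx) - np.floor(weights * len(idx)).sum())) % N
        stops = np.cumsum(counts)
        start = 0
        for i, stop in enumerate(stops):
            shards[i].append(idx[start:stop])
            start = stop
    sizes = [sum(len(p) for p in parts) for parts in shards]
    if min(sizes) == 0:
        raise ValueError(
            f"ramp_ratio={ramp_ratio} with N={N} starves the smallest client"
        )
    return [ds.subset(np.sort(np.concatenate(parts))) for parts in shards]


def split_class_imbalance(
    ds: Dataset, N: int, fraction_range: tuple, seed: int
) -> list[Dataset]:
    """Equal-size clients with a gradient of class proportions.

    Binary labels: client ``i``'s positive-class fraction interpolates
    linearly from ``lo`` to ``hi``. Multiclass: per-client class proportions
    are drawn from a symmetric Dirichlet whose concentration shrinks as the
    requested range widens (wide range -> strongly skewed clients).
    """
    lo, hi = float(fraction_range[0]), float(fraction_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"need 0 <= lo <= hi <= 1, got ({lo}, {hi})")
    if N > ds.n_samples:
        raise ValueError(f"cannot split {ds.n_samples} samples over {N} clients")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(12,)))
    classes = np.unique(ds.y)
    C = len(classes)
    if C > 2:
        props = _ci_proportions(rng, N, C, lo, hi)
    else:
        f = lo + (hi - lo) * (np.arange(N) / (N - 1) if N > 1 else np.zeros(1))
        props = np.column_stack([1.0 - f, f])

    sizes = _largest_remainder(np.full(N, ds.n_samples / N), ds.n_samples)
    # per-class allocation: scale the requested per-client counts so each
    # class's column sums to the samples actually available
    want = props * sizes[:, None]  # (N, C)
    by_class = _class_indices(ds, rng)
    counts = np.zeros((N, C), dtype=int)
    for j, c in enumerate(classes):
        avail = len(by_class[int(c)])
        col = want[:, j]
        if col.sum() <= 0:
            if avail > 0:
                raise InfeasiblePartition(
                    f"class {c} has {avail} samples but every client requests 0"
                )
            continue
        counts[:, j] = _largest_remainder(col * (avail / col.sum()), avail)
    shards: list[list[np.ndarray]] = [[] for _ in range(N)]
    for j, c in enumerate(classes):
        idx = by_class[int(c)]
        start = 0
        for i in range(N):
            shards[i].append(idx[start : start + counts[i, j]])
            start += counts[i, j]
    out = [np.sort(np.concatenate(parts)) for parts in shards]
    if min(len(o) for o in out) == 0:
        raise InfeasiblePartition("a client received zero samples")
    return [ds.subset(o) for o in out]


def _ci_proportions(rng, N: int, C: int, lo: float, hi: float) -> np.ndarray:
    width = hi - lo
    if width == 0:
        return np.full((N, C), 1.0 / C)
    # concentration -> infinity as the range narrows (IID limit), -> 0.3 as it
    # spans the whole unit interval (strongly skewed clients)
    alpha = max((1.0 - width) / width, 0.3)
    return rng.dirichlet(np.full(C, alpha), size=N)


def split_disjoint_classes(
    ds: Dataset, N: int, classes_per_client: int, seed: int
) -> list[Dataset]:
    """Each client holds only `classes_per_client` of the C classes.

    Class subsets are assigned round-robin over the sorted class list, so
    with ``classes_per_client * N >= C`` every class lands on at least one
    client; subsets of different clients need not overlap.
    """
    classes = np.unique(ds.y)
    C = len(classes)
    if classes_per_client < 1 or classes_per_client > C:
        raise ValueError(f"classes_per_client must be in 1..{C}")
    if classes_per_client * N < C:
        raise InfeasiblePartition(
            f"{N} clients x {classes_per_client} classes cannot cover {C} classes"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    assignment = [
        [int(classes[(i * classes_per_client + t) % C]) for t in range(classes_per_client)]
        for i in range(N)
    ]
    holders: dict[int, list[int]] = {int(c): [] for c in classes}
    for i, cls_list in enumerate(assignment):
        for c in cls_list:
            if i not in holders[c]:
                holders[c].append(i)
    shards: list[list[np.ndarray]] = [[] for _ in range(N)]
    for c, idx in _class_indices(ds, rng).items():
        who = holders[int(c)]
        counts = _largest_remainder(np.full(len(who), len(idx) / len(who)), len(idx))
        start = 0
        for i, cnt in zip(who, counts):
            shards[i].append(idx[start : start + cnt])
            start += cnt
    out = []
    for i, parts in enumerate(shards):
        rows = np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
        shard = ds.subset(rows)
        shard.meta["assigned_classes"] = assignment[i]
        out.append(shard)
    return out


def train_test_split(
    shard: Dataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Stratified train/test split of one client's shard.

    The train size is ``round(n * train_fraction)`` overall, apportioned over
    classes by largest remainder; classes with a single sample go to train.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = shard.n_samples
    if n < 2:
        raise ValueError("cannot split a shard with fewer than 2 samples")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(14,)))
    n_train_target = int(round(n * train_fraction))
    n_train_target = min(max(n_train_target, 1), n - 1)

    by_class = _class_indices(shard, rng)
    classes = sorted(by_class)
    sizes = np.array([len(by_class[c]) for c in classes])
    quotas = sizes * (n_train_target / n)
    n_train_per = _largest_remainder(quotas, n_train_target)
    # singletons are forced into train
    for j, c in enumerate(classes):
        if sizes[j] == 1:
            n_train_per[j] = 1
    if int(n_train_per.sum()) >= n:
        # all-singleton (or rounding) edge: keep at least one test sample,
        # taken from the largest class
        j = int(np.argmax(sizes))
        n_train_per[j] -= 1
    train_rows, test_rows = [], []
    for j, c in enumerate(classes):
        idx = by_class[c]
        train_rows.append(idx[: n_train_per[j]])
        test_rows.append(idx[n_train_per[j] :])
    train = shard.subset(np.sort(np.concatenate(train_rows)))
    test = shard.subset(np.sort(np.concatenate(test_rows)))
    return train, test


def make_clients(ds: Dataset, spec: PartitionSpec) -> list[ClientData]:
    """Partition a dataset per the spec, then split each shard 80/20 (default)."""
    if spec.kind == "iid":
        shards = split_iid(ds, spec.N, spec.seed)
    elif spec.kind == "si":
        shards = split_sample_imbalance(ds, spec.N, spec.ramp_ratio, spec.seed)
    elif spec.kind == "ci":
        shards = split_class_imbalance(ds, spec.N, spec.fraction_range, spec.seed)
    else:
        cpc = spec.classes_per_client
        if cpc == 0:
            C = len(np.unique(ds.y))
            cpc = (C + 1) // 2
        shards = split_disjoint_classes(ds, spec.N, cpc, spec.seed)
    clients = []
    for i, shard in enumerate(shards):
        train, test = train_test_split(shard, spec.train_fraction, seed=spec.seed + 1000 + i)
        clients.append(ClientData(train=train, test=test))
    return clients


def save_manifest(shards: list[Dataset], spec: PartitionSpec, path: str | Path) -> None:
    """Persist per-client row indices plus the spec as a JSON manifest."""
    manifest = {
        "spec": {
            "kind": spec.kind, "N": spec.N, "seed": spec.seed,
            "ramp_ratio": spec.ramp_ratio,
            "fraction_range": list(spec.fraction_range),
            "classes_per_client": spec.classes_per_client,
            "train_fraction": spec.train_fraction,
        },
        "clients": [s.meta.get("rows", []) for s in shards],
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
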