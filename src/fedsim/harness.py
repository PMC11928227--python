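"""Paired federated/centralized experiments, comparison metrics, and sweeps.

An experiment is specified by a plain dictionary (typically loaded from a
YAML file): a synthetic dataset generator, a partition spec, a model, an
aggregator, learning rates, round count, and a list of seeds. The harness
runs the federated and centralized arms under the matched protocol — same
initialization seed, same learning rate unless swept, rounds equal to epochs,
server-side evaluation on the pooled/concatenated test set — and summarizes
each arm by the normalized area under its accuracy curve (AUC) and its final
accuracy, per seed.

The learning-rate sweep quantifies the clients-versus-learning-rate
relationship: for a federated run at rate eta over N equal clients with a
full-batch sum-reduction loss, one centralized epoch at eta/N takes exactly
the same parameter step, so a grid search over centralized rates recovers the
factor N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic_data
from .fed_core import TrainConfig, run_centralized, run_federated
from .fed_gbdt import GBDTConfig, run_inprivate
from .models import ConvArch, LinearArch, LossSpec, MLPArch
from .partitioner import ClientData, PartitionSpec, make_clients
from .synthetic_data import Dataset

__all__ = [
    "ComparisonReport",
    "ExperimentConfig",
    "accuracy_curve_auc",
    "update_divergence",
    "run_comparison",
    "sweep_learning_rate",
    "build_dataset",
    "build_arch",
    "pooled_train_test",
]

DEFAULT_CENTRAL_GRID = (0.005, 0.01, 0.05, 0.1, 0.5, 1.0)


def accuracy_curve_auc(curve) -> float:
    """Normalized trapezoidal area under an accuracy-versus-round curve.

    Divides by the number of round intervals so a constant curve at accuracy
    ``a`` maps to ``a``; the value is always bounded by the curve's min/max.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or curve.size < 2:
        raise ValueError("need a 1-D curve with at least 2 points")
    return float(np.trapezoid(curve) / (curve.size - 1))


def update_divergence(client_params: list, global_params: list) -> np.ndarray:
    """Per-client, per-round Euclidean distance from the aggregated model.

    ``client_params[r][i]`` is client i's returned model in round r and
    ``global_params[r+1]`` the global model aggregated from those returns
    (``global_params[0]`` being the initial model). Row i of the output is
    client i's distance trajectory — the numeric form of the update-divergence
    heatmap: under class imbalance the most skewed clients sit consistently
    farthest from the global model.
    """
    R = len(client_params)
    if len(global_params) != R + 1:
        raise ValueError("need one global snapshot per round plus the initial model")
    if R == 0:
        return np.zeros((0, 0))
    N = len(client_params[0])
    out = np.zeros((N, R))
    for r in range(R):
        g = global_params[r + 1].theta
        if len(client_params[r]) != N:
            raise ValueError("client count changed between rounds")
        for i, m in enumerate(client_params[r]):
            out[i, r] = float(np.linalg.norm(m.theta - g))
    return out


# --------------------------------------------------------------------------
# experiment configuration
# --------------------------------------------------------------------------

_DATASET_KEYS = {
    "blobs": {"n", "d", "C", "separation"},
    "expression": {"n", "d", "k_informative", "noise_sd", "latent_sd", "class_sep"},
    "fingerprints": {"n", "d", "density", "class_imbalance"},
}

_KNOWN_KEYS = {
    "dataset", "partition", "model", "aggregator", "scaffold_variant",
    "eta_l", "eta_g", "rounds", "local_epochs", "n_batches", "seeds",
    "loss", "reduction", "hidden", "n_filters", "kernel",
    "shrinkage", "max_depth", "output_dir",
}


@dataclass
class ExperimentConfig:
    """Validated experiment description; unknown keys are hard errors."""

    dataset: dict
    partition: dict
    model: str = "logistic"
    aggregator: str = "fedavg"
    scaffold_variant: str = "additive"
    eta_l: float = 0.1
    eta_g: float = 1.0
    rounds: int = 30
    local_epochs: int = 1
    n_batches: int = 1
    seeds: tuple = (0, 1, 2, 3)
    reduction: str = "sum"
    hidden: int = 64
    n_filters: int = 8
    kernel: int = 3
    shrinkage: float = 0.1
    max_depth: int = 3
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        unknown = set(raw) - _KNOWN_KEYS - {"loss"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        raw.pop("loss", None)
        kind = raw.get("dataset", {}).get("kind")
        if kind not in _DATASET_KEYS:
            raise ValueError(f"dataset.kind must be one of {sorted(_DATASET_KEYS)}")
        extra = set(raw["dataset"]) - _DATASET_KEYS[kind] - {"kind", "seed"}
        if extra:
            raise ValueError(f"unknown dataset keys for {kind}: {sorted(extra)}")
        if "partition" not in raw:
            raise ValueError("config needs a 'partition' section")
        cfg = cls(**raw)
        if isinstance(cfg.seeds, list):
            cfg.seeds = tuple(cfg.seeds)
        return cfg

    def loss_spec(self) -> LossSpec:
        name = {"logistic": "logistic", "svm": "hinge", "hinge": "hinge",
                "mlp": "cross_entropy", "cnn": "cross_entropy"}.get(self.model)
        if name is None:
            raise ValueError(f"model {self.model!r} has no gradient loss")
        return LossSpec(name=name, reduction=self.reduction)


def build_dataset(spec: dict, seed: int) -> Dataset:
    """Instantiate a synthetic dataset from a config section."""
    spec = dict(spec)
    kind = spec.pop("kind")
    spec.setdefault("seed", seed)
    if kind == "blobs":
        return synthetic_data.make_blobs(**spec)
    if kind == "expression":
        return synthetic_data.make_expression(**spec)
    if kind == "fingerprints":
        return synthetic_data.make_fingerprints(**spec)
    raise ValueError(f"unknown dataset kind {kind!r}")


def build_arch(cfg: ExperimentConfig, d: int, C: int):
    if cfg.model in ("logistic", "svm", "hinge"):
        return LinearArch(d, C)
    if cfg.model == "mlp":
        return MLPArch(d, C, hidden=cfg.hidden)
    if cfg.model == "cnn":
        return ConvArch(d, C, n_filters=cfg.n_filters, kernel=cfg.kernel)
    raise ValueError(f"unknown model {cfg.model!r}")


def pooled_train_test(clients: list[ClientData]) -> tuple[Dataset, Dataset]:
    """Concatenate client shards into the centralized arm's train/test pair."""
    Xtr = np.vstack([c.train.X for c in clients])
    ytr = np.concatenate([c.train.y for c in clients])
    Xte = np.vstack([c.test.X for c in clients])
    yte = np.concatenate([c.test.y for c in clients])
    return Dataset(Xtr, ytr), Dataset(Xte, yte)


def _make_clients_for_seed(cfg: ExperimentConfig, seed: int) -> list[ClientData]:
    ds = build_dataset(cfg.dataset, seed)
    pspec = PartitionSpec(seed=seed, **cfg.partition)
    return make_clients(ds, pspec)


def _train_config(cfg: ExperimentConfig, seed: int, eta_l: float | None = None,
                  record: bool = False) -> TrainConfig:
    return TrainConfig(
        eta_l=cfg.eta_l if eta_l is None else eta_l,
        eta_g=cfg.eta_g, rounds=cfg.rounds, local_epochs=cfg.local_epochs,
        n_batches=cfg.n_batches, aggregator=cfg.aggregator,
        scaffold_variant=cfg.scaffold_variant, seed=seed, record_params=record,
    )


@dataclass
class ComparisonReport:
    """Per-seed AUC and final accuracy for both arms, plus summaries."""

    config: dict
    federated_auc: list = field(default_factory=list)
    centralized_auc: list = field(default_factory=list)
    federated_final: list = field(default_factory=list)
    centralized_final: list = field(default_factory=list)
    federated_diverged: list = field(default_factory=list)
    centralized_diverged: list = field(default_factory=list)
    federated_runs: list = field(default_factory=list)
    centralized_runs: list = field(default_factory=list)

    def summary(self) -> dict:
        def stats(xs):
            arr = np.asarray(xs, dtype=float)
            return {"mean": float(arr.mean()), "std": float(arr.std())}
        return {
            "federated_auc": stats(self.federated_auc),
            "centralized_auc": stats(self.centralized_auc),
            "federated_final": stats(self.federated_final),
            "centralized_final": stats(self.centralized_final),
            "any_diverged": bool(any(self.federated_diverged)
                                 or any(self.centralized_diverged)),
        }

    def save(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "per_seed": {
                "federated_auc": self.federated_auc,
                "centralized_auc": self.centralized_auc,
                "federated_final": self.federated_final,
                "centralized_final": self.centralized_final,
            },
            "summary": self.summary(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_comparison(config: dict | ExperimentConfig, record_params: bool = False,
                   log=None) -> ComparisonReport:
    """Run the federated and centralized arms over every seed in the config."""
    cfg = config if isinstance(config, ExperimentConfig) else ExperimentConfig.from_dict(config)
    report = ComparisonReport(config=cfg.__dict__.copy())
    for seed in cfg.seeds:
        clients = _make_clients_for_seed(cfg, seed)
        train, test = pooled_train_test(clients)
        if cfg.model == "gbdt":
            gcfg = GBDTConfig(rounds=cfg.rounds, shrinkage=cfg.shrinkage,
                              max_depth=cfg.max_depth, seed=seed)
            fed = run_inprivate(gcfg, clients)
            cen = run_inprivate(gcfg, [ClientData(train=train, test=test)])
        else:
            arch = build_arch(cfg, train.n_features, max(train.n_classes, test.n_classes))
            loss = cfg.loss_spec()
            tc = _train_config(cfg, seed, record=record_params)
            fed = run_federated(tc, clients, arch, loss)
            cen = run_centralized(tc, train, test, arch, loss)
        for arm, auc_list, fin_list, div_list, run_list in (
            (fed, report.federated_auc, report.federated_final,
             report.federated_diverged, report.federated_runs),
            (cen, report.centralized_auc, report.centralized_final,
             report.centralized_diverged, report.centralized_runs),
        ):
            auc_list.append(accuracy_curve_auc(arm.global_accuracy))
            fin_list.append(arm.global_accuracy[-1])
            div_list.append(arm.diverged)
            run_list.append(arm)
        if log is not None:
            print(f"seed {seed}: fed final {fed.global_accuracy[-1]:.3f}, "
                  f"central final {cen.global_accuracy[-1]:.3f}", file=log)
    return report


def run_batch_effect_comparison(
    n: int = 360,
    d: int = 500,
    n_clients: int = 3,
    k: int = 100,
    znorm: bool = True,
    seed: int = 0,
    rounds: int = 40,
    eta_l: float = 0.5,
    hidden: int = 32,
) -> dict:
    """Batch-effect experiment: multi-site expression data, PCA features, MLP.

    Expression-like data is split IID over ``n_clients`` sites, then each
    site's features are distorted by its own random affine batch effect
    (emulating different measurement platforms). The federated PCA pipeline
    runs with or without per-client z-normalization, and a small fully
    connected net is trained federated and centralized on the reduced
    features. Without the local normalization the top principal components
    encode site identity rather than biology and the classifier collapses to
    chance; with it, federated and centralized accuracy agree.
    """
    from .fed_pca import reduce_clients
    from .partitioner import ClientData, split_iid, train_test_split
    from .synthetic_data import inject_batch_effect, make_expression, random_batch_effect

    ds = make_expression(n, d, 5, 1.0, seed)
    shards = split_iid(ds, n_clients, seed)
    clients = []
    for g, shard in enumerate(shards):
        spec = random_batch_effect(shard, np.zeros(shard.n_samples, dtype=int),
                                   seed=seed * n_clients + g)
        distorted = inject_batch_effect(shard, spec)
        tr, te = train_test_split(distorted, 0.8, seed=seed + g)
        clients.append(ClientData(train=tr, test=te))
    reduced, _ = reduce_clients(clients, k=k, znorm=znorm)
    arch = MLPArch(k, 2, hidden=hidden)
    loss = LossSpec("cross_entropy", "mean")
    cfg = TrainConfig(eta_l=eta_l, rounds=rounds, seed=seed, record_params=False)
    fed = run_federated(cfg, reduced, arch, loss)
    train, test = pooled_train_test(reduced)
    cen = run_centralized(cfg, train, test, arch, loss)
    return {"federated_final": fed.global_accuracy[-1],
            "centralized_final": cen.global_accuracy[-1],
            "federated_curve": fed.global_accuracy,
            "centralized_curve": cen.global_accuracy}


def _curve_distance(a, b) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    m = min(a.size, b.size)
    return float(np.mean(np.abs(a[:m] - b[:m])))


def sweep_learning_rate(
    config: dict | ExperimentConfig,
    federated_lrs: tuple = (0.05, 0.1, 0.5, 1.0),
    central_grid: tuple = DEFAULT_CENTRAL_GRID,
    log=None,
) -> dict:
    """Match each federated learning rate to its closest centralized rate.

    For every federated rate, both arms are run over the config's seeds and
    the centralized rate minimizing the mean absolute difference between the
    per-round global accuracy curves (averaged over seeds) is selected. Ties
    go to the smaller rate. Returns per-federated-rate matches, the implied
    federated/centralized ratios, and the modal ratio.
    """
    cfg = config if isinstance(config, ExperimentConfig) else ExperimentConfig.from_dict(config)
    loss = cfg.loss_spec()

    clients_by_seed, pooled_by_seed = {}, {}
    for seed in cfg.seeds:
        clients_by_seed[seed] = _make_clients_for_seed(cfg, seed)
        pooled_by_seed[seed] = pooled_train_test(clients_by_seed[seed])

    central_curves: dict[float, dict[int, list]] = {}
    for lr in central_grid:
        central_curves[lr] = {}
        for seed in cfg.seeds:
            train, test = pooled_by_seed[seed]
            arch = build_arch(cfg, train.n_features, train.n_classes)
            run = run_centralized(_train_config(cfg, seed, eta_l=lr), train, test,
                                  arch, loss)
            central_curves[lr][seed] = run.global_accuracy

    matches, ratios = {}, []
    for fed_lr in federated_lrs:
        fed_curves = {}
        for seed in cfg.seeds:
            train, _ = pooled_by_seed[seed]
            arch = build_arch(cfg, train.n_features, train.n_classes)
            run = run_federated(_train_config(cfg, seed, eta_l=fed_lr),
                                clients_by_seed[seed], arch, loss)
            fed_curves[seed] = run.global_accuracy
        distances = {
            lr: float(np.mean([_curve_distance(fed_curves[s], central_curves[lr][s])
                               for s in cfg.seeds]))
            for lr in central_grid
        }
        best = min(sorted(distances), key=lambda lr: distances[lr])
        matches[fed_lr] = {"best_central_lr": best, "distances": distances}
        ratios.append(fed_lr / best)
        if log is not None:
            print(f"federated lr {fed_lr}: best centralized lr {best} "
                  f"(distance {distances[best]:.4g})", file=log)

    vals, counts = np.unique(np.round(ratios, 6), return_counts=True)
    modal_ratio = float(vals[np.argmax(counts)])
    return {"matches": matches, "ratios": ratios, "modal_ratio": modal_ratio}
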