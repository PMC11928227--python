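"""The federated round loop (fedAVG / SCAFFOLD) and the matched centralized baseline.

One communication round: the server broadcasts the global parameters, every
client evaluates them on its local test shard, runs one local epoch of
gradient descent, and returns its updated parameters (plus control-variate
deltas under SCAFFOLD); the server aggregates. The centralized baseline runs
the identical local step on the pooled training data, one epoch per round, so
round r of the federated run is directly comparable with epoch r of the
centralized run.

Aggregation rules:

* fedAVG — sample-size-weighted mean of client parameters,
  ``W_g = (1/S) * sum_i s_i * W_i``.
* SCAFFOLD — client drift is corrected with control variates. As implemented
  here (the default, ``variant="additive"``), the local update is

      W_i = W_g - eta_l * grad + (c_g - c_i)

  i.e. the correction is added to the step un-scaled by the learning rate;
  ``variant="scaled"`` instead folds the correction into the gradient,
  ``W_i = W_g - eta_l * (grad - c_i + c_g)``, which is the form in the
  original SCAFFOLD publication. Either way, within the same round

      c_i' = c_i - c_g + (1/eta_l) * (W_i_before - W_i_after)

  and the server updates ``W_g += (eta_g/N) * sum_i (W_i' - W_i)`` and
  ``c_g += (1/N) * sum_i (c_i' - c_i)`` — note the unweighted 1/N, in
  contrast with fedAVG's size weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .models import Architecture, LossSpec, ModelParams, accuracy, gradient, init_params, local_step
from .partitioner import ClientData

__all__ = [
    "TrainConfig",
    "GlobalState",
    "ClientState",
    "RunResult",
    "fedavg_global_step",
    "scaffold_local_step",
    "scaffold_global_step",
    "run_federated",
    "run_centralized",
]


@dataclass
class TrainConfig:
    """Protocol constants shared by the federated and centralized arms."""

    eta_l: float = 0.1
    eta_g: float = 1.0            # SCAFFOLD global learning rate
    rounds: int = 30
    local_epochs: int = 1         # one full local pass per round, per protocol
    n_batches: int = 1            # 1 = full-batch gradient step
    aggregator: Literal["fedavg", "scaffold"] = "fedavg"
    scaffold_variant: Literal["additive", "scaled"] = "additive"
    seed: int = 0
    record_params: bool = True

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.aggregator not in ("fedavg", "scaffold"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


@dataclass
class GlobalState:
    """Server-side state: global parameters, control variate, round counter."""

    W: ModelParams
    c: np.ndarray
    round: int = 0


@dataclass
class ClientState:
    """One client's data plus its local model and control variate."""

    data: ClientData
    W: ModelParams | None = None
    c: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.data.size


@dataclass
class RunResult:
    """Everything one run produces: accuracy curves, snapshots, provenance."""

    config: dict
    seed: int
    global_accuracy: list = field(default_factory=list)      # length rounds+1
    client_accuracy: list = field(default_factory=list)      # per round, per client
    global_params: list = field(default_factory=list)        # ModelParams per round
    client_params: list = field(default_factory=list)        # per round, list of ModelParams
    diverged: bool = False

    @property
    def final_accuracy(self) -> float:
        return self.global_accuracy[-1]

    def save(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "global_accuracy": self.global_accuracy,
            "client_accuracy": self.client_accuracy,
            "diverged": self.diverged,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def fedavg_global_step(W_list: list[ModelParams], sizes: list[int]) -> ModelParams:
    """Sample-size-weighted average of client parameter vectors."""
    if not W_list or len(W_list) != len(sizes):
        raise ValueError("need one size per client model")
    sizes = np.asarray(sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("client sizes must be positive")
    weights = sizes / sizes.sum()
    theta = sum(w * m.theta for w, m in zip(weights, W_list))
    return ModelParams(theta, W_list[0].arch)


def scaffold_local_step(
    W_g: ModelParams,
    c_g: np.ndarray,
    c_i: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    eta_l: float,
    loss: LossSpec,
    variant: str = "additive",
    n_batches: int = 1,
    seed: int = 0,
) -> tuple[ModelParams, np.ndarray]:
    """One SCAFFOLD local epoch: drift-corrected descent plus control update.

    Returns the updated local parameters and the new client control variate.
    With zero control variates this reduces exactly to the fedAVG local step,
    and the new control variate equals the gradient actually taken.
    """
    if eta_l <= 0:
        raise ValueError("eta_l must be positive for SCAFFOLD")
    if c_g.shape != W_g.theta.shape or c_i.shape != W_g.theta.shape:
        raise ValueError("control variates must match the parameter shape")
    correction = c_g - c_i
    theta = W_g.theta.copy()
    n = np.asarray(X).shape[0]
    if n_batches < 1 or n_batches > n:
        raise ValueError(f"n_batches must be in 1..{n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    order = rng.permutation(n) if n_batches > 1 else np.arange(n)
    cur = ModelParams(theta, W_g.arch)
    for batch in np.array_split(order, n_batches):
        g = gradient(cur, np.asarray(X)[batch], np.asarray(y)[batch], loss)
        if variant == "additive":
            step = eta_l * g - correction
        elif variant == "scaled":
            step = eta_l * (g + correction)
        else:
            raise ValueError(f"unknown SCAFFOLD variant {variant!r}")
        cur = ModelParams(cur.theta - step, W_g.arch)
    c_i_new = c_i - c_g + (W_g.theta - cur.theta) / eta_l
    return cur, c_i_new


def scaffold_global_step(
    W_g: ModelParams,
    W_new_list: list[ModelParams],
    W_sent: ModelParams,
    c_g: np.ndarray,
    c_old_list: list[np.ndarray],
    c_new_list: list[np.ndarray],
    eta_g: float,
) -> tuple[ModelParams, np.ndarray]:
    """Unweighted (1/N) SCAFFOLD aggregation of parameter and variate deltas."""
    N = len(W_new_list)
    if N == 0 or len(c_old_list) != N or len(c_new_list) != N:
        raise ValueError("client lists must be nonempty and of equal length")
    dW = sum(m.theta - W_sent.theta for m in W_new_list)
    dc = sum(cn - co for cn, co in zip(c_new_list, c_old_list))
    W_new = ModelParams(W_g.theta + (eta_g / N) * dW, W_g.arch)
    return W_new, c_g + dc / N


def _subseed(seed: int, r: int, i: int) -> int:
    """Deterministic per-(round, client) shuffle seed below 2**31."""
    return int(np.random.SeedSequence(seed, spawn_key=(r, i)).generate_state(1)[0] % (2**31))


def run_federated(
    cfg: TrainConfig,
    clients: list[ClientData],
    arch: Architecture,
    loss: LossSpec,
) -> RunResult:
    """Execute the full federated round loop and record accuracy curves.

    Per round r: broadcast W_g, record each client's accuracy of the received
    model on its local test shard, run the local step(s), aggregate, and
    record the new global model's accuracy on the concatenation of all client
    test shards (server-side evaluation). The global curve has rounds+1
    entries: the initial model plus one per round. Non-finite parameters mark
    the run as diverged and stop training; the result is still returned.
    """
    if not clients:
        raise ValueError("need at least one client")
    states = [ClientState(data=c) for c in clients]
    W_g = init_params(arch, cfg.seed)
    c_g = np.zeros_like(W_g.theta)
    for st in states:
        st.c = np.zeros_like(W_g.theta)

    X_test = np.vstack([c.test.X for c in clients])
    y_test = np.concatenate([c.test.y for c in clients])

    result = RunResult(config=_config_dict(cfg, len(clients)), seed=cfg.seed)
    result.global_accuracy.append(accuracy(W_g, X_test, y_test))
    if cfg.record_params:
        result.global_params.append(W_g.copy())

    for r in range(cfg.rounds):
        round_acc, new_models, new_cs = [], [], []
        W_sent = W_g
        for i, st in enumerate(states):
            round_acc.append(accuracy(W_sent, st.data.test.X, st.data.test.y))
            X_tr, y_tr = st.data.train.X, st.data.train.y
            if cfg.aggregator == "fedavg":
                W_i = W_sent
                for e in range(cfg.local_epochs):
                    W_i = local_step(W_i, X_tr, y_tr, cfg.eta_l, loss,
                                     cfg.n_batches, seed=_subseed(cfg.seed, r * cfg.local_epochs + e, i))
                new_models.append(W_i)
            else:
                W_i, c_i = scaffold_local_step(
                    W_sent, c_g, st.c, X_tr, y_tr, cfg.eta_l, loss,
                    variant=cfg.scaffold_variant, n_batches=cfg.n_batches,
                    seed=_subseed(cfg.seed, r, i),
                )
                new_models.append(W_i)
                new_cs.append(c_i)
        result.client_accuracy.append(round_acc)

        if cfg.aggregator == "fedavg":
            W_g = fedavg_global_step(new_models, [st.size for st in states])
        else:
            old_cs = [st.c for st in states]
            W_g, c_g = scaffold_global_step(
                W_g, new_models, W_sent, c_g, old_cs, new_cs, cfg.eta_g
            )
            for st, c_i in zip(states, new_cs):
                st.c = c_i
        if cfg.record_params:
            result.client_params.append([m.copy() for m in new_models])
            result.global_params.append(W_g.copy())
        if not W_g.is_finite:
            result.diverged = True
            break
        result.global_accuracy.append(accuracy(W_g, X_test, y_test))
    return result


def run_centralized(
    cfg: TrainConfig,
    train,  # Dataset
    test,   # Dataset
    arch: Architecture,
    loss: LossSpec,
) -> RunResult:
    """Centralized baseline: the same local step on pooled data, one epoch/round."""
    W = init_params(arch, cfg.seed)
    result = RunResult(config=_config_dict(cfg, 1), seed=cfg.seed)
    result.global_accuracy.append(accuracy(W, test.X, test.y))
    if cfg.record_params:
        result.global_params.append(W.copy())
    for r in range(cfg.rounds):
        for e in range(cfg.local_epochs):
            W = local_step(W, train.X, train.y, cfg.eta_l, loss,
                           cfg.n_batches, seed=_subseed(cfg.seed, r * cfg.local_epochs + e, 0))
        if cfg.record_params:
            result.global_params.append(W.copy())
        if not W.is_finite:
            result.diverged = True
            break
        result.global_accuracy.append(accuracy(W, test.X, test.y))
    return result


def _config_dict(cfg: TrainConfig, n_clients: int) -> dict:
    return {
        "eta_l": cfg.eta_l, "eta_g": cfg.eta_g, "rounds": cfg.rounds,
        "local_epochs": cfg.local_epochs, "n_batches": cfg.n_batches,
        "aggregator": cfg.aggregator, "scaffold_variant": cfg.scaffold_variant,
        "n_clients": n_clients, "seed": cfg.seed,
    }
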