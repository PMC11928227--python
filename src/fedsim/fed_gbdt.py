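"""Sequential federated gradient boosting ("inPrivate" protocol).

Trees do not average, so the GBDT federates differently from the other
classifiers: exactly one client is active per round (round-robin,
``active = r mod N``). The active client receives the current ensemble,
computes the pseudo-residuals of the binomial (or softmax) deviance on its
own training data, fits one regression tree (one per class for C > 2) to
those residuals, re-fits the leaf values with a one-step Newton estimate, and
appends the shrunken tree to the ensemble. With a single client the protocol
collapses to ordinary gradient boosting: staged raw scores match
scikit-learn's ``GradientBoostingClassifier`` with the same tree parameters
to machine precision, which serves as the reference oracle.

Because each tree is grown on one client's class mix, the protocol is
sensitive to disjoint-class partitions: trees built by a client that never
sees some classes produce residual structure that is unhelpful — or actively
harmful — for the clients that do, and accuracy degrades where parameter
averaging would not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit
from sklearn.tree import DecisionTreeRegressor

from .fed_core import RunResult
from .partitioner import ClientData

__all__ = [
    "GBDTConfig",
    "TreeEnsemble",
    "select_active_client",
    "boost_loss",
    "inprivate_round",
    "run_inprivate",
]

#: keep ensemble probabilities away from {0, 1} so the deviance stays finite
PROB_CLIP = 1e-12


@dataclass
class GBDTConfig:
    """Tree-fitting hyperparameters (library defaults, restated explicitly)."""

    rounds: int = 30
    shrinkage: float = 0.1
    max_depth: int = 3
    seed: int = 0


@dataclass
class TreeEnsemble:
    """An additive model: initial raw score + shrinkage-weighted tree outputs.

    Binary problems keep one tree per round (raw score = log-odds of class 1);
    multiclass problems keep C trees per round (one raw score per class,
    softmax link).
    """

    n_classes: int
    init_raw: np.ndarray                      # () -> shape (K,) raw offsets
    shrinkage: float = 0.1
    max_depth: int = 3
    trees: list = field(default_factory=list)  # list of [tree per score dim]

    @property
    def n_rounds(self) -> int:
        return len(self.trees)

    @property
    def n_score_dims(self) -> int:
        return 1 if self.n_classes == 2 else self.n_classes

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, K) raw additive scores, K = 1 (binary) or C (multiclass)."""
        X = np.asarray(X, dtype=float)
        raw = np.tile(self.init_raw, (X.shape[0], 1))
        for group in self.trees:
            for k, tree in enumerate(group):
                raw[:, k] += self.shrinkage * _tree_predict(tree, X)
        return raw

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.raw_scores(X)
        if self.n_classes == 2:
            p1 = expit(raw[:, 0])
            P = np.column_stack([1.0 - p1, p1])
        else:
            z = raw - raw.max(axis=1, keepdims=True)
            e = np.exp(z)
            P = e / e.sum(axis=1, keepdims=True)
        return np.clip(P, PROB_CLIP, 1.0 - PROB_CLIP)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def staged_raw_scores(self, X: np.ndarray):
        """Yield raw scores after each completed round (the boosting oracle hook)."""
        X = np.asarray(X, dtype=float)
        raw = np.tile(self.init_raw, (X.shape[0], 1))
        for group in self.trees:
            for k, tree in enumerate(group):
                raw[:, k] += self.shrinkage * _tree_predict(tree, X)
            yield raw.copy()

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n_classes": self.n_classes,
            "init_raw": self.init_raw.tolist(),
            "shrinkage": self.shrinkage,
            "max_depth": self.max_depth,
            "trees": [[_export_tree(t) for t in group] for group in self.trees],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TreeEnsemble":
        payload = json.loads(text)
        ens = cls(
            n_classes=payload["n_classes"],
            init_raw=np.asarray(payload["init_raw"], dtype=float),
            shrinkage=payload["shrinkage"],
            max_depth=payload["max_depth"],
        )
        ens.trees = [[_ArrayTree(**t) for t in group] for group in payload["trees"]]
        return ens

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


class _ArrayTree:
    """Minimal array-backed regression tree (deserialized form)."""

    def __init__(self, feature, threshold, left, right, value):
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.left = np.asarray(left, dtype=int)
        self.right = np.asarray(right, dtype=int)
        self.value = np.asarray(value, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            node = 0
            while self.left[node] != -1:
                node = self.left[node] if x[self.feature[node]] <= self.threshold[node] \
                    else self.right[node]
            out[i] = self.value[node]
        return out


def _export_tree(tree) -> dict:
    if isinstance(tree, _ArrayTree):
        return {"feature": tree.feature.tolist(), "threshold": tree.threshold.tolist(),
                "left": tree.left.tolist(), "right": tree.right.tolist(),
                "value": tree.value.tolist()}
    t = tree.tree_
    return {
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "left": t.children_left.tolist(),
        "right": t.children_right.tolist(),
        "value": t.value.reshape(-1).tolist(),
    }


def _tree_predict(tree, X: np.ndarray) -> np.ndarray:
    if isinstance(tree, _ArrayTree):
        return tree.predict(X)
    return tree.predict(X)


def select_active_client(r: int, N: int) -> int:
    """Round-robin active-client index for round r."""
    if N < 1 or r < 0:
        raise ValueError("need N >= 1 and r >= 0")
    return r % N


def boost_loss(y: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, float]:
    """Pseudo-residuals and deviance of the current ensemble on labeled data.

    Returns ``(residuals, deviance)`` where residuals are the negative
    gradient of the deviance with respect to raw scores — ``y - p`` for
    binary labels, ``Y_onehot - P`` columnwise for multiclass — to be used as
    the regression targets of the next tree.
    """
    y = np.asarray(y, dtype=int)
    P = np.clip(np.asarray(P, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)
    C = P.shape[1]
    if C == 2:
        p1 = P[:, 1]
        res = (y - p1)[:, None]
        dev = -float(np.sum(y * np.log(p1) + (1 - y) * np.log(1 - p1)))
    else:
        Y = np.zeros_like(P)
        Y[np.arange(len(y)), y] = 1.0
        res = Y - P
        dev = -float(np.sum(np.log(P[np.arange(len(y)), y])))
    return res, dev


def _fit_boost_tree(X, residual, p_times_q, max_depth, rng, multiclass_factor=1.0):
    """Fit one regression tree to residuals, Newton-refit its leaf values."""
    tree = DecisionTreeRegressor(
        criterion="squared_error", splitter="best", max_depth=max_depth,
        random_state=rng,
    )
    tree.fit(X, residual)
    leaves = tree.apply(X)
    values = np.zeros(tree.tree_.node_count)
    for leaf in np.unique(leaves):
        m = leaves == leaf
        denom = np.sum(p_times_q[m])
        values[leaf] = multiclass_factor * residual[m].sum() / denom if denom > PROB_CLIP else 0.0
    # overwrite the tree's leaf values so .predict returns the Newton estimate
    tree.tree_.value[:, 0, 0] = values
    return tree


def init_ensemble(y: np.ndarray, n_classes: int, cfg: GBDTConfig) -> TreeEnsemble:
    """Empty ensemble whose initial raw score is the label prior's link value.

    In the federated protocol the prior comes from the first active client's
    training labels (the server never sees data); with one client this is the
    pooled prior, matching the centralized reference.
    """
    y = np.asarray(y, dtype=int)
    if n_classes == 2:
        p = np.clip(np.mean(y == 1), PROB_CLIP, 1 - PROB_CLIP)
        init_raw = np.array([logit(p)])
    else:
        priors = np.array([np.mean(y == c) for c in range(n_classes)])
        init_raw = np.log(np.clip(priors, PROB_CLIP, None))
    return TreeEnsemble(n_classes=n_classes, init_raw=init_raw,
                        shrinkage=cfg.shrinkage, max_depth=cfg.max_depth)


def inprivate_round(
    ens: TreeEnsemble, client: ClientData, rng: np.random.RandomState
) -> TreeEnsemble:
    """One boosting round on the active client; earlier trees are untouched.

    The client computes pseudo-residuals of its own labels under the current
    ensemble and fits one tree (C trees for multiclass) to them. If the
    client holds a single class the residuals are degenerate but a (stump)
    tree is still fitted and appended.
    """
    X, y = client.train.X, client.train.y
    if X.shape[0] < 1:
        raise ValueError("active client has no training samples")
    P = ens.predict_proba(X)
    res, _ = boost_loss(y, P)
    group = []
    if ens.n_classes == 2:
        pq = P[:, 1] * (1.0 - P[:, 1])
        group.append(_fit_boost_tree(X, res[:, 0], pq, ens.max_depth, rng))
    else:
        K = ens.n_classes
        factor = (K - 1.0) / K
        for k in range(K):
            pq = P[:, k] * (1.0 - P[:, k])
            group.append(_fit_boost_tree(X, res[:, k], pq, ens.max_depth, rng,
                                         multiclass_factor=factor))
    ens.trees.append(group)
    return ens


def run_inprivate(cfg: GBDTConfig, clients: list[ClientData]) -> RunResult:
    """R rounds of round-robin boosting with per-round accuracy bookkeeping.

    Records, per round, the active client's accuracy on its own test shard
    (the only accuracy the protocol itself reveals) and the server-side
    accuracy on the concatenation of all client test shards. The global curve
    has rounds+1 entries including the constant prior model.
    """
    if not clients:
        raise ValueError("need at least one client")
    n_classes = int(max(c.train.y.max() for c in clients)) + 1
    X_test = np.vstack([c.test.X for c in clients])
    y_test = np.concatenate([c.test.y for c in clients])
    rng = np.random.RandomState(cfg.seed)

    ens = init_ensemble(clients[0].train.y, n_classes, cfg)
    result = RunResult(
        config={"model": "gbdt", "rounds": cfg.rounds, "shrinkage": cfg.shrinkage,
                "max_depth": cfg.max_depth, "n_clients": len(clients),
                "seed": cfg.seed},
        seed=cfg.seed,
    )
    result.global_accuracy.append(ens.accuracy(X_test, y_test))
    for r in range(cfg.rounds):
        a = select_active_client(r, len(clients))
        active = clients[a]
        single_class = len(np.unique(active.train.y)) == 1
        ens = inprivate_round(ens, active, rng)
        result.client_accuracy.append({
            "active": a,
            "active_test_accuracy": ens.accuracy(active.test.X, active.test.y),
            "single_class": bool(single_class),
        })
        result.global_accuracy.append(ens.accuracy(X_test, y_test))
    result.config["ensemble_size"] = ens.n_rounds
    result.config["final_ensemble"] = None  # set by callers that persist trees
    result.ensemble = ens
    return result
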