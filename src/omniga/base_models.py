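"""The four local classifiers an omnivariate tree node may host.

Every node model — ridge-penalized logistic regression (MLR), a C4.5-style
decision tree (C45), a single-hidden-layer neural network (ANN) and a random
forest (RF) — is exposed behind one contract:

* parameters are drawn from finite grids (:data:`PARAM_GRIDS`), so the genome
  can index them with fixed-width bit fields;
* an ``effort_fraction`` in ``(0, 1]`` scales the training effort for the
  early-stopping add-on (epoch budget for ANN, tree count for RF, optimizer
  iterations for MLR, depth cap for C45);
* :meth:`FittedNodeModel.predict_proba` returns one ``(P(class1), P(class2))``
  pair per sample, each summing to 1.

The C4.5-style tree is an entropy decision tree with a minimum-instances
constraint and bottom-up error-based pruning: a subtree is collapsed when the
Clopper-Pearson upper confidence bound (at the configured confidence factor)
on its training error is no better than that of the collapsed leaf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .data import Dataset

__all__ = [
    "MODEL_KINDS",
    "PARAM_GRIDS",
    "EFFORT_LEVELS",
    "ANN_EPOCH_BUDGET",
    "MLR_ITER_BUDGET",
    "NodeModelSpec",
    "FittedNodeModel",
    "fit_node_model",
    "predict_node",
    "default_params",
]

MODEL_KINDS = ("MLR", "C45", "ANN", "RF")

# Finite parameter grids, indexable by the genome's fixed-width bit fields.
# Symbolic entries ("sqrt", "half_d", ...) resolve against the data dimension
# at fit time.
PARAM_GRIDS: dict[str, dict[str, tuple]] = {
    "MLR": {"ridge": (1e-8, 1e-4, 1e-2, 1.0, 10.0)},
    "RF": {
        "n_trees": (10, 50, 100, 200),
        "max_features": ("sqrt", "log2plus1", "quarter"),
    },
    "ANN": {
        "hidden_nodes": (2, 5, 10, "half_d"),
        "learning_rate": (0.3, 0.1, 0.01),
    },
    "C45": {
        "confidence": (0.1, 0.25, 0.5),
        "min_instances": (2, 5, 10),
    },
}

# Effort levels the 2-bit ES gene indexes.
EFFORT_LEVELS = (0.25, 0.5, 0.75, 1.0)

ANN_EPOCH_BUDGET = 120
MLR_ITER_BUDGET = 200


def default_params(kind: str) -> dict:
    """Middle-of-grid defaults for a model kind."""
    grids = PARAM_GRIDS[kind]
    return {name: vals[len(vals) // 2] for name, vals in grids.items()}


@dataclass(frozen=True)
class NodeModelSpec:
    """Which model a node hosts, with which grid parameters and effort."""

    model_kind: str
    params: dict = field(default_factory=dict)
    effort_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        grids = PARAM_GRIDS[self.model_kind]
        for name, value in self.params.items():
            if name not in grids:
                raise ValueError(f"{self.model_kind} has no parameter {name!r}")
            if value not in grids[name]:
                raise ValueError(
                    f"{self.model_kind}.{name}={value!r} is off-grid {grids[name]}"
                )
        if not 0.0 < self.effort_fraction <= 1.0:
            raise ValueError("effort_fraction must be in (0, 1]")

    def resolved_params(self) -> dict:
        p = default_params(self.model_kind)
        p.update(self.params)
        return p


def _resolve_max_features(symbol: str, d: int) -> int:
    if symbol == "sqrt":
        return max(1, math.ceil(math.sqrt(d)))
    if symbol == "log2plus1":
        return max(1, math.ceil(math.log2(d)) + 1) if d > 1 else 1
    if symbol == "quarter":
        return max(1, round(d / 4))
    raise ValueError(symbol)


def _resolve_hidden(symbol, d: int) -> int:
    if symbol == "half_d":
        return max(2, math.ceil((d + 2) / 2))
    return int(symbol)


class _C45Tree:
    """Entropy tree with min-instances constraint and pessimistic pruning."""

    def __init__(self, confidence: float, min_instances: int,
                 max_depth: int | None, random_state: int):
        self.confidence = confidence
        self.min_instances = min_instances
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_C45Tree":
        self._clf = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_split=max(2, self.min_instances),
            max_depth=self.max_depth,
            random_state=self.random_state,
        )
        self._clf.fit(X, y)
        self.classes_ = self._clf.classes_
        t = self._clf.tree_
        # class counts per node on the training data
        self._counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        self._pruned = np.zeros(t.node_count, dtype=bool)
        self._prune(0)
        return self

    def _leaf_error_bound(self, node: int) -> float:
        counts = self._counts[node]
        n = counts.sum()
        e = n - counts.max()
        # Clopper-Pearson upper bound on the true error rate at 1 - confidence
        if n == 0:
            return 0.0
        if e >= n:
            return float(n)
        ub = beta_dist.ppf(1.0 - self.confidence, e + 1, n - e)
        return float(n * ub)

    def _prune(self, node: int) -> float:
        """Bottom-up pessimistic pruning; returns the node's error estimate."""
        t = self._clf.tree_
        left, right = t.children_left[node], t.children_right[node]
        leaf_est = self._leaf_error_bound(node)
        if left == -1:  # already a leaf
            return leaf_est
        subtree_est = self._prune(left) + self._prune(right)
        if leaf_est <= subtree_est:
            self._pruned[node] = True
            return leaf_est
        return subtree_est

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        t = self._clf.tree_
        X = np.ascontiguousarray(X, dtype=np.float32)
        out = np.zeros((len(X), len(self.classes_)))
        # walk samples down, stopping at pruned nodes
        stack = [(0, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if len(idx) == 0:
                continue
            left = t.children_left[node]
            if left == -1 or self._pruned[node]:
                counts = self._counts[node]
                out[idx] = counts / counts.sum()
                continue
            go_left = X[idx, t.feature[node]] <= t.threshold[node]
            stack.append((left, idx[go_left]))
            stack.append((t.children_right[node], idx[~go_left]))
        return out

    @property
    def effective_depth(self) -> int:
        t = self._clf.tree_
        depth = [0]

        def walk(node: int, d: int) -> None:
            depth[0] = max(depth[0], d)
            if t.children_left[node] == -1 or self._pruned[node]:
                return
            walk(t.children_left[node], d + 1)
            walk(t.children_right[node], d + 1)

        walk(0, 0)
        return depth[0]


@dataclass
class FittedNodeModel:
    """A trained node model honoring the two-probability contract."""

    spec: NodeModelSpec
    estimator: object
    classes_: np.ndarray
    n_features_: int
    training_log: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        raw = self.estimator.predict_proba(X)
        # align columns to internal class codes {0, 1}
        proba = np.zeros((len(X), 2))
        for col, cls in enumerate(self.classes_):
            proba[:, int(cls)] = raw[:, col]
        # numerical guard: re-normalize
        proba /= proba.sum(axis=1, keepdims=True)
        return proba


def _coerce_xy(train) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(train, Dataset):
        return train.X, train.y.astype(int)
    X, y = train
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def fit_node_model(spec: NodeModelSpec, train, seed: int = 0) -> FittedNodeModel:
    """Fit one node model; deterministic given (spec, data, seed).

    ``train`` is a :class:`~omniga.data.Dataset` or an ``(X, y)`` pair.
    The ``effort_fraction`` scales the kind's training budget (see module
    docstring); at 1.0 the model trains fully.
    """
    X, y = _coerce_xy(train)
    if len(X) == 0:
        raise ValueError("empty training data")
    if len(np.unique(y)) < 2:
        raise ValueError("node model needs both classes present")
    p = spec.resolved_params()
    frac = spec.effort_fraction
    d = X.shape[1]
    log: dict = {"effort_fraction": frac}

    if spec.model_kind == "MLR":
        iters = max(1, math.ceil(frac * MLR_ITER_BUDGET))
        est = LogisticRegression(
            C=1.0 / p["ridge"], solver="lbfgs",
            max_iter=iters, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        log["max_iter"] = iters
    elif spec.model_kind == "RF":
        n_trees = max(1, round(frac * p["n_trees"]))
        est = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=_resolve_max_features(p["max_features"], d),
            random_state=seed,
        )
        est.fit(X, y)
        log["n_trees"] = n_trees
    elif spec.model_kind == "ANN":
        epochs = max(1, math.ceil(frac * ANN_EPOCH_BUDGET))
        est = MLPClassifier(
            hidden_layer_sizes=(_resolve_hidden(p["hidden_nodes"], d),),
            learning_rate_init=p["learning_rate"],
            max_iter=epochs,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        log["epoch_budget"] = epochs
        log["epochs_run"] = int(est.n_iter_)
    elif spec.model_kind == "C45":
        max_depth = None
        if frac < 1.0:
            probe = _C45Tree(p["confidence"], p["min_instances"], None, seed)
            probe.fit(X, y)
            full_depth = max(1, probe._clf.get_depth())
            max_depth = max(1, math.ceil(frac * full_depth))
            log["full_depth"] = full_depth
        est = _C45Tree(p["confidence"], p["min_instances"], max_depth, seed)
        est.fit(X, y)
        log["depth"] = est.effective_depth
    else:  # pragma: no cover - spec validation rules this out
        raise ValueError(spec.model_kind)

    return FittedNodeModel(
        spec=spec, estimator=est, classes_=np.asarray(est.classes_),
        n_features_=d, training_log=log,
    )


def predict_node(model: FittedNodeModel, samples: np.ndarray) -> np.ndarray:
    """Score pairs ``(P(class1), P(class2))`` for a batch of samples."""
    return model.predict_proba(samples)
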