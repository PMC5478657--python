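"""Omnivariate decision tree induction, routing and the three add-ons.

A tree is decoded from a genome (breadth-first node genes; see
:mod:`omniga.ga`): each non-pruned, non-stopped node fits its encoded local
model on the data reaching it, scores those samples, and routes them to its
two children by the threshold rule below.  Nodes are indexed breadth-first
with the root at 1, so node ``i`` has children ``2i`` and ``2i + 1`` and a
depth-5 tree holds at most 31 nodes.

Routing (the data-splitting rule) is applied verbatim as specified for the
dominant class of each sample's score pair:

* class-1 dominant (``P1 >= P2``): branch 1 iff ``P1 >= threshold``;
* class-2 dominant: branch 2 iff ``P2 <= threshold``, else branch 1.

Note the second clause routes *high-confidence* class-2 samples (``P2`` above
the threshold) to branch 1; ``symmetric_routing=True`` selects the symmetric
variant (branch 2 iff ``P2 >= threshold``) instead.

Add-ons: SMOTE (local minority oversampling before a node model is fitted,
synthetic rows never inherited by children), ES (genome-encoded early
stopping of node-model training) and DL (each child receives the parent's
per-sample prediction score and split threshold as two extra features,
cumulatively along the path, so a depth-k node sees ``d + 2(k-1)`` columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .base_models import FittedNodeModel, fit_node_model
from .data import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "AddOnConfig",
    "StoppingConfig",
    "ODTNode",
    "ODTree",
    "route_sample",
    "route_batch",
    "smote_percentage",
    "smote_triggered",
    "apply_smote",
    "check_stopping",
    "induce_odt",
    "predict_odt",
]


@dataclass(frozen=True)
class AddOnConfig:
    """The three induction add-ons; 2^3 = 8 distinct configurations."""

    smote: bool = False
    es: bool = False
    dl: bool = False

    @staticmethod
    def all_configs() -> list["AddOnConfig"]:
        return [AddOnConfig(s, e, d) for s, e, d in product([False, True], repeat=3)]

    def label(self) -> str:
        return f"smote={int(self.smote)},es={int(self.es)},dl={int(self.dl)}"


@dataclass(frozen=True)
class StoppingConfig:
    """Stopping criteria for tree expansion (root at depth 1).

    A node becomes a leaf when the maximum depth is reached, the node is pure
    or nearly so (minority:majority ratio at most ``impurity_ratio``), or it
    holds fewer than the minimum number of instances: ``min_instances_absolute``
    for training sets larger than ``min_instances_threshold_n`` samples, else
    ``ceil(min_instances_fraction * n_train)``.
    """

    max_depth: int = 5
    impurity_ratio: float = 1.0 / 500.0
    min_instances_threshold_n: int = 2000
    min_instances_absolute: int = 100
    min_instances_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 < self.impurity_ratio < 1.0:
            raise ValueError("impurity_ratio must be in (0, 1)")

    def min_instances(self, n_train_total: int) -> int:
        if n_train_total > self.min_instances_threshold_n:
            return self.min_instances_absolute
        return int(np.ceil(self.min_instances_fraction * n_train_total))

    @property
    def max_nodes(self) -> int:
        return 2 ** self.max_depth - 1


THRESHOLD_RANGE = (-0.65, 0.65)


def route_sample(
    score_c1: float, score_c2: float, threshold: float, symmetric: bool = False
) -> int:
    """Route one score pair; returns 1 (class-1 branch) or 2."""
    if score_c1 >= score_c2:
        return 1 if score_c1 >= threshold else 2
    if symmetric:
        return 2 if score_c2 >= threshold else 1
    return 2 if score_c2 <= threshold else 1


def route_batch(proba: np.ndarray, threshold: float, symmetric: bool = False) -> np.ndarray:
    """Vectorized routing; True means branch 1."""
    s1, s2 = proba[:, 0], proba[:, 1]
    dom1 = s1 >= s2
    if symmetric:
        b1_given_dom2 = s2 < threshold
    else:
        b1_given_dom2 = s2 > threshold
    return np.where(dom1, s1 >= threshold, b1_given_dom2)


def smote_triggered(minority: int, majority: int) -> bool:
    """Oversampling fires only when the imbalance *exceeds* 1:5."""
    if minority < 1:
        raise ValueError("minority count must be >= 1")
    return majority / minority > 5.0


def smote_percentage(minority: int, majority: int) -> float:
    """Minority percentage increase: (majority/minority - 1) * 50.

    Adding ``round(minority * pct / 100)`` synthetic samples brings the
    minority to ``round((minority + majority) / 2)``.
    """
    if minority < 1:
        raise ValueError("minority count must be >= 1")
    return (majority / minority - 1.0) * 50.0


def apply_smote(
    node_data, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow the minority class by nearest-neighbor interpolation.

    ``node_data`` is a Dataset or an ``(X, y)`` pair.  Returns
    ``(X_aug, y_aug, synthetic_mask)``; synthetic rows are appended after the
    originals and flagged so children never inherit them.
    """
    if isinstance(node_data, Dataset):
        X, y = node_data.X, node_data.y.astype(int)
    else:
        X, y = node_data
        X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    min_cls = int(np.argmin(counts))
    minority, majority = int(counts[min_cls]), int(counts[1 - min_cls])
    if not smote_triggered(minority, majority):
        raise ValueError("SMOTE trigger condition (ratio > 1:5) does not hold")
    # minority * pct / 100 == (majority - minority) / 2 exactly; integer
    # half-up rounding keeps the identity new_minority = round((min+maj)/2)
    n_new = (majority - minority + 1) // 2
    rng = np.random.default_rng(seed)
    Xmin = X[y == min_cls]
    k = min(k_neighbors, minority - 1)
    if k < k_neighbors:
        logger.info("SMOTE: reducing k from %d to %d (minority=%d)",
                    k_neighbors, k, minority)
    if k >= 1:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
        _, nbrs = nn.kneighbors(Xmin)
        base = rng.integers(0, minority, size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)  # skip self at column 0
        gaps = rng.random(size=(n_new, 1))
        anchors = Xmin[base]
        partners = Xmin[nbrs[base, pick]]
        X_new = anchors + gaps * (partners - anchors)
    else:  # a single minority sample: duplicate it
        X_new = np.repeat(Xmin, n_new, axis=0)
    X_aug = np.vstack([X, X_new])
    y_aug = np.concatenate([y, np.full(n_new, min_cls, dtype=int)])
    mask = np.zeros(len(y_aug), dtype=bool)
    mask[len(y):] = True
    return X_aug, y_aug, mask


def check_stopping(
    y_node: np.ndarray, depth: int, stopping: StoppingConfig, n_train_total: int
) -> bool:
    """True when the node must become a leaf."""
    y_node = np.asarray(y_node, dtype=int)
    if len(y_node) == 0:
        raise ValueError("empty node")
    if depth >= stopping.max_depth:
        return True
    counts = np.bincount(y_node, minlength=2)
    lo, hi = counts.min(), counts.max()
    if lo == 0:  # pure node
        return True
    if lo / hi <= stopping.impurity_ratio:
        return True
    if len(y_node) < stopping.min_instances(n_train_total):
        return True
    return False


@dataclass
class ODTNode:
    """One tree position: an internal (model, threshold) or a leaf."""

    index: int
    depth: int
    role: str  # "internal" | "leaf"
    n_samples: int
    model: FittedNodeModel | None = None
    threshold: float = 0.0
    leaf_distribution: np.ndarray | None = None


@dataclass
class ODTree:
    """A fitted omnivariate tree, nodes indexed breadth-first from 1."""

    nodes: dict[int, ODTNode]
    addons: AddOnConfig
    stopping: StoppingConfig
    base_d: int
    symmetric_routing: bool = False
    dl_cumulative: bool = True
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    def to_text(self) -> str:
        lines = []
        for i in sorted(self.nodes):
            n = self.nodes[i]
            pad = "  " * (n.depth - 1)
            if n.role == "leaf":
                dist = np.round(n.leaf_distribution, 3)
                lines.append(f"{pad}[{i}] leaf n={n.n_samples} p={dist.tolist()}")
            else:
                lines.append(
                    f"{pad}[{i}] {n.model.spec.model_kind} "
                    f"thr={n.threshold:+.3f} n={n.n_samples}"
                )
        return "\n".join(lines)


def _laplace(y_node: np.ndarray) -> np.ndarray:
    counts = np.bincount(np.asarray(y_node, dtype=int), minlength=2)
    return (counts + 1.0) / (counts.sum() + 2.0)


def _node_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))


def induce_odt(
    genome,
    train: Dataset,
    addons: AddOnConfig = AddOnConfig(),
    stopping: StoppingConfig = StoppingConfig(),
    seed: int = 0,
    symmetric_routing: bool = False,
    smote_k: int = 5,
    dl_cumulative: bool = True,
) -> ODTree:
    """Decode a genome into a fitted tree on the training partition.

    ``genome`` must provide ``node_spec(index, es_active)`` returning
    ``(pruned, threshold, NodeModelSpec)``; see :class:`omniga.ga.Genome`.
    With ``dl_cumulative=False`` the DL add-on forwards only the immediate
    parent's two columns instead of accumulating them along the path.
    """
    n_total = train.n
    if n_total == 0:
        raise ValueError("empty training data")
    nodes: dict[int, ODTNode] = {}
    # queue entries: (index, depth, sample_idx, feature_matrix, parent_dist)
    queue: list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray | None]] = [
        (1, 1, np.arange(n_total), train.X, None)
    ]
    while queue:
        index, depth, idx, Xmat, parent_dist = queue.pop(0)
        if len(idx) == 0:
            nodes[index] = ODTNode(index, depth, "leaf", 0,
                                   leaf_distribution=parent_dist.copy())
            continue
        y_node = train.y[idx].astype(int)
        pruned, threshold, spec = genome.node_spec(index, es_active=addons.es)
        if pruned or check_stopping(y_node, depth, stopping, n_total):
            nodes[index] = ODTNode(index, depth, "leaf", len(idx),
                                   leaf_distribution=_laplace(y_node))
            continue

        node_seed = _node_seed(seed, index)
        X_fit, y_fit = Xmat, y_node
        counts = np.bincount(y_node, minlength=2)
        if addons.smote and smote_triggered(int(counts.min()), int(counts.max())):
            X_fit, y_fit, _ = apply_smote((Xmat, y_node), k_neighbors=smote_k,
                                          seed=node_seed)
        try:
            model = fit_node_model(spec, (X_fit, y_fit), seed=node_seed)
        except Exception as exc:
            logger.warning("node %d model fit failed (%s); making leaf", index, exc)
            nodes[index] = ODTNode(index, depth, "leaf", len(idx),
                                   leaf_distribution=_laplace(y_node))
            continue
        proba = model.predict_proba(Xmat)
        to_b1 = route_batch(proba, threshold, symmetric=symmetric_routing)
        nodes[index] = ODTNode(index, depth, "internal", len(idx),
                               model=model, threshold=threshold)
        my_dist = _laplace(y_node)
        for child, mask in ((2 * index, to_b1), (2 * index + 1, ~to_b1)):
            child_idx = idx[mask]
            child_X = Xmat[mask] if dl_cumulative else Xmat[mask, :train.d]
            if addons.dl:
                extra = np.column_stack([
                    proba[mask, 0], np.full(mask.sum(), threshold)
                ])
                child_X = np.hstack([child_X, extra])
            queue.append((child, depth + 1, child_idx, child_X, my_dist))
    return ODTree(nodes=nodes, addons=addons, stopping=stopping,
                  base_d=train.d, symmetric_routing=symmetric_routing,
                  dl_cumulative=dl_cumulative,
                  classes_=train.classes_ if train.classes_ is not None
                  else np.array([0, 1]))


def _traverse(tree: ODTree, X: np.ndarray):
    """Route samples to leaves; returns (proba, last_internal_threshold)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != tree.base_d:
        raise ValueError(f"expected {tree.base_d} features, got {X.shape[1]}")
    n = len(X)
    proba = np.zeros((n, 2))
    last_thr = np.zeros(n)
    stack = [(1, np.arange(n), X, np.zeros(n))]
    while stack:
        index, idx, Xmat, thr_so_far = stack.pop()
        if len(idx) == 0:
            continue
        node = tree.nodes[index]
        if node.role == "leaf":
            proba[idx] = node.leaf_distribution
            last_thr[idx] = thr_so_far
            continue
        p = node.model.predict_proba(Xmat)
        to_b1 = route_batch(p, node.threshold, symmetric=tree.symmetric_routing)
        for child, mask in ((2 * index, to_b1), (2 * index + 1, ~to_b1)):
            child_X = Xmat[mask] if tree.dl_cumulative else Xmat[mask, :tree.base_d]
            if tree.addons.dl:
                extra = np.column_stack([
                    p[mask, 0], np.full(int(mask.sum()), node.threshold)
                ])
                child_X = np.hstack([child_X, extra])
            stack.append((child, idx[mask], child_X,
                          np.full(int(mask.sum()), node.threshold)))
    return proba, last_thr


def predict_odt(tree: ODTree, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class-probability pairs for a batch of samples.

    The label is the argmax of the leaf distribution; ties go to class 1
    (code 0).  DL feature columns are computed on the fly along each
    sample's own root-to-leaf path.
    """
    proba, _ = _traverse(tree, samples)
    labels = np.argmax(proba, axis=1)  # argmax breaks ties toward class 1
    return labels, proba


def decision_trace(tree: ODTree, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels, probabilities and the threshold at the last internal node on
    each sample's path (0 for a single-leaf tree)."""
    proba, last_thr = _traverse(tree, samples)
    labels = np.argmax(proba, axis=1)
    return labels, proba, last_thr
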