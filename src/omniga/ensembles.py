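"""The three prediction schemes of an evolved model and their selection.

Scheme 1 predicts with the single tree of the fittest genome.  Scheme 2
builds ``population_size - 3`` candidate majority-voting ensembles of sizes
3 .. population_size - 1 — each the fittest tree plus randomly drawn distinct
others — and keeps the candidate that scores best on the validation set.
Scheme 3 stacks, for every tree in the population, three per-sample features
(signed score ``P(c1) - P(c2)``, the split threshold at the last internal
node on the sample's path, and the predicted label as ±1) into a
``3 × population_size``-wide vector and trains a random-forest meta-learner
on the validation set, with the tree count chosen by out-of-bag score.

The scheme kept for the final model is the one with the best validation
performance; ties go to the simpler (lower-numbered) scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .base_models import FittedNodeModel, NodeModelSpec, PARAM_GRIDS, fit_node_model
from .data import Dataset
from .metrics import compute_metrics
from .odt import ODTree, decision_trace, predict_odt

logger = logging.getLogger(__name__)

__all__ = [
    "VotingEnsemble",
    "StackerModel",
    "OmniGAModel",
    "predict_scheme1",
    "build_voting_ensemble",
    "predict_voting",
    "build_stacker_features",
    "fit_stacker",
    "predict_scheme3",
    "choose_scheme",
]


def _metric_score(metric: str, y_pred, y_true, positive_class: int) -> float:
    m = compute_metrics(y_pred, y_true, positive_class=positive_class)
    return float(getattr(m, metric))


def predict_scheme1(best_tree: ODTree, samples: np.ndarray):
    """Prediction of the fittest genome's single tree."""
    return predict_odt(best_tree, samples)


@dataclass
class VotingEnsemble:
    """A validation-selected majority-voting committee of trees.

    ``member_indices[0]`` is always the fittest genome's index; ties in the
    vote are broken by the fittest member's prediction.
    """

    member_indices: list[int]
    trees: list[ODTree]
    validation_score: float = 0.0

    @property
    def size(self) -> int:
        return len(self.member_indices)


def _vote(trees: list[ODTree], X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.stack([predict_odt(t, X)[0] for t in trees])
    probas = np.stack([predict_odt(t, X)[1] for t in trees])
    votes1 = (labels == 1).sum(axis=0)
    votes0 = (labels == 0).sum(axis=0)
    out = np.where(votes1 > votes0, 1, np.where(votes0 > votes1, 0, labels[0]))
    return out, probas.mean(axis=0)


def build_voting_ensemble(
    population_trees: list[ODTree | None],
    fittest_index: int,
    validation: Dataset,
    seed: int = 0,
    metric: str = "f1",
    positive_class: int = 1,
) -> VotingEnsemble:
    """Enumerate the ``m = population - 3`` candidates and keep the best.

    Candidate ``k`` (k = 0..m-1) has size ``3 + k``: the fittest tree plus
    ``2 + k`` distinct others drawn uniformly, seeded per candidate.  Each
    candidate is scored by majority vote on the validation set.
    """
    pop_size = len(population_trees)
    if pop_size < 4:
        raise ValueError("population must have at least 4 genomes")
    usable = [i for i, t in enumerate(population_trees) if t is not None]
    if fittest_index not in usable:
        raise ValueError("fittest genome has no fitted tree")
    others = [i for i in usable if i != fittest_index]
    m = pop_size - 3
    best: VotingEnsemble | None = None
    for k in range(m):
        n_extra = min(2 + k, len(others))
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, k)).generate_state(1)[0]
        )
        extra = list(rng.choice(others, size=n_extra, replace=False)) if n_extra else []
        members = [fittest_index] + [int(i) for i in extra]
        trees = [population_trees[i] for i in members]
        labels, _ = _vote(trees, validation.X)
        score = _metric_score(metric, labels, validation.y, positive_class)
        cand = VotingEnsemble(members, trees, score)
        if best is None or score > best.validation_score:
            best = cand
    return best


def predict_voting(ensemble: VotingEnsemble, samples: np.ndarray):
    """Majority-vote labels and the members' mean probability."""
    return _vote(ensemble.trees, samples)


def build_stacker_features(
    population_trees: list[ODTree], samples: np.ndarray
) -> np.ndarray:
    """Per-sample 3-features-per-tree stacked representation.

    For each tree, in population order: (a) signed score ``P(c1) - P(c2)`` in
    [-1, 1], positive meaning class 1; (b) the threshold at the internal node
    immediately preceding the sample's leaf (0 for a single-leaf tree);
    (c) the predicted label encoded +1 (class 1) / -1 (class 2).
    """
    cols = []
    for tree in population_trees:
        if tree is None:
            raise ValueError("every population tree must be fitted")
        labels, proba, last_thr = decision_trace(tree, samples)
        signed = proba[:, 0] - proba[:, 1]
        enc = np.where(labels == 0, 1.0, -1.0)
        cols.extend([signed, last_thr, enc])
    return np.column_stack(cols)


@dataclass
class StackerModel:
    """Random-forest meta-learner over stacked tree features."""

    model: FittedNodeModel
    n_trees: int
    population_size: int


def fit_stacker(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> StackerModel:
    """Fit the meta-learner; tree count picked from the grid by OOB score."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("stacker needs both classes in the validation labels")
    grid = PARAM_GRIDS["RF"]["n_trees"]
    best_nt, best_score = grid[0], -np.inf
    for nt in grid:
        rf = RandomForestClassifier(n_estimators=nt, oob_score=True,
                                    random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(features, labels)
        score = getattr(rf, "oob_score_", np.nan)
        if not np.isfinite(score):
            score = rf.score(features, labels)
        if score > best_score:
            best_nt, best_score = nt, score
    spec = NodeModelSpec("RF", {"n_trees": best_nt, "max_features": "sqrt"})
    model = fit_node_model(spec, (features, labels), seed=seed)
    return StackerModel(model, best_nt, population_size=features.shape[1] // 3)


def predict_scheme3(stacker: StackerModel, features: np.ndarray):
    """Labels and probabilities from the meta-learner."""
    proba = stacker.model.predict_proba(features)
    return np.argmax(proba, axis=1), proba


@dataclass
class OmniGAModel:
    """The final evolved model: best genome plus the chosen prediction scheme."""

    best_tree: ODTree
    population_trees: list[ODTree]
    scheme: int  # 1, 2 or 3
    voting: VotingEnsemble | None = None
    stacker: StackerModel | None = None
    validation_scores: dict = field(default_factory=dict)
    positive_class: int = 1
    metric: str = "f1"

    def predict(self, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.scheme == 1:
            return predict_scheme1(self.best_tree, samples)
        if self.scheme == 2:
            return predict_voting(self.voting, samples)
        feats = build_stacker_features(self.population_trees, samples)
        return predict_scheme3(self.stacker, feats)


def choose_scheme(
    best_tree: ODTree,
    population_trees: list[ODTree | None],
    fittest_index: int,
    validation: Dataset,
    seed: int = 0,
    metric: str = "f1",
    positive_class: int = 1,
) -> OmniGAModel:
    """Build all three schemes, score each on validation, keep the best.

    Ties are broken in scheme order (1 < 2 < 3: the simpler scheme wins).
    Scheme 3 requires every population tree; genomes whose induction failed
    disqualify scheme 3 (logged) rather than aborting the model.
    """
    scores: dict[int, float] = {}
    labels1, _ = predict_scheme1(best_tree, validation.X)
    scores[1] = _metric_score(metric, labels1, validation.y, positive_class)

    voting = build_voting_ensemble(
        population_trees, fittest_index, validation, seed=seed,
        metric=metric, positive_class=positive_class,
    )
    scores[2] = voting.validation_score

    stacker = None
    usable = [t for t in population_trees if t is not None]
    if len(usable) == len(population_trees):
        feats = build_stacker_features(population_trees, validation.X)
        try:
            stacker = fit_stacker(feats, validation.y, seed=seed)
            labels3, _ = predict_scheme3(stacker, feats)
            scores[3] = _metric_score(metric, labels3, validation.y,
                                      positive_class)
        except ValueError as exc:
            logger.warning("stacker disabled: %s", exc)
    else:
        logger.warning("stacker disabled: %d population trees missing",
                       len(population_trees) - len(usable))

    chosen = max(sorted(scores), key=lambda s: scores[s])
    return OmniGAModel(
        best_tree=best_tree,
        population_trees=[t for t in population_trees],
        scheme=chosen,
        voting=voting,
        stacker=stacker,
        validation_scores=scores,
        positive_class=positive_class,
        metric=metric,
    )
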