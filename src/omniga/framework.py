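"""Full framework orchestration: preprocessing, 8 add-on configurations × a
(p_c, p_m) grid of GA runs, validation-based final-model selection, and test
evaluation.

For every add-on combination (SMOTE/ES/DL on or off, 2^3 = 8) and every
crossover/mutation-probability grid point, one GA run evolves a population of
tree genomes and the three prediction schemes are built and compared on the
validation set.  The framework's final model is the run (and scheme) with the
best validation score; the untouched test partition is scored only once, at
the end.  Seeds are derived hierarchically (run seed → (add-on, grid point) →
generation → genome) so any single run is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    Dataset,
    Normalizer,
    SplitSpec,
    apply_normalizer,
    fit_minmax_normalizer,
    gain_ratio_select,
    make_splits,
)
from .ensembles import OmniGAModel, choose_scheme
from .ga import GAConfig, evolve
from .metrics import Metrics, compute_metrics, f1_error, relative_f1_error
from .odt import AddOnConfig, StoppingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Metrics",
    "compute_metrics",
    "f1_error",
    "relative_f1_error",
    "DEFAULT_PC_GRID",
    "DEFAULT_PM_GRID",
    "FEATURE_SELECT_THRESHOLD",
    "Preprocessing",
    "RunRecord",
    "FrameworkModel",
    "FrameworkResult",
    "preprocess",
    "run_framework",
    "evaluate_on_test",
    "run_framework_cv",
]

DEFAULT_PC_GRID = (0.6, 0.8, 0.95)
DEFAULT_PM_GRID = (0.01, 0.05, 0.10)
FEATURE_SELECT_THRESHOLD = 300


@dataclass
class Preprocessing:
    """Fitted preprocessing artifacts: normalizer and feature subset."""

    normalizer: Normalizer
    feature_indices: np.ndarray | None  # None when no selection was applied
    classes_: np.ndarray

    def transform(self, data: Dataset) -> Dataset:
        out = apply_normalizer(self.normalizer, data)
        if self.feature_indices is not None:
            out = replace(
                out,
                X=out.X[:, self.feature_indices],
                feature_names=[out.feature_names[j] for j in self.feature_indices],
            )
        return out


def preprocess(
    data: Dataset, splits: dict[str, np.ndarray], top_k: int = 300
) -> tuple[Dataset, Dataset, Dataset, Preprocessing]:
    """Normalize on train and (for wide data, d > 300) select top features.

    The normalizer and the gain-ratio ranking are fitted on the training
    partition only, then applied to validation and test.
    """
    raw_train = data.subset(splits["train"])
    normalizer = fit_minmax_normalizer(raw_train)
    sel = None
    train_n = apply_normalizer(normalizer, raw_train)
    if data.d > FEATURE_SELECT_THRESHOLD:
        sel = gain_ratio_select(train_n, k=top_k)
    prep = Preprocessing(normalizer, sel, data.classes_)
    train = prep.transform(data.subset(splits["train"]))
    validation = prep.transform(data.subset(splits["validation"]))
    test = prep.transform(data.subset(splits["test"]))
    return train, validation, test, prep


@dataclass
class RunRecord:
    """One framework run: an add-on configuration at one grid point."""

    addons: AddOnConfig
    p_c: float
    p_m: float
    seed: int
    validation_score: float = np.nan
    scheme: int | None = None
    generations_run: int = 0
    error: str | None = None
    fitness_history: list[dict] = field(default_factory=list)


@dataclass
class FrameworkModel:
    """The deployable artifact: preprocessing + the selected evolved model."""

    preprocessing: Preprocessing
    model: OmniGAModel
    addons: AddOnConfig
    ga_config: GAConfig
    positive_class: int

    def predict(self, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
        """Internal {0,1} labels and class probabilities for raw-feature data."""
        transformed = self.preprocessing.transform(data)
        return self.model.predict(transformed.X)

    def predict_decoded(self, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
        labels, proba = self.predict(data)
        return self.preprocessing.classes_[labels], proba


@dataclass
class FrameworkResult:
    runs: list[RunRecord]
    final_model: FrameworkModel
    splits: dict[str, np.ndarray]
    test_metrics: Metrics | None = None
    history: dict = field(default_factory=dict)

    @property
    def best_run(self) -> RunRecord:
        ok = [r for r in self.runs if r.error is None]
        return max(ok, key=lambda r: r.validation_score)


def _run_seed(seed: int, addon_idx: int, grid_idx: int) -> int:
    return int(
        np.random.SeedSequence((seed, addon_idx, grid_idx)).generate_state(1)[0]
        % (2**31)
    )


def run_framework(
    data: Dataset,
    split_spec: SplitSpec | None = None,
    pc_grid: tuple[float, ...] = DEFAULT_PC_GRID,
    pm_grid: tuple[float, ...] = DEFAULT_PM_GRID,
    seed: int = 0,
    addon_configs: list[AddOnConfig] | None = None,
    ga_base: GAConfig | None = None,
    stopping: StoppingConfig | None = None,
    symmetric_routing: bool = False,
    positive_class: int | None = None,
    top_k_features: int = 300,
) -> FrameworkResult:
    """Run the full model search and return the validation-selected model.

    ``addon_configs`` defaults to all 8 combinations; restricting it (or the
    grids) gives the reduced runs used for fast experiments.  The positive
    class for F1 defaults to the minority class of the training partition.
    A failed run is logged and excluded from the final argmax, never silently
    substituted.
    """
    split_spec = split_spec or SplitSpec(seed=seed)
    stopping = stopping or StoppingConfig()
    ga_base = ga_base or GAConfig()
    splits = make_splits(data, split_spec)
    train, validation, test, prep = preprocess(data, splits, top_k=top_k_features)
    runs, best = _search(
        train, validation, prep, pc_grid, pm_grid, seed, addon_configs,
        ga_base, stopping, symmetric_routing, positive_class,
    )
    result = FrameworkResult(runs=runs, final_model=best, splits=splits)
    result.test_metrics = evaluate_on_test(best, test)
    return result


def _search(
    train: Dataset,
    validation: Dataset,
    prep: Preprocessing,
    pc_grid,
    pm_grid,
    seed: int,
    addon_configs,
    ga_base: GAConfig,
    stopping: StoppingConfig,
    symmetric_routing: bool,
    positive_class: int | None,
) -> tuple[list[RunRecord], FrameworkModel]:
    """The add-on × grid search on fixed partitions; returns audit + best."""
    addon_configs = (addon_configs if addon_configs is not None
                     else AddOnConfig.all_configs())
    if positive_class is None:
        counts = train.class_counts()
        positive_class = int(np.argmin(counts))

    grid = [(pc, pm) for pc in pc_grid for pm in pm_grid]
    runs: list[RunRecord] = []
    best: tuple[float, FrameworkModel, RunRecord] | None = None
    for g_idx, (pc, pm) in enumerate(grid):
        for a_idx, addons in enumerate(addon_configs):
            r_seed = _run_seed(seed, a_idx, g_idx)
            cfg = replace(ga_base, crossover_probability=pc,
                          mutation_probability=pm, seed=r_seed)
            rec = RunRecord(addons=addons, p_c=pc, p_m=pm, seed=r_seed)
            try:
                ev = evolve(train, validation, cfg, addons=addons,
                            stopping=stopping,
                            symmetric_routing=symmetric_routing,
                            positive_class=positive_class)
                fittest_idx = int(np.argmax(ev.population_fitness))
                model = choose_scheme(
                    ev.best_tree, ev.population_trees, fittest_idx,
                    validation, seed=r_seed, metric=cfg.fitness_metric,
                    positive_class=positive_class,
                )
                rec.validation_score = model.validation_scores[model.scheme]
                rec.scheme = model.scheme
                rec.generations_run = len(ev.history)
                rec.fitness_history = ev.history
                fw_model = FrameworkModel(prep, model, addons, cfg,
                                          positive_class)
                if best is None or rec.validation_score > best[0]:
                    best = (rec.validation_score, fw_model, rec)
            except Exception as exc:
                logger.warning("run %s pc=%s pm=%s failed: %s",
                               addons.label(), pc, pm, exc)
                rec.error = str(exc)
            runs.append(rec)
    if best is None:
        raise RuntimeError("every framework run failed")
    return runs, best[1]


def evaluate_on_test(model: FrameworkModel, test: Dataset) -> Metrics:
    """Score the final model on the held-out (already preprocessed) test set."""
    labels, _ = model.model.predict(test.X)
    return compute_metrics(labels, test.y, positive_class=model.positive_class)


def run_framework_cv(
    data: Dataset,
    split_spec: SplitSpec,
    pc_grid: tuple[float, ...] = DEFAULT_PC_GRID,
    pm_grid: tuple[float, ...] = DEFAULT_PM_GRID,
    seed: int = 0,
    addon_configs: list[AddOnConfig] | None = None,
    ga_base: GAConfig | None = None,
    stopping: StoppingConfig | None = None,
    symmetric_routing: bool = False,
    positive_class: int | None = None,
    top_k_features: int = 300,
) -> tuple[list[Metrics], dict[str, float]]:
    """Cross-validation mode: the whole framework per fold; mean metrics.

    ``split_spec.cv_folds`` must be set.  Each fold gets its own
    preprocessing, model search, and test evaluation; returns the per-fold
    test metrics and their means.
    """
    if split_spec.cv_folds is None:
        raise ValueError("split_spec.cv_folds must be set for CV mode")
    folds = make_splits(data, split_spec)
    stopping = stopping or StoppingConfig()
    ga_base = ga_base or GAConfig()
    fold_metrics: list[Metrics] = []
    for f_idx, fold in enumerate(folds):
        train, validation, test, prep = preprocess(data, fold, top_k=top_k_features)
        _, best = _search(
            train, validation, prep, pc_grid, pm_grid, seed + f_idx,
            addon_configs, ga_base, stopping, symmetric_routing, positive_class,
        )
        fold_metrics.append(evaluate_on_test(best, test))
    keys = ("f1", "precision", "sensitivity", "specificity", "accuracy")
    means = {k: float(np.mean([getattr(m, k) for m in fold_metrics])) for k in keys}
    return fold_metrics, means
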