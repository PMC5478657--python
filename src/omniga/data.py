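"""Tabular dataset loading, normalization, gain-ratio feature ranking and splits.

The unit every stage of the pipeline consumes is a :class:`Dataset`: a dense
real-valued feature matrix, a binary label vector encoded as ``{0, 1}`` (class 1
and class 2 in the order of ``classes_``), and the feature names.  All
preprocessing artifacts (normalizer, feature subset) are fitted on the training
partition only and reapplied verbatim to validation and test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SplitSpec",
    "Normalizer",
    "read_table",
    "fit_minmax_normalizer",
    "apply_normalizer",
    "gain_ratio_scores",
    "gain_ratio_select",
    "make_splits",
]


@dataclass
class Dataset:
    """A binary-classification dataset.

    Parameters
    ----------
    X : ndarray of shape (n_samples, d)
        Feature matrix.  After normalization every value lies in ``[-1, 1]``.
    y : ndarray of shape (n_samples,)
        Integer labels in ``{0, 1}``; ``0`` is class 1, ``1`` is class 2.
    feature_names : list of str
        Column names, length ``d``.
    classes_ : ndarray of shape (2,)
        The original label values, in the order mapped to ``0`` and ``1``.
        Used to invert the mapping at prediction time.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    classes_: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("labels and features disagree on sample count")
        if self.classes_ is None:
            self.classes_ = np.array([0, 1])
        uniq = np.unique(self.y)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("labels must be encoded as {0, 1}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row subset preserving metadata."""
        return Dataset(self.X[idx], self.y[idx], list(self.feature_names), self.classes_)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y.astype(int), minlength=2)

    def decode_labels(self, y: np.ndarray) -> np.ndarray:
        """Map internal {0,1} labels back to the original label values."""
        return self.classes_[np.asarray(y, dtype=int)]


@dataclass
class SplitSpec:
    """Train / validation / test partitioning scheme.

    ``train_fraction`` of the data (default 2/3) forms the training pool and
    the rest is the test set; ``validation_fraction_of_train`` (default 0.15)
    of the training pool is reserved exclusively for validation.  In
    cross-validation mode (``cv_folds`` set) the train/test division is
    replaced by stratified folds, with validation carved from each fold's
    training side.
    """

    train_fraction: float = 2.0 / 3.0
    validation_fraction_of_train: float = 0.15
    cv_folds: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 < self.validation_fraction_of_train < 1.0:
            raise ValueError("validation_fraction_of_train must be in (0, 1)")
        if self.cv_folds is not None and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _dataset_from_frame(
    frame: pd.DataFrame, label_column: str, missing: str = "reject"
) -> Dataset:
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found")
    y_raw = frame[label_column]
    Xf = frame.drop(columns=[label_column])
    if Xf.shape[1] < 2:
        raise ValueError("need at least 2 features")

    n_missing = int(Xf.isna().any(axis=1).sum() + y_raw.isna().sum())
    if n_missing:
        if missing == "reject":
            logger.info("dropping %d rows with missing values", n_missing)
            keep = ~(Xf.isna().any(axis=1) | y_raw.isna())
            Xf, y_raw = Xf[keep], y_raw[keep]
        elif missing == "impute":
            logger.info("imputing %d rows with per-feature medians", n_missing)
            keep = ~y_raw.isna()
            Xf, y_raw = Xf[keep], y_raw[keep]
            Xf = Xf.fillna(Xf.median(numeric_only=True))
        else:
            raise ValueError(f"unknown missing-value policy {missing!r}")

    if len(Xf) == 0:
        raise ValueError("empty dataset")
    classes = np.array(sorted(pd.unique(y_raw)), dtype=object)
    if len(classes) > 2:
        raise ValueError(f"more than two classes in label column: {list(classes)}")
    if len(classes) < 2:
        raise ValueError("label column has fewer than two classes")
    y = np.searchsorted(classes, y_raw.to_numpy())
    try:
        X = Xf.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature values: {exc}") from exc
    return Dataset(X, y, [str(c) for c in Xf.columns], classes)


def read_table(
    path: str,
    fmt: str | None = None,
    label_column: str = "label",
    missing: str = "reject",
) -> Dataset:
    """Read a CSV/TSV/ARFF file into a :class:`Dataset`.

    ``fmt`` is inferred from the filename extension when omitted.  Labels are
    mapped to internal codes ``{0, 1}`` in sorted order of the original
    values; the mapping is recorded on the dataset for inverse transform.
    """
    if fmt is None:
        lower = str(path).lower()
        fmt = "arff" if lower.endswith(".arff") else (
            "tsv" if lower.endswith((".tsv", ".txt")) else "csv"
        )
    if fmt == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        frame = pd.DataFrame(data)
        # scipy returns nominal attributes as bytes
        for col in frame.columns:
            if frame[col].dtype == object:
                frame[col] = frame[col].map(
                    lambda v: v.decode() if isinstance(v, bytes) else v
                )
    elif fmt in ("csv", "tsv"):
        frame = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _dataset_from_frame(frame, label_column, missing=missing)


@dataclass
class Normalizer:
    """Per-feature affine map sending the training min/max to -1/+1.

    Out-of-range values seen at transform time are clipped to ``[-1, 1]``;
    constant training features map to 0.
    """

    min_: np.ndarray | None = None
    max_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.min_ is not None

    def fit(self, train: Dataset) -> "Normalizer":
        self.min_ = train.X.min(axis=0)
        self.max_ = train.X.max(axis=0)
        return self

    def transform(self, data: Dataset) -> Dataset:
        if not self.fitted:
            raise RuntimeError("normalizer has not been fitted")
        span = self.max_ - self.min_
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = 2.0 * (data.X - self.min_) / span - 1.0
        Z = np.where(span == 0, 0.0, Z)
        Z = np.clip(Z, -1.0, 1.0)
        return replace(data, X=Z)


def fit_minmax_normalizer(train: Dataset) -> Normalizer:
    """Fit the [-1, 1] min-max normalizer on the training partition."""
    return Normalizer().fit(train)


def apply_normalizer(normalizer: Normalizer, data: Dataset) -> Dataset:
    return normalizer.transform(data)


def _entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _discretize_equal_frequency(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning by training quantiles; returns integer bin ids."""
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, col, side="right")


def gain_ratio_scores(train: Dataset, n_bins: int = 10) -> np.ndarray:
    """Gain ratio (information gain / split information) of every feature.

    Numeric features are discretized into ``n_bins`` equal-frequency bins on
    the training partition before the entropies are computed.  A feature with
    zero split information scores 0.
    """
    y = train.y.astype(int)
    h_y = _entropy(np.bincount(y, minlength=2))
    scores = np.zeros(train.d)
    n = train.n
    for j in range(train.d):
        bins = _discretize_equal_frequency(train.X[:, j], n_bins)
        uniq, inv = np.unique(bins, return_inverse=True)
        cond = 0.0
        split_counts = np.zeros(len(uniq))
        for b in range(len(uniq)):
            mask = inv == b
            split_counts[b] = mask.sum()
            cond += (split_counts[b] / n) * _entropy(np.bincount(y[mask], minlength=2))
        split_info = _entropy(split_counts)
        ig = h_y - cond
        scores[j] = ig / split_info if split_info > 0 else 0.0
    return scores


def gain_ratio_select(train: Dataset, k: int = 300, n_bins: int = 10) -> np.ndarray:
    """Indices of the top-``k`` features by gain ratio, ties by column order.

    Ranking is computed on the training partition only.  Returns the selected
    column indices in ranked order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    scores = gain_ratio_scores(train, n_bins=n_bins)
    # stable sort on -score keeps original column order among ties
    order = np.argsort(-scores, kind="stable")
    return order[: min(k, train.d)]


def make_splits(
    data: Dataset, spec: SplitSpec
) -> dict[str, np.ndarray] | list[dict[str, np.ndarray]]:
    """Stratified train/validation/test index sets.

    Holdout mode returns ``{"train", "validation", "test"}`` index arrays with
    ``|train ∪ validation| = floor(train_fraction · n)`` and
    ``|validation| = floor(validation_fraction_of_train · |pool|)``.
    In cross-validation mode (``spec.cv_folds``) a list of such dicts is
    returned, one per stratified fold, with validation carved from each
    fold's training side.
    """
    n = data.n
    y = data.y
    if spec.cv_folds is not None:
        skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
        folds = []
        for train_pool, test_idx in skf.split(data.X, y):
            tr, val = _carve_validation(train_pool, y, spec)
            folds.append({"train": tr, "validation": val, "test": test_idx})
        return folds

    pool_size = int(np.floor(spec.train_fraction * n))
    test_size = n - pool_size
    if pool_size < 2 or test_size < 1:
        raise ValueError("dataset too small for the requested split")
    idx = np.arange(n)
    try:
        pool, test_idx = train_test_split(
            idx, test_size=test_size, stratify=y, random_state=spec.seed
        )
    except ValueError as exc:
        raise ValueError(f"cannot stratify split: {exc}") from exc
    train_idx, val_idx = _carve_validation(pool, y, spec)
    for name, part in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"class absent from {name} partition")
    return {"train": np.sort(train_idx), "validation": np.sort(val_idx), "test": np.sort(test_idx)}


def _carve_validation(
    pool: np.ndarray, y: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    val_size = int(np.floor(spec.validation_fraction_of_train * len(pool)))
    if val_size < 1 or len(pool) - val_size < 1:
        raise ValueError("pool too small to carve a validation set")
    train_idx, val_idx = train_test_split(
        pool, test_size=val_size, stratify=y[pool], random_state=spec.seed + 1
    )
    return train_idx, val_idx
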