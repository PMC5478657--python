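"""Synthetic fixture datasets with known structure.

Two generators cover the regimes the framework must handle:

* :func:`generate_rule_dataset` — features uniform in ``[-1, 1]^d`` labelled by
  a set of mutually exclusive, exhaustive conjunctive threshold rules (an
  axis-aligned partition of the feature space), optionally with label noise
  and a controlled class ratio.  This emulates rule-generated benchmark data
  (2,000 samples × 65 features, balanced, in the default "syn" preset).
* :func:`generate_imbalanced_gaussians` — two spherical Gaussian classes with
  a controlled majority:minority ratio, the fixture for oversampling logic.

Both are seed-deterministic; with ``noise_rate=0`` re-applying the returned
:class:`RuleSpec` to the features reproduces the labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset

__all__ = [
    "Rule",
    "RuleSpec",
    "generate_rule_dataset",
    "generate_imbalanced_gaussians",
    "make_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Rule:
    """One conjunctive rule: all clauses must hold for the rule to fire.

    A clause ``(j, op, cut)`` reads ``x[j] <= cut`` when ``op`` is ``"<="``
    and ``x[j] > cut`` when ``op`` is ``">"``.
    """

    clauses: tuple[tuple[int, str, float], ...]
    label: int

    def matches(self, x: np.ndarray) -> bool:
        for j, op, cut in self.clauses:
            if op == "<=":
                if not x[j] <= cut:
                    return False
            elif op == ">":
                if not x[j] > cut:
                    return False
            else:  # pragma: no cover - construction guarantees valid ops
                raise ValueError(f"bad comparator {op!r}")
        return True


@dataclass
class RuleSpec:
    """A mutually exclusive, exhaustive rule set over ``[-1, 1]^d``."""

    rules: list[Rule]
    d: int
    n_relevant: int
    noise_rate: float = 0.0

    @property
    def n_irrelevant(self) -> int:
        return self.d - self.n_relevant

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Noise-free labels for each row; exactly one rule fires per row."""
        X = np.asarray(X, dtype=float)
        labels = np.full(len(X), -1, dtype=int)
        for i, x in enumerate(X):
            for rule in self.rules:
                if rule.matches(x):
                    labels[i] = rule.label
                    break
        if np.any(labels < 0):  # pragma: no cover - rules are exhaustive
            raise RuntimeError("rule set is not exhaustive")
        return labels

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "n_relevant": self.n_relevant,
            "noise_rate": self.noise_rate,
            "rules": [
                {"label": r.label, "clauses": [list(c) for c in r.clauses]}
                for r in self.rules
            ],
        }


def _build_partition(
    n_rules: int, n_relevant: int, rng: np.random.Generator
) -> list[tuple[tuple[tuple[int, str, float], ...], float]]:
    """Recursively split boxes until n_rules leaves; returns (clauses, volume)."""
    # each box: (clauses, bounds) with bounds an (n_relevant, 2) array
    boxes: list[tuple[tuple, np.ndarray]] = [
        ((), np.tile([-1.0, 1.0], (n_relevant, 1)))
    ]
    while len(boxes) < n_rules:
        # split the largest-volume box to keep leaves of comparable mass
        vols = [float(np.prod(b[:, 1] - b[:, 0])) for _, b in boxes]
        i = int(np.argmax(vols))
        clauses, bounds = boxes.pop(i)
        widths = bounds[:, 1] - bounds[:, 0]
        j = int(rng.choice(np.flatnonzero(widths == widths.max())))
        lo, hi = bounds[j]
        cut = float(rng.uniform(lo + 0.3 * (hi - lo), hi - 0.3 * (hi - lo)))
        left = bounds.copy()
        left[j, 1] = cut
        right = bounds.copy()
        right[j, 0] = cut
        boxes.append((clauses + ((j, "<=", cut),), left))
        boxes.append((clauses + ((j, ">", cut),), right))
    out = []
    for clauses, bounds in boxes:
        vol = float(np.prod((bounds[:, 1] - bounds[:, 0]) / 2.0))
        out.append((clauses, vol))
    return out


def _assign_labels(
    leaves: list[tuple[tuple, float]], target_frac1: float
) -> list[Rule]:
    """Greedily label leaves so the class-0 probability mass ≈ target_frac1."""
    order = sorted(range(len(leaves)), key=lambda i: -leaves[i][1])
    mass = [0.0, 0.0]
    targets = [target_frac1, 1.0 - target_frac1]
    labels = [0] * len(leaves)
    for i in order:
        deficit = [targets[c] - mass[c] for c in (0, 1)]
        c = int(np.argmax(deficit))
        labels[i] = c
        mass[c] += leaves[i][1]
    if len({*labels}) < 2:  # both classes must be reachable
        labels[order[-1]] = 1 - labels[order[0]]
    return [Rule(clauses, labels[i]) for i, (clauses, _) in enumerate(leaves)]


def generate_rule_dataset(
    n: int,
    d: int,
    n_rules: int = 8,
    noise_rate: float = 0.0,
    class_ratio: float = 1.0,
    seed: int = 0,
    max_draw_factor: int = 400,
) -> tuple[Dataset, RuleSpec]:
    """Rule-labelled dataset with the requested class ratio.

    ``class_ratio`` is the class1:class2 count ratio (1.0 = balanced).  Labels
    are assigned by the rules, the requested per-class counts are met exactly
    by bounded rejection sampling, and finally each label is flipped
    independently with probability ``noise_rate``.

    Returns the dataset together with the generating :class:`RuleSpec`.
    """
    if min(n, d, n_rules) < 1:
        raise ValueError("n, d and n_rules must all be >= 1")
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must be in [0, 1)")
    if class_ratio <= 0:
        raise ValueError("class_ratio must be positive")
    rng = np.random.default_rng(seed)
    n_relevant = min(d, max(2, int(np.ceil(np.log2(max(n_rules, 2)))) + 1))
    leaves = _build_partition(n_rules, n_relevant, rng)
    frac1 = class_ratio / (1.0 + class_ratio)
    spec = RuleSpec(_assign_labels(leaves, frac1), d=d, n_relevant=n_relevant,
                    noise_rate=noise_rate)

    targets = {0: int(round(n * frac1))}
    targets[1] = n - targets[0]
    if min(targets.values()) < 1:
        raise ValueError("class_ratio leaves an empty class at this n")
    collected: dict[int, list[np.ndarray]] = {0: [], 1: []}
    drawn = 0
    batch = max(256, n)
    while (len(collected[0]) < targets[0] or len(collected[1]) < targets[1]):
        if drawn > max_draw_factor * n:
            raise RuntimeError(
                "class_ratio unsatisfiable under this rule set "
                f"(drew {drawn} samples)"
            )
        Xb = rng.uniform(-1.0, 1.0, size=(batch, d))
        yb = spec.apply(Xb)
        drawn += batch
        for c in (0, 1):
            need = targets[c] - len(collected[c])
            if need > 0:
                rows = Xb[yb == c][:need]
                collected[c].extend(rows)
    X = np.vstack([np.vstack(collected[0]), np.vstack(collected[1])])
    y = np.concatenate([np.zeros(targets[0], int), np.ones(targets[1], int)])
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    if noise_rate > 0:
        flips = rng.random(n) < noise_rate
        y = np.where(flips, 1 - y, y)
    names = [f"f{j + 1}" for j in range(d)]
    return Dataset(X, y, names), spec


def generate_imbalanced_gaussians(
    n: int, ratio: float, separation: float = 2.0, d: int = 10, seed: int = 0
) -> Dataset:
    """Two spherical Gaussians with majority:minority count ratio ``ratio``.

    The minority class (class 1, label code 0) sits at the origin and the
    majority class mean is ``separation`` away along the first axis.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1 (majority:minority)")
    if d < 1:
        raise ValueError("d must be >= 1")
    n_min = int(round(n / (1.0 + ratio)))
    n_maj = n - n_min
    if n_min < 2:
        raise ValueError("n too small for the requested ratio")
    rng = np.random.default_rng(seed)
    mu = np.zeros(d)
    mu_maj = mu.copy()
    mu_maj[0] = separation
    X = np.vstack([
        rng.normal(mu, 1.0, size=(n_min, d)),
        rng.normal(mu_maj, 1.0, size=(n_maj, d)),
    ])
    y = np.concatenate([np.zeros(n_min, int), np.ones(n_maj, int)])
    perm = rng.permutation(n)
    names = [f"g{j + 1}" for j in range(d)]
    return Dataset(X[perm], y[perm], names)


PRESETS = {
    # balanced rule data emulating the 2,000 × 65 synthetic benchmark
    "syn": dict(kind="rules", n=2000, d=65, n_rules=8, noise_rate=0.0, class_ratio=1.0),
    # small-n wide data (gene-expression scale)
    "smalln": dict(kind="rules", n=60, d=50, n_rules=4, noise_rate=0.0, class_ratio=1.0),
    # 1:10 imbalance, the oversampling trigger regime
    "imbalanced10": dict(kind="gaussians", n=1100, ratio=10.0, separation=2.0, d=10),
}


def make_preset(name: str, seed: int = 0):
    """Instantiate a named fixture preset.

    Returns ``(Dataset, RuleSpec | None)``.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = dict(PRESETS[name])
    kind = p.pop("kind")
    if kind == "rules":
        return generate_rule_dataset(seed=seed, **p)
    return generate_imbalanced_gaussians(seed=seed, **p), None
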