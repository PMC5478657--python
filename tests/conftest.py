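import numpy as np
import pytest

from omniga.data import Dataset, SplitSpec, make_splits
from omniga.synthetic import generate_rule_dataset


@pytest.fixture(scope="session")
def rule_data():
    """Noise-free rule-labelled dataset, moderate size, with its RuleSpec."""
    ds, spec = generate_rule_dataset(
        n=400, d=12, n_rules=4, noise_rate=0.0, class_ratio=1.0, seed=7
    )
    return ds, spec


@pytest.fixture(scope="session")
def rule_splits(rule_data):
    ds, _ = rule_data
    splits = make_splits(ds, SplitSpec(seed=7))
    return {k: ds.subset(v) for k, v in splits.items()}


@pytest.fixture(scope="session")
def noisy_data():
    """Labels from a smooth probability in one feature: impure everywhere."""
    rng = np.random.default_rng(42)
    n, d = 600, 8
    X = rng.uniform(-1, 1, size=(n, d))
    p = 0.5 + 0.4 * X[:, 0]
    y = (rng.random(n) < p).astype(int)
    return Dataset(X, y, [f"f{j}" for j in range(d)])


@pytest.fixture(scope="session")
def tiny_xy():
    """20-sample linearly separable 2-D problem."""
    rng = np.random.default_rng(3)
    X = np.vstack([
        rng.normal([-1, -1], 0.2, size=(10, 2)),
        rng.normal([1, 1], 0.2, size=(10, 2)),
    ])
    y = np.array([0] * 10 + [1] * 10)
    return X, y
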