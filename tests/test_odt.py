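"""Tree induction: routing, SMOTE, stopping, DL augmentation, prediction."""

import numpy as np
import pytest

from omniga.data import Dataset
from omniga.ga import GAConfig, init_population, random_genome
from omniga.metrics import compute_metrics
from omniga.odt import (
    AddOnConfig,
    StoppingConfig,
    apply_smote,
    check_stopping,
    induce_odt,
    predict_odt,
    route_batch,
    route_sample,
    smote_percentage,
    smote_triggered,
)


def _oracle_route(s1, s2, t):
    """Literal pseudocode, written independently as nested conditionals."""
    if s1 >= s2:
        if s1 >= t:
            return 1
        return 2
    if s2 <= t:
        return 2
    return 1


class TestRouting:
    @pytest.mark.parametrize("s1,s2,t,expected", [
        (0.9, 0.1, 0.5, 1),    # class-1 dominant, above threshold
        (0.55, 0.45, 0.6, 2),  # class-1 dominant, below threshold
        (0.3, 0.7, 0.8, 2),    # class-2 dominant, below threshold
        (0.3, 0.7, 0.5, 1),    # class-2 dominant, above: literal rule
    ])
    def test_printed_examples(self, s1, s2, t, expected):
        assert route_sample(s1, s2, t) == expected

    def test_truth_table_oracle_grid(self):
        """Exhaustive agreement on a 101 x 27 (score, threshold) grid."""
        scores = np.linspace(0.0, 1.0, 101)
        thresholds = np.linspace(-0.65, 0.65, 27)
        for t in thresholds:
            got = np.array([route_sample(s, 1 - s, t) for s in scores])
            want = np.array([_oracle_route(s, 1 - s, t) for s in scores])
            np.testing.assert_array_equal(got, want)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(0)
        s1 = rng.random(500)
        proba = np.column_stack([s1, 1 - s1])
        for t in (-0.3, 0.4, 0.55, 0.65):
            batch = route_batch(proba, t)
            scalar = np.array([route_sample(a, b, t) == 1 for a, b in proba])
            np.testing.assert_array_equal(batch, scalar)

    def test_symmetric_variant_splits_by_predicted_class(self):
        # at threshold 0.5 the symmetric rule routes by the argmax class
        assert route_sample(0.9, 0.1, 0.5, symmetric=True) == 1
        assert route_sample(0.1, 0.9, 0.5, symmetric=True) == 2


class TestSmote:
    def test_percentage_formula(self):
        assert smote_percentage(100, 900) == pytest.approx(400.0)
        assert smote_percentage(50, 50) == pytest.approx(0.0)

    def test_trigger_strictly_exceeds_one_to_five(self):
        assert not smote_triggered(100, 500)
        assert smote_triggered(100, 501)

    def test_minority_grows_to_half_total(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(100, 4))
        y = np.array([0] * 10 + [1] * 90)
        X_aug, y_aug, mask = apply_smote((X, y), seed=3)
        counts = np.bincount(y_aug)
        assert counts[0] == round((10 + 90) / 2) == 50
        assert mask.sum() == 40
        assert not mask[:100].any()

    def test_synthetic_rows_on_minority_segments(self):
        rng = np.random.default_rng(2)
        Xmin = rng.uniform(-1, 1, size=(8, 2))
        X = np.vstack([Xmin, rng.uniform(2, 3, size=(72, 2))])
        y = np.array([0] * 8 + [1] * 72)
        X_aug, y_aug, mask = apply_smote((X, y), seed=0)
        synth = X_aug[mask]
        # synthetic points lie within the minority bounding box
        assert np.all(synth >= Xmin.min(axis=0) - 1e-9)
        assert np.all(synth <= Xmin.max(axis=0) + 1e-9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, size=(70, 3))
        y = np.array([0] * 10 + [1] * 60)
        a = apply_smote((X, y), seed=11)[0]
        b = apply_smote((X, y), seed=11)[0]
        np.testing.assert_array_equal(a, b)

    def test_not_triggered_raises(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="trigger"):
            apply_smote((X, y))


class TestStopping:
    def test_max_depth_always_leaf(self):
        y = np.array([0, 1] * 100)
        assert check_stopping(y, depth=5, stopping=StoppingConfig(),
                              n_train_total=5000)

    def test_near_pure_ratio_rule(self):
        y = np.array([0] * 1000 + [1] * 2)
        assert check_stopping(y, 2, StoppingConfig(), 5000)
        y2 = np.array([0] * 1000 + [1] * 3)
        assert not check_stopping(y2, 2, StoppingConfig(), 5000)

    def test_min_instances_five_percent_rule(self):
        stop = StoppingConfig()
        assert stop.min_instances(1000) == 50
        y = np.array([0, 1] * 24 + [0])  # 49 samples
        assert check_stopping(y, 2, stop, 1000)
        y = np.array([0, 1] * 25)  # 50 samples, balanced
        assert not check_stopping(y, 2, stop, 1000)

    def test_large_dataset_absolute_rule(self):
        assert StoppingConfig().min_instances(2001) == 100
        assert StoppingConfig().min_instances(2000) == 100  # 5% of 2000

    def test_default_bounds(self):
        stop = StoppingConfig()
        assert stop.max_depth == 5 and stop.max_nodes == 31


def _all_internal_genome(kind="C45", threshold=0.6, seed=0):
    """Genome with every slot hosting the same model kind, no pruning."""
    from omniga.ga import GENOME_LENGTH, NodeGene, Genome

    kind_code = {"MLR": 0, "C45": 1, "ANN": 2, "RF": 3}[kind]
    genes = tuple(
        NodeGene(kind_code, threshold, (0, 0, 0, 0), (1, 1))
        for _ in range(GENOME_LENGTH)
    )
    return Genome(genes)


def _pruned_root_genome():
    from omniga.ga import GENOME_LENGTH, NodeGene, Genome

    genes = tuple(NodeGene(-1, 0.0, (0, 0, 0, 0)) for _ in range(GENOME_LENGTH))
    return Genome(genes)


class TestInduction:
    def test_pruned_root_gives_single_leaf_majority(self, rule_splits):
        train = rule_splits["train"]
        tree = induce_odt(_pruned_root_genome(), train)
        assert tree.n_nodes == 1
        labels, proba = predict_odt(tree, train.X)
        maj = int(np.argmax(train.class_counts()))
        assert np.all(labels == maj)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_depth_and_size_bounds(self, noisy_data):
        rng = np.random.default_rng(0)
        for _ in range(5):
            tree = induce_odt(random_genome(rng), noisy_data, seed=1)
            assert tree.depth <= 5
            assert tree.n_nodes <= 31

    def test_conservation_at_internal_nodes(self, noisy_data):
        tree = induce_odt(_all_internal_genome("MLR", 0.6), noisy_data, seed=2)
        for i, node in tree.nodes.items():
            if node.role == "internal":
                left = tree.nodes[2 * i]
                right = tree.nodes[2 * i + 1]
                assert left.n_samples + right.n_samples == node.n_samples

    def test_rule_recovery_training_f1(self, rule_data):
        """On noise-free rule data a C45-rooted tree fits the rules."""
        ds, _ = rule_data
        tree = induce_odt(_all_internal_genome("C45", 0.6), ds, seed=3,
                          symmetric_routing=True)
        labels, _ = predict_odt(tree, ds.X)
        f1 = compute_metrics(labels, ds.y, positive_class=0).f1
        assert f1 >= 0.95

    def test_dl_schema_depth_columns(self, noisy_data):
        addons = AddOnConfig(dl=True)
        tree = induce_odt(_all_internal_genome("C45", 0.6), noisy_data,
                          addons=addons, seed=4)
        for i, node in tree.nodes.items():
            if node.role == "internal":
                depth = node.depth
                assert node.model.n_features_ == noisy_data.d + 2 * (depth - 1)

    def test_dl_parent_only_mode_two_extra_columns(self, noisy_data):
        tree = induce_odt(_all_internal_genome("C45", 0.6), noisy_data,
                          addons=AddOnConfig(dl=True), seed=4,
                          dl_cumulative=False)
        assert any(n.depth >= 3 for n in tree.nodes.values()
                   if n.role == "internal")
        for node in tree.nodes.values():
            if node.role == "internal":
                expect = noisy_data.d + (2 if node.depth > 1 else 0)
                assert node.model.n_features_ == expect
        # prediction must mirror the same schema
        labels, _ = predict_odt(tree, noisy_data.X)
        assert labels.shape == (noisy_data.n,)

    def test_dl_off_schema_constant(self, noisy_data):
        tree = induce_odt(_all_internal_genome("C45", 0.6), noisy_data, seed=4)
        for node in tree.nodes.values():
            if node.role == "internal":
                assert node.model.n_features_ == noisy_data.d

    def test_smote_addon_augments_only_locally(self):
        rng = np.random.default_rng(8)
        n = 660
        X = rng.uniform(-1, 1, size=(n, 4))
        y = (rng.random(n) < 0.12).astype(int)  # ~1:8 imbalance
        ds = Dataset(X, y, list("abcd"))
        tree = induce_odt(_all_internal_genome("C45", 0.6), ds,
                          addons=AddOnConfig(smote=True), seed=5)
        # children of any internal node partition only the original samples
        for i, node in tree.nodes.items():
            if node.role == "internal":
                total = tree.nodes[2 * i].n_samples + tree.nodes[2 * i + 1].n_samples
                assert total == node.n_samples

    def test_es_addon_uses_effort_gene(self, noisy_data):
        # es gene bits (1,1) decode to full effort; (0,0) to 0.25
        from omniga.ga import NodeGene, Genome, GENOME_LENGTH

        genes = tuple(NodeGene(3, 0.6, (0, 0, 0, 0), (0, 0))
                      for _ in range(GENOME_LENGTH))
        tree = induce_odt(Genome(genes), noisy_data,
                          addons=AddOnConfig(es=True), seed=6)
        root = tree.nodes[1]
        assert root.role == "internal"
        assert root.model.spec.effort_fraction == 0.25

    def test_prediction_order_invariant(self, noisy_data, rule_data):
        ds, _ = rule_data
        tree = induce_odt(_all_internal_genome("C45", 0.6), ds, seed=7)
        labels, proba = predict_odt(tree, ds.X)
        perm = np.random.default_rng(0).permutation(ds.n)
        labels_p, proba_p = predict_odt(tree, ds.X[perm])
        np.testing.assert_array_equal(labels[perm], labels_p)
        np.testing.assert_allclose(proba[perm], proba_p)

    def test_single_leaf_tree_constant_prediction(self, rule_splits):
        train = rule_splits["train"]
        tree = induce_odt(_pruned_root_genome(), train)
        _, proba = predict_odt(tree, train.X[:7])
        assert np.allclose(proba, proba[0])

    def test_dimension_mismatch_rejected(self, rule_splits):
        tree = induce_odt(_pruned_root_genome(), rule_splits["train"])
        with pytest.raises(ValueError, match="features"):
            predict_odt(tree, np.zeros((2, 99)))

    def test_induction_seed_determinism(self, noisy_data):
        g = _all_internal_genome("RF", 0.6)
        t1 = induce_odt(g, noisy_data, seed=11)
        t2 = induce_odt(g, noisy_data, seed=11)
        l1, p1 = predict_odt(t1, noisy_data.X)
        l2, p2 = predict_odt(t2, noisy_data.X)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(p1, p2)
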