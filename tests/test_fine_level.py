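"""Fine-level protocol: half split, average accuracy, subset scoring, SFS."""


import numpy as np
import pytest

from tonguegeom import (
    ClassifierConfig,
    LabeledFeatureTable,
    average_accuracy,
    evaluate_subset,
    sfs,
    stratified_half_split,
)


def make_table(n_a, n_b, rng=None, informative=None, sep=10.0, n_features=13):
    """Two-class table; optionally one feature column carries the signal."""
    rng = rng or np.random.default_rng(0)
    n = n_a + n_b
    x = rng.normal(0.0, 0.1, size=(n, n_features))
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    if informative is not None:
        x[n_a:, informative - 1] += sep
    return LabeledFeatureTable(
        ids=[f"s{i}" for i in range(n)], features=x, labels=labels
    )


class TestStratifiedHalfSplit:
    def test_even_classes_split_in_half(self):
        table = make_table(4, 4)
        train, test = stratified_half_split(table, seed=0)
        assert len(train) == len(test) == 4
        for cls in ("A", "B"):
            assert (table.labels[train] == cls).sum() == 2

    def test_odd_class_uses_floor_for_training(self):
        table = make_table(19, 4)
        train, test = stratified_half_split(table, seed=1)
        assert (table.labels[train] == "A").sum() == 9
        assert (table.labels[test] == "A").sum() == 10

    def test_disjoint_covering_and_deterministic(self):
        table = make_table(10, 7)
        s1 = stratified_half_split(table, seed=5)
        s2 = stratified_half_split(table, seed=5)
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])
        merged = np.concatenate(s1)
        assert sorted(merged) == list(range(17))

    def test_tiny_class_rejected(self):
        table = make_table(5, 1)
        with pytest.raises(ValueError):
            stratified_half_split(table, seed=0)


class TestAverageAccuracy:
    def test_macro_average_of_per_class_recall(self):
        assert average_accuracy(["A", "A", "B", "B"], ["A", "B", "B", "B"]) == 0.75

    def test_perfect_and_total_failure(self):
        assert average_accuracy(["A", "B"], ["A", "B"]) == 1.0
        assert average_accuracy(["A", "B"], ["B", "A"]) == 0.0

    def test_plain_mode_counts_samples_not_classes(self):
        truth = ["A", "A", "A", "B"]
        pred = ["A", "A", "A", "A"]
        assert average_accuracy(truth, pred, average="plain") == 0.75
        assert average_accuracy(truth, pred) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_accuracy([], [])


class TestEvaluateSubset:
    def test_wide_margin_feature_scores_one(self):
        table = make_table(20, 20, informative=1)
        split = stratified_half_split(table, seed=0)
        assert evaluate_subset(table, [1], split) == 1.0

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(123)
        table = make_table(100, 100, rng=rng, informative=1)
        table.labels = rng.permutation(table.labels)
        split = stratified_half_split(table, seed=0)
        j = evaluate_subset(table, [1], split)
        assert 0.35 <= j <= 0.65

    def test_single_sample_test_classes_return_valid_fraction(self):
        table = make_table(2, 2, informative=1)
        split = stratified_half_split(table, seed=0)
        j = evaluate_subset(table, [1, 2], split)
        assert 0.0 <= j <= 1.0

    def test_constant_train_feature_uses_sd_fallback(self):
        table = make_table(10, 10, informative=1)
        table.features[:, 2] = 7.0  # constant column
        split = stratified_half_split(table, seed=0)
        j = evaluate_subset(table, [3], split)
        assert 0.0 <= j <= 1.0

    def test_empty_subset_rejected(self):
        table = make_table(4, 4)
        split = stratified_half_split(table, seed=0)
        with pytest.raises(ValueError):
            evaluate_subset(table, [], split)


class TestSFS:
    def test_single_informative_feature_is_picked_first(self):
        table = make_table(20, 20, informative=7)
        res = sfs(table, seed=0)
        assert res.order[0] == 7
        assert res.best_J == res.criterion_path[0] == 1.0
        assert res.best_subset == (7,)

    def test_identical_columns_fall_back_to_index_order(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=(20, 1))
        table = LabeledFeatureTable(
            ids=[f"s{i}" for i in range(20)],
            features=np.repeat(col, 13, axis=1),
            labels=np.array(["A"] * 10 + ["B"] * 10),
        )
        res = sfs(table, seed=0)
        assert res.order == tuple(range(1, 14))

    def test_path_contract(self):
        table = make_table(10, 10, rng=np.random.default_rng(9), informative=3, sep=0.3)
        res = sfs(table, seed=2)
        assert len(res.criterion_path) == 13
        assert sorted(res.order) == list(range(1, 14))
        assert res.best_J == max(res.criterion_path)
        k = len(res.best_subset)
        assert res.best_subset == res.order[:k]
        assert res.criterion_path[k - 1] == res.best_J
        # earliest prefix on ties
        assert all(j < res.best_J for j in res.criterion_path[: k - 1])

    def test_first_pick_matches_exhaustive_single_feature_search(self):
        rng = np.random.default_rng(7)
        table = make_table(15, 15, rng=rng, informative=2, sep=0.5, n_features=3)
        res = sfs(table, seed=1)
        split = stratified_half_split(table, seed=1)
        scores = [evaluate_subset(table, [i], split) for i in (1, 2, 3)]
        assert res.order[0] == int(np.argmax(scores)) + 1

    def test_reproducible(self):
        table = make_table(12, 12, rng=np.random.default_rng(4), informative=5, sep=0.4)
        assert sfs(table, seed=3) == sfs(table, seed=3)

    def test_requires_exactly_two_classes(self):
        table = make_table(6, 6)
        table.labels[:4] = "C"
        with pytest.raises(ValueError):
            sfs(table, seed=0)


def test_classifier_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(average="weird")
    with pytest.raises(ValueError):
        ClassifierConfig(C=0.0)
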