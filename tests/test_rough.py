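import itertools
import math

import numpy as np
import pytest

from phonodeform import (
    C45DecisionTreeClassifier,
    Cut,
    DecisionRule,
    DecisionSystem,
    Interval,
    LEM2Classifier,
    boundary_cuts,
    c45_tree,
    classify,
    lem2,
    load_laryngopathy_dataset,
    md_discretize,
    training_report,
    tree_to_rules,
)
from phonodeform.rough import InconsistentTableError

from conftest import random_consistent_table


def make_ds(values, labels, attrs=("a1",)):
    rows = [(v,) if np.isscalar(v) else tuple(v) for v in values]
    return DecisionSystem(
        tuple(f"c{i}" for i in range(len(rows))),
        tuple(attrs),
        tuple(rows),
        tuple(labels),
    )


class TestPackagedDataset:
    def test_counts_and_labels(self, dataset):
        assert len(dataset) == 30
        assert dataset.decisions.count("no") == 10
        assert dataset.decisions.count("yes") == 20
        assert dataset.attributes == ("a1", "a2")

    def test_known_cases(self, dataset):
        i = dataset.case_ids.index("w1_CG")
        assert dataset.values[i] == (0.0061, 0.0228)
        assert dataset.decisions[i] == "no"
        j = dataset.case_ids.index("w2_LP")
        assert dataset.values[j] == (0.3107, 0.2108)
        assert dataset.decisions[j] == "yes"

    def test_csv_round_trip(self, dataset, tmp_path):
        path = tmp_path / "ds.csv"
        dataset.to_dataframe().to_csv(path, index=False)
        import pandas as pd

        back = DecisionSystem.from_dataframe(pd.read_csv(path))
        assert back.case_ids == dataset.case_ids
        assert back.values == dataset.values
        assert back.decisions == dataset.decisions


class TestBoundaryCuts:
    def test_single_class_boundary(self):
        ds = make_ds([1, 2, 3], ["no", "no", "yes"])
        assert [c.threshold for c in boundary_cuts(ds, "a1")] == [2.5]

    def test_pure_table_has_no_cuts(self):
        ds = make_ds([1, 2, 3], ["no", "no", "no"])
        assert boundary_cuts(ds, "a1") == []

    def test_reference_data_contains_printed_a1_cut(self, dataset):
        thresholds = [c.threshold for c in boundary_cuts(dataset, "a1")]
        assert any(t == pytest.approx(0.0326) for t in thresholds)

    def test_unknown_attribute_rejected(self, dataset):
        with pytest.raises(KeyError):
            boundary_cuts(dataset, "a3")


class TestMdDiscretize:
    def test_reference_data_cut_sequence(self, dataset):
        cuts = md_discretize(dataset)
        assert [(c.attribute, c.threshold) for c in cuts] == [
            ("a1", 0.0326),
            ("a2", 0.0695),
        ]

    def test_single_attribute_forced_cut(self):
        ds = make_ds([1, 3], ["no", "yes"])
        assert md_discretize(ds) == [Cut("a1", 2.0)]

    def test_single_label_needs_no_cuts(self):
        ds = make_ds([1, 2], ["no", "no"])
        assert md_discretize(ds) == []

    def test_inconsistent_table_reported_with_ids(self):
        ds = make_ds([1, 1], ["no", "yes"])
        with pytest.raises(InconsistentTableError, match="c0"):
            md_discretize(ds)

    def test_discerns_all_pairs_on_random_tables(self):
        """Oracle check: on random consistent tables, the greedy cut set
        separates every differently-labeled pair, and exhaustive search over
        all boundary-cut subsets confirms such a cut set exists."""
        rng = np.random.default_rng(20)
        for _ in range(100):
            ds = random_consistent_table(rng, int(rng.integers(3, 9)))
            cuts = md_discretize(ds)

            def discerned(i, j, cut_list):
                return any(
                    min(ds.value(i, c.attribute), ds.value(j, c.attribute))
                    < c.threshold
                    < max(ds.value(i, c.attribute), ds.value(j, c.attribute))
                    for c in cut_list
                )

            pairs = [
                (i, j)
                for i, j in itertools.combinations(range(len(ds)), 2)
                if ds.decisions[i] != ds.decisions[j]
            ]
            assert all(discerned(i, j, cuts) for i, j in pairs)
            # oracle: the full boundary-cut set must also discern everything
            all_cuts = [
                c for a in ds.attributes for c in boundary_cuts(ds, a)
            ]
            assert all(discerned(i, j, all_cuts) for i, j in pairs)
            assert len(cuts) <= len(all_cuts)


class TestLem2:
    def test_reference_data_reproduces_printed_rules(self, dataset):
        rules = lem2(dataset, md_discretize(dataset), coverage_fraction=0.9)
        assert len(rules) == 2
        by_label = {r.decision: r for r in rules}
        yes_rule = by_label["yes"]
        assert yes_rule.conditions == (
            ("a1", Interval(lo=0.0326)),
        )
        no_rule = by_label["no"]
        assert no_rule.conditions == (
            ("a1", Interval(hi=0.0326)),
            ("a2", Interval(hi=0.0695)),
        )
        assert len(yes_rule.support) == 19
        assert len(no_rule.support) == 10

    def test_single_label_table_gives_unconditional_rule(self):
        ds = make_ds([1, 2], ["yes", "yes"])
        rules = lem2(ds, [], coverage_fraction=1.0)
        assert len(rules) == 1
        assert rules[0].conditions == ()
        assert classify(rules, {"a1": 99.0}) == "yes"

    def test_outlier_left_uncovered(self, dataset):
        rules = lem2(dataset, md_discretize(dataset), coverage_fraction=0.9)
        assert classify(rules, {"a1": 0.0258, "a2": 0.0853}) == "uncovered"

    def test_full_coverage_adds_rule_for_outlier(self, dataset):
        rules = lem2(dataset, md_discretize(dataset), coverage_fraction=1.0)
        assert classify(rules, {"a1": 0.0258, "a2": 0.0853}) == "yes"
        report = training_report(rules, dataset)
        assert report.uncovered_count == 0
        assert report.error_rate == 0.0

    def test_rules_consistent_on_training_set(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ds = random_consistent_table(rng, int(rng.integers(3, 9)))
            rules = lem2(ds, md_discretize(ds), coverage_fraction=1.0)
            for rule in rules:
                for i in range(len(ds)):
                    features = dict(zip(ds.attributes, ds.values[i]))
                    if rule.matches(features) and i in [
                        ds.case_ids.index(cid) for cid in rule.support
                    ]:
                        assert ds.decisions[i] == rule.decision


class TestC45Tree:
    def test_reference_data_reproduces_printed_tree(self, dataset):
        tree = c45_tree(dataset)
        assert tree.root.attribute == "a1"
        assert tree.root.threshold == 0.0301
        left = tree.root.left
        assert left.attribute == "a2"
        assert left.threshold == 0.0545
        assert tree.root.right.is_leaf and tree.root.right.label == "yes"
        assert left.left.label == "no" and left.right.label == "yes"

    def test_leaf_counts_sum_to_training_size(self, dataset):
        tree = c45_tree(dataset)
        counts = []

        def walk(node):
            if node.is_leaf:
                counts.append(node.n_cases)
            else:
                walk(node.left)
                walk(node.right)

        walk(tree.root)
        assert sum(counts) == 30

    def test_pure_input_gives_single_leaf(self):
        ds = make_ds([1, 2, 3], ["yes", "yes", "yes"])
        tree = c45_tree(ds)
        assert tree.root.is_leaf and tree.root.label == "yes"

    def test_root_split_matches_brute_force_gain(self):
        """Oracle check: the root's information gain equals the maximum over
        every midpoint of every attribute, found by exhaustive search."""
        rng = np.random.default_rng(31)

        def entropy(labels):
            _, counts = np.unique(labels, return_counts=True)
            p = counts / counts.sum()
            return float(-(p * np.log2(p)).sum())

        for _ in range(100):
            ds = random_consistent_table(rng, int(rng.integers(3, 11)))
            tree = c45_tree(ds, min_leaf=2)
            if tree.root.is_leaf:
                continue
            labels = np.array(ds.decisions)
            parent = entropy(labels)
            best_gain = -1.0
            for attribute in ds.attributes:
                values = np.array(
                    [ds.value(i, attribute) for i in range(len(ds))]
                )
                for t in (np.sort(values)[:-1] + np.sort(values)[1:]) / 2:
                    below = values <= t
                    gain = parent - (
                        below.sum() * entropy(labels[below])
                        + (~below).sum() * entropy(labels[~below])
                    ) / len(ds)
                    best_gain = max(best_gain, gain)
            values = np.array(
                [ds.value(i, tree.root.attribute) for i in range(len(ds))]
            )
            below = values <= tree.root.threshold
            achieved = parent - (
                below.sum() * entropy(labels[below])
                + (~below).sum() * entropy(labels[~below])
            ) / len(ds)
            assert achieved == pytest.approx(best_gain, abs=1e-12)

    def test_threshold_is_an_observed_value(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ds = random_consistent_table(rng, 8)
            tree = c45_tree(ds)
            if tree.root.is_leaf:
                continue
            observed = [
                ds.value(i, tree.root.attribute) for i in range(len(ds))
            ]
            assert tree.root.threshold in observed

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            c45_tree(
                DecisionSystem((), ("a1",), (), (), decision_domain=("no",))
            )


class TestTreeToRules:
    def test_reference_data_three_printed_rules(self, dataset):
        rules = tree_to_rules(c45_tree(dataset))
        printed = {str(r) for r in rules}
        assert printed == {
            "IF a1 in (-inf, 0.0301] AND a2 in (-inf, 0.0545], THEN d = no",
            "IF a1 in (-inf, 0.0301] AND a2 in (0.0545, inf), THEN d = yes",
            "IF a1 in (0.0301, inf), THEN d = yes",
        }

    def test_single_leaf_tree_gives_unconditional_rule(self):
        tree = c45_tree(make_ds([1, 2], ["no", "no"]))
        rules = tree_to_rules(tree)
        assert len(rules) == 1 and rules[0].conditions == ()

    def test_rule_count_equals_leaf_count(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            ds = random_consistent_table(rng, int(rng.integers(3, 10)))
            tree = c45_tree(ds)
            leaves = []

            def walk(node):
                if node.is_leaf:
                    leaves.append(node)
                else:
                    walk(node.left)
                    walk(node.right)

            walk(tree.root)
            assert len(tree_to_rules(tree)) == len(leaves)


class TestClassify:
    @pytest.fixture
    def reference_rules(self, dataset):
        return lem2(dataset, md_discretize(dataset), coverage_fraction=0.9)

    @pytest.mark.parametrize(
        "a1, a2, expected",
        [
            (0.05, 0.01, "yes"),
            (0.01, 0.01, "no"),
            (0.0258, 0.0853, "uncovered"),
        ],
    )
    def test_rule_application(self, reference_rules, a1, a2, expected):
        assert classify(reference_rules, {"a1": a1, "a2": a2}) == expected

    def test_tree_classification_is_total(self, dataset):
        tree = c45_tree(dataset)
        rng = np.random.default_rng(3)
        for _ in range(50):
            features = {"a1": rng.uniform(0, 0.5), "a2": rng.uniform(0, 0.5)}
            assert classify(tree, features) in ("no", "yes")

    def test_missing_attribute_rejected(self, reference_rules):
        with pytest.raises(KeyError):
            classify(reference_rules, {"a1": 0.5})


class TestTrainingReport:
    def test_lem2_report_on_reference_data(self, dataset):
        rules = lem2(dataset, md_discretize(dataset), coverage_fraction=0.9)
        report = training_report(rules, dataset)
        assert report.error_rate == 0.0
        assert report.uncovered_count == 1
        uncovered_ids = [
            cid
            for cid, p in zip(dataset.case_ids, report.predictions)
            if p == "uncovered"
        ]
        assert uncovered_ids == ["w4_LP"]

    def test_tree_report_on_reference_data(self, dataset):
        report = training_report(c45_tree(dataset), dataset)
        assert report.error_rate == 0.0
        assert report.uncovered_count == 0

    def test_empty_rule_list_warns_and_reports_zero(self, dataset):
        with pytest.warns(UserWarning):
            report = training_report([], dataset)
            assert report.uncovered_count == 30
            assert report.error_rate == 0.0


class TestDeterminism:
    def test_fixture_to_rules_bit_identical(self, dataset):
        runs = []
        for _ in range(2):
            cuts = md_discretize(dataset)
            rules = lem2(dataset, cuts)
            tree = c45_tree(dataset)
            runs.append(
                (
                    [(c.attribute, c.threshold) for c in cuts],
                    [str(r) for r in rules],
                    tree.to_json(),
                )
            )
        assert runs[0] == runs[1]


class TestEstimators:
    def test_lem2_classifier_fit_predict(self, dataset):
        X = np.array(dataset.values)
        y = np.array(dataset.decisions)
        model = LEM2Classifier(feature_names=("a1", "a2")).fit(X, y)
        assert [(c.attribute, c.threshold) for c in model.cuts_] == [
            ("a1", 0.0326),
            ("a2", 0.0695),
        ]
        preds = model.predict(X)
        covered = preds != "uncovered"
        assert (preds[covered] == y[covered]).all()
        assert (~covered).sum() == 1

    def test_tree_classifier_fit_predict_score(self, dataset):
        X = np.array(dataset.values)
        y = np.array(dataset.decisions)
        model = C45DecisionTreeClassifier(feature_names=("a1", "a2")).fit(X, y)
        assert model.score(X, y) == 1.0
        assert model.tree_.root.threshold == 0.0301

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = LEM2Classifier(coverage_fraction=0.8)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
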