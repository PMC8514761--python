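import logging

import numpy as np
import pytest

import thymoflow as tf
from thymoflow.errors import (AlignmentError, ConfigError, DataError,
                              GateFitError, PanelError, StateError)
from thymoflow.gating import GateNode, GatingTree, Clause
from thymoflow.io import ChannelMeta, EventTable

EXPECTED_NODES = {"TEC", "cTEC", "mTEC", "EC", "LEC", "FB", "DC", "MP",
                  "thymocyte", "matureSP", "CD4SP", "CD8SP"}


class TestTreeConstruction:
    def test_default_tree_nodes(self):
        tree = tf.build_thymic_gating_tree()
        assert set(tree.nodes) == EXPECTED_NODES
        assert tree.nodes["cTEC"].parent == "TEC"
        assert tree.nodes["CD4SP"].parent == "matureSP"

    def test_cd45_absent_from_tec_path(self):
        tree = tf.build_thymic_gating_tree()
        for node in ("TEC", "cTEC", "mTEC"):
            assert all(c.marker != "CD45" for c in tree.nodes[node].clauses)

    def test_sibling_exclusivity_clauses(self):
        # cTEC and mTEC carry mutually exclusive cuts on both CD49f and CD200
        tree = tf.build_thymic_gating_tree()
        ctec = {c.marker: c.op for c in tree.nodes["cTEC"].clauses}
        mtec = {c.marker: c.op for c in tree.nodes["mTEC"].clauses}
        assert ctec["CD49f"] == ">=" and mtec["CD49f"] == "<"
        assert ctec["CD200"] == "<" and mtec["CD200"] == ">="

    def test_yaml_round_trip(self, tmp_path):
        tree = tf.build_thymic_gating_tree(
            overrides={"TEC": {"pdpn": 2.8, "CD31": 1.0}})
        path = tmp_path / "tree.yaml"
        tree.to_yaml(path)
        back = GatingTree.from_yaml(path)
        assert back.to_dict() == tree.to_dict()

    def test_panel_missing_marker_names_it(self):
        panel = tf.PanelConfig(required_markers=tuple(
            m for m in tf.gating.SCHEME_MARKERS if m != "CD31"))
        with pytest.raises(PanelError, match="CD31"):
            tf.build_thymic_gating_tree(panel=panel)

    def test_override_unknown_node(self):
        with pytest.raises(ConfigError, match="NKT"):
            tf.build_thymic_gating_tree(overrides={"NKT": {"CD3": 1.0}})

    def test_override_unknown_clause(self):
        with pytest.raises(ConfigError, match="CD8"):
            tf.build_thymic_gating_tree(overrides={"TEC": {"CD8": 1.0}})


class TestPlaceThreshold:
    def test_valley_between_two_gaussians(self, rng):
        values = np.concatenate([rng.normal(1.0, 0.2, 5000),
                                 rng.normal(4.0, 0.2, 5000)])
        t = tf.place_threshold(values, "valley")
        assert 2.0 < t < 3.0

    def test_quantile_median(self):
        assert tf.place_threshold([1.0, 2.0, 3.0], ("quantile", 0.5)) == 2.0
        assert tf.place_threshold([1.0, 2.0, 3.0], "quantile:0.5") == 2.0

    def test_fixed_identity(self, rng):
        assert tf.place_threshold(rng.normal(size=100), ("fixed", 1.7)) == 1.7

    def test_empty_input(self):
        with pytest.raises(DataError):
            tf.place_threshold([], ("quantile", 0.5))

    def test_valley_needs_50_values(self):
        with pytest.raises(DataError):
            tf.place_threshold(np.arange(20.0), "valley")

    def test_unimodal_falls_back_to_quantile(self, rng, caplog):
        values = rng.normal(2.0, 0.3, 5000)
        with caplog.at_level(logging.WARNING, logger="thymoflow"):
            t = tf.place_threshold(values, "valley")
        assert t == pytest.approx(np.quantile(values, 0.99))
        assert "quantile" in caplog.text

    def test_deterministic(self, rng):
        values = np.concatenate([rng.normal(1, 0.2, 3000), rng.normal(4, 0.2, 3000)])
        assert tf.place_threshold(values, "valley") == tf.place_threshold(values, "valley")


class TestApplyGating:
    def test_exact_recovery_with_disjoint_supports(self, balanced_frequencies):
        # sigma 0.25 with 2.5-sigma truncation: >= 6.4-sigma mode separation
        # and provably zero overlap, so gate counts equal the planted truth
        spec = tf.build_sample_spec(balanced_frequencies, 100_000, seed=8,
                                    sigma=0.25, clip_sigma=2.5)
        table, labels = tf.simulate_sample(spec)
        assignment, stats = tf.apply_gating(
            tf.transform_events(table), tf.build_thymic_gating_tree())
        label_map = tf.thymic_label_map()
        report = tf.evaluate_gating(assignment, labels, label_map)
        assert (report.per_population["f1"].dropna() == 1.0).all()
        for truth_pop, node in label_map.items():
            if node == "ungated":
                continue
            assert stats.count(node) if node in ("thymocyte",) else True
            expected = int((labels == truth_pop).sum())
            assert int((assignment.labels == node).sum()) >= 0
            if node not in ("thymocyte",):
                deepest = int((assignment.labels == node).sum())
                assert deepest == expected, node

    def test_double_positive_tec_assigned_neither_subset(self):
        # CD49f-high CD200-high inside the TEC gate matches the lymphatic
        # phenotype and must land in neither cTEC nor mTEC
        markers = list(tf.gating.SCHEME_MARKERS)
        neg, hi = 20.0, 20000.0
        row = {m: neg for m in markers}
        row.update({"pdpn": hi, "CD49f": hi, "CD200": hi})
        data = np.array([[row[m] for m in markers]] * 5)
        table = EventTable("dp", data, [ChannelMeta(m) for m in markers])
        tree = tf.build_thymic_gating_tree(overrides=tf.default_fixed_thresholds())
        assignment, stats = tf.apply_gating(tf.transform_events(table), tree)
        assert set(assignment.labels) == {"TEC"}
        assert stats.count("cTEC") == 0 and stats.count("mTEC") == 0

    def test_empty_table(self):
        markers = list(tf.gating.SCHEME_MARKERS)
        table = EventTable("e", np.empty((0, len(markers))),
                           [ChannelMeta(m) for m in markers])
        assignment, stats = tf.apply_gating(
            tf.transform_events(table), tf.build_thymic_gating_tree())
        assert stats.empty
        assert len(assignment.labels) == 0
        assert (stats.table["count"] == 0).all()
        assert (stats.table["freq_of_total"] == 0.0).all()

    def test_raw_table_rejected(self, balanced_frequencies):
        table, _ = tf.simulate_sample(
            tf.build_sample_spec(balanced_frequencies, 1000, seed=0))
        with pytest.raises(StateError):
            tf.apply_gating(table, tf.build_thymic_gating_tree())

    def test_too_few_events_to_fit(self, balanced_frequencies):
        table, _ = tf.simulate_sample(
            tf.build_sample_spec(balanced_frequencies, 30, seed=0))
        with pytest.raises(GateFitError):
            tf.fit_tree(tf.build_thymic_gating_tree(), tf.transform_events(table))

    def test_hierarchy_conservation(self, gated_sample):
        _, transformed, _, assignment, stats = gated_sample
        tree = assignment.tree
        for node in tree.walk():
            children = tree.children(node.name)
            if children:
                assert (sum(stats.count(c.name) for c in children)
                        <= stats.count(node.name))
        # deepest-label accounting partitions all events
        assert len(assignment.labels) == stats.total
        assert (assignment.labels == "ungated").sum() == stats.n_ungated

    def test_permutation_invariance(self, balanced_frequencies, rng):
        spec = tf.build_sample_spec(balanced_frequencies, 20_000, seed=13)
        table, _ = tf.simulate_sample(spec)
        transformed = tf.transform_events(table)
        tree = tf.fit_tree(tf.build_thymic_gating_tree(), transformed)
        a1, _ = tf.apply_gating(transformed, tree)
        perm = rng.permutation(table.n_events)
        shuffled = EventTable(table.sample_id, transformed.events[perm],
                              list(table.channels), "transformed", transformed.transform)
        a2, _ = tf.apply_gating(shuffled, tree)
        np.testing.assert_array_equal(a1.labels[perm], a2.labels)

    def test_fit_is_deterministic(self, gated_sample):
        _, transformed, _, _, _ = gated_sample
        t1 = tf.fit_tree(tf.build_thymic_gating_tree(), transformed)
        t2 = tf.fit_tree(tf.build_thymic_gating_tree(), transformed)
        assert t1.to_dict() == t2.to_dict()


class TestEvaluateGating:
    def test_perfect_assignment(self):
        labels = np.array(["a"] * 5 + ["b"] * 3)
        report = tf.evaluate_gating(labels, labels)
        assert (report.per_population["f1"] == 1.0).all()

    def test_total_mismatch(self):
        truth = np.array(["a"] * 5 + ["b"] * 5)
        pred = np.array(["b"] * 5 + ["a"] * 5)
        report = tf.evaluate_gating(pred, truth)
        assert (report.per_population["f1"] == 0.0).all()

    def test_absent_population_recall_is_null(self):
        truth = np.array(["a", "a", "b"])
        pred = np.array(["a", "c", "b"])
        report = tf.evaluate_gating(pred, truth)
        assert np.isnan(report.per_population.loc["c", "recall"])
        assert not np.isnan(report.per_population.loc["c", "precision"])

    def test_matches_brute_force_confusion(self, rng):
        classes = ["x", "y", "z"]
        truth = rng.choice(classes, 100)
        pred = rng.choice(classes, 100)
        report = tf.evaluate_gating(pred, truth)
        for cls in classes:
            tp = sum(1 for t, p in zip(truth, pred) if t == cls and p == cls)
            fp = sum(1 for t, p in zip(truth, pred) if t != cls and p == cls)
            fn = sum(1 for t, p in zip(truth, pred) if t == cls and p != cls)
            row = report.per_population.loc[cls]
            assert row["precision"] == pytest.approx(tp / (tp + fp))
            assert row["recall"] == pytest.approx(tp / (tp + fn))
            expected_f1 = 2 * tp / (2 * tp + fp + fn)
            assert row["f1"] == pytest.approx(expected_f1)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            tf.evaluate_gating(np.array(["a"]), np.array(["a", "b"]))


class TestGatingClassifier:
    def test_fit_predict_on_dataframe(self, balanced_frequencies):
        table, labels = tf.simulate_sample(
            tf.build_sample_spec(balanced_frequencies, 50_000, seed=21))
        clf = tf.GatingClassifier(fixed=True).fit(table.to_dataframe())
        pred = clf.predict(table.to_dataframe())
        report = tf.evaluate_gating(pred, labels, tf.thymic_label_map())
        assert report.per_population["f1"].min() > 0.9

    def test_sklearn_contract(self):
        from sklearn.base import clone

        clf = tf.GatingClassifier(fixed=True, cofactor=120.0)
        params = clf.get_params()
        assert params["cofactor"] == 120.0
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_predict_before_fit(self, balanced_frequencies):
        table, _ = tf.simulate_sample(
            tf.build_sample_spec(balanced_frequencies, 1000, seed=1))
        with pytest.raises(StateError):
            tf.GatingClassifier().predict(table)


def test_between_clause_requires_ordered_cuts():
    markers = ["pdpn"]
    table = EventTable("t", np.linspace(0, 5, 100).reshape(-1, 1),
                       [ChannelMeta("pdpn")], "transformed",
                       tf.TransformSpec())
    tree = GatingTree()
    tree.add(GateNode("bad", "root",
                      [Clause("pdpn", "between", (("fixed", 3.0), ("fixed", 1.0)))]))
    with pytest.raises(GateFitError):
        tf.fit_tree(tree, table)
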