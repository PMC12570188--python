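"""Responsibility aggregation, cluster labeling, ECG-level screening."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from rhythmmap.gtm import LatentGrid
from rhythmmap.macrocluster import MacroclusterPartition
from rhythmmap.screening import (
    ClusterDiagnosisMap,
    Screener,
    aggregate_responsibilities,
    cluster_totals,
    evaluate,
    label_clusters,
)


def make_partition(labels):
    labels = np.asarray(labels)
    g = nx.complete_graph(labels.size)
    return MacroclusterPartition(labels=labels, M=int(labels.max()), graph=g)


class TestAggregate:
    def test_single_row_unchanged(self):
        row = np.array([0.2, 0.3, 0.5])
        assert np.array_equal(aggregate_responsibilities(row[None, :]), row)

    def test_two_one_hot_rows_average_to_half(self):
        R = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(aggregate_responsibilities(R), [0.5, 0.5])

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        R = rng.random((6, 10))
        R /= R.sum(axis=1, keepdims=True)
        expected = [sum(R[n, k] for n in range(6)) / 6 for k in range(10)]
        assert np.allclose(aggregate_responsibilities(R), expected)
        assert aggregate_responsibilities(R).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_snippets_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            aggregate_responsibilities(np.empty((0, 5)))


class TestClusterTotals:
    def test_single_cluster_total_is_one(self):
        part = make_partition([1, 1, 1, 1])
        dist = np.array([0.1, 0.2, 0.3, 0.4])
        assert cluster_totals(dist, part).tolist() == [pytest.approx(1.0)]

    def test_uniform_distribution_proportional_to_cluster_size(self):
        labels = np.array([1] * 32 + [2] * 32)
        part = make_partition(labels)
        dist = np.full(64, 1 / 64)
        assert np.allclose(cluster_totals(dist, part), [0.5, 0.5])

    def test_matches_accumulation_oracle(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 4, size=12)
        labels[:3] = [1, 2, 3]  # ensure every cluster occupied
        part = make_partition(labels)
        dist = rng.random(12)
        dist /= dist.sum()
        totals = cluster_totals(dist, part)
        for m in range(1, 4):
            assert totals[m - 1] == pytest.approx(
                sum(dist[k] for k in range(12) if labels[k] == m)
            )
        assert totals.sum() == pytest.approx(1.0, abs=1e-9)


class TestLabelClusters:
    def test_pure_af_cluster_labeled_af(self):
        part = make_partition([1, 1, 2, 2])
        R = np.eye(4)
        cmap = label_clusters(R, part, ["af", "af", "normal", "normal"])
        assert cmap[1] == "af" and cmap[2] == "normal"

    def test_5050_tie_breaks_toward_higher_risk(self):
        part = make_partition([1, 1])
        R = np.eye(2)
        cmap = label_clusters(R, part, ["af", "normal"])
        assert cmap[1] == "af"
        cmap2 = label_clusters(R, part, ["possible_af", "normal"])
        assert cmap2[1] == "possible_af"

    def test_three_class_fixture_matches_counting_oracle(self):
        rng = np.random.default_rng(2)
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        part = make_partition(labels)
        n = 60
        nodes = rng.integers(0, 9, size=n)
        R = np.zeros((n, 9))
        R[np.arange(n), nodes] = 1.0
        dx = rng.choice(["normal", "possible_af", "af"], size=n)
        cmap = label_clusters(R, part, dx)
        for m in (1, 2, 3):
            member = dx[labels[nodes] == m]
            counts = {d: np.sum(member == d) for d in ("normal", "possible_af", "af")}
            top = max(counts.values())
            candidates = [d for d, c in counts.items() if c == top]
            assert cmap[m] in candidates
            if len(candidates) == 1:
                assert cmap[m] == candidates[0]

    def test_empty_cluster_flagged_unassigned(self):
        part = make_partition([1, 1, 2])
        R = np.zeros((2, 3))
        R[:, 0] = 1.0  # everything lands on cluster 1 nodes
        with pytest.warns(UserWarning, match="no training snippets"):
            cmap = label_clusters(R, part, ["normal", "normal"])
        assert cmap[2] == "unassigned"

    def test_unknown_diagnosis_rejected(self):
        part = make_partition([1, 1])
        with pytest.raises(ValueError, match="unknown diagnosis"):
            label_clusters(np.eye(2), part, ["normal", "svt"])


class FakeResults:
    """Stand-in results object exposing only what Screener touches."""

    def __init__(self, K):
        self.K = K


class TestScreener:
    def _screener(self):
        part = make_partition([1, 1, 2, 2, 3, 3])
        cmap = ClusterDiagnosisMap(
            labels={1: "normal", 2: "possible_af", 3: "af"},
            composition=pd.DataFrame(),
        )
        return Screener(FakeResults(6), part, cmap)

    def test_distribution_inside_cluster_assigns_that_cluster(self):
        s = self._screener()
        R = np.array([[0.0, 0.0, 0.6, 0.4, 0.0, 0.0]])
        res = s.screen_responsibilities("e1", R)
        assert res.assigned_cluster == 2
        assert res.assigned_diagnosis == "possible_af"

    def test_probability_conservation(self):
        rng = np.random.default_rng(3)
        R = rng.random((9, 6))
        R /= R.sum(axis=1, keepdims=True)
        res = self._screener().screen_responsibilities("e2", R)
        assert res.node_distribution.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.cluster_totals.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shuffling_snippets_changes_trajectory_not_assignment(self):
        rng = np.random.default_rng(4)
        R = rng.random((7, 6))
        R /= R.sum(axis=1, keepdims=True)
        s = self._screener()
        a = s.screen_responsibilities("e", R)
        perm = rng.permutation(7)
        b = s.screen_responsibilities("e", R[perm])
        assert a.assigned_cluster == b.assigned_cluster
        assert a.assigned_diagnosis == b.assigned_diagnosis
        assert np.array_equal(b.trajectory, a.trajectory[perm])

    def test_assignment_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(5)
        s = self._screener()
        R = rng.random((5, 6))
        R /= R.sum(axis=1, keepdims=True)
        res = s.screen_responsibilities("e3", R)
        dist = R.mean(axis=0)
        totals = [dist[[0, 1]].sum(), dist[[2, 3]].sum(), dist[[4, 5]].sum()]
        assert res.assigned_cluster == int(np.argmax(totals)) + 1

    def test_no_snippets_flagged_unscreenable(self):
        res = self._screener().screen_responsibilities("empty", np.empty((0, 6)))
        assert res.unscreenable and res.assigned_diagnosis == "unscreenable"


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["normal", "af", "possible_af", "af"]
        mat, acc = evaluate(y, y)
        assert acc == 1.0
        assert np.trace(mat.to_numpy()) == 4
        assert mat.to_numpy().sum() == 4

    def test_single_mislabel(self):
        y = ["normal"] * 9 + ["af"]
        p = ["normal"] * 9 + ["possible_af"]
        mat, acc = evaluate(y, p)
        assert acc == pytest.approx(0.9)
        assert mat.loc["af", "possible_af"] == 1

    def test_matrix_matches_hand_tally(self):
        rng = np.random.default_rng(6)
        classes = ["normal", "possible_af", "af"]
        y = rng.choice(classes, 50).tolist()
        p = rng.choice(classes, 50).tolist()
        mat, acc = evaluate(y, p)
        for t in classes:
            for q in classes:
                assert mat.loc[t, q] == sum(
                    1 for a, b in zip(y, p) if a == t and b == q
                )
        assert acc == pytest.approx(sum(a == b for a, b in zip(y, p)) / 50)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            evaluate(["normal"], ["flutter"])
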