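"""Two-level top-down k-means on restoration profiles."""

import numpy as np
import pandas as pd
import pytest

from combsec import (
    RatioVector,
    TreatmentCode,
    annotate_with_need,
    canonical_partition,
    cluster_treatments,
)
from combsec.clustering import canonical_level2, level2_structure, partition_structure

LABELS7 = ["T1", "T2", "T3", "T12", "T13", "T23", "T123"]


def matrix(rows, labels=None, d=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or LABELS7[: rows.shape[0]]
    cols = [f"P{i + 1}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=labels, columns=cols)


class TestClusterTreatments:
    def test_far_outlier_isolated_at_level_one(self):
        """One treatment far from six near-identical ones forms its own
        level-1 cluster (the adverse-responder structure)."""
        rng = np.random.default_rng(0)
        rows = np.vstack([0.05 * rng.normal(size=(6, 4)), np.full((1, 4), -0.9)])
        q3 = matrix(rows, labels=["T1", "T2", "T3", "T12", "T13", "T123", "T23"])
        tree = cluster_treatments(q3, k1=2, seed=1)
        parts = partition_structure(tree)
        assert frozenset({"T23"}) in parts

    def test_identical_rows_share_the_common_centroid(self):
        q3 = matrix(np.tile([0.2, -0.4, 0.0], (7, 1)))
        tree = cluster_treatments(q3, k1=2, seed=0)
        for c in tree.clusters:
            np.testing.assert_allclose(c.centroid, [0.2, -0.4, 0.0])

    def test_planted_prototypes_recovered(self):
        """Four well-separated prototypes, two per planted level-1 group."""
        rng = np.random.default_rng(5)
        protos = {
            "T1": [0.8, 0.8, 0.8], "T2": [0.7, 0.9, 0.7],
            "T12": [-0.8, -0.8, -0.8], "T123": [-0.7, -0.9, -0.7],
        }
        rows = np.array([protos[l] for l in protos]) + 0.02 * rng.normal(size=(4, 3))
        tree = cluster_treatments(matrix(rows, labels=list(protos)), k1=2, k2=2, seed=2)
        parts = set(partition_structure(tree))
        assert parts == {frozenset({"T1", "T2"}), frozenset({"T12", "T123"})}

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        q3 = matrix(rng.uniform(-1, 1, size=(7, 5)))
        t1 = cluster_treatments(q3, seed=42)
        t2 = cluster_treatments(q3, seed=42)
        assert canonical_level2(t1) == canonical_level2(t2)
        for c1, c2 in zip(t1.clusters, t2.clusters):
            np.testing.assert_array_equal(c1.centroid, c2.centroid)

    def test_centroids_are_member_means(self):
        rng = np.random.default_rng(3)
        q3 = matrix(rng.uniform(-1, 1, size=(7, 4)))
        tree = cluster_treatments(q3, seed=0)
        for c in tree.clusters:
            np.testing.assert_allclose(
                c.centroid, q3.loc[list(c.members)].mean(axis=0), atol=1e-12
            )
            if c.subclusters:
                for s in c.subclusters:
                    np.testing.assert_allclose(
                        s.centroid, q3.loc[list(s.members)].mean(axis=0), atol=1e-12
                    )

    def test_small_clusters_not_split(self):
        rng = np.random.default_rng(1)
        rows = np.vstack([0.05 * rng.normal(size=(5, 3)), np.full((2, 3), 0.9)])
        tree = cluster_treatments(matrix(rows), k1=2, k2=2, seed=0)
        by_size = {len(c.members): c for c in tree.clusters}
        assert by_size[2].subclusters is None
        assert by_size[5].subclusters is not None

    def test_partition_covers_panel_disjointly(self):
        rng = np.random.default_rng(2)
        q3 = matrix(rng.uniform(-1, 1, size=(7, 4)))
        tree = cluster_treatments(q3, seed=0)
        members = [t for c in tree.clusters for t in c.members]
        assert sorted(members) == sorted(LABELS7)
        for c in tree.clusters:
            if c.subclusters:
                sub = [t for s in c.subclusters for t in s.members]
                assert sorted(sub) == sorted(c.members)

    def test_too_few_rows_rejected(self):
        q3 = matrix([[0.1, 0.2]], labels=["T1"])
        with pytest.raises(ValueError):
            cluster_treatments(q3, k1=2)

    def test_recovery_rate_across_seeds(self):
        """Two prototypes separated by >= 10x the noise SD are recovered in
        at least 99 of 100 seeded runs."""
        protos = np.array([[0.8, 0.8, 0.8, 0.8], [-0.8, -0.8, -0.8, -0.8]])
        assignment = [0, 0, 0, 1, 1, 1, 1]
        noise_sd = 0.05  # separation ~3.2, 10x noise SD
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = protos[assignment] + noise_sd * rng.normal(size=(7, 4))
            tree = cluster_treatments(matrix(rows), k1=2, seed=seed)
            parts = set(partition_structure(tree))
            want = {
                frozenset(np.array(LABELS7)[np.array(assignment) == g]) for g in (0, 1)
            }
            hits += parts == want
        assert hits >= 99


class TestCanonicalPartition:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        rows = np.vstack([np.full((1, 3), -0.9), 0.05 * rng.normal(size=(6, 3))])
        q3a = matrix(rows, labels=["T23", "T1", "T2", "T3", "T12", "T13", "T123"])
        q3b = q3a.iloc[::-1]
        la = canonical_partition(cluster_treatments(q3a, seed=1))
        lb = canonical_partition(cluster_treatments(q3b, seed=99))
        assert la == lb

    def test_different_partitions_different_labels(self):
        rng = np.random.default_rng(6)
        rows = rng.uniform(-1, 1, size=(7, 3))
        t1 = cluster_treatments(matrix(rows), k1=2, seed=0)
        t2 = cluster_treatments(matrix(rows), k1=3, seed=0)
        if partition_structure(t1) != partition_structure(t2):
            assert canonical_partition(t1) != canonical_partition(t2)

    def test_singleton_panel_single_cluster(self):
        q3 = matrix([[0.1, 0.2]], labels=["T1"])
        tree = cluster_treatments(q3, k1=1)
        assert canonical_partition(tree) == "{T1}"


class TestAnnotateWithNeed:
    def _need(self, values, proteins):
        return RatioVector("Q1", TreatmentCode(), 0, proteins, np.asarray(values, float))

    def test_aligned_series(self):
        rng = np.random.default_rng(8)
        q3 = matrix(rng.uniform(-1, 1, size=(7, 3)))
        tree = cluster_treatments(q3, seed=0)
        need = self._need([0.3, -0.2, 0.1], tree.proteins)
        table = annotate_with_need(tree, need)
        assert list(table.columns) == list(tree.proteins)
        assert table.index[0] == "need"
        n_series = 1 + sum(
            1 + (len(c.subclusters) if c.subclusters else 0) for c in tree.clusters
        )
        assert table.shape[0] == n_series

    def test_zero_need_line_is_zero(self):
        q3 = matrix(np.tile([0.2, 0.2], (7, 1)))
        tree = cluster_treatments(q3, seed=0)
        table = annotate_with_need(tree, self._need([0.0, 0.0], tree.proteins))
        np.testing.assert_array_equal(table.loc["need"], [0.0, 0.0])

    def test_protein_mismatch_rejected(self):
        q3 = matrix(np.tile([0.2, 0.2], (7, 1)))
        tree = cluster_treatments(q3, seed=0)
        with pytest.raises(ValueError, match="protein"):
            annotate_with_need(tree, self._need([0.0], ("X",)))
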