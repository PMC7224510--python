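"""Two-level top-down partitioning of restoration profiles.

Treatments' Q3 (restoration) vectors are clustered with k-means at a first
level; each first-level cluster that is large enough is split once more by
k-means.  This exposes prototypical restoration behaviors without collapsing
the multi-protein profiles to a scalar.  Distances are Euclidean on the raw
ratio vectors (all entries already share the [-1, 1] scale); k-means runs
multiple seeded restarts and keeps the best inertia, so results are
deterministic given the seed.  Clusters with fewer than three members are
not split (a 2-way split of <= 2 points is degenerate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .ratios import RatioVector

__all__ = [
    "SubCluster",
    "Cluster",
    "ClusterTree",
    "cluster_treatments",
    "canonical_partition",
    "canonical_level2",
    "partition_structure",
    "level2_structure",
    "annotate_with_need",
]


@dataclass(frozen=True)
class SubCluster:
    members: tuple[str, ...]
    centroid: np.ndarray


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    centroid: np.ndarray
    subclusters: tuple[SubCluster, ...] | None  # None = not split


@dataclass(frozen=True)
class ClusterTree:
    """Level-1 partition of the treatment panel plus optional level-2 splits."""

    proteins: tuple[str, ...]
    clusters: tuple[Cluster, ...]
    stimulation: int
    k1: int
    k2: int

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(t for c in self.clusters for t in c.members)


def _kmeans_split(
    X: np.ndarray, labels: Sequence[str], k: int, seed: int, n_init: int
) -> list[tuple[tuple[str, ...], np.ndarray]]:
    """Partition rows into <= k groups; returns (members, centroid=row mean)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        assign = km.fit_predict(X)
    groups: list[tuple[tuple[str, ...], np.ndarray]] = []
    for g in np.unique(assign):
        idx = np.where(assign == g)[0]
        members = tuple(sorted(labels[i] for i in idx))
        groups.append((members, X[idx].mean(axis=0)))
    # deterministic reporting order, independent of k-means label numbering
    groups.sort(key=lambda mc: mc[0])
    return groups


def cluster_treatments(
    q3_matrix: pd.DataFrame,
    k1: int = 2,
    k2: int = 2,
    seed: int = 0,
    n_init: int = 50,
    min_split_size: int = 3,
    stimulation: int = 0,
) -> ClusterTree:
    """Top-down two-level k-means on a treatments x proteins ratio matrix.

    Rows are Q3 vectors indexed by treatment label.  Level 1 partitions all
    rows into ``k1`` clusters; each level-1 cluster with at least
    ``max(k2, min_split_size)`` members is split into ``k2`` sub-clusters.
    Every centroid is the arithmetic mean of its members' rows.
    """
    labels = [str(i) for i in q3_matrix.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels in the ratio matrix")
    X = q3_matrix.to_numpy(dtype=float)
    if X.shape[0] < k1:
        raise ValueError(f"cannot form {k1} clusters from {X.shape[0]} treatments")

    rng = np.random.SeedSequence(seed)
    level_seeds = rng.generate_state(1 + X.shape[0]) % (2**31)

    clusters: list[Cluster] = []
    for i, (members, centroid) in enumerate(
        _kmeans_split(X, labels, k1, int(level_seeds[0]), n_init)
    ):
        subclusters = None
        if len(members) >= max(k2, min_split_size):
            idx = [labels.index(m) for m in members]
            subs = _kmeans_split(
                X[idx], members, k2, int(level_seeds[1 + i]), n_init
            )
            subclusters = tuple(SubCluster(m, c) for m, c in subs)
        clusters.append(Cluster(members, centroid, subclusters))
    return ClusterTree(
        proteins=tuple(str(c) for c in q3_matrix.columns),
        clusters=tuple(clusters),
        stimulation=stimulation,
        k1=k1,
        k2=k2,
    )


def partition_structure(tree: ClusterTree) -> tuple[frozenset, ...]:
    """Level-1 partition as an order-canonical tuple of member sets."""
    sets = [frozenset(c.members) for c in tree.clusters]
    return tuple(sorted(sets, key=lambda s: sorted(s)))


def level2_structure(
    tree: ClusterTree,
) -> tuple[tuple[frozenset, tuple[frozenset, ...] | None], ...]:
    """Per level-1 cluster: (members, sub-partition or None), canonically ordered."""
    items = []
    for c in sorted(tree.clusters, key=lambda c: c.members):
        subs = None
        if c.subclusters is not None:
            subs = tuple(
                sorted((frozenset(s.members) for s in c.subclusters), key=sorted)
            )
        items.append((frozenset(c.members), subs))
    return tuple(items)


def _fmt_set(s: frozenset) -> str:
    return "{" + ",".join(sorted(s)) + "}"


def canonical_partition(tree: ClusterTree) -> str:
    """Order-invariant label for the level-1 set-of-sets.

    Identical partitions produced by different runs (with arbitrary cluster
    numbering) collide on this label.
    """
    return "|".join(_fmt_set(s) for s in partition_structure(tree))


def canonical_level2(tree: ClusterTree) -> str:
    """Order-invariant label including per-cluster sub-partitions."""
    parts = []
    for members, subs in level2_structure(tree):
        if subs is None:
            parts.append(_fmt_set(members))
        else:
            parts.append("+".join(_fmt_set(s) for s in subs))
    return "|".join(parts)


def annotate_with_need(tree: ClusterTree, q1: RatioVector) -> pd.DataFrame:
    """Align (sub-)cluster centroids with the total therapeutic need (Q1).

    Rows: ``need`` (the Q1 vector an ideal treatment should bring to zero)
    followed by one row per level-1 centroid and per level-2 centroid, all
    over the same protein axis.
    """
    if tuple(q1.proteins) != tree.proteins:
        raise ValueError("protein panel mismatch between cluster tree and Q1 vector")
    rows: dict[str, np.ndarray] = {"need": q1.values}
    for i, c in enumerate(sorted(tree.clusters, key=lambda c: c.members), start=1):
        rows[f"C{i} {_fmt_set(frozenset(c.members))}"] = c.centroid
        if c.subclusters is not None:
            for j, s in enumerate(
                sorted(c.subclusters, key=lambda s: s.members), start=1
            ):
                rows[f"C{i}.{j} {_fmt_set(frozenset(s.members))}"] = s.centroid
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tree.proteins))
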