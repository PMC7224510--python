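"""Leave-one-out resampling over intra-plate replicates.

To tell biological effects from technical variability, the whole analysis
(GHSA scoring and two-level clustering) is re-run on ``N_v`` validation
datasets, each created by randomly leaving out one replicate per cell state
(blanks are not cell states and pass through untouched).  Every cell state
therefore needs at least two replicates.  The N_v GHSA indices per
combination are summarized by five numbers (min, 25th, 50th, 75th
percentiles, max; linear interpolation between order statistics), and the
stability of the clustering is summarized by the frequency of each unique
level-1 partition.  Centroids reported for the dominant partition are
recomputed on the full (non-left-out) data.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import (
    Cluster,
    ClusterTree,
    SubCluster,
    canonical_level2,
    canonical_partition,
    cluster_treatments,
    level2_structure,
    partition_structure,
)
from .combination_design import exhaustive_panel
from .errors import CombSecError, QCError
from .ghsa import GHSAResult, ghsa_panel
from .plate_io import TISSUE_BLANK, CellState, PlateTable, TreatmentCode
from .quality_control import collapse_replicates
from .ratios import restoration_matrix

__all__ = [
    "LeaveOneOutPlate",
    "ValidationRun",
    "GHSASummary",
    "generate_validation_datasets",
    "run_validation",
    "summarize_ghsa",
    "partition_frequencies",
    "dominant_centroids",
]

_MAX_EXHAUSTIVE = 100_000


@dataclass
class LeaveOneOutPlate:
    """One reduced plate: exactly one replicate removed per cell state."""

    run_id: int
    plate: PlateTable
    left_out: dict[CellState, str]  # state -> well_id removed
    kept_replicates: dict[CellState, tuple[int, ...]]


@dataclass
class ValidationRun:
    """Recomputed GHSA indices and cluster partition for one reduced plate."""

    run_id: int
    kept_replicates: dict[CellState, tuple[int, ...]]
    ghsa: list[GHSAResult]
    tree: ClusterTree
    partition_label: str
    level2_label: str


@dataclass(frozen=True)
class GHSASummary:
    """Five-number summary of a combination's N_v GHSA indices."""

    combination: TreatmentCode
    five_numbers: tuple[float, float, float, float, float]  # min,p25,p50,p75,max

    def __post_init__(self):
        fn = self.five_numbers
        if any(fn[i] > fn[i + 1] + 1e-12 for i in range(4)):
            raise ValueError(f"unordered five-number summary {fn}")
        if any(abs(v) > 1 + 1e-12 for v in fn):
            raise ValueError(f"five-number summary outside [-1, 1]: {fn}")


def _state_groups(plate: PlateTable) -> dict[CellState, list]:
    groups = plate.states(include_blanks=False)
    for state, ws in groups.items():
        if len(ws) < 2:
            raise QCError(
                f"cell state {state.label} has a single replicate; resampling "
                "validation requires at least two intra-plate replicates per "
                "cell state"
            )
    return groups


def _reduce(plate: PlateTable, drop: dict[CellState, int], run_id: int) -> LeaveOneOutPlate:
    groups = plate.states(include_blanks=False)
    drop_ids = {groups[s][i].well_id: s for s, i in drop.items()}
    wells = [w for w in plate.wells if w.well_id not in drop_ids]
    kept = {
        s: tuple(w.replicate for w in ws if w.well_id not in drop_ids)
        for s, ws in groups.items()
    }
    left_out = {s: groups[s][i].well_id for s, i in drop.items()}
    return LeaveOneOutPlate(run_id, plate.with_wells(wells), left_out, kept)


def generate_validation_datasets(
    plate: PlateTable,
    n_v: int,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[LeaveOneOutPlate]:
    """Create leave-one-out validation datasets from a QC-passed plate.

    By default draws ``n_v`` independent configurations uniformly (with
    replacement over the configuration space).  With ``exhaustive=True`` the
    full space of distinct configurations is enumerated instead and ``n_v``
    is ignored.
    """
    groups = _state_groups(plate)
    states = list(groups)
    sizes = [len(groups[s]) for s in states]

    if exhaustive:
        total = int(np.prod(sizes, dtype=np.float64))
        if total > _MAX_EXHAUSTIVE:
            raise CombSecError(
                f"{total} leave-one-out configurations exceed the enumeration "
                f"cap ({_MAX_EXHAUSTIVE}); use sampled mode"
            )
        combos = itertools.product(*(range(m) for m in sizes))
        return [
            _reduce(plate, dict(zip(states, c)), i + 1) for i, c in enumerate(combos)
        ]

    rng = np.random.default_rng(seed)
    out = []
    for run_id in range(1, n_v + 1):
        drop = {s: int(rng.integers(m)) for s, m in zip(states, sizes)}
        out.append(_reduce(plate, drop, run_id))
    return out


def run_validation(
    plate: PlateTable,
    stimulation: int = 0,
    n_v: int = 1000,
    seed: int = 0,
    k1: int = 2,
    k2: int = 2,
    n_init: int = 50,
    exhaustive: bool = False,
    panel: Sequence[TreatmentCode] | None = None,
) -> list[ValidationRun]:
    """Re-run GHSA and clustering on each leave-one-out dataset."""
    if panel is None:
        panel = exhaustive_panel(plate.n_drugs)
    ss = np.random.SeedSequence(seed)
    gen_seed, cluster_root = (int(s) for s in ss.generate_state(2) % (2**31))
    datasets = generate_validation_datasets(plate, n_v, gen_seed, exhaustive)
    cluster_seeds = np.random.SeedSequence(cluster_root).generate_state(
        max(len(datasets), 1)
    ) % (2**31)

    runs: list[ValidationRun] = []
    for ds, cseed in zip(datasets, cluster_seeds):
        collapsed = collapse_replicates(ds.plate)
        q3 = restoration_matrix(collapsed, stimulation, panel)
        tree = cluster_treatments(
            q3, k1=k1, k2=k2, seed=int(cseed), n_init=n_init, stimulation=stimulation
        )
        runs.append(
            ValidationRun(
                run_id=ds.run_id,
                kept_replicates=ds.kept_replicates,
                ghsa=ghsa_panel(collapsed, stimulation, panel),
                tree=tree,
                partition_label=canonical_partition(tree),
                level2_label=canonical_level2(tree),
            )
        )
    return runs


def summarize_ghsa(runs: Sequence[ValidationRun]) -> list[GHSASummary]:
    """Five-number summary (min, p25, p50, p75, max) per combination."""
    if not runs:
        raise ValueError("no validation runs to summarize")
    combos = [r.combination for r in runs[0].ghsa]
    for run in runs:
        if [r.combination for r in run.ghsa] != combos:
            raise ValueError("validation runs analyzed different combination panels")
    out = []
    for i, combo in enumerate(combos):
        values = np.array([run.ghsa[i].index_value for run in runs])
        q = np.percentile(values, [0, 25, 50, 75, 100])  # linear interpolation
        out.append(GHSASummary(combo, tuple(float(v) for v in q)))
    return out


def partition_frequencies(runs: Sequence[ValidationRun]) -> pd.DataFrame:
    """Percentage of runs per unique level-1 partition, sorted descending."""
    if not runs:
        raise ValueError("no validation runs")
    counts = Counter(r.partition_label for r in runs)
    df = pd.DataFrame(
        [
            {"partition": label, "runs": n, "percent": 100.0 * n / len(runs)}
            for label, n in counts.items()
        ]
    )
    return df.sort_values(
        ["percent", "partition"], ascending=[False, True], ignore_index=True
    )


def dominant_centroids(
    plate: PlateTable,
    runs: Sequence[ValidationRun],
    stimulation: int = 0,
    panel: Sequence[TreatmentCode] | None = None,
) -> ClusterTree:
    """Centroids of the dominant partitions, recomputed on all replicates.

    The dominant level-1 partition is the most frequent one across runs; the
    dominant level-2 sub-partition is the most frequent one *among runs
    showing the dominant level-1 partition* (conditional dominance).
    Centroids are means of the full-data Q3 vectors of each group's members.
    """
    if not runs:
        raise ValueError("no validation runs")
    freq = partition_frequencies(runs)
    dominant_l1 = freq.iloc[0]["partition"]
    matching = [r for r in runs if r.partition_label == dominant_l1]
    l2_counts = Counter(r.level2_label for r in matching)
    dominant_l2 = max(l2_counts, key=lambda lbl: (l2_counts[lbl], lbl))
    template = next(r for r in matching if r.level2_label == dominant_l2)

    if panel is None:
        panel = exhaustive_panel(plate.n_drugs)
    collapsed = collapse_replicates(plate)
    q3 = restoration_matrix(collapsed, stimulation, panel)

    clusters = []
    for members, subs in level2_structure(template.tree):
        mem = tuple(sorted(members))
        centroid = q3.loc[list(mem)].to_numpy().mean(axis=0)
        subclusters = None
        if subs is not None:
            subclusters = tuple(
                SubCluster(
                    tuple(sorted(s)), q3.loc[sorted(s)].to_numpy().mean(axis=0)
                )
                for s in subs
            )
        clusters.append(Cluster(mem, centroid, subclusters))
    return ClusterTree(
        proteins=tuple(str(c) for c in q3.columns),
        clusters=tuple(clusters),
        stimulation=stimulation,
        k1=template.tree.k1,
        k2=template.tree.k2,
    )
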