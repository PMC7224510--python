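"""Synthetic plates with known ground truth.

The generator emulates a single-plate exhaustive combination screen: healthy
(H) and disease-associated (D) samples, an exhaustive treatment panel on D,
a stimulation panel on both tissues, intra-plate replicates and cell-free
blank wells.  Defaults mirror the reference experimental design: 3 drugs
(7-treatment panel), 3 stimulations, 23 proteins, and per-state replicate
counts that total 87 wells.

The measurement model is multiplicative: every protein has a healthy
baseline level; disease multiplies it by a per-protein shift; a treatment
with restoration fraction ``rho`` moves the diseased level geometrically
back toward healthy (``level = D^(1-rho) * H^rho``, so rho=1 restores
exactly and rho=0 does nothing); stimulation scales both tissues by a
common gain; replicate noise is multiplicative log-normal (measurements are
non-negative fluorescence-like intensities).  Blanks are drawn around a
background floor.  Closed-form zero-noise expectations for every downstream
quantity are available from :func:`ground_truth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .combination_design import exhaustive_panel, proper_subtreatments
from .plate_io import (
    TISSUE_BLANK,
    TISSUE_D,
    TISSUE_H,
    PlateTable,
    TreatmentCode,
    WellRecord,
)

__all__ = ["StateReplicates", "FixtureSpec", "generate_plate", "ground_truth", "GroundTruth"]


@dataclass(frozen=True)
class StateReplicates:
    """Replicate count per design-row class (defaults total 87 wells for
    a 3-drug x 3-stimulation panel with 23 proteins)."""

    treated_stimulated: int = 2
    treated_unstimulated: int = 3
    disease_untreated_stimulated: int = 2
    disease_untreated_unstimulated: int = 4
    healthy_stimulated: int = 2
    healthy_unstimulated: int = 4
    blank: int = 4

    @classmethod
    def uniform(cls, n: int) -> "StateReplicates":
        return cls(n, n, n, n, n, n, n)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic plate.

    treatment_effects maps a treatment to its per-protein restoration
    fraction(s) in [0, 1]: 1 = full restoration to the healthy level,
    0 = no effect (the default for unlisted treatments).
    low_signal_proteins lists protein indices pinned below the blank
    detection floor in every sample well (planted QC casualties).
    """

    n_drugs: int = 3
    n_stimulations: int = 3
    d: int = 23
    replicates: StateReplicates = field(default_factory=StateReplicates)
    blank_level: float = 60.0
    blank_noise: float = 6.0
    healthy_level_range: tuple[float, float] = (200.0, 8000.0)
    disease_shift: float | np.ndarray = 2.0
    treatment_effects: Mapping[TreatmentCode, float | np.ndarray] = field(
        default_factory=dict
    )
    stimulation_gain: float = 3.0
    noise_sd: float = 0.1
    low_signal_proteins: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_stimulations, self.d) < 1:
            raise ValueError("n_drugs, n_stimulations and d must all be >= 1")
        if isinstance(self.replicates, int):
            self.replicates = StateReplicates.uniform(self.replicates)
        if self.noise_sd < 0 or self.blank_noise < 0:
            raise ValueError("noise scales must be non-negative")
        for t, rho in self.treatment_effects.items():
            r = np.asarray(rho, dtype=float)
            if np.any(r < 0) or np.any(r > 1):
                raise ValueError(f"restoration fraction for {t.label} outside [0, 1]")

    # --- derived, noise-free level model ------------------------------------

    def protein_names(self) -> tuple[str, ...]:
        width = len(str(self.d))
        return tuple(f"P{i + 1:0{width}d}" for i in range(self.d))

    def healthy_levels(self) -> np.ndarray:
        """Per-protein healthy baselines (log-uniform over the given range)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        lo, hi = self.healthy_level_range
        levels = np.exp(rng.uniform(np.log(lo), np.log(hi), size=self.d))
        levels[list(self.low_signal_proteins)] = 0.25 * self.blank_level
        return levels

    def shift_vector(self) -> np.ndarray:
        shift = np.broadcast_to(
            np.asarray(self.disease_shift, dtype=float), (self.d,)
        ).copy()
        shift[list(self.low_signal_proteins)] = 1.0  # flat where undetectable
        return shift

    def restoration_vector(self, treatment: TreatmentCode) -> np.ndarray:
        rho = self.treatment_effects.get(treatment, 0.0)
        rho = np.broadcast_to(np.asarray(rho, dtype=float), (self.d,)).copy()
        rho[list(self.low_signal_proteins)] = 0.0
        return rho

    def expected_level(
        self, tissue: str, treatment: TreatmentCode, stimulation: int
    ) -> np.ndarray:
        """Noise-free mean level of one cell state."""
        h = self.healthy_levels()
        gain = self.stimulation_gain if stimulation > 0 else 1.0
        if tissue == TISSUE_H:
            return gain * h
        dis = h * self.shift_vector()
        if treatment.is_untreated:
            return gain * dis
        rho = self.restoration_vector(treatment)
        return gain * dis ** (1.0 - rho) * h**rho


def generate_plate(spec: FixtureSpec, plate_id: str = "synthetic") -> PlateTable:
    """Materialize the full exhaustive design as a validated plate."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    reps = spec.replicates
    panel = exhaustive_panel(spec.n_drugs)
    to = TreatmentCode.untreated()
    stims = list(range(spec.n_stimulations + 1))  # 0 = unstimulated

    design: list[tuple[str, TreatmentCode, int, int]] = []
    for t in panel:
        for s in stims:
            design.append(
                (TISSUE_D, t, s, reps.treated_stimulated if s else reps.treated_unstimulated)
            )
    for s in stims:
        design.append(
            (
                TISSUE_D,
                to,
                s,
                reps.disease_untreated_stimulated if s else reps.disease_untreated_unstimulated,
            )
        )
    for s in stims:
        design.append(
            (TISSUE_H, to, s, reps.healthy_stimulated if s else reps.healthy_unstimulated)
        )
    design.append((TISSUE_BLANK, to, 0, reps.blank))

    wells: list[WellRecord] = []
    counter = 0
    for tissue, treatment, stim, n_rep in design:
        for rep in range(1, n_rep + 1):
            counter += 1
            if tissue == TISSUE_BLANK:
                f = np.maximum(
                    rng.normal(spec.blank_level, spec.blank_noise, size=spec.d), 0.0
                )
            else:
                level = spec.expected_level(tissue, treatment, stim)
                noise = (
                    np.exp(rng.normal(0.0, spec.noise_sd, size=spec.d))
                    if spec.noise_sd > 0
                    else 1.0
                )
                f = level * noise
            wells.append(
                WellRecord(
                    well_id=f"W{counter:03d}",
                    tissue=tissue,
                    treatment=treatment,
                    stimulation=stim,
                    replicate=rep,
                    f=f,
                )
            )
    return PlateTable(plate_id, spec.protein_names(), wells, spec.n_drugs)


@dataclass
class GroundTruth:
    """Zero-noise expectations over the detectable protein panel."""

    proteins: tuple[str, ...]  # detectable proteins only
    q1: np.ndarray  # therapeutic need, same for every stimulation
    q3: dict[str, np.ndarray]  # treatment label -> restoration vector
    effects: dict[str, float]  # treatment label -> E
    ghsa: dict[str, float]  # combination label -> I
    partition: tuple[frozenset, ...]  # treatments grouped by identical Q3


def _ratio_from_factor(m: np.ndarray) -> np.ndarray:
    """Closed form for the normalized difference when f_alpha = m * f_beta."""
    return (m - 1.0) / (m + 1.0)


def ground_truth(spec: FixtureSpec) -> GroundTruth:
    """Closed-form expectations for Q1/Q3, effects, GHSA and the partition.

    Computed over the detectable proteins only (planted low-signal proteins
    are what QC is expected to drop), independently of the pipeline: ratios
    from the multiplicative factors, effects as mean |ratio|, GHSA by
    brute-force minimum over enumerated proper subsets.
    """
    detectable = [i for i in range(spec.d) if i not in set(spec.low_signal_proteins)]
    names = spec.protein_names()
    shift = spec.shift_vector()[detectable]

    q1 = _ratio_from_factor(shift)
    q3: dict[str, np.ndarray] = {}
    effects: dict[str, float] = {}
    panel = exhaustive_panel(spec.n_drugs)
    for t in panel:
        rho = spec.restoration_vector(t)[detectable]
        # D,Tx level = H * shift^(1-rho)  ->  factor vs healthy
        factor = shift ** (1.0 - rho)
        q3[t.label] = _ratio_from_factor(factor)
        effects[t.label] = float(np.mean(np.abs(q3[t.label])))

    ghsa: dict[str, float] = {}
    for t in panel:
        if t.order >= 2:
            sub_min = min(effects[s.label] for s in proper_subtreatments(t))
            ghsa[t.label] = sub_min - effects[t.label]

    groups: dict[tuple, list[str]] = {}
    for t in panel:
        key = tuple(np.round(q3[t.label], 9))
        groups.setdefault(key, []).append(t.label)
    partition = tuple(
        sorted((frozenset(m) for m in groups.values()), key=sorted)
    )

    return GroundTruth(
        proteins=tuple(names[i] for i in detectable),
        q1=q1,
        q3=q3,
        effects=effects,
        ghsa=ghsa,
        partition=partition,
    )
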