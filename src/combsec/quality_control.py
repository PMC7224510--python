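"""Plate quality control: detection limits, replicate outliers, collapsing.

Three steps run before any analysis:

1. *Detection filter* — per protein, a detection limit is estimated from the
   cell-free blank wells as ``median(blanks) + k * MAD(blanks)`` (raw, i.e.
   unscaled, median absolute deviation).  A protein is "detected" in a well
   when its value exceeds the limit; proteins detected in too small a
   fraction of non-blank wells are dropped from the panel.
2. *Replicate outlier filter* — within each (tissue, treatment, stimulation)
   state with at least three replicates, a replicate is dropped when the
   median (over proteins) of its relative deviation from the state's
   per-protein median profile exceeds a threshold.  A state that started
   with >= 2 replicates is never reduced below 2.
3. *Collapse* — surviving replicates are reduced to one median profile per
   cell state (element-wise median; even counts average the two central
   values, the numpy convention).

Values below the detection limit for surviving proteins are retained, not
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QCError
from .plate_io import (
    TISSUE_BLANK,
    CellState,
    PlateTable,
    WellRecord,
)

__all__ = [
    "QCConfig",
    "QCReport",
    "CollapsedPlate",
    "detection_filter",
    "replicate_outlier_filter",
    "collapse_replicates",
    "apply_qc",
]


@dataclass(frozen=True)
class QCConfig:
    """Tunable quality-control thresholds.

    blank_k
        Multiplier ``k`` in the blank-based detection limit
        ``median + k * MAD``.  0 uses the blank median alone.
    replicate_max_dev
        Maximal allowed median relative deviation of a replicate profile
        from its state median profile (0.5 = 50%).
    protein_min_detected_frac
        Minimal fraction of non-blank wells in which a protein must exceed
        its detection limit to stay in the panel.
    """

    blank_k: float = 3.0
    replicate_max_dev: float = 0.5
    protein_min_detected_frac: float = 0.5

    def __post_init__(self):
        if self.blank_k < 0 or self.replicate_max_dev < 0:
            raise ValueError("QC parameters must be non-negative")
        if not 0.0 <= self.protein_min_detected_frac <= 1.0:
            raise ValueError("protein_min_detected_frac must lie in [0, 1]")


@dataclass
class QCReport:
    """What QC removed and what remains."""

    dropped_wells: list[tuple[str, str]] = field(default_factory=list)
    dropped_proteins: list[tuple[str, str]] = field(default_factory=list)
    retained_shape: tuple[int, int] = (0, 0)

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            dropped_wells=self.dropped_wells + other.dropped_wells,
            dropped_proteins=self.dropped_proteins + other.dropped_proteins,
            retained_shape=other.retained_shape,
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"entity": "well", "id": wid, "reason": reason}
            for wid, reason in self.dropped_wells
        ] + [
            {"entity": "protein", "id": p, "reason": reason}
            for p, reason in self.dropped_proteins
        ]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


def detection_limits(plate: PlateTable, blank_k: float) -> np.ndarray:
    """Per-protein detection limit from the blank wells: median + k * MAD."""
    blanks = plate.blank_wells()
    if not blanks:
        raise QCError(
            "plate has no BLANK wells; detection filtering needs a background "
            "estimate — skip detection_filter explicitly if none exists"
        )
    B = np.vstack([w.f for w in blanks])
    med = np.median(B, axis=0)
    mad = np.median(np.abs(B - med), axis=0)
    return med + blank_k * mad


def detection_filter(plate: PlateTable, cfg: QCConfig) -> tuple[PlateTable, QCReport]:
    """Drop proteins detected in too few non-blank wells."""
    limits = detection_limits(plate, cfg.blank_k)
    samples = [w for w in plate.wells if w.tissue != TISSUE_BLANK]
    if not samples:
        raise QCError("plate has no sample (non-blank) wells")
    F = np.vstack([w.f for w in samples])
    detected_frac = np.mean(F > limits, axis=0)
    keep = detected_frac >= cfg.protein_min_detected_frac

    report = QCReport()
    for j, p in enumerate(plate.proteins):
        if not keep[j]:
            report.dropped_proteins.append(
                (
                    p,
                    f"detected in {detected_frac[j]:.0%} of sample wells "
                    f"(limit {limits[j]:.4g}, required {cfg.protein_min_detected_frac:.0%})",
                )
            )
    reduced = plate.with_proteins([p for p, k in zip(plate.proteins, keep) if k])
    if reduced.d == 0:
        raise QCError("detection filter removed every protein; lower blank_k "
                      "or protein_min_detected_frac")
    report.retained_shape = (reduced.n_wells, reduced.d)
    return reduced, report


def _replicate_deviations(group: list[WellRecord]) -> np.ndarray:
    """Median relative deviation of each replicate from the state median profile."""
    F = np.vstack([w.f for w in group])
    med = np.median(F, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(F - med) / med
    # where the state median is zero: zero deviation if the value is zero too,
    # otherwise treat as maximally deviant
    rel = np.where(med > 0, rel, np.where(F == 0, 0.0, np.inf))
    return np.median(rel, axis=1)


def replicate_outlier_filter(plate: PlateTable, cfg: QCConfig) -> tuple[PlateTable, QCReport]:
    """Drop deviant replicates per state; states with < 3 replicates are skipped."""
    report = QCReport()
    drop_ids: set[str] = set()
    for state, group in plate.states().items():
        if len(group) < 3:
            continue
        devs = _replicate_deviations(group)
        order = np.argsort(devs)[::-1]  # worst first
        remaining = len(group)
        for idx in order:
            if devs[idx] <= cfg.replicate_max_dev or remaining <= 2:
                break
            w = group[idx]
            drop_ids.add(w.well_id)
            report.dropped_wells.append(
                (
                    w.well_id,
                    f"replicate {w.replicate} of {state.label}: median relative "
                    f"deviation {devs[idx]:.3g} > {cfg.replicate_max_dev:.3g}",
                )
            )
            remaining -= 1
    reduced = plate.with_wells([w for w in plate.wells if w.well_id not in drop_ids])
    report.retained_shape = (reduced.n_wells, reduced.d)
    return reduced, report


@dataclass
class CollapsedPlate:
    """One median profile per surviving cell state (blanks excluded)."""

    plate_id: str
    proteins: tuple[str, ...]
    profiles: dict[CellState, np.ndarray]
    n_drugs: int

    @property
    def d(self) -> int:
        return len(self.proteins)

    def profile(self, state: CellState) -> np.ndarray:
        try:
            return self.profiles[state]
        except KeyError:
            raise QCError(f"no surviving replicates for cell state {state.label}")


def collapse_replicates(plate: PlateTable) -> CollapsedPlate:
    """Element-wise median over each state's replicates (order-invariant)."""
    profiles: dict[CellState, np.ndarray] = {}
    for state, group in plate.states(include_blanks=False).items():
        if not group:
            raise QCError(f"cell state {state.label} has zero surviving replicates")
        profiles[state] = np.median(np.vstack([w.f for w in group]), axis=0)
    return CollapsedPlate(plate.plate_id, plate.proteins, profiles, plate.n_drugs)


def apply_qc(
    plate: PlateTable,
    cfg: QCConfig | None = None,
    detection: bool = True,
    outliers: bool = True,
) -> tuple[PlateTable, QCReport]:
    """Run the QC chain (detection filter, then replicate outlier filter)."""
    cfg = cfg or QCConfig()
    report = QCReport(retained_shape=(plate.n_wells, plate.d))
    if detection:
        plate, frag = detection_filter(plate, cfg)
        report = report.merge(frag)
    if outliers:
        plate, frag = replicate_outlier_filter(plate, cfg)
        report = report.merge(frag)
    report.retained_shape = (plate.n_wells, plate.d)
    return plate, report
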