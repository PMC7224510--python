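"""Per-plate normalized protein-release differences (bounded ratios).

The difference in release of protein ``k`` between two cell states alpha and
beta on one plate is normalized as::

    r(k) = (f_alpha(k) - f_beta(k)) / (f_alpha(k) + f_beta(k))

which is restricted to [-1, 1]: +1 when alpha releases far more than beta,
0 at equality, -1 when beta dominates.  Because raw plate readouts are not
comparable across plates, ratios are always computed per plate first; a
cross-plate mean of per-plate ratios is provided for multi-plate designs.

Three questions are answered with this ratio, by choosing the states:

Q1 (therapeutic need)    alpha = (D, To, S), beta = (H, To, S)
Q2 (modulation capacity) alpha = (D, Tx, S), beta = (D, To, S)
Q3 (restoration capacity)alpha = (D, Tx, S), beta = (H, To, S)

A zero Q3 ratio means the treatment fully restored the healthy release level
of that protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .combination_design import exhaustive_panel
from .errors import MissingStateError
from .plate_io import (
    TISSUE_D,
    TISSUE_H,
    CellState,
    TreatmentCode,
    stimulation_label,
)
from .quality_control import CollapsedPlate

__all__ = [
    "RatioVector",
    "normalized_difference",
    "therapeutic_need",
    "modulation_capacity",
    "restoration_capacity",
    "restoration_matrix",
    "average_ratio_vectors",
]


@dataclass
class RatioVector:
    """A d'-dimensional ratio vector for one (question, treatment, stimulation)."""

    question: str  # "Q1" | "Q2" | "Q3"
    treatment: TreatmentCode
    stimulation: int
    proteins: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.proteins),):
            raise ValueError("ratio vector length must match protein panel")
        if np.any(np.isnan(self.values)):
            raise ValueError("NaN ratio")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("ratio outside [-1, 1]")

    @property
    def context_label(self) -> str:
        return f"{self.question}({self.treatment.label}, {stimulation_label(self.stimulation)})"


def normalized_difference(
    f_alpha: Sequence[float] | np.ndarray, f_beta: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Element-wise (fa - fb) / (fa + fb), with 0/0 defined as 0.

    Inputs are state-median measurement vectors and must be non-negative;
    a negative entry indicates an upstream QC bug and raises.
    """
    fa = np.asarray(f_alpha, dtype=float)
    fb = np.asarray(f_beta, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {fb.shape}")
    if np.any(fa < 0) or np.any(fb < 0):
        raise ValueError("negative measurement passed to normalized_difference")
    denom = fa + fb
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (fa - fb) / denom
    # both states release nothing -> no difference
    return np.where(denom > 0, r, 0.0)


def _profile(states: CollapsedPlate, tissue: str, treatment: TreatmentCode, stim: int) -> np.ndarray:
    key = CellState(tissue, treatment, stim)
    if key not in states.profiles:
        raise MissingStateError(f"required cell state {key.label} is missing from the plate")
    return states.profiles[key]


def therapeutic_need(states: CollapsedPlate, stimulation: int = 0) -> RatioVector:
    """Q1: untreated diseased vs untreated healthy release, per protein."""
    to = TreatmentCode.untreated()
    r = normalized_difference(
        _profile(states, TISSUE_D, to, stimulation),
        _profile(states, TISSUE_H, to, stimulation),
    )
    return RatioVector("Q1", to, stimulation, states.proteins, r)


def modulation_capacity(
    states: CollapsedPlate, treatment: TreatmentCode, stimulation: int = 0
) -> RatioVector:
    """Q2: treated vs untreated diseased release, per protein."""
    if treatment.is_untreated:
        raise ValueError("Q2 requires a treatment (Tx != To)")
    to = TreatmentCode.untreated()
    r = normalized_difference(
        _profile(states, TISSUE_D, treatment, stimulation),
        _profile(states, TISSUE_D, to, stimulation),
    )
    return RatioVector("Q2", treatment, stimulation, states.proteins, r)


def restoration_capacity(
    states: CollapsedPlate, treatment: TreatmentCode, stimulation: int = 0
) -> RatioVector:
    """Q3: treated diseased vs untreated healthy release, per protein.

    Zero everywhere = the treatment fully restored healthy release levels;
    positive = still higher in D than H, negative = higher in H than D.
    """
    if treatment.is_untreated:
        raise ValueError("Q3 requires a treatment (Tx != To)")
    r = normalized_difference(
        _profile(states, TISSUE_D, treatment, stimulation),
        _profile(states, TISSUE_H, TreatmentCode.untreated(), stimulation),
    )
    return RatioVector("Q3", treatment, stimulation, states.proteins, r)


def restoration_matrix(
    states: CollapsedPlate,
    stimulation: int = 0,
    panel: Sequence[TreatmentCode] | None = None,
) -> pd.DataFrame:
    """Q3 ratios for a whole treatment panel: rows = treatments, cols = proteins."""
    if panel is None:
        panel = exhaustive_panel(states.n_drugs)
    rows = {
        t.label: restoration_capacity(states, t, stimulation).values for t in panel
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(states.proteins))


def average_ratio_vectors(vectors: Iterable[RatioVector]) -> RatioVector:
    """Cross-plate mean of per-plate ratio vectors sharing one context."""
    vecs = list(vectors)
    if not vecs:
        raise ValueError("no ratio vectors to average")
    first = vecs[0]
    for v in vecs[1:]:
        if (
            v.question != first.question
            or v.treatment != first.treatment
            or v.stimulation != first.stimulation
            or v.proteins != first.proteins
        ):
            raise ValueError("ratio vectors from different contexts cannot be averaged")
    mean = np.mean([v.values for v in vecs], axis=0)
    return RatioVector(first.question, first.treatment, first.stimulation, first.proteins, mean)
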