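"""Generalized highest-single-agent (GHSA) synergy scoring.

Classic HSA calls a drug pair useful when it beats its best single
constituent.  The generalization scores a combination of any order against
*all* of its lower-order subsets (singles, pairs, ...), on multi-protein
readouts scalarized via the restoration profile:

    E(Tx) = (1/d) * sum_k |rQ3(k, Tx)|            (normalized L1 norm, [0, 1])
    I(T)  = min{ E(T') : T' proper subset of T } - E(T)

E is a divergence from the healthy secretion pattern (0 = fully restored),
so I in [-1, 1] reads: +1 maximal emergent synergy (the combination restores
while every lower-order treatment maximally diverges), -1 maximal emergent
antagonism, 0 no gain over the best lower-order treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real
from typing import Mapping, Sequence

import numpy as np

from .combination_design import exhaustive_panel, proper_subtreatments
from .errors import DesignError
from .plate_io import TreatmentCode
from .quality_control import CollapsedPlate
from .ratios import RatioVector, restoration_capacity

__all__ = [
    "EffectScore",
    "GHSAResult",
    "treatment_effect",
    "ghsa_index",
    "ghsa_panel",
    "panel_effects",
]


@dataclass(frozen=True)
class EffectScore:
    """Scalar divergence of a treatment's restoration profile, in [0, 1]."""

    treatment: TreatmentCode
    stimulation: int
    E: float

    def __post_init__(self):
        if not 0.0 <= self.E <= 1.0 + 1e-12:
            raise ValueError(f"effect {self.E} outside [0, 1]")


@dataclass(frozen=True)
class GHSAResult:
    """GHSA index of one combination treatment in one stimulation context."""

    combination: TreatmentCode
    stimulation: int
    index_value: float
    argmin_subtreatment: TreatmentCode
    effect_combination: float
    min_subtreatment_effect: float

    def __post_init__(self):
        if abs(self.index_value) > 1 + 1e-12:
            raise ValueError(f"GHSA index {self.index_value} outside [-1, 1]")


def treatment_effect(rq3: RatioVector) -> EffectScore:
    """Normalized L1 norm of a restoration (Q3) vector: mean absolute ratio."""
    if rq3.question != "Q3":
        raise ValueError(f"effects are defined on Q3 vectors, got {rq3.question}")
    if rq3.values.size == 0:
        raise ValueError("empty ratio vector")
    return EffectScore(rq3.treatment, rq3.stimulation, float(np.mean(np.abs(rq3.values))))


def _effect_value(e) -> float:
    if isinstance(e, EffectScore):
        return e.E
    if isinstance(e, Real):
        return float(e)
    raise TypeError(f"cannot interpret {e!r} as an effect")


def ghsa_index(
    combination: TreatmentCode,
    effects: Mapping[TreatmentCode, "EffectScore | float"],
    stimulation: int = 0,
) -> GHSAResult:
    """min over proper subtreatments of E, minus E(combination).

    Requires an exhaustive effect map: every proper subtreatment of the
    combination must be present.  Ties in the argmin are broken by the
    deterministic panel order (size, then lexicographic).
    """
    subs = proper_subtreatments(combination)  # validates order >= 2
    missing = [t.label for t in (subs + [combination]) if t not in effects]
    if missing:
        raise DesignError(
            f"effect map is not exhaustive for {combination.label}: "
            f"missing {', '.join(missing)}"
        )
    e_combo = _effect_value(effects[combination])
    # subs is in deterministic panel order; min keeps the first of tied effects
    argmin = min(subs, key=lambda t: _effect_value(effects[t]))
    e_min = _effect_value(effects[argmin])
    return GHSAResult(
        combination=combination,
        stimulation=stimulation,
        index_value=e_min - e_combo,
        argmin_subtreatment=argmin,
        effect_combination=e_combo,
        min_subtreatment_effect=e_min,
    )


def panel_effects(
    states: CollapsedPlate, stimulation: int = 0, panel: Sequence[TreatmentCode] | None = None
) -> dict[TreatmentCode, EffectScore]:
    """E(Tx) for every treatment in the exhaustive panel, from Q3 vectors."""
    if panel is None:
        panel = exhaustive_panel(states.n_drugs)
    return {
        t: treatment_effect(restoration_capacity(states, t, stimulation)) for t in panel
    }


def ghsa_panel(
    states: CollapsedPlate, stimulation: int = 0, panel: Sequence[TreatmentCode] | None = None
) -> list[GHSAResult]:
    """GHSA index for every combination of order >= 2 in the panel.

    For a 3-drug exhaustive panel this yields T12, T13, T23, T123.
    """
    if panel is None:
        panel = exhaustive_panel(states.n_drugs)
    effects = panel_effects(states, stimulation, panel)
    return [
        ghsa_index(t, effects, stimulation) for t in panel if t.order >= 2
    ]
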