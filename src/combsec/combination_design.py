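"""Exhaustive combination panels and subset relations among treatments.

An exhaustive combination experiment tests every non-empty subset of the
``N_t`` pre-selected single drugs at one fixed concentration each, so the
panel has ``2^N_t - 1`` treatments.  The subset-search operation reduces a
group of treatments to its minimal members: a treatment is redundant inside a
group whenever a strict subset of its drugs is also in the group (the smaller
treatment already induces the group's prototypical profile).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

from .errors import DesignError
from .plate_io import TreatmentCode

__all__ = ["exhaustive_panel", "proper_subtreatments", "subset_search", "panel_size"]


def panel_size(n_drugs: int) -> int:
    """Number of wells (treatments) in an exhaustive design: 2^N_t - 1."""
    if n_drugs < 1:
        raise DesignError(f"n_drugs must be >= 1, got {n_drugs}")
    return 2**n_drugs - 1


def exhaustive_panel(n_drugs: int) -> list[TreatmentCode]:
    """All non-empty drug subsets, ordered by size then lexicographically.

    For three drugs: T1, T2, T3, T12, T13, T23, T123.
    """
    if n_drugs < 1:
        raise DesignError(f"n_drugs must be >= 1, got {n_drugs}")
    panel: list[TreatmentCode] = []
    for size in range(1, n_drugs + 1):
        for combo in combinations(range(1, n_drugs + 1), size):
            panel.append(TreatmentCode(combo))
    return panel


def proper_subtreatments(t: TreatmentCode) -> list[TreatmentCode]:
    """Every non-empty strict subset of a combination treatment's drugs.

    Single-drug treatments have no lower order, so ``|t| >= 2`` is required.
    """
    if t.order < 2:
        raise DesignError(
            f"{t.label} is not a combination treatment; single drugs have no "
            "lower-order subtreatments"
        )
    drugs = sorted(t.drugs)
    subs: list[TreatmentCode] = []
    for size in range(1, len(drugs)):
        for combo in combinations(drugs, size):
            subs.append(TreatmentCode(combo))
    return subs


def subset_search(group: Iterable[TreatmentCode]) -> list[TreatmentCode]:
    """Minimal treatments of a group: drop any member that strictly contains
    another member's drug set.

    E.g. {T1, T23, T13} -> {T1, T23}: T13 is covered by T1.  Survivors are
    ranked equally (no ordering beyond the deterministic panel order is
    imposed).  Idempotent.
    """
    members = sorted(set(group))
    if not members:
        raise DesignError("subset search requires a non-empty group")
    kept = [
        t
        for t in members
        if not any(other.is_proper_subset(t) for other in members)
    ]
    return kept
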