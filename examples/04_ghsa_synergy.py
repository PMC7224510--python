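"""Generalized highest-single-agent (GHSA) scoring of combination treatments.

Each treatment's restoration profile is scalarized to an effect
E = mean |Q3| in [0, 1] (0 = healthy pattern restored); a combination's
index is min(E over all its lower-order subsets) - E(combination), so
positive = emergent synergy, negative = emergent antagonism.

Here T2 alone fully restores, so every combination containing drug 2 that
does nothing by itself is flagged antagonistic (negative index).
"""

from combsec import (
    FixtureSpec,
    StateReplicates,
    TreatmentCode,
    collapse_replicates,
    generate_plate,
    ghsa_panel,
)

spec = FixtureSpec(
    n_stimulations=1,
    d=8,
    replicates=StateReplicates.uniform(3),
    treatment_effects={TreatmentCode([2]): 1.0},
    noise_sd=0.0,
    seed=7,
)
collapsed = collapse_replicates(generate_plate(spec))

print(f"{'combination':>12} {'E(combo)':>9} {'min sub E':>10} {'argmin':>7} {'I_GHSA':>8}")
for res in ghsa_panel(collapsed, stimulation=1):
    print(
        f"{res.combination.label:>12} {res.effect_combination:9.3f} "
        f"{res.min_subtreatment_effect:10.3f} {res.argmin_subtreatment.label:>7} "
        f"{res.index_value:8.3f}"
    )
# T12, T23 and T123 score ~-0.33: their best lower-order subset (T2, E=0)
# already restores, so the combination only loses ground. T13 scores 0:
# no gain, no loss over its equally ineffective parts.
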