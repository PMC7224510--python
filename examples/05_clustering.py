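"""Two-level top-down clustering of restoration profiles, with subset search.

T2 and T3 (and their pair) fully restore while the rest do nothing, so the
level-1 partition should separate the restoring treatments from the inert
ones; the subset search then reduces each group to its minimal members.
"""

from combsec import (
    FixtureSpec,
    StateReplicates,
    TreatmentCode,
    canonical_partition,
    cluster_treatments,
    collapse_replicates,
    generate_plate,
    restoration_matrix,
    subset_search,
    therapeutic_need,
)
from combsec.clustering import annotate_with_need

spec = FixtureSpec(
    n_stimulations=1,
    d=6,
    replicates=StateReplicates.uniform(3),
    treatment_effects={
        TreatmentCode([2]): 1.0,
        TreatmentCode([3]): 1.0,
        TreatmentCode([2, 3]): 1.0,
    },
    noise_sd=0.05,
    seed=7,
)
collapsed = collapse_replicates(generate_plate(spec))
q3 = restoration_matrix(collapsed, stimulation=1)

tree = cluster_treatments(q3, k1=2, k2=2, seed=0)
print("level-1 partition:", canonical_partition(tree))
for c in tree.clusters:
    minimal = subset_search([TreatmentCode.parse(t) for t in c.members])
    print(f"  group {set(c.members)} -> minimal treatments "
          f"{{{', '.join(t.label for t in minimal)}}}")

table = annotate_with_need(tree, therapeutic_need(collapsed, 1))
print("\ncentroids aligned with the therapeutic-need line:")
print(table.round(3).to_string())
# The restoring group {T2,T3,T23,...} reduces to {T2, T3}: the pair T23 adds
# nothing its single constituents do not already achieve (equal rank).
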