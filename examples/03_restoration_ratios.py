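"""Therapeutic need (Q1), modulation (Q2) and restoration (Q3) ratios.

Disease doubles every protein's release (ratio (2-1)/(2+1) = +1/3 vs
healthy); treatment T1 fully restores healthy levels, so its Q3 vector
should sit at zero.
"""

import numpy as np

from combsec import (
    FixtureSpec,
    StateReplicates,
    TreatmentCode,
    collapse_replicates,
    generate_plate,
    modulation_capacity,
    restoration_matrix,
    therapeutic_need,
)

spec = FixtureSpec(
    n_stimulations=1,
    d=6,
    replicates=StateReplicates.uniform(3),
    treatment_effects={TreatmentCode([1]): 1.0},
    noise_sd=0.0,
    seed=7,
)
collapsed = collapse_replicates(generate_plate(spec))

need = therapeutic_need(collapsed, stimulation=1)
print("Q1 therapeutic need:", np.round(need.values, 3))

q2 = modulation_capacity(collapsed, TreatmentCode([1]), stimulation=1)
print("Q2 modulation by T1:", np.round(q2.values, 3))

q3 = restoration_matrix(collapsed, stimulation=1)
print("\nQ3 restoration capacity (0 = fully restored):")
print(q3.round(3).to_string())
# Q1 = +0.333 per protein (the planted 2x disease shift); T1's Q3 row is all
# zeros (full restoration) while untouched treatments stay at +0.333.
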