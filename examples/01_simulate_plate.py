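"""Generate a synthetic exhaustive-combination plate and inspect its layout.

The default design uses 3 drugs (a 7-treatment exhaustive panel), 3 protein
stimulations, 23 measured proteins, and per-state replicate counts that
total 87 wells — diseased (D) and healthy (H) samples plus cell-free blanks
on one plate.
"""

from combsec import FixtureSpec, generate_plate, summarize_layout

spec = FixtureSpec(seed=7)
plate = generate_plate(spec)

print(f"plate: {plate.n_wells} wells x {plate.d} proteins")
layout = summarize_layout(plate)
print(layout.to_string(index=False))
print(f"total wells: {layout['wells'].sum()}")
# Each row is one (tissue, treatment, stimulation) cell state with its
# replicate count; the total confirms the 87-well exhaustive design.
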