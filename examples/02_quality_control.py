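"""Quality control: detection limits from blanks, replicate outliers, medians.

Fifteen of the 23 proteins are planted below the blank detection floor, so
the detection filter should reduce the panel to 8 proteins — the kind of
attrition a real multiplex immunoassay panel shows.
"""

from combsec import FixtureSpec, QCConfig, apply_qc, collapse_replicates, generate_plate

spec = FixtureSpec(low_signal_proteins=tuple(range(15)), seed=7)
plate = generate_plate(spec)

reduced, report = apply_qc(plate, QCConfig(blank_k=3.0, protein_min_detected_frac=0.5))
n, d = report.retained_shape
print(f"before QC: {plate.n_wells} wells x {plate.d} proteins")
print(f"after QC:  {n} wells x {d} proteins")
print(f"dropped proteins: {[p for p, _ in report.dropped_proteins]}")

collapsed = collapse_replicates(reduced)
print(f"{len(collapsed.profiles)} cell states collapsed to median profiles")
# Proteins whose signal never clears blank-median + 3*MAD in at least half
# of the sample wells are excluded before any ratio is computed.
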