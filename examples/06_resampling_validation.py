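"""Leave-one-out resampling: GHSA sampling distributions + partition stability.

Each of N_v validation datasets drops one random replicate per cell state
and re-runs the whole analysis.  A combination is called antagonistic when
all five summary numbers (min, p25, median, p75, max) of its GHSA indices
are negative; partition frequencies say how stable the clustering is.
"""

from combsec import (
    FixtureSpec,
    StateReplicates,
    TreatmentCode,
    dominant_centroids,
    generate_plate,
    partition_frequencies,
    run_validation,
    summarize_ghsa,
)

spec = FixtureSpec(
    n_stimulations=1,
    d=8,
    replicates=StateReplicates.uniform(3),
    treatment_effects={TreatmentCode([2]): 1.0, TreatmentCode([3]): 1.0},
    noise_sd=0.08,
    seed=7,
)
plate = generate_plate(spec)

runs = run_validation(plate, stimulation=1, n_v=300, seed=1)

print("GHSA five-number summaries over 300 leave-one-out datasets:")
for s in summarize_ghsa(runs):
    lo, q1, med, q3, hi = s.five_numbers
    verdict = "antagonistic" if hi < 0 else ("synergistic" if lo > 0 else "neutral")
    print(f"  {s.combination.label:>5}: [{lo:+.3f}, {q1:+.3f}, {med:+.3f}, "
          f"{q3:+.3f}, {hi:+.3f}]  -> {verdict}")

freq = partition_frequencies(runs)
print("\nlevel-1 partition frequencies:")
print(freq.head(3).to_string(index=False))

tree = dominant_centroids(plate, runs, stimulation=1)
print("\ndominant-partition groups (centroids over all replicates):")
for c in tree.clusters:
    print(f"  {set(c.members)}")
# T23 pairs two individually restoring drugs into an inert combination, so
# its whole sampling distribution sits below zero — the antagonism call.
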