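# Methods

## Data model and scope

One analysis unit is a single microtiter plate holding disease-associated
(`D`) and healthy (`H`) samples, cultivated, treated and stimulated in
parallel (single-plate design avoids inter-plate batch effects).  Each well
yields a `d`-vector `f` of non-negative, concentration-proportional
measurements; the plate is an `N × d` matrix with well annotations: tissue
(`D`/`H`/`BLANK`), treatment (a subset of the `N_t` single drugs; empty =
untreated `To`; healthy wells are analyzed untreated only), stimulation
index (0 = unstimulated `So`), and intra-plate replicate number.  Cell-free
`BLANK` wells estimate assay background.  An exhaustive combination design
tests all `2^N_t − 1` non-empty drug subsets at one fixed concentration
each; the package enumerates them in a fixed order (by subset size, then
lexicographically), which also serves as the deterministic tie-break
wherever one is needed.

Cross-plate analysis is limited to averaging per-plate ratio vectors
(arithmetic mean; `average_ratio_vectors`).  The mean was chosen over the
median for unbiasedness at the small plate counts typical of these screens;
this path is exercised only by unit tests, since the package's reference
workflows are single-plate.

## Quality control

The QC chain is deliberately pluggable — each rule is a standalone function
— because laboratories differ in what they trust:

1. **Detection filter.**  Per protein, the detection limit is
   `median(blanks) + blank_k · MAD(blanks)` with the raw (unscaled) median
   absolute deviation; default `blank_k = 3`.  A protein is kept when it
   exceeds its limit in at least `protein_min_detected_frac` (default 0.5)
   of the non-blank wells.  Running it on a plate without blanks is an
   error rather than a silent no-op.
2. **Replicate outlier filter.**  Within each cell state with ≥ 3
   replicates, a replicate is dropped when the median over proteins of its
   relative deviation from the state's per-protein median profile exceeds
   `replicate_max_dev` (default 0.5).  Worst replicates are removed first
   and a state that began with ≥ 2 replicates is never reduced below 2;
   states with < 3 replicates are skipped (no reference majority exists).
   Where the state median is zero, a zero measurement counts as zero
   deviation and a non-zero one as maximally deviant.
3. **Collapse.**  Surviving replicates reduce to one element-wise median
   profile per state (even counts: mean of the two central values).

Values below the detection limit for surviving proteins are retained, not
imputed: the normalization tolerates small values and imputation would add
an assumption the measurement does not support.  The QC report records
every dropped well and protein with the statistic that condemned it.

## Normalization and the three questions

The bounded ratio `r = (f_α − f_β)/(f_α + f_β)` is antisymmetric, scale
invariant (so per-plate gain differences cancel), and confined to
`[−1, 1]`.  The degenerate case `f_α = f_β = 0` is defined as `r = 0`
(neither state releases the protein, hence no difference); this preserves
boundedness and the equality semantics.  Negative inputs raise — they can
only arise from an upstream bug, since raw intensities are non-negative and
medians preserve that.

Q1 (therapeutic need), Q2 (modulation capacity) and Q3 (restoration
capacity) are the three state-pairings listed in the README; each is
computed per stimulation context, unstimulated included, and reported
separately per context.

## GHSA scoring

Effects are `E = mean |r_Q3|`, a divergence from the healthy pattern in
`[0, 1]`; the index of a combination is the minimum effect over *all* its
proper (non-empty, strict) subsets minus the combination's own effect.  The
subtraction order keeps positive = synergy even though `E` is
smaller-is-better.  An effect map missing any required subset raises with
the gaps listed — the method is only defined for exhaustive designs.  The
argmin subset is reported; ties resolve to the first in panel order.

## Clustering

Restoration vectors (rows = treatments) are partitioned by k-means
(Euclidean distance on the raw ratios — all coordinates already share the
`[−1, 1]` scale, so no re-scaling), then each first-level cluster with at
least `max(k2, 3)` members is split once more by k-means.  Defaults
`k1 = k2 = 2`: binary splits match the prototypical two-group structure
these screens exhibit, and the two-level depth is the framework's
supported hierarchy.  k-means uses 50 seeded restarts keeping the best
inertia, so trees are reproducible given the seed; clusters with ≤ 2
members are not split (a 2-way split of ≤ 2 points is degenerate).
Centroids are recomputed as arithmetic means of member rows rather than
taken from the k-means state.  Partitions are compared across runs via an
order-canonical label (clusters sorted by their sorted member labels).
The optional subset search reduces each cluster to its minimal members —
treatments whose drug set does not strictly contain another member's —
reported as equally ranked.

## Resampling validation

`N_v` validation datasets are built by removing one uniformly chosen
replicate per cell state (blanks are not cell states and pass through);
each state therefore needs ≥ 2 replicates, enforced with a named error.
Configurations are drawn independently across runs and states (sampling
with replacement over the configuration space); an opt-in exhaustive mode
enumerates all distinct configurations when their number is ≤ 10^5.  GHSA
and clustering are re-run per dataset.  Summaries:

- per combination, the five numbers (min, 25th, 50th, 75th percentile,
  max) of the `N_v` indices, with linear interpolation between order
  statistics (stated because box-plot conventions differ);
- the frequency (%) of each unique level-1 partition label, and, among
  runs showing the dominant level-1 partition, the dominant level-2
  structure (conditional dominance keeps level-2 labels comparable);
- dominant-partition centroids recomputed on the full, non-left-out data.

A practical decision rule: a combination whose five numbers all lie below
zero is called antagonistic; all above zero, synergistic.

## Synthetic plates and what they show

The generator emulates the reference experimental design: defaults are 3
drugs (7 treatments), 3 stimulations, 23 proteins, and per-state replicate
counts (2 for treated-stimulated, 3 treated-unstimulated, 2 untreated-
stimulated, 4 untreated-unstimulated D, 2/4 for H, 4 blanks) totalling 87
wells.  The measurement model is multiplicative: healthy baselines are
log-uniform on [200, 8000] (arbitrary fluorescence units spanning the
usable range of a multiplex readout); disease multiplies each protein by
`disease_shift` (default 2, a moderate disease signature); a treatment
with restoration fraction ρ moves the diseased level geometrically back
toward healthy, `level = D^(1−ρ) H^ρ`, so ρ = 1 restores exactly;
stimulation applies a common ×3 gain to both tissues; replicate noise is
log-normal with σ = 0.1 (≈ 10% CV, typical of multiplex immunoassays);
blanks are Gaussian around a floor of 60 ± 6.  Planted "low-signal"
proteins sit at a quarter of the blank floor so the detection filter has a
known truth.

Ground truth is closed-form under zero noise: with `f_α = m · f_β` the
ratio is `(m − 1)/(m + 1)`; effects and GHSA indices follow by direct
enumeration, and the planted partition groups treatments with identical
restoration vectors.  Ground truth covers the detectable proteins only
(planted casualties are what QC is meant to remove).

What passing tests show — and what they do not: the generator produces
i.i.d. multiplicative noise with no plate-position (edge) effects, no
cross-reactivity between analytes, no bead-count failures, no saturation,
and stimulation gains identical across tissues and proteins.  Recovery of
planted structure under these conditions validates the computational
chain, not the behavior of any particular assay chemistry.

## Problem sizes and numerical choices

The test suite and the reproduction script use desk-scale problems chosen
to exercise every code path: 7-treatment panels, 4–23 proteins, 2–4
replicates per state, `N_v` up to 10³ leave-one-out datasets, and 10⁴
random draws for the empirical bound checks.  Zero-noise end-to-end
agreement is asserted at 10⁻¹² absolute tolerance; stochastic recovery
claims use ≥ 99/100 seeded repetitions.  All randomness flows through
`numpy.random.SeedSequence`-derived generators, so every result is
reproducible from the input plate, the configuration and one seed.

## Known limitations

- Single-plate normalization only; no cross-plate batch correction beyond
  averaging per-plate ratios.
- The QC rules are reasonable defaults from multiplex-immunoassay
  practice, not a calibration to any specific instrument; substitute
  strategies can be slotted in at the function boundary.
- No automatic choice of cluster counts (silhouette or gap statistics);
  `k1`/`k2` are user parameters.
- Non-parametric throughout by design: no p-values or parametric
  confidence intervals are produced.
- Bliss independence and Loewe additivity scores are out of scope; the
  index implemented is the highest-single-agent generalization.
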