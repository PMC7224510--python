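# combsec

Model-free analysis of multiplexed protein-release (secretomic) plate data
for second- and higher-order drug combination screening.

## The problem

Many diseases distort the mixture of proteins that cells secrete.  A
pragmatic way to screen candidate therapies is to cultivate
disease-associated (`D`) and healthy (`H`) samples on one microtiter plate,
expose the `D` samples to **every** non-empty subset of `N_t` candidate
drugs (an exhaustive combination panel of `2^N_t − 1` treatments at fixed
concentrations), optionally stimulate all samples with disease-relevant
protein mixtures, and measure the release of a panel of `d` proteins per
well.  The question is then which (combination) treatment moves the
diseased secretion pattern back toward the healthy one — and whether a
higher-order combination earns its complexity over its own lower-order
subsets.

`combsec` implements that analysis for users of any plate-based readout
that yields concentration-proportional values (multiplex immunoassays,
targeted MS): plate QC, bounded effect ratios, a generalized
highest-single-agent synergy index, two-level top-down clustering of
restoration profiles, and leave-one-out resampling statistics.

## The model

Release differences between two cell states α and β are normalized per
plate and per protein *k*:

    r(k) = (f_α(k) − f_β(k)) / (f_α(k) + f_β(k))   ∈ [−1, 1]

Three state choices answer three questions: **Q1** therapeutic need
(`α = D,To,S` vs `β = H,To,S`), **Q2** modulation capacity
(`D,Tx,S` vs `D,To,S`), **Q3** restoration capacity
(`D,Tx,S` vs `H,To,S`; 0 = fully restored).

Each treatment's restoration profile is scalarized by the normalized
L¹ norm, and a combination is scored against *all* its lower-order subsets
(the generalized highest-single-agent index):

    E(Tx) = (1/d) Σ_k |r_Q3(k, Tx)|                ∈ [0, 1]
    I(T)  = min{ E(T′) : T′ ⊊ T, T′ ≠ ∅ } − E(T)   ∈ [−1, 1]

`I = +1` is maximal emergent synergy, `−1` maximal emergent antagonism,
`0` no gain over the best lower-order treatment.  Complementarily, the Q3
vectors are partitioned by two-level top-down k-means to expose
prototypical restoration behaviors, and the whole analysis is repeated on
`N_v` leave-one-out datasets (one replicate removed per cell state) to
yield five-number GHSA sampling summaries and partition-stability
frequencies.

## Worked example

A synthetic plate (see `examples/04_ghsa_synergy.py`) where drug `T2` alone
fully restores healthy release while everything else is inert:

```
 combination  E(combo)  min sub E  argmin   I_GHSA
         T12     0.333      0.000      T2   -0.333
         T13     0.333      0.333      T1    0.000
         T23     0.333      0.000      T2   -0.333
        T123     0.333      0.000      T2   -0.333
```

Every combination containing the restoring drug scores negative (the
combination only loses ground relative to `T2` alone, `E = 0`), while `T13`
— two equally ineffective drugs — scores exactly 0: no gain, no loss.  The
`examples/` directory walks through each capability the same way:
simulation, QC, the Q1/Q2/Q3 ratios, GHSA, clustering with subset search,
and resampling validation.

A thin CLI wraps the same library calls:

```sh
combsec simulate --out plate.csv --seed 3
combsec run --input plate.csv --out results/ --nv 1000 --seed 1
```

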