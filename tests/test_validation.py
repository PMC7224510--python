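"""Leave-one-out resampling, five-number summaries, partition stability."""

import numpy as np
import pytest

from combsec import (
    FixtureSpec,
    GHSASummary,
    StateReplicates,
    TreatmentCode,
    collapse_replicates,
    dominant_centroids,
    generate_plate,
    generate_validation_datasets,
    ground_truth,
    partition_frequencies,
    restoration_matrix,
    run_validation,
    summarize_ghsa,
)
from combsec.errors import QCError
from combsec.validation import ValidationRun


class TestGenerateValidationDatasets:
    def test_each_state_loses_exactly_one_replicate(self, small_plate):
        states = small_plate.states(include_blanks=False)
        for ds in generate_validation_datasets(small_plate, n_v=5, seed=1):
            reduced = ds.plate.states(include_blanks=False)
            assert ds.plate.n_wells == small_plate.n_wells - len(states)
            for state, ws in states.items():
                assert len(reduced[state]) == len(ws) - 1

    def test_two_replicates_keep_exactly_one(self):
        spec = FixtureSpec(
            n_stimulations=1, d=3, replicates=StateReplicates.uniform(2), seed=1
        )
        plate = generate_plate(spec)
        for ds in generate_validation_datasets(plate, n_v=3, seed=0):
            for state, kept in ds.kept_replicates.items():
                assert len(kept) == 1

    def test_four_replicates_keep_three(self):
        spec = FixtureSpec(
            n_stimulations=1, d=3, replicates=StateReplicates.uniform(4), seed=1
        )
        plate = generate_plate(spec)
        ds = generate_validation_datasets(plate, n_v=1, seed=0)[0]
        assert all(len(k) == 3 for k in ds.kept_replicates.values())

    def test_zero_runs_empty_sequence(self, small_plate):
        assert generate_validation_datasets(small_plate, n_v=0, seed=0) == []

    def test_single_replicate_state_named_in_error(self, small_plate):
        # drop one replicate of one state permanently
        target = small_plate.wells[0]
        wells = [
            w for w in small_plate.wells
            if not (w.state == target.state and w.replicate != target.replicate)
        ]
        plate = small_plate.with_wells(wells)
        with pytest.raises(QCError, match="at least two intra-plate replicates"):
            generate_validation_datasets(plate, n_v=1, seed=0)

    def test_deterministic_under_seed(self, small_plate):
        a = generate_validation_datasets(small_plate, n_v=4, seed=9)
        b = generate_validation_datasets(small_plate, n_v=4, seed=9)
        for da, db in zip(a, b):
            assert da.left_out == db.left_out

    def test_exhaustive_enumeration_is_complete(self):
        spec = FixtureSpec(
            n_drugs=2, n_stimulations=1, d=3,
            replicates=StateReplicates.uniform(2), seed=1,
        )
        plate = generate_plate(spec)
        n_states = len(plate.states(include_blanks=False))
        datasets = generate_validation_datasets(plate, n_v=0, seed=0, exhaustive=True)
        assert len(datasets) == 2**n_states
        configs = {tuple(sorted(ds.left_out.items())) for ds in datasets}
        assert len(configs) == len(datasets)

    def test_leave_out_frequency_is_uniform(self):
        """Each of m replicates is left out with frequency 1/m +- 3 SE."""
        spec = FixtureSpec(
            n_drugs=1, n_stimulations=1, d=2,
            replicates=StateReplicates.uniform(4), seed=1,
        )
        plate = generate_plate(spec)
        n_v = 2000
        datasets = generate_validation_datasets(plate, n_v=n_v, seed=3)
        state = next(iter(plate.states(include_blanks=False)))
        counts = {}
        for ds in datasets:
            counts[ds.left_out[state]] = counts.get(ds.left_out[state], 0) + 1
        p = 1 / 4
        se = np.sqrt(p * (1 - p) / n_v)
        for c in counts.values():
            assert abs(c / n_v - p) <= 3 * se


class TestSummaries:
    def _runs_with_indices(self, values_per_run):
        from combsec.ghsa import GHSAResult

        combo = TreatmentCode([1, 2])
        runs = []
        for i, v in enumerate(values_per_run, 1):
            res = GHSAResult(combo, 0, v, TreatmentCode([1]), 0.0, v)
            runs.append(ValidationRun(i, {}, [res], None, "{p}", "{p}"))
        return runs

    def test_degenerate_distribution(self):
        runs = self._runs_with_indices([0.25] * 10)
        (summary,) = summarize_ghsa(runs)
        assert summary.five_numbers == (0.25,) * 5

    def test_linear_interpolation_quartiles(self):
        values = [-0.2, -0.1, -0.3, -0.25]
        runs = self._runs_with_indices(values)
        (summary,) = summarize_ghsa(runs)
        expected = tuple(np.percentile(np.array(values), [0, 25, 50, 75, 100]))
        assert summary.five_numbers == pytest.approx(expected)
        assert summary.five_numbers[0] == -0.3 and summary.five_numbers[4] == -0.1

    def test_summary_ordering_enforced(self):
        with pytest.raises(ValueError, match="unordered"):
            GHSASummary(TreatmentCode([1, 2]), (0.5, 0.1, 0.2, 0.3, 0.4))

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            summarize_ghsa([])

    def test_planted_antagonism_gives_all_negative_five_numbers(self):
        """A combination whose parts restore but which itself does nothing
        has its entire sampling distribution below zero — the decision rule
        for calling a combination antagonistic."""
        spec = FixtureSpec(
            n_stimulations=1,
            d=8,
            replicates=StateReplicates.uniform(3),
            treatment_effects={TreatmentCode([2]): 1.0, TreatmentCode([3]): 1.0},
            noise_sd=0.08,
            seed=13,
        )
        plate = generate_plate(spec)
        runs = run_validation(plate, stimulation=1, n_v=200, seed=2)
        summary = {s.combination.label: s for s in summarize_ghsa(runs)}
        assert summary["T23"].five_numbers[4] < 0  # max below zero

    def test_bounded_five_numbers(self, small_plate):
        runs = run_validation(small_plate, stimulation=1, n_v=20, seed=0)
        for s in summarize_ghsa(runs):
            assert all(-1 <= v <= 1 for v in s.five_numbers)
            assert all(
                s.five_numbers[i] <= s.five_numbers[i + 1] + 1e-12 for i in range(4)
            )


class TestPartitionFrequencies:
    def test_identical_replicates_dominant_at_100(self, noise_free_spec):
        plate = generate_plate(noise_free_spec)
        runs = run_validation(plate, stimulation=1, n_v=30, seed=4)
        freq = partition_frequencies(runs)
        assert len(freq) == 1 and freq.loc[0, "percent"] == 100.0

    def test_percentages_sum_to_100(self, small_plate):
        runs = run_validation(small_plate, stimulation=1, n_v=25, seed=5)
        freq = partition_frequencies(runs)
        assert freq["percent"].sum() == pytest.approx(100.0)
        assert freq["percent"].is_monotonic_decreasing

    def test_synthetic_split_60_40(self):
        runs = []
        for i in range(1000):
            label = "{a}|{b}" if i < 600 else "{a,b}"
            runs.append(ValidationRun(i + 1, {}, [], None, label, label))
        freq = partition_frequencies(runs)
        assert list(freq["percent"]) == [60.0, 40.0]

    def test_noise_never_helps_stability(self):
        """The dominant partition frequency is non-increasing along a
        replicate-noise ladder (matched seeds)."""
        freqs = []
        for noise in (0.0, 0.15, 0.6):
            spec = FixtureSpec(
                n_stimulations=1,
                d=5,
                replicates=StateReplicates.uniform(3),
                treatment_effects={TreatmentCode([1]): 1.0},
                noise_sd=noise,
                seed=21,
            )
            runs = run_validation(generate_plate(spec), 1, n_v=60, seed=6)
            freqs.append(partition_frequencies(runs).loc[0, "percent"])
        assert freqs[0] >= freqs[1] >= freqs[2]


class TestDominantCentroids:
    def test_single_run_dominant_is_that_partition(self, small_plate):
        runs = run_validation(small_plate, stimulation=1, n_v=1, seed=7)
        tree = dominant_centroids(small_plate, runs, stimulation=1)
        labels = {frozenset(c.members) for c in tree.clusters}
        from combsec.clustering import partition_structure

        assert labels == set(partition_structure(runs[0].tree))

    def test_noise_free_centroids_equal_planted_prototypes(self, noise_free_spec):
        plate = generate_plate(noise_free_spec)
        truth = ground_truth(noise_free_spec)
        runs = run_validation(plate, stimulation=1, n_v=10, seed=8)
        tree = dominant_centroids(plate, runs, stimulation=1)
        for c in tree.clusters:
            proto = np.mean([truth.q3[m] for m in c.members], axis=0)
            np.testing.assert_allclose(c.centroid, proto, atol=1e-9)

    def test_centroids_use_all_replicates(self, small_plate):
        runs = run_validation(small_plate, stimulation=1, n_v=5, seed=9)
        tree = dominant_centroids(small_plate, runs, stimulation=1)
        q3_full = restoration_matrix(collapse_replicates(small_plate), 1)
        for c in tree.clusters:
            np.testing.assert_allclose(
                c.centroid, q3_full.loc[list(c.members)].mean(axis=0), atol=1e-12
            )

    def test_noisy_centroid_near_planted_prototype(self):
        spec = FixtureSpec(
            n_stimulations=1,
            d=6,
            replicates=StateReplicates.uniform(4),
            treatment_effects={TreatmentCode([1]): 1.0},
            noise_sd=0.05,
            seed=30,
        )
        plate = generate_plate(spec)
        truth = ground_truth(spec)
        runs = run_validation(plate, stimulation=1, n_v=30, seed=10)
        tree = dominant_centroids(plate, runs, stimulation=1)
        for c in tree.clusters:
            proto = np.mean([truth.q3[m] for m in c.members], axis=0)
            assert np.max(np.abs(c.centroid - proto)) < 0.05


class TestDeterminism:
    def test_fixed_seed_reproduces_everything(self, small_plate):
        r1 = run_validation(small_plate, 1, n_v=15, seed=123)
        r2 = run_validation(small_plate, 1, n_v=15, seed=123)
        assert [r.partition_label for r in r1] == [r.partition_label for r in r2]
        v1 = [g.index_value for r in r1 for g in r.ghsa]
        v2 = [g.index_value for r in r2 for g in r.ghsa]
        assert v1 == v2
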