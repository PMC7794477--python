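"""Melt-curve simulation, peak calling, partitioning, counting, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltmark import (
    Epiallele,
    MeltModel,
    WellCall,
    WellSpec,
    call_well,
    count_methylated_fragments,
    density_of_tm,
    equivalent_plasma_volume,
    normalized_fragments,
    partition_copies,
    poisson_corrected_count,
    simulate_well,
    spikein_sensitivity,
    tm_of_density,
)


def local_maxima(signal):
    return [
        i
        for i in range(1, len(signal) - 1)
        if signal[i] > signal[i - 1] and signal[i] >= signal[i + 1]
        and signal[i] > 0.05 * signal.max()
    ]


def expected_occupied(n_copies, n_wells):
    """Closed-form mean occupied wells under uniform random assignment."""
    return n_wells * (1 - (1 - 1 / n_wells) ** n_copies)


def occupancy_pmf(n_copies, n_wells):
    """Exact occupancy distribution via Stirling partition numbers (DP)."""
    # S[n][k]: Stirling numbers of the second kind
    S = [[0] * (n_copies + 1) for _ in range(n_copies + 1)]
    S[0][0] = 1
    for n in range(1, n_copies + 1):
        for k in range(1, n + 1):
            S[n][k] = k * S[n - 1][k] + S[n - 1][k - 1]
    pmf = {}
    for k in range(0, min(n_copies, n_wells) + 1):
        pmf[k] = (
            math.comb(n_wells, k) * S[n_copies][k] * math.factorial(k)
            / n_wells**n_copies
        )
    return pmf


class TestTmDensityMapping:
    def test_unmethylated_identity(self, melt_model):
        assert tm_of_density(0, melt_model) == melt_model.tm_u

    def test_linear_closed_form(self):
        model = MeltModel(tm_u=74.0, delta_per_cpg=0.4)
        assert tm_of_density(14, model) == pytest.approx(79.6)

    def test_round_trip_exhaustive(self, melt_model):
        for d in range(0, 15):
            tm = tm_of_density(d, melt_model)
            assert density_of_tm(tm, melt_model, clip=False) == d

    def test_monotone_in_density(self, melt_model):
        tms = [tm_of_density(d, melt_model) for d in range(15)]
        assert all(b > a for a, b in zip(tms, tms[1:]))

    def test_out_of_range_errors(self, melt_model):
        with pytest.raises(ValueError):
            tm_of_density(15, melt_model)
        with pytest.raises(ValueError):
            tm_of_density(-1, melt_model)


class TestSimulateWell:
    def test_background_only_single_peak_at_tmu(self, melt_model):
        curve = simulate_well(WellSpec(), melt_model, noise_sd=0.0)
        peaks = local_maxima(curve.signal)
        assert len(peaks) == 1
        assert curve.temperatures[peaks[0]] == pytest.approx(melt_model.tm_u, abs=melt_model.grid_step / 2)

    def test_fully_methylated_two_peaks_at_analytic_centers(self, melt_model):
        spec = WellSpec(methylated=(Epiallele(14),))
        curve = simulate_well(spec, melt_model, noise_sd=0.0)
        peaks = local_maxima(curve.signal)
        assert len(peaks) == 2
        second = curve.temperatures[peaks[1]]
        expected = melt_model.tm_u + 14 * melt_model.delta_per_cpg
        assert second == pytest.approx(expected, abs=melt_model.grid_step / 2)

    def test_seed_determinism(self, melt_model):
        spec = WellSpec(methylated=(Epiallele(5),))
        a = simulate_well(spec, melt_model, noise_sd=0.05, seed=42)
        b = simulate_well(spec, melt_model, noise_sd=0.05, seed=42)
        c = simulate_well(spec, melt_model, noise_sd=0.05, seed=43)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_empty_spec_warns_flat(self, melt_model):
        with pytest.warns(UserWarning, match="empty well"):
            curve = simulate_well(WellSpec(background_copies=0), melt_model)
        assert curve.signal.max() == 0.0


class TestCallWell:
    def test_background_only_not_methylated(self, melt_model):
        curve = simulate_well(WellSpec(), melt_model, noise_sd=0.0)
        call = call_well(curve, melt_model)
        assert call.amplified and not call.is_methylated
        assert call.secondary_peak_tm is None

    def test_forward_then_inverse_density(self, melt_model):
        spec = WellSpec(methylated=(Epiallele(7),))
        call = call_well(simulate_well(spec, melt_model, noise_sd=0.0), melt_model)
        assert call.is_methylated
        assert call.inferred_density == 7

    def test_flat_curve_is_no_amplification(self, melt_model):
        with pytest.warns(UserWarning):
            curve = simulate_well(WellSpec(background_copies=0), melt_model)
        call = call_well(curve, melt_model)
        assert not call.amplified and not call.is_methylated

    def test_hottest_secondary_reported_for_multiple_epialleles(self, melt_model):
        spec = WellSpec(methylated=(Epiallele(4), Epiallele(12)))
        call = call_well(simulate_well(spec, melt_model, noise_sd=0.0), melt_model)
        assert call.inferred_density == 12

    def test_noisy_calls_correct_at_density_two_or_more(self, melt_model):
        # >= 99% correct (methylated + exact density) at noise_sd 0.05
        # over 1,000 seeded replicates
        rng = np.random.default_rng(99)
        densities = rng.integers(2, 15, size=1000)
        correct = 0
        for i, d in enumerate(densities):
            spec = WellSpec(methylated=(Epiallele(int(d)),))
            curve = simulate_well(spec, melt_model, noise_sd=0.05, seed=10_000 + i)
            call = call_well(curve, melt_model)
            correct += call.is_methylated and call.inferred_density == d
        assert correct / 1000 >= 0.99

    def test_invariants_on_call_object(self):
        with pytest.raises(ValueError):
            WellCall(primary_peak_tm=74.0, secondary_peak_tm=None, is_methylated=True)
        with pytest.raises(ValueError):
            WellCall(primary_peak_tm=80.0, secondary_peak_tm=74.0, is_methylated=True)


class TestPartitionCopies:
    def test_zero_copies(self):
        assert partition_copies(0, 12, seed=1).sum() == 0

    @given(st.integers(0, 40), st.integers(1, 24), st.integers(0, 2**20))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_counts_sum_preserved(self, n_copies, n_wells, seed):
        counts = partition_copies(n_copies, n_wells, seed=seed)
        assert counts.sum() == n_copies
        assert len(counts) == n_wells

    @pytest.mark.parametrize("copies,expected", [(3, 2.757), (5, 4.233)])
    def test_occupancy_mean_matches_closed_form(self, copies, expected):
        rng = np.random.default_rng(2024)
        draws = rng.multinomial(copies, np.full(12, 1 / 12), size=10_000)
        mean_occ = np.count_nonzero(draws, axis=1).mean()
        closed = expected_occupied(copies, 12)
        assert closed == pytest.approx(expected, abs=5e-4)
        assert mean_occ == pytest.approx(closed, rel=0.01)

    def test_zero_wells_errors(self):
        with pytest.raises(ValueError):
            partition_copies(3, 0)


class TestCountingAndNormalization:
    def test_direct_count(self):
        calls = [WellCall(primary_peak_tm=74.0)] * 9 + [
            WellCall(primary_peak_tm=74.0, secondary_peak_tm=79.0, is_methylated=True)
        ] * 3
        assert count_methylated_fragments(calls) == 3

    def test_all_unmethylated(self):
        assert count_methylated_fragments([WellCall(primary_peak_tm=74.0)] * 12) == 0

    def test_no_amplification_excluded(self):
        calls = [
            WellCall(primary_peak_tm=None, amplified=False),
            WellCall(primary_peak_tm=74.0, secondary_peak_tm=79.0, is_methylated=True),
        ]
        assert count_methylated_fragments(calls) == 1

    def test_end_to_end_noiseless_equals_occupied_wells(self, melt_model):
        for seed in range(5):
            counts = partition_copies(4, 12, seed=seed)
            calls = [
                call_well(
                    simulate_well(
                        WellSpec(methylated=tuple(Epiallele(14) for _ in range(int(k)))),
                        melt_model,
                        noise_sd=0.0,
                    ),
                    melt_model,
                )
                for k in counts
            ]
            assert count_methylated_fragments(calls) == np.count_nonzero(counts)

    def test_equivalent_volume_arithmetic(self):
        assert equivalent_plasma_volume(4.0, 0.5) == 2.0
        assert equivalent_plasma_volume(1.5, 1.0) == 1.5
        # beta-actin qPCR: 400 of 1,000 targets loaded -> fraction 0.4
        assert equivalent_plasma_volume(3.0, 400 / 1000) == pytest.approx(1.2)

    def test_fraction_above_one_errors(self):
        with pytest.raises(ValueError, match="elution"):
            equivalent_plasma_volume(3.0, 1.2)

    def test_normalized_fragments(self):
        assert normalized_fragments(10, 2.0) == 5.0
        assert normalized_fragments(0, 1.7) == 0.0
        with pytest.raises(ValueError):
            normalized_fragments(1, 0.0)

    @given(st.integers(0, 100), st.floats(0.1, 10, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_normalization_scale_equivariance(self, count, volume):
        assert normalized_fragments(count, 2 * volume) == pytest.approx(
            normalized_fragments(count, volume) / 2
        )

    def test_poisson_correction(self):
        # lambda-hat = -W ln(1 - k/W); saturated plate is unbounded
        assert poisson_corrected_count(0, 12) == 0.0
        assert poisson_corrected_count(3, 12) == pytest.approx(-12 * np.log(1 - 3 / 12))
        assert poisson_corrected_count(12, 12) == np.inf


class TestSpikeIn:
    def test_noiseless_detected_equals_occupied(self):
        res = spikein_sensitivity(3, seed=5)
        assert res.detected == res.occupied
        expected_mae = np.mean([abs(o - 3) for o in res.occupied])
        assert res.mean_absolute_error == pytest.approx(expected_mae)

    def test_zero_copies(self):
        res = spikein_sensitivity(0, seed=1)
        assert set(res.detected) == {0}
        assert res.mean_absolute_error == 0.0

    def test_detection_saturation(self):
        for seed in range(10):
            res = spikein_sensitivity(5, seed=seed)
            assert all(d <= min(12, 5) for d in res.detected)

    @pytest.mark.parametrize("copies", [3, 5])
    def test_mae_converges_to_occupancy_expectation(self, copies):
        # MAE over many seeded reps ~ E|occupied - copies| from the exact pmf
        pmf = occupancy_pmf(copies, 12)
        expected = sum(p * abs(k - copies) for k, p in pmf.items())
        maes = [
            spikein_sensitivity(copies, reps=5, seed=s).mean_absolute_error
            for s in range(40)  # 200 replicates total
        ]
        assert np.mean(maes) == pytest.approx(expected, abs=0.08)
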