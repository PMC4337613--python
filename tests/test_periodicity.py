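import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mpskel import (
    AutocorrResult,
    DegenerateInputError,
    InvalidArgumentError,
    LatticeConfig,
    autocorr_amplitude,
    autocorrelation,
    average_autocorrelation,
    density_profile,
    dominant_period,
    periodicity_vs_distance,
    profile_from_localizations,
    simulate_lattice,
    subsample_robustness,
)


def brute_force_autocorr(counts, max_lag_bins):
    """Independent O(n^2) oracle for the biased normalized autocorrelation."""
    d = counts - counts.mean()
    var = np.mean(d * d)
    n = len(counts)
    out = np.zeros(max_lag_bins + 1)
    for lag in range(max_lag_bins + 1):
        acc = 0.0
        for s in range(n - lag):
            acc += d[s] * d[s + lag]
        out[lag] = acc / (n * var)
    return out


class TestDensityProfile:
    def test_three_points_one_per_bin(self):
        prof = density_profile([5.0, 15.0, 25.0], 10.0, (0.0, 30.0))
        assert prof.counts.tolist() == [1.0, 1.0, 1.0]

    def test_empty_input_gives_zero_profile(self):
        prof = density_profile([], 10.0, (0.0, 100.0))
        assert prof.counts.sum() == 0 and prof.n_bins == 10

    def test_counts_conserved_when_range_covers(self, rng):
        pos = rng.uniform(0, 5000, 777)
        prof = density_profile(pos, 10.0)
        assert prof.counts.sum() == 777

    def test_uniform_positions_pass_chi_square(self, rng):
        pos = rng.uniform(0, 10000, 1000)
        prof = density_profile(pos, 10.0, (0.0, 10000.0))
        _, p = stats.chisquare(prof.counts)
        assert p > 0.001

    def test_bad_bin_rejected(self):
        with pytest.raises(InvalidArgumentError):
            density_profile([1.0], 0.0)

    @given(n=st.integers(1, 300), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_sum_conservation_property(self, n, seed):
        pos = np.random.default_rng(seed).uniform(0, 2000, n)
        assert density_profile(pos, 7.0).counts.sum() == n


class TestAutocorrelation:
    def test_matches_brute_force_oracle(self, rng):
        counts = rng.poisson(3.0, 50).astype(float)
        prof = density_profile([], 10.0, (0.0, 500.0))
        prof = type(prof)(10.0, 0.0, counts)
        ac = autocorrelation(prof, max_lag_nm=250.0)
        oracle = brute_force_autocorr(counts, 25)
        assert np.allclose(ac.ac, oracle, atol=1e-10)

    def test_zero_lag_is_exactly_one(self, rng):
        from mpskel import DensityProfile
        prof = DensityProfile(10.0, 0.0, rng.poisson(2.0, 800).astype(float))
        assert autocorrelation(prof, 1000.0).ac[0] == 1.0

    def test_cosine_profile_recovers_cosine_autocorrelation(self):
        from mpskel import DensityProfile
        s = np.arange(0, 30000, 10.0)
        prof = DensityProfile(10.0, 0.0, 10 + 5 * np.cos(2 * np.pi * s / 190.0))
        ac = autocorrelation(prof, 1000.0)
        assert ac.first_peak_lag_nm == 190.0
        assert ac.ac[19] == pytest.approx(np.cos(2 * np.pi * 190 / 190), abs=0.02)
        assert ac.amplitude == pytest.approx(2.0, abs=0.05)

    def test_white_noise_stays_under_bound(self, rng):
        from mpskel import DensityProfile
        prof = DensityProfile(10.0, 0.0, rng.normal(10, 1, 3000))
        ac = autocorrelation(prof, 1000.0)
        bound = 4.0 / np.sqrt(3000)
        assert np.mean(np.abs(ac.ac[1:]) <= bound) >= 0.99

    def test_constant_profile_is_degenerate(self):
        from mpskel import DensityProfile
        prof = DensityProfile(10.0, 0.0, np.full(500, 4.0))
        with pytest.raises(DegenerateInputError):
            autocorrelation(prof, 500.0)

    def test_scale_invariance(self, straight_trace, default_lattice):
        from mpskel import DensityProfile
        prof = profile_from_localizations(default_lattice, straight_trace)
        scaled = DensityProfile(prof.bin_size_nm, prof.s0_nm, prof.counts * 7.5)
        a = autocorrelation(prof, 1000.0)
        b = autocorrelation(scaled, 1000.0)
        assert np.allclose(a.ac, b.ac, atol=1e-12)
        assert a.amplitude == pytest.approx(b.amplitude, abs=1e-12)

    def test_translation_invariance(self, straight_trace, default_lattice):
        base = profile_from_localizations(default_lattice, straight_trace)
        shifted_tab = default_lattice
        from mpskel import LocalizationTable
        shifted_tab = LocalizationTable.from_arrays(
            default_lattice.x_nm + 500.0, default_lattice.y_nm, default_lattice.z_nm)
        long_trace = type(straight_trace)(np.array([[0.0, 0, 0], [31000.0, 0, 0]]))
        shifted = profile_from_localizations(shifted_tab, long_trace, s_range=(500.0, 30500.0))
        a = autocorrelation(base, 1000.0)
        b = autocorrelation(shifted, 1000.0)
        assert abs(a.first_peak_lag_nm - b.first_peak_lag_nm) <= a.bin_size_nm
        spec_a = dominant_period(base).dominant_period_nm
        spec_b = dominant_period(shifted).dominant_period_nm
        assert abs(spec_a - spec_b) < 2.0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_bounded_by_one_property(self, seed):
        from mpskel import DensityProfile
        counts = np.random.default_rng(seed).poisson(2.0, 400).astype(float)
        if counts.std() == 0:
            return
        ac = autocorrelation(DensityProfile(5.0, 0.0, counts), 500.0)
        assert np.all(np.abs(ac.ac) <= 1.0 + 1e-12)


class TestAmplitude:
    def test_ideal_cosine_amplitude_is_two(self):
        lags = np.arange(0, 1000.0, 10.0)
        ac = AutocorrResult(lags, np.cos(2 * np.pi * lags / 190.0), 10.0)
        amp, peak = autocorr_amplitude(ac)
        assert peak == 190.0
        # valleys are quantized to the 10-nm lag grid, so slightly above -1
        assert amp == pytest.approx(2.0, abs=0.02)

    def test_flat_curve_scores_zero(self):
        lags = np.arange(0, 1000.0, 10.0)
        vals = np.zeros_like(lags)
        vals[0] = 1.0
        amp, _ = autocorr_amplitude(AutocorrResult(lags, vals, 10.0))
        assert amp == 0.0

    def test_band_outside_lags_rejected(self):
        lags = np.arange(0, 200.0, 10.0)
        with pytest.raises(InvalidArgumentError):
            autocorr_amplitude(AutocorrResult(lags, np.zeros_like(lags), 10.0))


class TestDominantPeriod:
    def test_noiseless_comb_gives_190(self, straight_trace):
        cfg = LatticeConfig(background_fraction=0.0, loc_precision_nm=0.0,
                            ring_jitter_nm=0.0, seed=2)
        locs = simulate_lattice(straight_trace, cfg)
        prof = profile_from_localizations(locs, straight_trace)
        spec = dominant_period(prof)
        assert spec.dominant_period_nm == pytest.approx(190.0, abs=2.0)
        assert not spec.low_confidence

    def test_stronger_comb_wins(self):
        from mpskel import DensityProfile
        s = np.arange(0, 30000, 10.0)
        counts = 20 + 8 * np.cos(2 * np.pi * s / 190) + 2 * np.cos(2 * np.pi * s / 150)
        spec = dominant_period(DensityProfile(10.0, 0.0, counts))
        assert spec.dominant_period_nm == pytest.approx(190.0, abs=2.0)

    def test_white_noise_flagged_low_confidence(self, rng):
        from mpskel import DensityProfile
        prof = DensityProfile(10.0, 0.0, rng.poisson(5.0, 3000).astype(float))
        spec = dominant_period(prof)
        assert spec.low_confidence

    def test_all_zero_profile_degenerate(self):
        from mpskel import DensityProfile
        with pytest.raises(DegenerateInputError):
            dominant_period(DensityProfile(10.0, 0.0, np.zeros(3000)))


class TestAveraging:
    def test_idempotent_on_identical_inputs(self, straight_trace, default_lattice):
        prof = profile_from_localizations(default_lattice, straight_trace)
        ac = autocorrelation(prof, 1000.0)
        avg = average_autocorrelation([ac] * 5)
        assert np.allclose(avg.ac, ac.ac)
        assert avg.amplitude == pytest.approx(ac.amplitude, abs=1e-12)

    def test_curve_plus_negation_cancels(self):
        lags = np.arange(0, 1000.0, 10.0)
        vals = np.cos(2 * np.pi * lags / 190.0)
        avg = average_autocorrelation([
            AutocorrResult(lags, vals, 10.0), AutocorrResult(lags, -vals, 10.0)])
        assert np.allclose(avg.ac, 0.0)
        assert avg.amplitude == 0.0

    def test_mixed_bin_sizes_rejected(self):
        lags = np.arange(0, 1000.0, 10.0)
        a = AutocorrResult(lags, np.zeros_like(lags), 10.0)
        b = AutocorrResult(lags * 2, np.zeros_like(lags), 20.0)
        with pytest.raises(InvalidArgumentError):
            average_autocorrelation([a, b])

    def test_averaging_reduces_amplitude_variance(self, straight_trace):
        amps, group_amps = [], []
        acs = []
        for seed in range(20):
            locs = simulate_lattice(straight_trace, LatticeConfig(seed=seed))
            ac = autocorrelation(profile_from_localizations(locs, straight_trace), 1000.0)
            acs.append(ac)
            amps.append(ac.amplitude)
        for g in range(4):
            group_amps.append(average_autocorrelation(acs[5 * g:5 * (g + 1)]).amplitude)
        assert np.std(group_amps) < np.std(amps)


class TestSubsampling:
    def test_full_count_row_is_reference(self, straight_trace, default_lattice):
        n = len(default_lattice)
        table = subsample_robustness(default_lattice, straight_trace, [n], n_reps=3, seed=0)
        ref = table[table.is_reference].iloc[0]
        assert ref.sd_amplitude == 0.0
        ac = autocorrelation(
            profile_from_localizations(default_lattice, straight_trace), 1000.0)
        assert ref.mean_amplitude == pytest.approx(ac.amplitude, abs=1e-12)

    def test_oversized_target_rejected(self, straight_trace, default_lattice):
        with pytest.raises(InvalidArgumentError):
            subsample_robustness(default_lattice, straight_trace,
                                 [len(default_lattice) + 1], 2, 0)

    def test_fixed_seed_reproducible(self, straight_trace, default_lattice):
        n = len(default_lattice)
        a = subsample_robustness(default_lattice, straight_trace, [n // 2], 5, seed=3)
        b = subsample_robustness(default_lattice, straight_trace, [n // 2], 5, seed=3)
        assert a.equals(b)


class TestPeriodicityVsDistance:
    def test_single_segment_equals_whole_trace(self, straight_trace, default_lattice):
        table = periodicity_vs_distance(default_lattice, straight_trace, 30.0)
        assert len(table) == 1
        prof = profile_from_localizations(default_lattice, straight_trace)
        whole = autocorrelation(prof, 390.0)
        assert table.amplitude.iloc[0] == pytest.approx(whole.amplitude, abs=1e-12)

    def test_segment_longer_than_trace_rejected(self, straight_trace, default_lattice):
        with pytest.raises(InvalidArgumentError):
            periodicity_vs_distance(default_lattice, straight_trace, 31.0)

    def test_decaying_lattice_loses_periodicity_distally(self, straight_trace):
        rhos = []
        for seed in range(10):
            cfg = LatticeConfig(density_decay_length_um=6.0, seed=seed)
            locs = simulate_lattice(straight_trace, cfg)
            t = periodicity_vs_distance(locs, straight_trace, 10.0)
            rho, _ = stats.spearmanr(t.segment_center_s_nm, t.amplitude)
            rhos.append(rho)
        assert np.median(rhos) < 0

    def test_uniform_lattice_shows_no_trend(self, straight_trace):
        diffs = []
        for seed in range(10):
            locs = simulate_lattice(straight_trace, LatticeConfig(seed=seed))
            t = periodicity_vs_distance(locs, straight_trace, 10.0)
            diffs.append(t.amplitude.iloc[-1] - t.amplitude.iloc[0])
        assert abs(np.median(diffs)) < 0.15
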