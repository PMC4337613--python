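import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from mpskel import (
    CompartmentMasks,
    FrapSimConfig,
    InvalidArgumentError,
    LatticeConfig,
    LiveSeriesConfig,
    PolarityImageConfig,
    frap_preset,
    intensity_ratio,
    make_trace,
    polarity_preset,
    project_onto_trace,
    simulate_frap,
    simulate_irregular,
    simulate_lattice,
    simulate_live_series,
    simulate_polarity_image,
)


class TestLattice:
    def test_same_seed_is_bit_identical(self, straight_trace):
        cfg = LatticeConfig(seed=11)
        a = simulate_lattice(straight_trace, cfg)
        b = simulate_lattice(straight_trace, cfg)
        assert a.equals(b)

    def test_total_count_matches_poisson_expectation(self, straight_trace, default_lattice):
        # 158 rings x 30 locs each, inflated by the 10% background share
        expected = 158 * 30 / (1 - 0.10)
        sd = math.sqrt(expected)
        assert abs(len(default_lattice) - expected) < 3 * sd

    def test_noiseless_limit_is_an_exact_comb(self, straight_trace):
        cfg = LatticeConfig(background_fraction=0.0, loc_precision_nm=0.0,
                            ring_jitter_nm=0.0, seed=4)
        locs = simulate_lattice(straight_trace, cfg)
        s = project_onto_trace(locs, straight_trace, 400.0).s_nm
        residue = np.mod(s, 190.0)
        # all axial positions are one global phase plus multiples of the period
        assert np.ptp(residue) < 1e-6

    def test_ground_truth_labels_partition_the_table(self, default_lattice):
        bg = default_lattice.truth_ring == -1
        assert bg.sum() + (~bg).sum() == len(default_lattice)
        frac = bg.mean()
        assert 0.05 < frac < 0.15  # expected 10% background share

    def test_short_trace_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_lattice(make_trace(0.3, 0.0), LatticeConfig())

    def test_density_decay_reduces_distal_occupancy(self, straight_trace):
        cfg = LatticeConfig(density_decay_length_um=10.0, background_fraction=0.0, seed=8)
        locs = simulate_lattice(straight_trace, cfg)
        s = project_onto_trace(locs, straight_trace).s_nm
        prox = (s < 10000).sum()
        dist = (s >= 20000).sum()
        assert dist < 0.5 * prox  # e-folding over 10 µm


class TestIrregular:
    def test_deterministic(self, straight_trace):
        cfg = LatticeConfig(seed=9)
        assert simulate_irregular(straight_trace, cfg).equals(
            simulate_irregular(straight_trace, cfg))

    def test_no_ring_labels(self, straight_trace):
        locs = simulate_irregular(straight_trace, LatticeConfig(seed=9))
        assert np.all(locs.truth_ring == -1)

    def test_marginal_rate_matches_lattice(self, straight_trace):
        # two-sample rate test over 50 seeds at alpha = 0.01
        lat = [len(simulate_lattice(straight_trace, LatticeConfig(seed=s))) for s in range(50)]
        irr = [len(simulate_irregular(straight_trace, LatticeConfig(seed=s + 1000)))
               for s in range(50)]
        _, p = stats.ttest_ind(lat, irr)
        assert p > 0.01


class TestLiveSeries:
    def test_frames_span_the_movie(self, straight_trace):
        cfg = LiveSeriesConfig(n_frames=100, lattice=LatticeConfig(seed=3))
        locs = simulate_live_series(straight_trace, cfg)
        assert locs.frame.min() >= 1 and locs.frame.max() <= 100
        assert simulate_live_series(straight_trace, cfg).equals(locs)

    def test_single_frame_movie_rejected(self, straight_trace):
        with pytest.raises(InvalidArgumentError):
            simulate_live_series(straight_trace, LiveSeriesConfig(n_frames=1))

    def test_drift_translates_late_localizations(self, straight_trace):
        lat = LatticeConfig(seed=6, background_fraction=0.0, phase_nm=50.0)
        static = simulate_live_series(straight_trace, LiveSeriesConfig(
            n_frames=400, phase_drift_nm_per_s=0.0, lattice=lat))
        drifted = simulate_live_series(straight_trace, LiveSeriesConfig(
            n_frames=400, phase_drift_nm_per_s=1.0, lattice=lat))
        # same rng stream, so positions differ exactly by the per-frame shift
        # (away from the distal end, where the trace clamps the coordinate)
        interior = static.x_nm < 29000
        shift = (drifted.x_nm - static.x_nm)[interior]
        assert np.allclose(shift, (static.frame[interior] - 1) * 1.0, atol=1e-9)


class TestFrapSim:
    def test_noiseless_trace_matches_closed_form_everywhere(self):
        cfg = FrapSimConfig(mobile_fraction=0.6, recovery_halftime_s=80.0,
                            bleach_depth=0.8, acq_bleach_rate_per_s=0.002)
        tr = simulate_frap(cfg)
        env = np.exp(-0.002 * tr.t_s)
        expected = env.copy()
        post = tr.t_s >= tr.t_bleach_s
        tp = tr.t_s[post] - tr.t_bleach_s
        expected[post] = env[post] * (0.2 + 0.8 * 0.6 * (1 - 2.0 ** (-tp / 80.0)))
        assert np.allclose(tr.roi, expected, atol=1e-9)
        assert np.allclose(tr.reference, env, atol=1e-12)

    def test_full_bleach_full_mobility_halftime_point(self):
        cfg = FrapSimConfig(mobile_fraction=1.0, bleach_depth=1.0,
                            recovery_halftime_s=50.0)
        tr = simulate_frap(cfg)
        i = np.searchsorted(tr.t_s, tr.t_bleach_s + 50.0)
        assert tr.roi[i] == pytest.approx(0.5, abs=1e-12)

    def test_immobile_pool_stays_at_bleach_floor(self):
        tr = simulate_frap(FrapSimConfig(mobile_fraction=0.0, bleach_depth=0.9))
        post = tr.t_s >= tr.t_bleach_s
        assert np.allclose(tr.roi[post], 0.1, atol=1e-12)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            FrapSimConfig(mobile_fraction=1.2)
        with pytest.raises(InvalidArgumentError):
            FrapSimConfig(bleach_depth=0.0)

    def test_presets(self):
        hi = frap_preset("high_expression")
        assert hi.mobile_fraction == 0.75 and hi.noise_sd == 0.0
        assert frap_preset("low_expression").mobile_fraction == 0.0
        with pytest.raises(InvalidArgumentError):
            frap_preset("nope")


class TestPolaritySim:
    def test_noiseless_means_are_exact(self):
        cfg = PolarityImageConfig(axon_intensity=200.0, dendrite_intensity=100.0,
                                  background_intensity=0.0, poisson_noise=False)
        sim = simulate_polarity_image(cfg)
        assert sim.image.pixels[sim.axon_mask].mean() == 200.0
        assert sim.image.pixels[sim.dendrite_mask].mean() == 100.0
        res = intensity_ratio(sim.image, CompartmentMasks(
            sim.axon_mask, sim.dendrite_mask), background_subtract=False)
        assert res.ratio == 2.0

    def test_background_only_config(self):
        cfg = PolarityImageConfig(axon_intensity=0.0, dendrite_intensity=0.0,
                                  background_intensity=50.0, poisson_noise=False)
        sim = simulate_polarity_image(cfg)
        assert sim.image.pixels[sim.axon_mask].mean() == 50.0
        assert sim.image.pixels[sim.dendrite_mask].mean() == 50.0

    def test_overlapping_stripes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PolarityImageConfig(axon_rows_px=(10, 60), dendrite_rows_px=(50, 100))

    def test_poisson_ratio_within_delta_method_band(self):
        cfg = dataclasses.replace(polarity_preset("wild_type"), seed=5)
        sim = simulate_polarity_image(cfg)
        res = intensity_ratio(sim.image, CompartmentMasks(
            sim.axon_mask, sim.dendrite_mask, sim.background_mask))
        # delta-method sd of (A-B)/(D-B) with Poisson pixel variances
        n_ax = sim.axon_mask.sum()
        n_de = sim.dendrite_mask.sum()
        n_bg = sim.background_mask.sum()
        mu_a, mu_d, mu_b = 210.0, 110.0, 10.0
        va, vd, vb = mu_a / n_ax, mu_d / n_de, mu_b / n_bg
        da, dd = 1 / (mu_d - mu_b), -(mu_a - mu_b) / (mu_d - mu_b) ** 2
        db = -da - dd
        sd = math.sqrt((da ** 2) * va + (dd ** 2) * vd + (db ** 2) * vb)
        assert abs(res.ratio - 2.0) < 3 * sd
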