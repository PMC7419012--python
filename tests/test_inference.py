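"""Effective coupling, segmental Bayesian grid inference, model averaging."""

import numpy as np
import pytest

from olivenet.inference import (PosteriorGrid, default_likelihood_scale,
                                effective_coupling, fit_cc_mapping,
                                model_average, neuron_posterior,
                                point_estimate, segment_posterior,
                                segment_spikes)
from olivenet.synthetic import SurrogateSpec, surrogate_dataset

from conftest import make_planted_library


class TestEffectiveCoupling:
    def test_printed_condition_means(self):
        # three pharmacological conditions at their mean conductances
        assert effective_coupling(0.1, 0.88, 1.02) == pytest.approx(0.0306, abs=5e-4)
        assert effective_coupling(0.1, 1.19, 1.15) == pytest.approx(0.0328, abs=5e-4)
        assert effective_coupling(0.1, 1.16, 0.72) == pytest.approx(0.0369, abs=5e-4)

    def test_hand_evaluation(self):
        # 0.1 * 0.88 / (2*0.88 + 1.02 + 0.1)
        assert effective_coupling(0.1, 0.88, 1.02) == pytest.approx(
            0.1 * 0.88 / (2 * 0.88 + 1.02 + 0.1))

    def test_no_gap_junction_gives_zero(self):
        assert effective_coupling(0.1, 0.0, 1.0) == 0.0

    def test_monotonicity_and_bound(self):
        g = np.linspace(0.01, 2.0, 50)
        up = effective_coupling(0.1, g, 1.0)
        down = effective_coupling(0.1, 1.0, g)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)
        assert np.all(up < 0.05)  # bounded by g_s / 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            effective_coupling(0.0, 0.0, 0.0)


class TestSegmentation:
    def test_500s_gives_10_segments(self):
        ds = surrogate_dataset(SurrogateSpec(kind="poisson", n_neurons=2,
                                             rate=1.0, duration=500.0, seed=1))
        assert len(segment_spikes(ds)) == 10

    def test_too_short_recording_refused(self):
        ds = surrogate_dataset(SurrogateSpec(kind="poisson", n_neurons=2,
                                             rate=1.0, duration=49.0, seed=1))
        with pytest.raises(ValueError):
            segment_spikes(ds)

    def test_spike_count_conservation_minus_remainder(self):
        ds = surrogate_dataset(SurrogateSpec(kind="poisson", n_neurons=3,
                                             rate=2.0, duration=230.0, seed=2))
        segs = segment_spikes(ds)
        total_in_segments = sum(len(s.trains[0]) for s in segs)
        full = ds.trains[0]
        assert total_in_segments == (full < 200.0).sum()


class TestPosteriors:
    def test_posterior_normalization_enforced(self):
        with pytest.raises(ValueError):
            PosteriorGrid(np.full((3, 3), 0.2), np.arange(3.0), np.arange(3.0))

    def test_mode_at_matching_grid_point(self, planted_library):
        lib = planted_library
        flat = 17 * len(lib.g_c_axis) + 29
        pg = segment_posterior(lib.projections[flat], lib,
                               likelihood_scale=0.05)
        i, j = np.unravel_index(np.argmax(pg.probs), pg.probs.shape)
        assert (i, j) == (17, 29)
        assert pg.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infinite_scale_limit_is_uniform(self, planted_library):
        lib = planted_library
        pg = segment_posterior(lib.projections[0], lib, likelihood_scale=1e9)
        assert pg.probs.max() == pytest.approx(1.0 / lib.n_points, rel=1e-3)

    def test_non_finite_features_rejected(self, planted_library):
        with pytest.raises(ValueError):
            segment_posterior(np.array([np.nan, 0.0, 0.0]), planted_library)


class TestNeuronPosterior:
    def _loglik(self, lib, flat, scale=0.3):
        d2 = ((lib.projections - lib.projections[flat]) ** 2).sum(1)
        return (-0.5 * d2 / scale ** 2).reshape(lib.grid_shape())

    def test_single_segment_small_sigma_recovers_segment_posterior(self, planted_library):
        lib = planted_library
        ll = self._loglik(lib, 500)
        pg, sigma = neuron_posterior([ll], lib,
                                     variance_grid=np.array([0.05]))
        seg = segment_posterior(lib.projections[500], lib, likelihood_scale=0.3)
        assert np.argmax(pg.probs) == np.argmax(seg.probs)

    def test_identical_segments_sharpen_posterior(self, planted_library):
        lib = planted_library
        ll = self._loglik(lib, 500, scale=1.0)
        one, _ = neuron_posterior([ll], lib, variance_grid=np.array([0.3]))
        many, _ = neuron_posterior([ll] * 8, lib, variance_grid=np.array([0.3]))
        assert many.probs.max() > one.probs.max()

    def test_empty_input_rejected(self, planted_library):
        with pytest.raises(ValueError):
            neuron_posterior([], planted_library)


class TestModelAverage:
    def _uniform(self, n=5):
        p = np.full((n, n), 1.0 / n ** 2)
        ax = np.linspace(0, 2, n)
        return PosteriorGrid(p, ax, ax)

    def _delta(self, i, j, n=5):
        p = np.zeros((n, n))
        p[i, j] = 1.0
        ax = np.linspace(0, 2, n)
        return PosteriorGrid(p, ax, ax)

    def test_identical_posteriors_unchanged(self):
        pgs = [self._delta(2, 3) for _ in range(4)]
        out = model_average(pgs, np.log([0.3, 0.1, 0.5, 0.1]))
        np.testing.assert_allclose(out.probs, pgs[0].probs)

    def test_dominant_evidence_wins(self):
        out = model_average([self._delta(0, 0), self._delta(4, 4)],
                            np.array([0.0, -50.0]))
        assert out.probs[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_evidences_weight_quarter_each(self):
        pgs = [self._delta(i, i) for i in range(4)]
        out = model_average(pgs, np.zeros(4))
        for i in range(4):
            assert out.probs[i, i] == pytest.approx(0.25)

    def test_averaging_preserves_normalization(self, rng):
        n = 6
        pgs = []
        for _ in range(4):
            p = rng.random((n, n))
            p /= p.sum()
            pgs.append(PosteriorGrid(p, np.linspace(0, 2, n),
                                     np.linspace(0, 2, n)))
        out = model_average(pgs, rng.normal(0, 3, 4))
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestPointEstimate:
    def test_delta_posterior(self):
        n = 41
        ax = np.linspace(0, 2, n)
        p = np.zeros((n, n))
        p[20, 20] = 1.0
        pg = PosteriorGrid(p, ax, ax)
        assert point_estimate(pg) == pytest.approx((1.0, 1.0))

    def test_uniform_posterior_centered(self):
        n = 41
        ax = np.linspace(0, 2, n)
        pg = PosteriorGrid(np.full((n, n), 1 / n ** 2), ax, ax)
        assert point_estimate(pg) == pytest.approx((1.0, 1.0))

    def test_bimodal_symmetric_average(self):
        n = 41
        ax = np.linspace(0, 2, n)
        p = np.zeros((n, n))
        p[10, 5] = 0.5   # g_i = 0.5
        p[30, 5] = 0.5   # g_i = 1.5
        pg = PosteriorGrid(p, ax, ax)
        assert point_estimate(pg)[0] == pytest.approx(1.0)


class TestRecoveryOnPlantedLibrary:
    def test_median_recovery_error_within_three_grid_steps(self, rng):
        # >=20 synthetic neurons drawn on the interior grid; segments are the
        # library vector plus feature noise; median |error| <= 0.15 mS/cm^2
        lib = make_planted_library(seed=5)
        scale = default_likelihood_scale(lib)
        errs = []
        for _ in range(20):
            i = rng.integers(5, 36)
            j = rng.integers(5, 36)
            flat = i * 41 + j
            seg_logliks = []
            for _ in range(6):
                noisy = lib.projections[flat] + rng.normal(0, 2 * scale, 3)
                d2 = ((lib.projections - noisy) ** 2).sum(1)
                seg_logliks.append((-0.5 * d2 / scale ** 2).reshape(41, 41))
            pg, _ = neuron_posterior(seg_logliks, lib,
                                     variance_grid=np.array([0.3, 1.0]))
            gi, gc = point_estimate(pg)
            errs.append(abs(gi - lib.g_i_axis[i]))
            errs.append(abs(gc - lib.g_c_axis[j]))
        assert np.median(errs) <= 0.15


class TestCCMapping:
    def test_fit_and_monotone_prediction(self):
        g = np.linspace(0.01, 0.045, 60)
        cc = 0.3 * g + 2.0 * g ** 2
        m = fit_cc_mapping(g, cc)
        assert m.r2 == pytest.approx(1.0, abs=1e-9)
        xs = np.linspace(0.01, 0.045, 20)
        assert np.all(np.diff(m(xs)) > 0)

    def test_zero_coupling_maps_near_zero(self):
        g = np.linspace(0.0, 0.045, 60)
        cc = 0.35 * g
        m = fit_cc_mapping(g, cc)
        assert m(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_extrapolation_warns(self):
        m = fit_cc_mapping(np.linspace(0.02, 0.04, 30),
                           np.linspace(0.01, 0.02, 30))
        with pytest.warns(UserWarning, match="extrapolat"):
            m(0.1)
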