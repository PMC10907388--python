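"""RF mapping, optical flow, and naturalistic feature sensitivities."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage
from scipy.integrate import quad

from onbc import naturalistic as nat
from onbc import synthetic as syn


@pytest.fixture(scope="module")
def surrogate_movie():
    """Smooth power-law movie with alternating motion and static epochs."""
    segments = [(0.5, 1.5, 80.0, 0.0), (2.5, 3.5, 0.0, -60.0)]
    return syn.generate_naturalistic_surrogate(
        4.0, segments, frame_rate=30.0, shape=(72, 72), pixel_size=4.0, seed=21)


@pytest.fixture(scope="module")
def checker_movie():
    return syn.generate_checkerboard(n_unique=300, frame_rate=5.0, seed=3)


def response_rate_trace(movie, kind="luminance_center", rf=(0.0, 0.0), n_out=None):
    tr = nat.movie_feature_trace(movie, rf, kind)
    n_out = n_out or int(movie.duration * 9.5)
    return nat._bin_to(tr, n_out)


class TestCenterMask:
    def test_center_weight_one_boundary_zero(self):
        m = nat.gaussian_center_mask(50.0, 2.0, (101, 101))
        assert m[50, 50] == pytest.approx(1.0)
        assert m[50, 50 + 26] == 0.0  # 52 um > 50 um radius

    def test_weighted_average_of_uniform_frame_is_uniform_value(self):
        m = nat.gaussian_center_mask(40.0, 2.0, (64, 64))
        frame = np.full((64, 64), 0.37)
        assert (frame * m).sum() / m.sum() == pytest.approx(0.37)

    def test_sub_pixel_radius_rejected(self):
        with pytest.raises(ValueError):
            nat.gaussian_center_mask(0.5, 2.0, (10, 10))


class TestFeatureTraces:
    def test_constant_movie_constant_trace_with_unit_gain(self):
        frames = np.full((100, 40, 40), 0.25, np.float32)
        movie = syn.StimulusMovie(frames, 20.0, 4.0)
        tr = nat.movie_feature_trace(movie, (0, 0), "luminance_center")
        assert np.allclose(tr[-20:], 0.25, atol=1e-6)  # steady-state gain 1

    def test_step_rises_with_indicator_kinetics(self):
        frames = np.zeros((200, 40, 40), np.float32)
        frames[100:] = 0.5
        movie = syn.StimulusMovie(frames, 50.0, 4.0)
        tr = nat.movie_feature_trace(movie, (0, 0), "luminance_center",
                                     shift_ms=0)
        # half-rise delay consistent with the kernel's cumulative mass
        k = nat._g_kernel(50.0)
        half_kernel = np.searchsorted(np.cumsum(k), 0.5) / 50.0
        half_rise = (np.searchsorted(tr[100:], 0.25)) / 50.0
        assert half_rise == pytest.approx(half_kernel, abs=0.06)

    def test_shift_delays_by_expected_samples(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(0, 0.2, (80, 30, 30)).astype(np.float32)
        movie = syn.StimulusMovie(frames, 30.0, 4.0)
        t0 = nat.movie_feature_trace(movie, (0, 0), "luminance_center", shift_ms=0)
        t1 = nat.movie_feature_trace(movie, (0, 0), "luminance_center",
                                     shift_ms=200)
        k = round(0.2 * 30)
        assert np.allclose(t1[k:], t0[:-k])

    def test_rf_outside_movie_rejected(self, surrogate_movie):
        with pytest.raises(ValueError):
            nat.movie_feature_trace(surrogate_movie, (1000.0, 0.0))


class TestTemporalKernels:
    def test_bandpass_integral_matches_quadrature(self):
        rate = 1000.0
        k = nat.temporal_bandpass_kernel(rate)
        oracle = sum(
            w * quad(lambda t, m=m, s=s: np.exp(-0.5 * ((t - m) / s) ** 2),
                     0, 1.0)[0]
            for m, s, w in nat.F_B_COMPONENTS
        )
        assert k.sum() / rate == pytest.approx(oracle, rel=5e-3)

    def test_bandpass_response_recovered(self, surrogate_movie):
        sc = nat.movie_feature_trace(surrogate_movie, (0, 0), "luminance_center",
                                     apply_g_flag=False, shift_ms=0)
        from scipy.signal import fftconvolve
        rate = surrogate_movie.frame_rate
        fb = fftconvolve(sc, nat.temporal_bandpass_kernel(rate), mode="same")
        resp = nat._bin_to(nat._shift(nat.apply_g(fb, rate), rate, 200.0), 38)
        t_val = nat.temporal_contrast_sensitivity(surrogate_movie, (0, 0), resp)
        assert t_val > 0

    def test_white_noise_response_centered_near_zero(self, surrogate_movie):
        rng = np.random.default_rng(1)
        vals = [nat.temporal_contrast_sensitivity(surrogate_movie, (0, 0),
                                                  rng.normal(0, 1, 38))
                for _ in range(12)]
        assert abs(np.median(vals)) < 1.0


class TestSpatialSensitivity:
    def test_center_surround_response_positive_s(self, surrogate_movie):
        cs = response_rate_trace(surrogate_movie, "center_minus_surround")
        rng = np.random.default_rng(2)
        s = nat.spatial_contrast_sensitivity(surrogate_movie, (0, 0),
                                             cs + rng.normal(0, 0.01 * cs.std(),
                                                             cs.size))
        assert s > 0

    def test_luminance_response_negative_s(self, surrogate_movie):
        lum = response_rate_trace(surrogate_movie, "luminance_center")
        rng = np.random.default_rng(3)
        s = nat.spatial_contrast_sensitivity(surrogate_movie, (0, 0),
                                             lum + rng.normal(0, 0.01 * lum.std(),
                                                              lum.size))
        assert s < 0

    def test_exact_center_surround_gives_unit_numerator(self, surrogate_movie):
        cs = response_rate_trace(surrogate_movie, "center_minus_surround")
        s = nat.spatial_contrast_sensitivity(surrogate_movie, (0, 0), cs)
        # numerator correlation is 1, so S = -ln(corr(g(Sc), R)^2) >= 0
        assert np.isfinite(s) and s >= 0


class TestHornSchunck:
    def test_identical_frames_zero_flow(self):
        img = np.random.default_rng(4).normal(0, 1, (32, 32))
        flow = nat.horn_schunck_flow(img, img, 3.0, 50)
        assert np.abs(flow).max() == 0.0

    def test_one_pixel_shift_recovered(self):
        rng = np.random.default_rng(5)
        img = ndimage.gaussian_filter(rng.normal(0, 1, (48, 48)), 2)
        img = img / img.std() * 50  # strong texture
        flow = nat.horn_schunck_flow(img, np.roll(img, 1, axis=1), 3.0, 300)
        u = flow[8:-8, 8:-8, 0].mean()
        v = flow[8:-8, 8:-8, 1].mean()
        assert abs(u - 1.0) < 0.15
        assert abs(v) < 0.15

    def test_smoothness_reduces_laplacian_energy(self):
        rng = np.random.default_rng(6)
        a = ndimage.gaussian_filter(rng.normal(0, 1, (40, 40)), 1.5) * 30
        b = np.roll(a, 1, axis=0) + rng.normal(0, 0.5, a.shape)
        energies = []
        for alpha in (1.0, 3.0, 10.0):
            flow = nat.horn_schunck_flow(a, b, alpha, 100)
            lap = ndimage.laplace(flow[..., 0]) ** 2 + \
                ndimage.laplace(flow[..., 1]) ** 2
            energies.append(lap.mean())
        assert energies[0] > energies[1] > energies[2]


class TestMotionSensitivity:
    def test_coherent_translation_low_incoherence(self, surrogate_movie):
        o = nat.motion_coherence_trace(surrogate_movie, (0, 0), n_iter=60)
        # during rigid translation O_a - O_v stays near zero
        i0, i1 = int(0.7 * 30), int(1.4 * 30)
        flow_scale = np.percentile(np.abs(o), 95) + 1e-12
        assert np.median(o[i0:i1]) <= flow_scale
        assert np.all(o >= -1e-9)  # normalized O_v never exceeds O_a

    def test_exact_feature_response_gives_zero_m(self, surrogate_movie):
        o = nat.motion_coherence_trace(surrogate_movie, (0, 0), n_iter=40)
        rate = surrogate_movie.frame_rate
        resp = nat._bin_to(nat._shift(nat.apply_g(o, rate), rate, 200.0), 38)
        m = nat.motion_sensitivity(surrogate_movie, (0, 0), resp, n_iter=40)
        assert m == pytest.approx(0.0, abs=1e-6)

    def test_uncorrelated_response_large_m(self, surrogate_movie):
        rng = np.random.default_rng(7)
        m = nat.motion_sensitivity(surrogate_movie, (0, 0),
                                   rng.normal(0, 1, 38), n_iter=40)
        assert m > 2.0


class TestInCenterSensitivity:
    def test_pure_center_response_floors_beta(self, surrogate_movie):
        c = response_rate_trace(surrogate_movie, "luminance_center")
        i_val, beta = nat.in_center_contrast_sensitivity(surrogate_movie, (0, 0), c)
        assert i_val == pytest.approx(-3.0)
        assert beta <= 1e-3

    def test_blend_recovery_and_grid_oracle(self, surrogate_movie):
        c = response_rate_trace(surrogate_movie, "luminance_center")
        cin = response_rate_trace(surrogate_movie, "in_center")
        resp = 0.5 * cin + 0.5 * c
        _, beta = nat.in_center_contrast_sensitivity(surrogate_movie, (0, 0), resp)
        assert beta == pytest.approx(0.5, abs=0.05)
        # brute-force 0.001-step grid oracle
        grid = np.arange(0.0, 1.0001, 0.001)
        cors = [np.corrcoef(b * cin + (1 - b) * c, resp)[0, 1] for b in grid]
        assert beta == pytest.approx(grid[int(np.argmax(cors))], abs=0.002)


class TestReceptiveFieldMapping:
    @staticmethod
    def _cell_response(movie, center):
        cell = replace(syn.default_cell_params()["BC6"], rf_center=center,
                       noise_sd=0.0, transience_tau=20.0)
        return syn.simulate_cell_response(cell, movie, 9.5, seed=0)

    @pytest.mark.parametrize("center", [(8.0, -4.0), (0.0, 0.0), (-12.0, 16.0)])
    def test_recovers_planted_center_within_step(self, checker_movie, center):
        rf = nat.map_receptive_field(self._cell_response(checker_movie, center),
                                     checker_movie)
        err = np.hypot(rf.center[0] - center[0], rf.center[1] - center[1])
        assert err < 4.0
        assert not rf.flagged

    def test_noise_response_flagged(self, checker_movie):
        rng = np.random.default_rng(8)
        rf = nat.map_receptive_field(rng.normal(0, 1, 1140), checker_movie)
        assert rf.quality < 0.1
        assert rf.flagged


class TestLuminanceVariance:
    def test_exact_luminance_response_r2_one(self, surrogate_movie):
        lum = response_rate_trace(surrogate_movie, "luminance_center")
        res = nat.luminance_explained_variance(lum, surrogate_movie, (0, 0))
        assert res["r2"] == pytest.approx(1.0)

    def test_noise_response_r2_near_zero_with_ceiling(self, surrogate_movie):
        rng = np.random.default_rng(9)
        reps = rng.normal(0, 1, (3, 38))
        res = nat.luminance_explained_variance(reps.mean(0), surrogate_movie,
                                               (0, 0), repeats=reps)
        assert res["r2"] < 0.2
        assert res["ceiling"] < 0.2


class TestSpatialAutocorrelation:
    def test_luminance_decays_slower_than_in_center(self, surrogate_movie):
        d_l, r_l = nat.feature_spatial_autocorrelation(
            surrogate_movie, "luminance_center", half_um=24.0, step_um=8.0)
        d_i, r_i = nat.feature_spatial_autocorrelation(
            surrogate_movie, "in_center", half_um=24.0, step_um=8.0)
        # compare at the largest shared distance bin
        far = min(d_l.max(), d_i.max())
        assert r_l[d_l == far][0] > r_i[d_i == far][0]
        # smooth movies decay with distance
        assert r_l[0] > r_l[-1]


class TestVisualAngle:
    def test_projection_extent_matches_calibration(self):
        assert nat.visual_angle_extent(800, 1.98) == 49
        assert nat.visual_angle_extent(600, 1.98) == 37
        assert nat.visual_angle_extent(325, 1.0, round_deg=False) == \
            pytest.approx(10.0)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            nat.visual_angle_extent(0, 1.98)
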