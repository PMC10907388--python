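"""Generators: stimulus geometry, determinism, and model-cell behavior."""

from dataclasses import replace

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from onbc import imaging as im
from onbc import synthetic as syn
from onbc import temporal as tp


class TestSpotStimulus:
    def test_seven_sizes_five_repeats_gives_35_on_epochs(self, spot_movie):
        on = [e for e in spot_movie.log if e[0].endswith("_on")]
        assert len(on) == 35

    def test_single_size_single_repeat(self):
        mov = syn.generate_spot_stimulus(sizes=(100.0,), repeats=1, frame_rate=10.0)
        on = [e for e in mov.log if e[0].endswith("_on")]
        assert len(on) == 1
        # frames outside the disk stay at background during OFF
        _, off0, off1 = [e for e in mov.log if e[0].endswith("_off")][0]
        i = int((off0 + off1) / 2 * 10)
        assert mov.frames[i].max() <= 0.0

    def test_rendered_disk_diameter_matches_area(self):
        mov = syn.generate_spot_stimulus(sizes=(100.0,), repeats=1, frame_rate=5.0,
                                         pixel_size=2.0, shape=(80, 80))
        label, t0, t1 = [e for e in mov.log if e[0].endswith("_on")][0]
        frame = mov.frames[int((t0 + t1) / 2 * 5)]
        lit = np.sum(frame > 0)
        expected = np.pi * 25.0**2  # radius 50 um = 25 px
        assert abs(lit - expected) / expected < 0.05

    def test_log_epochs_non_overlapping_and_within_duration(self, spot_movie):
        events = sorted(spot_movie.log, key=lambda e: e[1])
        for (_, a0, a1), (_, b0, b1) in zip(events, events[1:]):
            assert a1 <= b0 + 1e-9
        assert events[-1][2] <= spot_movie.duration + 1e-6

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            syn.generate_spot_stimulus(sizes=(-5.0,))
        with pytest.raises(ValueError):
            syn.generate_spot_stimulus(on_s=0.0)


class TestFreqStimulus:
    def test_epoch_count_and_cycle_count(self):
        mov = syn.generate_freq_stimulus(diameters=(150.0,), frame_rate=52.5, seed=0)
        assert len(mov.log) == 30  # 6 freqs x 5 repeats
        label, t0, t1 = [e for e in mov.log if e[0].startswith("sine1Hz")][0]
        i0, i1 = int(round(t0 * 52.5)), int(round(t1 * 52.5))
        center = mov.frames[i0:i1, mov.frames.shape[1] // 2, mov.frames.shape[2] // 2]
        # 1 Hz for 2 s: spectral peak at two cycles per epoch
        spec = np.abs(np.fft.rfft(center.astype(float)))
        assert np.argmax(spec[1:]) + 1 == 2

    def test_f1_dominates_other_frequencies(self):
        mov = syn.generate_freq_stimulus(freqs=(1.0,), diameters=(150.0,), repeats=1,
                                         frame_rate=52.5, seed=0)
        _, t0, t1 = mov.log[0]
        i0, i1 = int(round(t0 * 52.5)), int(round(t1 * 52.5))
        trace = mov.frames[i0:i1, mov.frames.shape[1] // 2, mov.frames.shape[2] // 2]
        p1 = tp.f1_power(trace.astype(float), 1.0, 52.5)
        p2 = tp.f1_power(trace.astype(float), 2.0, 52.5)
        assert p1 / max(p2, 1e-12) > 100

    def test_rejects_super_nyquist_frequency(self):
        with pytest.raises(ValueError):
            syn.generate_freq_stimulus(freqs=(30.0,), frame_rate=52.5)


class TestCheckerboard:
    def test_sequence_shown_twice(self):
        mov = syn.generate_checkerboard(n_unique=50, seed=0)
        assert len(mov.log) == 100
        assert np.array_equal(mov.frames[:50], mov.frames[50:])

    def test_on_fraction_matches_binomial(self):
        mov = syn.generate_checkerboard(n_unique=900, p_on=0.5, seed=1)
        frac = np.mean(mov.frames[:900] > 0)
        assert abs(frac - 0.5) < 0.01

    def test_deterministic_given_seed(self):
        a = syn.generate_checkerboard(n_unique=20, seed=9)
        b = syn.generate_checkerboard(n_unique=20, seed=9)
        assert np.array_equal(a.frames, b.frames)


class TestNaturalisticSurrogate:
    def test_static_movie_has_constant_frames(self):
        mov = syn.generate_naturalistic_surrogate(0.5, None, frame_rate=20.0, seed=2)
        c = np.corrcoef(mov.frames[0].ravel(), mov.frames[-1].ravel())[0, 1]
        assert c > 0.99

    def test_motion_segment_translates_at_requested_speed(self):
        mov = syn.generate_naturalistic_surrogate(
            1.0, [(0.0, 1.0, 100.0, 0.0)], frame_rate=60.0, shape=(48, 48),
            pixel_size=2.0, seed=4)
        # 100 um/s at 60 fps and 2 um/px -> 0.83 px/frame horizontal
        shifts = []
        for i in range(20, 26):
            sh, _, _ = phase_cross_correlation(mov.frames[i], mov.frames[i + 1],
                                               upsample_factor=50)
            shifts.append(sh)
        mean_shift = np.mean(shifts, axis=0)
        assert abs(abs(mean_shift[1]) - 0.833) < 0.25
        assert abs(mean_shift[0]) < 0.2

    def test_zero_exponent_gives_flat_spectrum(self):
        mov = syn.generate_naturalistic_surrogate(0.2, None, spatial_exponent=0.0,
                                                  frame_rate=20.0, shape=(64, 64), seed=5)
        f = np.abs(np.fft.fft2(mov.frames[0]))
        fy = np.fft.fftfreq(64)[:, None]
        fx = np.fft.fftfreq(64)[None, :]
        r = np.sqrt(fy**2 + fx**2).ravel()
        a = f.ravel()
        lo = a[(r > 0.05) & (r < 0.15)].mean()
        hi = a[(r > 0.3) & (r < 0.45)].mean()
        assert 0.5 < lo / hi < 2.0

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_naturalistic_surrogate(
                1.0, [(0.0, 0.6, 10, 0), (0.5, 0.9, 5, 0)], frame_rate=20.0)


class TestCellModel:
    def test_zero_contrast_movie_gives_constant_baseline(self, cell_params):
        frames = np.zeros((50, 20, 20), np.float32)
        mov = syn.StimulusMovie(frames, 10.0, 8.0)
        cell = replace(cell_params["BC6"], noise_sd=0.0)
        tr = syn.simulate_cell_response(cell, mov, 9.5, seed=0)
        assert np.allclose(tr, cell.baseline)

    def test_gcamp_lowpass_attenuates_high_frequencies(self, cell_params):
        mov = syn.generate_freq_stimulus(freqs=(0.5, 8.0), diameters=(150.0,),
                                         repeats=1, frame_rate=52.5, seed=0)
        cell = replace(cell_params["BC6"], noise_sd=0.0, transience_tau=20.0)
        tr = syn.simulate_cell_response(cell, mov, 52.5, seed=0)
        powers = {}
        for label, t0, t1 in mov.log:
            f = float(label.split("Hz")[0][4:])
            i0, i1 = int(round(t0 * 52.5)), int(round(t1 * 52.5))
            powers[f] = tp.f1_power(tr[i0:i1] - tr[i0:i1].mean(), f, 52.5)
        assert powers[8.0] < powers[0.5]

    def test_small_spot_beats_large_spot_iff_surround_positive(self, spot_movie):
        for w, expect in ((0.3, True), (0.0, False)):
            cell = syn.CellParams("test", surround_weight=w, noise_sd=0.0,
                                  transience_tau=20.0)
            tr = syn.simulate_cell_response(cell, spot_movie, 9.5, seed=0)
            resp = {}
            for size in (200.0, 800.0):
                vals = []
                for label, t0, t1 in spot_movie.log:
                    if label == f"spot{size:g}_on":
                        i0 = int(round(t0 * 9.5))
                        i1 = int(round(t1 * 9.5))
                        vals.append(tr[i0:i1].mean() - cell.baseline)
                resp[size] = np.mean(vals)
            assert (resp[200.0] > resp[800.0] + 1e-9) == expect

    def test_rf_outside_movie_rejected(self, cell_params):
        mov = syn.StimulusMovie(np.zeros((5, 10, 10), np.float32), 10.0, 2.0)
        cell = replace(cell_params["BC6"], rf_center=(500.0, 0.0))
        with pytest.raises(ValueError):
            syn.simulate_cell_response(cell, mov, 9.5)

    def test_deterministic_given_seed(self, cell_params):
        mov = syn.StimulusMovie(
            np.random.default_rng(0).normal(0, 0.2, (30, 20, 20)).astype(np.float32),
            10.0, 8.0)
        a = syn.simulate_cell_response(cell_params["BC7"], mov, 9.5, seed=3)
        b = syn.simulate_cell_response(cell_params["BC7"], mov, 9.5, seed=3)
        assert np.array_equal(a, b)


class TestRenderImageSeries:
    def test_single_blob_trace_proportional_to_input(self):
        t = np.linspace(0, 4 * np.pi, 100)
        trace = np.sin(t) + 2.0
        series = syn.render_image_series([(0.0, 0.0)], [trace], 10.0, shape=(16, 16))
        inner = series.data[:, 6:10, 6:10].mean(axis=(1, 2))
        assert np.corrcoef(inner, trace)[0, 1] > 0.999999

    def test_segmentation_recovers_two_rois(self):
        t = np.linspace(0, 20, 200)
        tr1, tr2 = np.sin(t) + 1.5, np.cos(0.7 * t) + 1.5
        series = syn.render_image_series([(-6, -5), (6, 5)], [tr1, tr2], 10.0,
                                         shape=(32, 32), photon_noise_sd=0.05, seed=2)
        _, mask, sd = im.preprocess(series)
        # blobs cover ~10% of the field, so raise the peak threshold
        # above the noise floor of the SD image
        rois = im.segment_rois(sd, threshold=float(np.percentile(sd, 90)),
                               min_distance=3)
        assert rois.n_rois == 2
        best = []
        for r in range(1, 3):
            tr = series.data[:, rois.labels == r].mean(axis=1)
            best.append(max(np.corrcoef(tr, tr1)[0, 1], np.corrcoef(tr, tr2)[0, 1]))
        assert min(best) > 0.9

    def test_bit_identical_given_seed(self):
        trace = np.ones(10)
        kw = dict(frame_rate=5.0, shape=(8, 8), photon_noise_sd=0.2, seed=11)
        a = syn.render_image_series([(0, 0)], [trace], **kw)
        b = syn.render_image_series([(0, 0)], [trace], **kw)
        assert np.array_equal(a.data, b.data)

    def test_roi_outside_fov_rejected(self):
        with pytest.raises(ValueError):
            syn.render_image_series([(100.0, 0.0)], [np.ones(5)], 5.0, shape=(8, 8))


class TestArborGenerator:
    def test_infinite_lambda_no_noise_gives_unit_correlations(self):
        sig = np.random.default_rng(0).normal(0, 1, 300)
        _, traces = syn.generate_arbor(8, 30.0, np.inf, sig, local_noise_sd=0.0, seed=1)
        flat = traces[:, 0, :]
        c = np.corrcoef(flat)
        assert np.allclose(c, 1.0, atol=1e-10)

    def test_correlations_follow_exponential_decay(self):
        from onbc import arbor as ab

        sig = np.random.default_rng(3).normal(0, 1, 400)
        arbor, traces = syn.generate_arbor(60, 60.0, 30.0, sig, local_noise_sd=0.0,
                                           seed=7)
        pg = ab.link_rois_to_skeleton(arbor.roi_positions, arbor.nodes, arbor.edges)
        path, _ = ab.pairwise_path_distances(pg)
        iu = np.triu_indices(60, 1)
        cors = np.array([np.corrcoef(traces[i, 0], traces[j, 0])[0, 1]
                         for i, j in zip(*iu)])
        pred = np.exp(-path[iu] / 30.0)
        ss_res = np.sum((cors - pred) ** 2)
        ss_tot = np.sum((cors - cors.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.8

    def test_correlation_decays_monotonically_with_distance(self):
        from onbc import arbor as ab

        sig = np.random.default_rng(5).normal(0, 1, 300)
        arbor, traces = syn.generate_arbor(40, 50.0, 20.0, sig, local_noise_sd=0.0,
                                           seed=9)
        pg = ab.link_rois_to_skeleton(arbor.roi_positions, arbor.nodes, arbor.edges)
        path, _ = ab.pairwise_path_distances(pg)
        iu = np.triu_indices(40, 1)
        d = path[iu]
        cors = np.array([np.corrcoef(traces[i, 0], traces[j, 0])[0, 1]
                         for i, j in zip(*iu)])
        # binned means decrease with distance
        edges = np.quantile(d, np.linspace(0, 1, 6))
        means = [cors[(d >= a) & (d < b)].mean() for a, b in zip(edges[:-2], edges[1:-1])]
        assert all(x > y for x, y in zip(means, means[1:]))

    def test_invalid_length_constant_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_arbor(5, 30.0, -2.0, np.random.default_rng(0).normal(0, 1, 50))


def test_movie_tiff_roundtrip(tmp_path):
    mov = syn.generate_checkerboard(n_unique=5, seed=0)
    p = tmp_path / "movie.tif"
    mov.save(p)
    back = syn.StimulusMovie.load(p)
    assert np.allclose(back.frames, mov.frames)
    assert back.log == mov.log
    assert back.frame_rate == mov.frame_rate
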