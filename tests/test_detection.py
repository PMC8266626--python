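"""Detection-stage contracts: image correction, sub-pixel localisation,
aperture photometry, linking, colocalisation and kymographs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import heliquant as hq
from heliquant.detection import EdgeProximityError, foci_to_table


def gaussian_frame(shape, x0, y0, amp, sigma, offset=0.0):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return offset + amp * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sigma ** 2))


def make_movie(frames, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return hq.Movie(frames=frames, times=np.arange(frames.shape[0]) * dt)


class TestCorrectMovie:
    def test_uniform_profile_offset_subtraction(self):
        movie = make_movie(np.full((1, 4, 4), 150.0))
        out = hq.correct_movie(movie, offset=100.0, beam_profile=np.ones((4, 4)))
        assert np.all(out.frames == 50.0)

    def test_bright_region_halved_after_unit_mean_normalisation(self):
        # profile 2x in one half, 1x in the other; unit-mean normalisation
        # makes the factors 4/3 and 2/3, so corrected = raw / factor
        profile = np.ones((4, 4))
        profile[:, 2:] = 2.0
        movie = make_movie(np.full((1, 4, 4), 120.0))
        out = hq.correct_movie(movie, offset=0.0, beam_profile=profile)
        assert np.allclose(out.frames[0][:, :2], 120.0 / (1.0 / 1.5))
        assert np.allclose(out.frames[0][:, 2:], 120.0 / (2.0 / 1.5))

    def test_offset_equal_to_image_gives_zero_movie(self):
        movie = make_movie(np.full((2, 3, 3), 80.0))
        out = hq.correct_movie(movie, offset=80.0, beam_profile=np.ones((3, 3)))
        assert np.all(out.frames == 0.0)
        assert out.meta["n_clipped_pixels"] == 0

    def test_negative_residuals_clipped_and_counted(self):
        frames = np.full((1, 3, 3), 50.0)
        frames[0, 0, 0] = 10.0
        out = hq.correct_movie(make_movie(frames), offset=20.0,
                               beam_profile=np.ones((3, 3)))
        assert out.frames[0, 0, 0] == 0.0
        assert out.meta["n_clipped_pixels"] == 1

    def test_idempotent_with_zero_offset_uniform_profile(self):
        frames = np.abs(np.random.default_rng(0).normal(100, 10, (2, 8, 8)))
        once = hq.correct_movie(make_movie(frames), 0.0, np.ones((8, 8)))
        twice = hq.correct_movie(once, 0.0, np.ones((8, 8)))
        assert np.allclose(once.frames, twice.frames)

    @pytest.mark.parametrize("profile", [np.ones((3, 3)), -np.ones((4, 4))])
    def test_bad_profile_rejected(self, profile):
        movie = make_movie(np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            hq.correct_movie(movie, 0.0, profile)


class TestDetectFoci:
    def test_blank_frame_yields_nothing(self):
        assert hq.detect_foci(np.full((32, 32), 7.0)) == []

    def test_noiseless_gaussian_localised_to_1e_3_px(self):
        frame = gaussian_frame((32, 32), 10.3, 7.8, 500.0, 1.3, offset=10.0)
        foci = hq.detect_foci(frame, min_snr=5, window=9)
        assert len(foci) == 1
        assert foci[0].x == pytest.approx(10.3, abs=1e-3)
        assert foci[0].y == pytest.approx(7.8, abs=1e-3)
        assert foci[0].fit_sigma == pytest.approx(1.3, abs=1e-3)

    def test_two_emitters_10px_apart_both_found(self):
        cfg = hq.SimConfig(seed=21, n_frames=1, field_shape=(40, 40),
                           read_noise_sd=2.0, background_rate=5.0,
                           offset=100.0, bleach_tau=1e9)
        truths = [
            hq.EmitterTruth(emitter_id=0, x=14.0, y=20.0, dye_counts=[5]),
            hq.EmitterTruth(emitter_id=1, x=24.0, y=20.0, dye_counts=[5]),
        ]
        movie, _ = hq.simulate_movie(cfg, truths)
        corrected = hq.correct_movie(movie, 100.0, np.ones((40, 40)))
        foci = hq.detect_foci(corrected.frames[0], min_snr=5)
        assert len(foci) == 2
        xs = sorted(f.x for f in foci)
        assert xs[0] == pytest.approx(14.0, abs=0.3)
        assert xs[1] == pytest.approx(24.0, abs=0.3)

    def test_localisation_rms_below_0p2_px_at_snr_10(self):
        # simulator ground truth: repeated noisy renders of one emitter
        errors = []
        for s in range(40):
            cfg = hq.SimConfig(seed=100 + s, n_frames=1, field_shape=(24, 24),
                               read_noise_sd=3.0, background_rate=10.0,
                               offset=100.0, psf_sigma=1.3, bleach_tau=1e9,
                               photons_per_dye_per_frame=400.0)
            truth = hq.EmitterTruth(emitter_id=0, x=11.4, y=12.7,
                                    dye_counts=[4])
            movie, _ = hq.simulate_movie(cfg, [truth])
            corrected = hq.correct_movie(movie, 100.0, np.ones((24, 24)))
            foci = hq.detect_foci(corrected.frames[0], min_snr=5)
            assert foci, "emitter missed at SNR >= 10"
            f = max(foci, key=lambda f: f.integrated_intensity)
            errors.append((f.x - 11.4) ** 2 + (f.y - 12.7) ** 2)
        rms = math.sqrt(np.mean(errors))
        assert rms <= 0.2

    def test_even_or_small_window_rejected(self):
        with pytest.raises(ValueError):
            hq.detect_foci(np.zeros((16, 16)), window=6)

    def test_foci_table_columns(self):
        frame = gaussian_frame((24, 24), 12.0, 12.0, 300.0, 1.3)
        table = foci_to_table(hq.detect_foci(frame))
        assert list(table.columns) == ["frame", "x_px", "y_px", "intensity",
                                       "background", "sigma_px"]


class TestIntegratedIntensity:
    def test_flat_background_gives_zero(self):
        movie = make_movie(np.full((1, 32, 32), 40.0))
        focus = hq.Focus(frame_index=0, x=16.0, y=16.0, integrated_intensity=0.0)
        assert hq.integrated_intensity(movie, focus, 4.0, (6.0, 9.0)) == 0.0

    def test_gaussian_mass_within_3_sigma_disc(self):
        # 2-D Gaussian mass within radius 3 sigma is ~98.9%
        sigma, total = 1.3, 5000.0
        amp = total / (2 * math.pi * sigma ** 2)
        frame = gaussian_frame((48, 48), 24.0, 24.0, amp, sigma, offset=20.0)
        movie = make_movie(frame[None])
        focus = hq.Focus(frame_index=0, x=24.0, y=24.0, integrated_intensity=0.0)
        got = hq.integrated_intensity(movie, focus, disc_radius=3 * sigma,
                                      annulus=(8.0, 12.0))
        assert got >= 0.98 * total
        assert got <= 1.0 * total + 1e-6

    def test_unbiased_over_noisy_draws(self):
        # Monte-Carlo: aperture sum recovers the emitted photons on average
        total_photons = 4 * 200.0
        estimates = []
        for s in range(300):
            cfg = hq.SimConfig(seed=500 + s, n_frames=1, field_shape=(32, 32),
                               read_noise_sd=3.0, background_rate=20.0,
                               offset=100.0, bleach_tau=1e9)
            truth = hq.EmitterTruth(emitter_id=0, x=16.0, y=16.0,
                                    dye_counts=[4])
            movie, _ = hq.simulate_movie(cfg, [truth])
            corrected = hq.correct_movie(movie, 100.0, np.ones((32, 32)))
            focus = hq.Focus(frame_index=0, x=16.0, y=16.0,
                             integrated_intensity=0.0)
            estimates.append(hq.integrated_intensity(corrected, focus,
                                                     5.0, (8.0, 12.0)))
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - total_photons) < 2 * sem + 0.01 * total_photons

    def test_edge_focus_flagged(self):
        movie = make_movie(np.zeros((1, 32, 32)))
        focus = hq.Focus(frame_index=0, x=2.0, y=2.0, integrated_intensity=0.0)
        with pytest.raises(EdgeProximityError):
            hq.integrated_intensity(movie, focus, 4.0, (6.0, 9.0))


class TestLinking:
    @staticmethod
    def _focus(frame, x, y, intensity=100.0):
        return hq.Focus(frame_index=frame, x=x, y=y,
                        integrated_intensity=intensity)

    def test_single_emitter_full_length(self):
        fb = {i: [self._focus(i, 10.0, 10.0)] for i in range(20)}
        trajs = hq.link_trajectories(fb, max_step=2.0, max_gap=1)
        assert len(trajs) == 1
        assert len(trajs[0]) == 20

    def test_two_distant_emitters_no_identity_swap(self):
        fb = {i: [self._focus(i, 5.0 + 0.1 * i, 5.0, 50.0),
                  self._focus(i, 25.0 - 0.1 * i, 5.0, 500.0)]
              for i in range(15)}
        trajs = hq.link_trajectories(fb, max_step=2.0, max_gap=0)
        assert len(trajs) == 2
        for tr in trajs:
            assert len(set(np.round(tr.intensities, 6))) == 1  # no swaps

    def test_gap_closing(self):
        fb = {i: [self._focus(i, 8.0, 8.0)] for i in range(10) if i != 4}
        trajs = hq.link_trajectories(fb, max_step=2.0, max_gap=2)
        assert len(trajs) == 1
        assert len(trajs[0]) == 9

    def test_gap_beyond_max_gap_splits(self):
        fb = {i: [self._focus(i, 8.0, 8.0)] for i in range(10)
              if i not in (4, 5, 6)}
        trajs = hq.link_trajectories(fb, max_step=2.0, max_gap=1)
        assert len(trajs) == 2

    def test_empty_input(self):
        assert hq.link_trajectories({}, 2.0, 1) == []


class TestColocalisation:
    @staticmethod
    def _foci(points):
        return [hq.Focus(frame_index=0, x=x, y=y, integrated_intensity=1.0)
                for x, y in points]

    def test_identical_lists_fraction_one(self):
        pts = [(3.0, 4.0), (10.0, 20.0), (30.0, 7.0)]
        res = hq.colocalize(self._foci(pts), self._foci(pts), radius=2.0)
        assert res.fraction_colocalised == 1.0
        assert all(d == 0.0 for _, _, d in res.pairs)

    def test_strictly_beyond_radius_not_paired(self):
        res = hq.colocalize(self._foci([(0.0, 0.0)]),
                            self._foci([(2.1, 0.0)]), radius=2.0)
        assert res.pairs == []
        assert res.fraction_colocalised == 0.0

    def test_one_to_one_matching(self):
        # two A foci near one B focus: only the closer pairs
        res = hq.colocalize(self._foci([(0.0, 0.0), (1.0, 0.0)]),
                            self._foci([(0.4, 0.0)]), radius=2.0)
        assert len(res.pairs) == 1
        assert res.pairs[0][0] == 0

    def test_pair_set_symmetric_under_channel_swap(self, rng):
        a = self._foci(rng.uniform(0, 50, size=(30, 2)))
        b = self._foci(rng.uniform(0, 50, size=(25, 2)))
        res_ab = hq.colocalize(a, b, radius=3.0)
        res_ba = hq.colocalize(b, a, radius=3.0)
        pairs_ab = {(ia, ib) for ia, ib, _ in res_ab.pairs}
        pairs_ba = {(ib, ia) for ia, ib, _ in res_ba.pairs}
        assert pairs_ab == pairs_ba
        if res_ab.pairs:
            assert res_ab.fraction_colocalised * 30 == pytest.approx(
                res_ba.fraction_colocalised * 25)

    def test_chance_model_trivials(self):
        assert hq.chance_colocalization(12.0, 100.0, 0) == 0.0
        assert hq.chance_colocalization(100.0, 100.0, 1) == 1.0

    def test_chance_model_example_value(self):
        c = hq.chance_colocalization(math.pi * 4.0, 512.0 * 512.0, 128)
        assert c == pytest.approx(6.14e-3, rel=0.01)

    @given(st.integers(min_value=0, max_value=1000),
           st.floats(min_value=0.1, max_value=100.0),
           st.floats(min_value=1.0, max_value=10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_chance_scales_linearly_in_n(self, n, a_r, scale):
        a_fov = a_r * scale * 1000.0
        assert hq.chance_colocalization(a_r, a_fov, n) == pytest.approx(
            n * a_r / a_fov)


class TestKymograph:
    def test_static_emitter_vertical_stripe(self):
        frame = gaussian_frame((16, 64), 30.0, 8.0, 400.0, 1.3)
        movie = make_movie(np.repeat(frame[None], 6, axis=0))
        kymo = hq.make_kymograph(movie, ((0.0, 8.0), (63.0, 8.0)), width=3)
        peaks = np.argmax(kymo.image, axis=1)
        assert np.all(peaks == peaks[0])
        assert peaks[0] == pytest.approx(30, abs=1)

    def test_blank_movie_flat_kymograph(self):
        movie = make_movie(np.full((4, 16, 32), 100.0))
        kymo = hq.make_kymograph(movie, ((0.0, 8.0), (31.0, 8.0)))
        assert np.all(kymo.image == 100.0)
        assert kymo.image.shape[0] == 4

    def test_zero_length_line_rejected(self):
        movie = make_movie(np.zeros((1, 8, 8)))
        with pytest.raises(ValueError):
            hq.make_kymograph(movie, ((2.0, 2.0), (2.0, 2.0)))
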