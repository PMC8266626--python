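"""Generator contracts: determinism, noise models, labelling and bleaching
statistics, telegraph kinetics and fork geometry."""

import math

import numpy as np
import pytest
from scipy import stats

import heliquant as hq
from heliquant.simulate import truncated_poisson_mean


class TestSimConfig:
    def test_duty_cycle_defaults_to_exposure_fraction(self):
        cfg = hq.SimConfig(frame_interval=8.0, exposure=0.4)
        assert cfg.duty == pytest.approx(0.05)

    @pytest.mark.parametrize("kwargs", [
        {"frame_interval": 0.2, "exposure": 0.4},   # interval < exposure
        {"duty_cycle": 1.5},
        {"bleach_tau": 0.0},
        {"max_dyes": 0},
        {"n_frames": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hq.SimConfig(**kwargs)

    def test_json_round_trip(self, tmp_path):
        cfg = hq.SimConfig(seed=3, field_shape=(32, 48), dol_lambda=2.52)
        cfg.to_json(tmp_path / "cfg.json")
        assert hq.SimConfig.from_json(tmp_path / "cfg.json") == cfg


class TestTrajectory:
    def test_noise_free_single_dye_is_exactly_constant(self, quiet_config):
        truth = hq.EmitterTruth(emitter_id=0, x=10.0, y=10.0, dye_counts=[1])
        traj, _ = hq.simulate_trajectory(quiet_config, truth)
        assert np.all(traj.intensities ==
                      quiet_config.photons_per_dye_per_frame)

    def test_same_seed_bit_identical(self):
        cfg = hq.SimConfig(seed=42, n_frames=100)
        runs = []
        for _ in range(2):
            truth = hq.EmitterTruth(emitter_id=0, x=5.0, y=5.0, dye_counts=[3])
            traj, echo = hq.simulate_trajectory(cfg, truth)
            runs.append((traj.intensities.copy(), list(echo.dye_bleach_times)))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_emitter_binding_after_acquisition_rejected(self, quiet_config):
        truth = hq.EmitterTruth(emitter_id=0, x=1.0, y=1.0, dye_counts=[1],
                                bind_time=1e9)
        with pytest.raises(ValueError):
            hq.simulate_trajectory(quiet_config, truth)

    def test_unbinding_zeroes_signal(self, quiet_config):
        # unbind exactly half-way: later frames carry no signal
        t_half = quiet_config.duration / 2
        truth = hq.EmitterTruth(emitter_id=0, x=1.0, y=1.0, dye_counts=[2],
                                unbind_time=t_half)
        traj, _ = hq.simulate_trajectory(quiet_config, truth)
        late = traj.times >= t_half
        assert np.all(traj.intensities[late] == 0)
        assert np.all(traj.intensities[~late] > 0)

    def test_telegraph_event_rate_matches_renewal_closed_form(self):
        # the number of bound episodes per unit time of an alternating
        # renewal process is 1 / (mean unbound wait + mean dwell)
        tel = hq.TelegraphParams(on_rate=0.84, mean_dwell=2.0)
        cfg = hq.SimConfig(seed=77, frame_interval=1.0, exposure=0.5,
                           n_frames=600, bleach_tau=1e9)
        n_emitters = 3000
        counts = []
        for i in range(n_emitters):
            truth = hq.EmitterTruth(emitter_id=i, x=1.0, y=1.0, dye_counts=[1],
                                    kinetics_class="transient-telegraph")
            _, echo = hq.simulate_trajectory(cfg, truth, telegraph=tel)
            counts.append(len(echo.bound_intervals))
        rate = np.mean(counts) / (cfg.duration / 60.0)
        expected = tel.event_rate
        se = np.std(counts, ddof=1) / math.sqrt(n_emitters) / (cfg.duration / 60.0)
        assert abs(rate - expected) < 3 * se
        assert expected == pytest.approx(0.84, rel=0.05)   # short-dwell regime


class TestLabellingStatistics:
    def test_dye_count_marginal_matches_truncated_poisson(self, rng):
        lam, cap, n = 3.5, 6, 10_000
        counts = hq.draw_dye_counts(rng, lam, cap, n)
        expected = truncated_poisson_mean(lam, cap)
        se = counts.std(ddof=1) / math.sqrt(n)
        assert abs(counts.mean() - expected) < 3 * se
        assert counts.max() <= cap

    def test_bleach_survival_is_exponential_in_exposure_time(self):
        # continuous excitation, noise off: the observed signal-loss time of a
        # single dye (including its partial final frame) reconstructs the
        # exposure-clock bleach time; the sample must pass a KS test against
        # Exp(bleach_tau)
        tau = 10.0
        cfg = hq.SimConfig(seed=5, frame_interval=0.5, exposure=0.5,
                           n_frames=400, read_noise_sd=0.0, bleach_tau=tau)
        observed = []
        for i in range(10_000):
            truth = hq.EmitterTruth(emitter_id=i, x=1.0, y=1.0, dye_counts=[1])
            traj, _ = hq.simulate_trajectory(cfg, truth)
            frac = traj.intensities / cfg.photons_per_dye_per_frame
            t_bleach = frac.sum() * cfg.exposure   # full + partial frames
            if t_bleach < cfg.duration * cfg.duty * 0.99:   # uncensored only
                observed.append(t_bleach)
        d, p = stats.kstest(np.asarray(observed) / tau, "expon")
        assert p > 0.01

    def test_intermittent_excitation_extends_wall_clock_lifetime(self):
        # same exposure-clock budget, two duty cycles -> wall-clock bleach
        # times scale as the inverse duty ratio (20x for 400 ms / 8 s)
        budget = 12.0   # s of cumulative exposure
        wall_times = {}
        for name, (interval, exposure) in {
            "continuous": (0.4, 0.4), "intermittent": (8.0, 0.4),
        }.items():
            cfg = hq.SimConfig(seed=1, frame_interval=interval,
                               exposure=exposure, n_frames=2000,
                               read_noise_sd=0.0, bleach_tau=1e9)
            truth = hq.EmitterTruth(emitter_id=0, x=1.0, y=1.0,
                                    dye_counts=[1], dye_bleach_times=[budget])
            traj, _ = hq.simulate_trajectory(cfg, truth)
            dark = np.nonzero(traj.intensities == 0)[0]
            wall_times[name] = traj.times[dark[0]]
        ratio = wall_times["intermittent"] / wall_times["continuous"]
        assert ratio == pytest.approx(8.0 / 0.4, rel=0.05)


class TestMovie:
    def test_zero_emitters_zero_noise_gives_flat_offset(self):
        cfg = hq.SimConfig(seed=1, n_frames=4, read_noise_sd=0.0,
                           background_rate=0.0, offset=100.0)
        movie, _ = hq.simulate_movie(cfg, [])
        assert np.all(movie.frames == 100.0)

    def test_movie_determinism(self):
        frames = []
        for _ in range(2):
            cfg = hq.SimConfig(seed=9, n_frames=5, field_shape=(32, 32))
            truth = hq.EmitterTruth(emitter_id=0, x=16.0, y=16.0, dye_counts=[4])
            movie, _ = hq.simulate_movie(cfg, [truth])
            frames.append(movie.frames.copy())
        assert np.array_equal(frames[0], frames[1])

    def test_out_of_field_emitter_rejected(self):
        cfg = hq.SimConfig(seed=1, n_frames=2, field_shape=(16, 16))
        truth = hq.EmitterTruth(emitter_id=0, x=20.0, y=5.0, dye_counts=[1])
        with pytest.raises(ValueError, match="outside"):
            hq.simulate_movie(cfg, [truth])

    def test_photon_conservation_in_5_sigma_window(self):
        # noise off: integrated PSF mass over +/-5 sigma equals the emitted
        # counts to within Gaussian truncation (<0.5%)
        cfg = hq.SimConfig(seed=1, n_frames=1, field_shape=(41, 41),
                           read_noise_sd=0.0, background_rate=0.0, offset=0.0,
                           psf_sigma=1.3, bleach_tau=1e12)
        truth = hq.EmitterTruth(emitter_id=0, x=20.3, y=19.6, dye_counts=[2],
                                dye_bleach_times=[1e11, 1e11])
        movie, _ = hq.simulate_movie(cfg, [truth])
        # Poisson sampling would break exactness; use the expectation instead
        # by regenerating without shot noise via a huge photon count
        expected = 2 * cfg.photons_per_dye_per_frame
        total = movie.frames[0].sum()     # Poisson draw of the expectation
        # compare the *expected* image: rebuild deterministically
        from heliquant.simulate import _pixel_gaussian
        x0, gx = _pixel_gaussian(20.3, 41, 1.3, 8)
        y0, gy = _pixel_gaussian(19.6, 41, 1.3, 8)
        mass = np.outer(gy, gx).sum() * expected
        assert mass == pytest.approx(expected, rel=5e-3)
        # and the Poisson realisation is statistically consistent
        assert abs(total - expected) < 5 * math.sqrt(expected)

    def test_movie_io_round_trip(self, tmp_path):
        cfg = hq.SimConfig(seed=2, n_frames=3, field_shape=(16, 16))
        truth = hq.EmitterTruth(emitter_id=0, x=8.0, y=8.0, dye_counts=[3])
        movie, truths = hq.simulate_movie(cfg, [truth])
        hq.write_movie(movie, tmp_path / "mv")
        back = hq.simulate.read_movie(tmp_path / "mv")
        assert back.frames.shape == movie.frames.shape
        assert np.allclose(back.times, movie.times)
        hq.write_truths(truths, tmp_path / "truth.json")
        loaded = hq.load_truths(tmp_path / "truth.json")
        assert loaded[0].dye_counts == truths[0].dye_counts
        assert loaded[0].bound_intervals == truths[0].bound_intervals


class TestForkScenario:
    def test_kymograph_shows_tilted_line(self):
        cfg = hq.SimConfig(seed=3, n_frames=20, field_shape=(24, 64),
                           frame_interval=1.0, exposure=0.5,
                           read_noise_sd=0.0, background_rate=0.0,
                           bleach_tau=1e9)
        anchored = hq.EmitterTruth(emitter_id=0, x=5.0, y=12.0, dye_counts=[4],
                                   dye_bleach_times=[1e8] * 4)
        movie, truths = hq.simulate_fork_scenario(cfg, fork_speed=2.0,
                                                  anchored=anchored)
        kymo = hq.make_kymograph(movie, ((0.0, 12.0), (63.0, 12.0)), width=5)
        peaks = np.argmax(kymo.image, axis=1)
        slope = np.polyfit(movie.times, peaks.astype(float), 1)[0]
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_fork_leaving_field_truncates_with_warning(self):
        cfg = hq.SimConfig(seed=3, n_frames=30, field_shape=(16, 32),
                           frame_interval=1.0)
        anchored = hq.EmitterTruth(emitter_id=0, x=5.0, y=8.0, dye_counts=[2])
        with pytest.warns(UserWarning, match="leaves the field"):
            movie, truths = hq.simulate_fork_scenario(cfg, fork_speed=5.0,
                                                      anchored=anchored)
        assert movie.meta["fork_truncated"]
        assert np.max(truths[0].x) <= 31.0
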