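import numpy as np
import pytest

import puffsd as P
from puffsd.fluctuation import NoiseCalibration

from _oracles import brute_force_sd_stack, expected_noise_variance_factor

GAIN, BLACK, READ = 5.0, 100.0, 1.5


class TestCalibration:
    def test_recovers_gain_times_band_fraction(self, noise_series, calibration,
                                               params):
        expected = GAIN * expected_noise_variance_factor(params, 125.0)
        assert calibration.slope == pytest.approx(expected, rel=0.03)
        assert calibration.scale_c == pytest.approx(np.sqrt(calibration.slope))
        assert calibration.r_squared > 0.99

    def test_sd_scale_below_variance_scale(self, calibration):
        # finite-window SD estimator bias: E[sqrt(v)] < sqrt(E[v])
        assert 0.85 < calibration.sd_slope / calibration.scale_c < 1.0

    def test_noise_free_stacks_give_zero_slope(self):
        stacks = [P.MovieStack(np.full((60, 24, 24), v), 0.008, 0.53)
                  for v in (50.0, 100.0, 200.0)]
        cal = P.calibrate_noise_scale(stacks)
        assert cal.slope == pytest.approx(0.0, abs=1e-12)
        assert cal.scale_c == pytest.approx(0.0, abs=1e-12)

    def test_too_few_levels_rejected(self):
        stacks = P.simulate_noise_series(GAIN, BLACK, READ, [50, 100, 200],
                                         shape=(40, 16, 16), seed=0)
        with pytest.raises(ValueError):
            P.calibrate_noise_scale(stacks[:2])

    def test_degenerate_levels_rejected(self):
        stacks = [P.MovieStack(np.full((60, 16, 16), 100.0), 0.008, 0.53)
                  for _ in range(3)]
        with pytest.raises(ValueError, match="degenerate"):
            P.calibrate_noise_scale(stacks)

    def test_json_round_trip(self, calibration, tmp_path):
        path = calibration.to_json(tmp_path / "cal.json")
        back = NoiseCalibration.from_json(path)
        assert back == calibration


class TestTemporalSDStack:
    def test_matches_explicit_loop_reimplementation(self, params):
        rng = np.random.default_rng(7)
        movie = P.MovieStack(rng.uniform(100, 300, (20, 16, 16)), 0.008, 0.53,
                             black_level=10.0)
        cal = NoiseCalibration(slope=0.04, intercept=0.0, scale_c=0.2,
                               r_squared=1.0, n_levels=5, sd_slope=0.19)
        sd = P.temporal_sd_stack(movie, params, cal)
        ref = brute_force_sd_stack(movie, params, cal)
        ok = np.isfinite(ref)
        assert ok.any()
        np.testing.assert_allclose(sd.data[ok], ref[ok], rtol=1e-6, atol=1e-9)

    def test_pure_shot_noise_nulls_to_zero(self, calibration):
        # spatially/temporally flat corrected SD with mean within 3 SEM of 0
        means = []
        for rep in range(5):
            stack = P.simulate_noise_series(GAIN, BLACK, READ, [80, 80, 80],
                                            shape=(250, 40, 40),
                                            seed=500 + rep)[0]
            sd = P.temporal_sd_stack(stack, calibration=calibration)
            # average over steady-state frames, past the filter transient
            means.append(np.nanmean(sd.data[52:-52, 8:-8, 8:-8]))
        mean = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mean) < 3 * sem

    def test_single_puff_localized(self, calibration):
        site = P.PuffSite(y=20, x=26, events=[(1.0, 0.5)])
        config = P.SyntheticConfig(shape=(400, 48, 48), puff_sites=[site],
                                   global_rise=None)
        movie, truth = P.simulate_movie(config, seed=3)
        sd = P.temporal_sd_stack(movie, calibration=calibration)
        lo, hi = sd.valid_range
        data = np.nan_to_num(sd.data[lo:hi])
        t_idx, y_idx, x_idx = np.unravel_index(np.argmax(data), data.shape)
        assert abs(y_idx - 20) <= 1 and abs(x_idx - 26) <= 1
        event_center = 1.0 + site.kernel_peak_time()
        frame_err = abs((t_idx + lo) * movie.frame_interval - event_center)
        assert frame_err <= (sd.window_frames / 2) * movie.frame_interval

    def test_short_record_rejected(self, params):
        movie = P.MovieStack(np.zeros((10, 8, 8)), 0.008, 0.53)
        with pytest.raises(ValueError):
            P.temporal_sd_stack(movie, params)

    def test_uncorrected_sd_grows_as_sqrt_intensity(self, params):
        # Poisson noise: SD proportional to sqrt(mean); corrected SD flat
        levels = [50.0, 100.0, 200.0, 400.0]
        stacks = P.simulate_noise_series(GAIN, BLACK, READ, levels,
                                         shape=(150, 32, 32), seed=77)
        sds = []
        for stack in stacks:
            sd = P.temporal_sd_stack(stack, params)  # no calibration
            lo, hi = sd.valid_range
            sds.append(np.nanmean(sd.data[lo:hi, 8:-8, 8:-8]))
        ratios = np.array(sds) / np.sqrt(GAIN * np.array(levels))
        assert np.std(ratios) / np.mean(ratios) < 0.05

    def test_doubling_amplitude_never_reduces_peak_sd(self, calibration):
        peaks = []
        for amp in (0.125, 0.25, 0.5, 1.0, 2.0):
            site = P.PuffSite(y=16, x=16, events=[(0.6, amp)])
            config = P.SyntheticConfig(shape=(220, 32, 32), puff_sites=[site],
                                       global_rise=None)
            movie, _ = P.simulate_movie(config, seed=9)
            sd = P.temporal_sd_stack(movie, calibration=calibration)
            peaks.append(np.nanmax(sd.data))
        assert np.all(np.diff(peaks) > 0)


class TestSpatialSDTrace:
    def test_uniform_flicker_has_no_spatial_variance(self):
        rng = np.random.default_rng(1)
        frame_course = rng.normal(0, 5, 300)
        data = 100.0 + np.tile(frame_course[:, None, None], (1, 24, 24))
        movie = P.MovieStack(data, 0.008, 0.53)
        trace = P.spatial_sd_trace(movie, None)
        assert np.abs(trace.values).max() < 1e-9

    def test_shot_noise_nulls_to_zero(self, spatial_calibration):
        means = []
        for rep in range(5):
            stack = P.simulate_noise_series(GAIN, BLACK, READ, [100] * 3,
                                            shape=(150, 64, 64),
                                            seed=900 + rep)[0]
            mask = np.zeros((64, 64), dtype=bool)
            mask[16:-16, 16:-16] = True
            tr = P.spatial_sd_trace(stack, mask, calibration=spatial_calibration)
            means.append(tr.values[40:-40].mean())
        mean = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mean) < 3 * sem

    def test_tracks_temporal_sd_during_flurry(self, flurry_recording,
                                              spatial_calibration):
        temporal = flurry_recording["sd_trace"]
        spatial = P.spatial_sd_trace(flurry_recording["movie"],
                                     flurry_recording["mask"],
                                     calibration=spatial_calibration)
        n = min(len(temporal), len(spatial))
        r = np.corrcoef(temporal.values[:n], spatial.values[:n])[0, 1]
        assert r > 0.8

    def test_empty_mask_rejected(self):
        movie = P.MovieStack(np.zeros((60, 16, 16)) + 100.0, 0.008, 0.53)
        with pytest.raises(ValueError):
            P.spatial_sd_trace(movie, np.zeros((16, 16), dtype=bool))


class TestPowerSpectrum:
    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(2)
        ps = P.power_spectrum(rng.normal(0, 1, (50, 1024)), fs=125.0)
        sel = (ps.frequencies >= 3) & (ps.frequencies <= 50)
        slope = np.polyfit(np.log(ps.frequencies[sel]), np.log(ps.power[sel]), 1)[0]
        assert abs(slope) < 0.1

    def test_sinusoid_peak_bin(self):
        t = np.arange(512) / 125.0
        x = np.sin(2 * np.pi * 10.0 * t)
        ps = P.power_spectrum(x[None, :], fs=125.0)
        f_peak = ps.frequencies[np.argmax(ps.power)]
        df = ps.frequencies[1] - ps.frequencies[0]
        assert abs(f_peak - 10.0) <= df

    def test_parseval_within_one_percent(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, (8, 512))
        ps = P.power_spectrum(x, fs=125.0)
        hp = P.temporal_highpass(x.T, 1.0, fs=125.0).T
        hp = hp - hp.mean(axis=1, keepdims=True)
        df = ps.frequencies[1] - ps.frequencies[0]
        assert np.sum(ps.power) * df == pytest.approx(hp.var(axis=1).mean(),
                                                      rel=0.01)

    def test_unequal_lengths_rejected(self):
        a = P.Trace(np.arange(100) * 0.008, np.zeros(100))
        b = P.Trace(np.arange(80) * 0.008, np.zeros(80))
        with pytest.raises(ValueError):
            P.power_spectrum([a, b])

    def test_short_traces_rejected(self):
        with pytest.raises(ValueError):
            P.power_spectrum(np.zeros((2, 32)), fs=125.0)
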