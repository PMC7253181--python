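import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import puffsd as P


def make_trace(values, dt=0.008, **kw):
    values = np.asarray(values, dtype=float)
    return P.Trace(np.arange(values.size) * dt, values, **kw)


class TestDff0:
    def test_baseline_equals_signal_gives_zero(self):
        tr = make_trace(np.full(200, 50.0))
        out = P.compute_dff0(tr, baseline_frames=100)
        np.testing.assert_allclose(out.values, 0.0)

    def test_doubling_gives_one(self):
        values = np.concatenate([np.full(100, 50.0), np.full(100, 100.0)])
        out = P.compute_dff0(make_trace(values), baseline_frames=100)
        assert out.values[-1] == pytest.approx(1.0)

    def test_movie_baseline_is_pixelwise(self):
        rng = np.random.default_rng(0)
        f0 = rng.uniform(50, 150, (8, 8))
        data = np.tile(f0, (120, 1, 1))
        data[100:] *= 3.0
        movie = P.MovieStack(data, 0.008, 0.53, t0_stimulus=100)
        out = P.compute_dff0(movie, baseline_frames=100)
        np.testing.assert_allclose(out.data[:100], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data[100:], 2.0, rtol=1e-12)

    def test_programmed_global_peak_recovered(self, calibration):
        config = P.SyntheticConfig(shape=(1200, 40, 40), puff_sites=[],
                                   global_rise=P.GlobalRise(amplitude=6.9,
                                                            onset_s=1.5))
        movie, _ = P.simulate_movie(config, seed=21)
        mask = np.zeros((40, 40), dtype=bool)
        mask[6:-6, 6:-6] = True
        cell = P.roi_trace(P.subtract_black(movie, movie.black_level), mask)
        cell.t0_stimulus = movie.t0_stimulus
        dff = P.compute_dff0(cell, baseline_frames=100)
        assert dff.values.max() == pytest.approx(6.9, rel=0.05)

    @given(gain=st.floats(0.1, 100.0))
    def test_invariant_to_camera_gain(self, gain):
        values = np.concatenate([np.full(50, 20.0), np.linspace(20, 80, 50)])
        a = P.compute_dff0(make_trace(values), baseline_frames=50)
        b = P.compute_dff0(make_trace(values * gain), baseline_frames=50)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        tr = make_trace(np.concatenate([np.zeros(50), np.ones(50)]))
        with pytest.raises(ValueError):
            P.compute_dff0(tr, baseline_frames=50)


class TestRoiTrace:
    def test_full_mask_on_constant_frames(self):
        movie = P.MovieStack(np.full((10, 6, 6), 4.2), 0.008, 0.53)
        tr = P.roi_trace(movie, np.ones((6, 6), dtype=bool))
        np.testing.assert_allclose(tr.values, 4.2)

    def test_single_pixel_mask(self):
        rng = np.random.default_rng(0)
        movie = P.MovieStack(rng.normal(size=(20, 6, 6)), 0.008, 0.53)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = True
        tr = P.roi_trace(movie, mask)
        np.testing.assert_array_equal(tr.values, movie.data[:, 2, 3])

    def test_union_of_disjoint_rois_averages(self):
        data = np.zeros((5, 4, 4))
        data[:, :2] = 1.0
        data[:, 2:] = 3.0
        movie = P.MovieStack(data, 0.008, 0.53)
        tr = P.roi_trace(movie, np.ones((4, 4), dtype=bool))
        np.testing.assert_allclose(tr.values, 2.0)


class TestScatter:
    def test_constant_sd_over_monotone_rise(self):
        dff = make_trace(np.linspace(0, 3, 400))
        sd = dff.with_values(np.ones(400))
        scatter = P.sd_vs_dff_scatter(sd, dff, t_start=0.0,
                                      t_peak=float(dff.times[-1]))
        occupied = np.isfinite(scatter.mean_sd)
        assert occupied.sum() >= 25
        np.testing.assert_allclose(scatter.mean_sd[occupied], 1.0)

    def test_inverted_u_argmax_near_two(self):
        # SD engineered to peak when dF/F0 crosses 2 during the rise
        dff = make_trace(np.linspace(0, 4, 2000))
        sd = dff.with_values(np.exp(-((dff.values - 2.0) ** 2) / (2 * 0.5**2)))
        scatter = P.sd_vs_dff_scatter(sd, dff)
        assert abs(scatter.argmax_center - 2.0) <= 0.1

    def test_normalized_peak_is_one(self):
        dff = make_trace(np.linspace(0, 3, 500))
        sd = dff.with_values(np.linspace(0, 5, 500))
        scatter = P.sd_vs_dff_scatter(sd, dff, normalize=True)
        assert np.nanmax(scatter.mean_sd) == pytest.approx(1.0)

    def test_resampling_changes_bins_little(self):
        t = np.linspace(0, 4, 800)
        dff_v = 3.0 * (t / 4.0)
        sd_v = np.exp(-((dff_v - 1.5) ** 2))
        coarse = P.sd_vs_dff_scatter(P.Trace(t, sd_v), P.Trace(t, dff_v))
        t2 = np.linspace(0, 4, 1600)
        dff2 = 3.0 * (t2 / 4.0)
        sd2 = np.exp(-((dff2 - 1.5) ** 2))
        fine = P.sd_vs_dff_scatter(P.Trace(t2, sd2), P.Trace(t2, dff2))
        n = min(len(coarse.mean_sd), len(fine.mean_sd))
        a, b = coarse.mean_sd[:n], fine.mean_sd[:n]
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.all(np.abs(a[ok] - b[ok]) / np.abs(b[ok]).max() < 0.02)

    def test_empty_window_rejected(self):
        dff = make_trace(np.linspace(0, 3, 100))
        sd = dff.with_values(np.ones(100))
        with pytest.raises(ValueError):
            P.sd_vs_dff_scatter(sd, dff, t_start=2.0, t_peak=1.0)


class TestIntegralsAndRatios:
    def test_zero_and_constant_integrals(self):
        t = np.linspace(0, 3, 301)
        assert P.puff_activity_integral(P.Trace(t, np.zeros(301)), 0, 3) == 0.0
        assert P.puff_activity_integral(P.Trace(t, np.full(301, 2.0)), 0, 3) == \
            pytest.approx(6.0)

    def test_matches_oversampled_rectangle_sum(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 2, 400)
        base = np.cumsum(rng.normal(size=40))
        v = np.interp(t, np.linspace(0, 2, 40), base)  # smooth random trace
        integral = P.puff_activity_integral(P.Trace(t, v), 0.1, 1.9)
        tf = np.linspace(0.1, 1.9, 40000)
        ref = np.sum(np.interp(tf, t, v)) * (tf[1] - tf[0])
        assert integral == pytest.approx(ref, rel=1e-3)

    def test_window_outside_record_rejected(self):
        tr = make_trace(np.ones(10))
        with pytest.raises(ValueError):
            P.puff_activity_integral(tr, -1.0, 0.05)

    def test_activity_ratio(self):
        assert P.activity_ratio(6.0, 3.0) == 2.0
        assert P.activity_ratio(6.0, 3.0, reference=(6.0, 3.0)) == 1.0
        with pytest.raises(ValueError):
            P.activity_ratio(6.0, 0.0)

    def test_proportional_decline_keeps_ratio_constant(self):
        # repeat-stimulus responses whose SD integral and peak both scale down
        rng = np.random.default_rng(11)
        t = np.linspace(0, 5, 500)
        base_sd = np.exp(-((t - 1.0) ** 2) / 0.1)
        ratios = []
        reference = None
        for scale in (1.0, 0.8, 0.6, 0.45, 0.3):
            sd = base_sd * scale * (1 + rng.normal(0, 0.01, t.size))
            integral = P.puff_activity_integral(P.Trace(t, sd), 0, 5)
            peak = 4.0 * scale
            if reference is None:
                reference = (integral, peak)
            ratios.append(P.activity_ratio(integral, peak, reference))
        assert np.all(np.abs(np.array(ratios) - 1.0) < 0.1)


class TestKinetics:
    def test_ideal_ramp(self):
        t = np.linspace(0, 1, 1001)
        kin = P.kinetics(P.Trace(t, t))
        assert kin.rise_20_80 == pytest.approx(0.6, abs=1e-6)

    def test_exponential_fall_closed_form(self):
        k = 0.32
        t = np.linspace(0, 30, 6001)
        values = np.concatenate([np.linspace(0, 1, 100), np.exp(-k * t[:-100])])
        tr = P.Trace(np.arange(values.size) * 0.005, values)
        kin = P.kinetics(tr)
        assert kin.fall_80_20 == pytest.approx(np.log(4.0) / k, rel=1e-3)

    def test_flat_trace_flagged(self):
        kin = P.kinetics(make_trace(np.zeros(50)))
        assert not kin.defined
        assert np.isnan(kin.rise_20_80)

    def test_monotone_tail_gives_nan_fall(self):
        t = np.linspace(0, 1, 200)
        kin = P.kinetics(P.Trace(t, t))  # never decays
        assert np.isnan(kin.fall_80_20)
        assert np.isfinite(kin.rise_20_80)

    @given(seed=st.integers(0, 50))
    def test_time_reversal_swaps_rise_and_fall(self, seed):
        rng = np.random.default_rng(seed)
        n = 201
        t = np.linspace(0, 2, n)
        up = np.sort(rng.uniform(0, 1, n // 2))
        values = np.concatenate([up, [1.0], up[::-1] * 0.0 + up[::-1]])
        fwd = P.kinetics(P.Trace(t, values))
        rev = P.kinetics(P.Trace(t, values[::-1]))
        if np.isfinite(fwd.rise_20_80) and np.isfinite(rev.fall_80_20):
            assert fwd.rise_20_80 == pytest.approx(rev.fall_80_20, abs=1e-9)
            assert fwd.fall_80_20 == pytest.approx(rev.rise_20_80, abs=1e-9)
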