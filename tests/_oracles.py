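"""Independent oracles used by the tests.

These deliberately avoid the package's optimized code paths: moments are
recomputed with explicit loops, expected noise transfer comes from the
analytic Butterworth frequency response, and the removal ODE is solved in
closed form for piecewise-constant flux.
"""

import numpy as np
from scipy import signal

from puffsd.filtering import GAUSS_TRUNCATE, spatial_blur, temporal_bandpass


def gaussian_kernel_1d(sigma, truncate=GAUSS_TRUNCATE):
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def expected_noise_variance_factor(params, fs):
    """Expected windowed variance of unit-variance white noise after the
    blur + (zero-phase) band-pass chain, from the analytic response.

    The temporal autocovariance of the filtered noise is the inverse FFT of
    |H|^4 (|H|^2 for a causal pass); a boxcar of n frames then shrinks the
    population variance to r0 - (1/n)[r0 + 2*sum (1 - l/n) r_l].  The spatial
    blur contributes an independent factor sum(kernel^2).
    """
    n = 1 << 14
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sos = signal.butter(params.butter_order, [params.band_low, params.band_high],
                        btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    power = np.abs(h) ** (4 if params.zero_phase else 2)
    acov = np.fft.irfft(power, n)
    w = params.window_frames
    lags = np.arange(1, w)
    temporal = acov[0] - (acov[0] + 2.0 * np.sum((1.0 - lags / w) * acov[lags])) / w
    g1 = gaussian_kernel_1d(params.spatial_sigma)
    spatial = float(np.sum(g1**2)) ** 2
    return float(temporal * spatial)


def brute_force_sd_stack(movie, params, calibration=None):
    """Explicit-loop re-implementation of the temporal SD pipeline."""
    x = movie.data - movie.black_level
    blurred = spatial_blur(x, params.spatial_sigma)
    filt = temporal_bandpass(blurred, params.band_low, params.band_high,
                             fs=movie.fs, order=params.butter_order,
                             zero_phase=params.zero_phase)
    T, Y, X = x.shape
    w = params.window_frames
    off = w // 2
    c = 0.0 if calibration is None else calibration.correction_scale
    out = np.full((T, Y, X), np.nan)
    for i in range(T - w + 1):
        for yy in range(Y):
            for xx in range(X):
                seg = filt[i : i + w, yy, xx]
                var = np.mean(seg**2) - np.mean(seg) ** 2
                sd = np.sqrt(max(var, 0.0))
                if c > 0:
                    m = np.mean(blurred[i : i + w, yy, xx])
                    sd -= c * np.sqrt(max(m, 0.0))
                out[i + off, yy, xx] = sd
    return out


def boxcar_response_closed_form(times, height, t_on, t_off, k):
    """F(t) solving dF/dt = r - k*F, F(0)=0, for a boxcar flux r."""
    f = np.zeros_like(times)
    during = (times >= t_on) & (times < t_off)
    f[during] = height / k * (1.0 - np.exp(-k * (times[during] - t_on)))
    f_end = height / k * (1.0 - np.exp(-k * (t_off - t_on)))
    after = times >= t_off
    f[after] = f_end * np.exp(-k * (times[after] - t_off))
    return f
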