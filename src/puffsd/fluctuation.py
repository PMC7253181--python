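"""Core fluctuation-analysis algorithms.

The temporal pipeline turns a fluorescence movie ``F`` (camera counts) into a
shot-noise-corrected running-SD stack::

    SD(t, y, x) = sqrt(var_w[bandpass(blur(F))]) - c * sqrt(mean_w[blur(F)])

where ``var_w``/``mean_w`` are population variance and mean over a centred
boxcar of ``window_frames`` frames and ``c`` is an empirically calibrated
shot-noise scale.  Hot spots in the SD stack report transient, localized
Ca2+ release (puffs) even when riding on a large, slow global elevation; the
corrected SD is *not* clipped at zero — around pure shot noise it fluctuates
about zero.

Shot-noise calibration
----------------------
For photon-counting (Poisson) noise the variance of the filtered movie grows
linearly with mean intensity; the scale is obtained by ordinary least squares
on uniform-intensity series (a fluorescein-style dilution ladder), processed
through the *identical* filter chain.  Two scales are fitted:

* ``scale_c = sqrt(slope)`` of filtered variance vs mean intensity — the
  classical definition;
* ``sd_slope``, the slope of mean running-*SD* vs sqrt(mean intensity).

The running SD of band-limited noise over a short (20-frame) window is
systematically below ``sqrt(slope * mean)`` because ``E[sqrt(v)] <
sqrt(E[v])`` (Jensen's inequality; 5–8% for the default chain).  Subtracting
the SD-scale prediction therefore nulls the corrected SD exactly in the mean,
and :func:`temporal_sd_stack` uses ``sd_slope`` whenever it is available.

The spatial pipeline is the cross-check: a per-frame difference-of-Gaussians
(σ = 2 px and 8 px) acts as a spatial band-pass, the spatial variance over
the cell mask is reduced to a per-frame SD, shot noise is subtracted with a
scale calibrated the same way on DoG-filtered images, and the trace is
smoothed with a 160 ms boxcar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .filtering import (
    FilterParams,
    running_moments,
    spatial_blur,
    subtract_black,
    temporal_bandpass,
    temporal_highpass,
    valid_window_range,
)
from .movie_io import MovieStack, ROIMask, Trace

__all__ = [
    "NoiseCalibration",
    "SDStack",
    "PowerSpectrumResult",
    "calibrate_noise_scale",
    "temporal_sd_stack",
    "spatial_sd_trace",
    "power_spectrum",
]


@dataclass
class NoiseCalibration:
    """Shot-noise scale from a variance-vs-mean regression.

    ``slope`` is filtered variance per camera count and ``scale_c`` its square
    root (SD per sqrt-count).  ``sd_slope`` is the directly fitted slope of
    mean running SD vs sqrt(mean count); it already includes the finite-window
    bias of the SD estimator and is what the SD correction should use.
    """

    slope: float
    intercept: float
    scale_c: float
    r_squared: float
    n_levels: int
    sd_slope: float | None = None
    sd_intercept: float | None = None
    mode: str = "temporal"

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if not np.isclose(self.scale_c, np.sqrt(self.slope)):
            raise ValueError("scale_c must equal sqrt(slope)")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def correction_scale(self) -> float:
        """Scale actually used for the sqrt(mean) subtraction."""
        return self.scale_c if self.sd_slope is None else self.sd_slope

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "scale_c": self.scale_c,
            "r_squared": self.r_squared,
            "n_levels": self.n_levels,
            "sd_slope": self.sd_slope,
            "sd_intercept": self.sd_intercept,
            "mode": self.mode,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "NoiseCalibration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SDStack:
    """Running-SD image stack (shot-noise corrected unless scale was 0).

    ``data`` has the source movie's shape; frames whose boxcar window was
    incomplete are NaN (see :attr:`valid_range`).  Values are in arbitrary
    units and may be negative after correction.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    window_frames: int
    params: FilterParams
    t0_stimulus: int | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def valid_range(self) -> tuple[int, int]:
        """Half-open frame range with complete windows."""
        return valid_window_range(self.n_frames, self.window_frames)

    def trace(self, mask: ROIMask | np.ndarray | None = None,
              name: str = "sd") -> Trace:
        """Whole-cell (or ROI) SD trace: per-frame mean over masked pixels,
        invalid edge frames dropped."""
        if mask is None:
            m = np.ones(self.frame_shape, dtype=bool)
        else:
            roi = mask if isinstance(mask, ROIMask) else ROIMask(mask)
            roi.check_compatible(self)
            m = roi.mask
        lo, hi = self.valid_range
        values = self.data[lo:hi, m].mean(axis=1)
        return Trace(self.times[lo:hi], values, units="SD A.U.", name=name)


@dataclass
class PowerSpectrumResult:
    """One-sided power spectral density averaged over traces."""

    frequencies: np.ndarray
    power: np.ndarray
    n_averaged: int

    def band_power(self, f_low: float, f_high: float) -> float:
        """Integrated power over [f_low, f_high] (trapezoidal, A.U.^2)."""
        sel = (self.frequencies >= f_low) & (self.frequencies <= f_high)
        if sel.sum() < 2:
            raise ValueError(f"band [{f_low}, {f_high}] Hz covers < 2 bins")
        return float(np.trapezoid(self.power[sel], self.frequencies[sel]))


def _as_movie(movie) -> MovieStack:
    if isinstance(movie, MovieStack):
        return movie
    raise TypeError(f"expected MovieStack, got {type(movie).__name__}")


def _interior(frame_shape: tuple[int, int], margin_px: int) -> tuple[slice, slice]:
    my = min(margin_px, (frame_shape[0] - 1) // 2)
    mx = min(margin_px, (frame_shape[1] - 1) // 2)
    return slice(my, frame_shape[0] - my or None), slice(mx, frame_shape[1] - mx or None)


def calibrate_noise_scale(
    level_stacks: Sequence[MovieStack],
    params: FilterParams | None = None,
    mode: str = "temporal",
) -> NoiseCalibration:
    """Fit the shot-noise scale from >= 3 uniform-intensity series.

    Each stack is black-subtracted and passed through the identical filter
    chain used by the corresponding SD pipeline before its variance is
    measured; the OLS slope of mean filtered variance vs mean raw intensity
    across levels gives ``slope`` (and ``scale_c = sqrt(slope)``).  Border
    pixels within the blur kernel support and frames within the filter
    start-up transient are excluded from the averages.
    """
    params = params or FilterParams()
    if mode not in ("temporal", "spatial"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    if len(level_stacks) < 3:
        raise ValueError(f"need >= 3 intensity levels, got {len(level_stacks)}")

    means, mean_vars, mean_sds = [], [], []
    for stack in level_stacks:
        stack = _as_movie(stack)
        fs = stack.fs
        params.validate_rate(fs)
        x = stack.data - stack.black_level
        sigma_max = params.spatial_sigma_wide if mode == "spatial" else params.spatial_sigma
        # cap the border crop so at least half the frame remains: the spatial
        # variance must be measured over a region much larger than the DoG
        # correlation length or the scale is badly underestimated
        margin = min(int(np.ceil(4 * sigma_max)),
                     stack.frame_shape[0] // 4, stack.frame_shape[1] // 4)
        ys, xs = _interior(stack.frame_shape, margin)
        t_margin = int(round(fs / params.band_low))
        t_sel = slice(min(t_margin, stack.n_frames // 4), stack.n_frames - min(t_margin, stack.n_frames // 4))

        if mode == "temporal":
            blurred = spatial_blur(x, params.spatial_sigma)
            filt = temporal_bandpass(blurred, params.band_low, params.band_high,
                                     fs=fs, order=params.butter_order,
                                     zero_phase=params.zero_phase)
            _, var = running_moments(filt, params.window_frames)
            region = var[t_sel, ys, xs]
            region = region[np.isfinite(region)]
            means.append(float(x[:, ys, xs].mean()))
            mean_vars.append(float(region.mean()))
            mean_sds.append(float(np.sqrt(region).mean()))
        else:
            filt = temporal_bandpass(x, params.band_low, params.band_high,
                                     fs=fs, order=params.butter_order,
                                     zero_phase=params.zero_phase)
            dog = (spatial_blur(filt, params.spatial_sigma)
                   - spatial_blur(filt, params.spatial_sigma_wide))
            patch = dog[t_sel, ys, xs]
            var_t = patch.reshape(patch.shape[0], -1).var(axis=1)
            means.append(float(x[:, ys, xs].mean()))
            mean_vars.append(float(var_t.mean()))
            mean_sds.append(float(np.sqrt(var_t).mean()))

    means = np.asarray(means)
    mean_vars = np.asarray(mean_vars)
    mean_sds = np.asarray(mean_sds)
    if np.ptp(means) <= 0:
        raise ValueError("intensity levels are degenerate (all means equal)")

    slope, intercept = np.polyfit(means, mean_vars, 1)
    slope = max(float(slope), 0.0)
    predicted = slope * means + intercept
    ss_res = float(np.sum((mean_vars - predicted) ** 2))
    ss_tot = float(np.sum((mean_vars - mean_vars.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sd_slope, sd_intercept = np.polyfit(np.sqrt(means), mean_sds, 1)

    return NoiseCalibration(
        slope=slope,
        intercept=float(intercept),
        scale_c=float(np.sqrt(slope)),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_levels=len(level_stacks),
        sd_slope=max(float(sd_slope), 0.0),
        sd_intercept=float(sd_intercept),
        mode=mode,
    )


def temporal_sd_stack(
    movie: MovieStack,
    params: FilterParams | None = None,
    calibration: NoiseCalibration | None = None,
) -> SDStack:
    """Run the temporal fluctuation pipeline on a movie.

    The movie is black-subtracted (using its ``black_level``), spatially
    blurred, temporally band-passed, reduced to a running SD, and corrected
    by subtracting ``c * sqrt(running mean of the blurred movie)`` with the
    same centred window for both moments.  Without a calibration the SD is
    returned uncorrected.
    """
    movie = _as_movie(movie)
    params = params or FilterParams()
    fs = movie.fs
    params.validate_rate(fs)
    if movie.n_frames < params.window_frames:
        raise ValueError(
            f"movie of {movie.n_frames} frames shorter than window "
            f"{params.window_frames}"
        )
    x = movie.data - movie.black_level
    blurred = spatial_blur(x, params.spatial_sigma)
    filtered = temporal_bandpass(blurred, params.band_low, params.band_high,
                                 fs=fs, order=params.butter_order,
                                 zero_phase=params.zero_phase)
    _, var = running_moments(filtered, params.window_frames)
    sd = np.sqrt(var)
    if calibration is not None and calibration.correction_scale > 0:
        mean_b, _ = running_moments(blurred, params.window_frames)
        # floor at 0 inside the sqrt: a negative running mean is pure noise
        sd = sd - calibration.correction_scale * np.sqrt(np.maximum(mean_b, 0.0))
    return SDStack(
        data=sd,
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        window_frames=params.window_frames,
        params=params,
        t0_stimulus=movie.t0_stimulus,
    )


def spatial_sd_trace(
    movie: MovieStack,
    cell_mask: ROIMask | np.ndarray | None,
    params: FilterParams | None = None,
    calibration: NoiseCalibration | None = None,
) -> Trace:
    """Spatial-fluctuation cross-check trace.

    Per frame of the band-passed movie: difference of weak (σ=2 px) and
    strong (σ=8 px) Gaussian blurs, spatial variance over the masked pixels,
    square root, subtraction of the predicted spatial shot noise
    (``c_spatial * sqrt(mean masked intensity)``), then a
    ``window_frames``-long boxcar average of the resulting trace.
    """
    movie = _as_movie(movie)
    params = params or FilterParams()
    params.validate_rate(movie.fs)
    if cell_mask is None:
        roi = ROIMask(np.ones(movie.frame_shape, dtype=bool), label="full-field")
    else:
        roi = cell_mask if isinstance(cell_mask, ROIMask) else ROIMask(cell_mask)
    roi.check_compatible(movie)

    x = movie.data - movie.black_level
    filtered = temporal_bandpass(x, params.band_low, params.band_high,
                                 fs=movie.fs, order=params.butter_order,
                                 zero_phase=params.zero_phase)
    dog = (spatial_blur(filtered, params.spatial_sigma)
           - spatial_blur(filtered, params.spatial_sigma_wide))
    pixels = dog[:, roi.mask]
    sd_t = pixels.std(axis=1)
    if calibration is not None and calibration.correction_scale > 0:
        mean_t = x[:, roi.mask].mean(axis=1)
        sd_t = sd_t - calibration.correction_scale * np.sqrt(np.maximum(mean_t, 0.0))
    # centred boxcar; trim frames with incomplete windows
    w = params.window_frames
    kernel = np.ones(w) / w
    smooth = np.convolve(sd_t, kernel, mode="valid")
    lo, hi = valid_window_range(movie.n_frames, w)
    return Trace(movie.times[lo:hi], smooth, units="spatial SD A.U.",
                 name="spatial_sd")


def power_spectrum(
    traces: Sequence[Trace] | np.ndarray,
    fs: float | None = None,
    highpass_cutoff: float = 1.0,
) -> PowerSpectrumResult:
    """Average one-sided PSD of ROI traces after a 1 Hz high-pass.

    Each trace is high-pass filtered to strip the slow global rise, tapered
    with a Hann window, and its periodogram rescaled so that total power
    integrates exactly to the filtered trace's variance (Parseval).  Spectra
    are then averaged across traces.
    """
    if isinstance(traces, np.ndarray):
        arr = np.atleast_2d(np.asarray(traces, dtype=np.float64))
        if fs is None:
            raise ValueError("fs must be given for bare arrays")
    else:
        traces = list(traces)
        if not traces:
            raise ValueError("need at least one trace")
        lengths = {len(tr) for tr in traces}
        if len(lengths) > 1:
            raise ValueError(f"traces have unequal lengths {sorted(lengths)}")
        fs = fs if fs is not None else 1.0 / traces[0].dt
        arr = np.stack([tr.values for tr in traces])
    if arr.shape[1] < 64:
        raise ValueError(f"traces of {arr.shape[1]} samples are too short (need >= 64)")

    hp = temporal_highpass(arr.T, cutoff=highpass_cutoff, fs=fs).T
    hp = hp - hp.mean(axis=1, keepdims=True)
    freqs, pxx = signal.periodogram(hp, fs=fs, window="hann",
                                    detrend=False, axis=1)
    df = freqs[1] - freqs[0]
    total = pxx.sum(axis=1) * df
    var = hp.var(axis=1)
    scale = np.where(total > 0, var / np.where(total > 0, total, 1.0), 0.0)
    pxx = pxx * scale[:, None]
    return PowerSpectrumResult(
        frequencies=freqs,
        power=pxx.mean(axis=0),
        n_averaged=arr.shape[0],
    )
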