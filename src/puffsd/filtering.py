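"""Shared signal-conditioning primitives.

Black-offset subtraction, per-frame spatial Gaussian blur (4-sigma truncated
kernel), pixel-wise temporal Butterworth band/high-pass filtering, and running
boxcar moments.  All operations accept either a bare array, a
:class:`~puffsd.movie_io.MovieStack` (metadata propagates unchanged) or, for
the temporal filters, a :class:`~puffsd.movie_io.Trace`.

Defaults follow the fluctuation-analysis recipe this package implements:
2-pixel blur, 3–20 Hz pass band, 20-frame (160 ms at 125 fps) boxcar window.
The Butterworth order is not part of the published recipe and defaults to 2;
zero-phase (forward–backward) application is the default so that SD transients
stay aligned in time with the fluorescence trace they are derived from.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, signal

from .movie_io import MovieStack, Trace

__all__ = [
    "FilterParams",
    "subtract_black",
    "spatial_blur",
    "temporal_bandpass",
    "temporal_highpass",
    "running_moments",
]

#: Kernel support of the spatial Gaussian, in units of sigma.
GAUSS_TRUNCATE = 4.0


@dataclass
class FilterParams:
    """Parameters of the fluctuation-analysis filter chain.

    spatial_sigma / spatial_sigma_wide are in pixels (the wide sigma is used
    only by the spatial difference-of-Gaussians pipeline); band cutoffs in Hz;
    window_frames is the boxcar length for running moments.
    """

    spatial_sigma: float = 2.0
    spatial_sigma_wide: float = 8.0
    band_low: float = 3.0
    band_high: float = 20.0
    butter_order: int = 2
    zero_phase: bool = True
    window_frames: int = 20

    def __post_init__(self) -> None:
        if not (self.spatial_sigma > 0):
            raise ValueError("spatial_sigma must be > 0")
        if not (self.spatial_sigma_wide > self.spatial_sigma):
            raise ValueError("spatial_sigma_wide must exceed spatial_sigma")
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")

    def validate_rate(self, fs: float) -> None:
        """Check the pass band against the Nyquist frequency of ``fs``."""
        if self.band_high >= fs / 2:
            raise ValueError(
                f"band_high {self.band_high} Hz >= Nyquist {fs / 2} Hz"
            )

    def window_duration(self, frame_interval: float) -> float:
        """Boxcar duration in seconds for a given frame interval."""
        return self.window_frames * frame_interval

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "FilterParams":
        return cls(**payload)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "FilterParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _unwrap(obj):
    """Return (array, wrapper) where wrapper re-attaches metadata."""
    if isinstance(obj, MovieStack):
        return obj.data, lambda out, **kw: obj.with_data(out, **kw)
    if isinstance(obj, Trace):
        return obj.values, lambda out, **kw: obj.with_values(out)
    arr = np.asarray(obj, dtype=np.float64)
    return arr, lambda out, **kw: out


def subtract_black(stack, black_level: float):
    """Subtract the camera black offset; negative results are retained (they
    represent noise about zero)."""
    if black_level < 0:
        raise ValueError("black_level must be >= 0")
    data, wrap = _unwrap(stack)
    out = data - black_level
    if isinstance(stack, MovieStack):
        return wrap(out, black_level=0.0)
    return wrap(out)


def spatial_blur(stack, sigma_px: float):
    """Blur each frame with a 2-D Gaussian of ``sigma_px`` truncated at 4σ.

    Borders are handled by reflection, so frame sums are conserved away from
    the borders.  A sigma larger than the frame is rejected.
    """
    if not (sigma_px > 0):
        raise ValueError("sigma must be > 0")
    data, wrap = _unwrap(stack)
    if data.ndim == 2:
        data = data[np.newaxis]
    if sigma_px > min(data.shape[1], data.shape[2]):
        raise ValueError(
            f"sigma {sigma_px} px exceeds frame dimensions {data.shape[1:]}"
        )
    out = ndimage.gaussian_filter(
        data, sigma=(0.0, sigma_px, sigma_px), mode="reflect", truncate=GAUSS_TRUNCATE
    )
    return wrap(out)


def _resolve_fs(obj, fs):
    if fs is not None:
        return float(fs)
    if isinstance(obj, MovieStack):
        return obj.fs
    if isinstance(obj, Trace):
        return 1.0 / obj.dt
    raise ValueError("fs must be given for bare arrays")


def _apply_sos(data: np.ndarray, sos: np.ndarray, fs: float, f_low: float,
               zero_phase: bool) -> np.ndarray:
    """Filter along axis 0 with generous reflective padding.

    The pad length is three periods of the lowest frequency of interest
    (capped at T-1), which suppresses the start-up transient of slow
    components far better than the default few-sample padding.
    """
    T = data.shape[0]
    padlen = int(min(T - 1, round(3.0 * fs / f_low)))
    if zero_phase:
        return signal.sosfiltfilt(sos, data, axis=0, padtype="even", padlen=padlen)
    if padlen > 0:
        idx = np.arange(padlen, 0, -1)
        head = data[idx, ...] if data.ndim > 1 else data[idx]
        padded = np.concatenate([head, data], axis=0)
        return signal.sosfilt(sos, padded, axis=0)[padlen:]
    return signal.sosfilt(sos, data, axis=0)


def temporal_bandpass(obj, band_low: float = 3.0, band_high: float = 20.0,
                      fs: float | None = None, order: int = 2,
                      zero_phase: bool = True):
    """Butterworth band-pass along the time axis, pixel by pixel.

    DC is removed and the pass-band gain is ~1 (exactly |H|^2 of the one-way
    filter when ``zero_phase``).  Raises if ``band_high`` reaches Nyquist or
    the record is too short for the filter order.
    """
    data, wrap = _unwrap(obj)
    fs = _resolve_fs(obj, fs)
    if not (0 < band_low < band_high):
        raise ValueError("need 0 < band_low < band_high")
    if band_high >= fs / 2:
        raise ValueError(f"band_high {band_high} Hz >= Nyquist {fs / 2} Hz")
    if data.shape[0] <= 3 * order:
        raise ValueError(f"record of {data.shape[0]} frames too short for order {order}")
    sos = signal.butter(order, [band_low, band_high], btype="bandpass", fs=fs,
                        output="sos")
    return wrap(_apply_sos(data, sos, fs, band_low, zero_phase))


def temporal_highpass(obj, cutoff: float = 1.0, fs: float | None = None,
                      order: int = 2, zero_phase: bool = True):
    """Butterworth high-pass along the time axis (single corner)."""
    data, wrap = _unwrap(obj)
    fs = _resolve_fs(obj, fs)
    if not (0 < cutoff < fs / 2):
        raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist={fs / 2}) Hz")
    if data.shape[0] <= 3 * order:
        raise ValueError(f"record of {data.shape[0]} frames too short for order {order}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return wrap(_apply_sos(data, sos, fs, cutoff, zero_phase))


def running_moments(obj, window_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Center-aligned running mean and population variance along time.

    For each pixel the population variance over a ``window_frames`` boxcar is
    computed as mean-of-square minus square-of-mean.  Output arrays have the
    input length; frames whose window would be incomplete are NaN.  The window
    assigned to output frame ``i`` covers frames
    ``[i - window_frames//2, i - window_frames//2 + window_frames)``.
    """
    data, _ = _unwrap(obj)
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    T = data.shape[0]
    if window_frames > T:
        raise ValueError(f"window of {window_frames} frames exceeds record length {T}")
    pad = np.zeros((1,) + data.shape[1:], dtype=np.float64)
    c1 = np.concatenate([pad, np.cumsum(data, axis=0)], axis=0)
    c2 = np.concatenate([pad, np.cumsum(data * data, axis=0)], axis=0)
    s1 = (c1[window_frames:] - c1[:-window_frames]) / window_frames
    s2 = (c2[window_frames:] - c2[:-window_frames]) / window_frames
    var = s2 - s1 * s1
    np.maximum(var, 0.0, out=var)  # clip tiny negative round-off
    mean_full = np.full(data.shape, np.nan)
    var_full = np.full(data.shape, np.nan)
    offset = window_frames // 2
    mean_full[offset : offset + s1.shape[0]] = s1
    var_full[offset : offset + var.shape[0]] = var
    return mean_full, var_full


def valid_window_range(n_frames: int, window_frames: int) -> tuple[int, int]:
    """Half-open frame range over which running-window outputs are defined."""
    offset = window_frames // 2
    return offset, offset + n_frames - window_frames + 1
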