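"""Derived measurements: ΔF/F₀, ROI traces, SD-vs-ΔF/F₀ binned scatter,
puff-activity integrals and rise/fall kinetics.

Conventions
-----------
* ΔF/F₀ uses F₀ = mean over a pre-stimulus baseline window (default 100
  frames, the light-sheet convention; configurable).
* The SD-vs-ΔF/F₀ scatter bins per-frame SD samples by the concurrent
  ΔF/F₀ at 0.1-wide intervals over the rising phase of the global signal.
* Rise/fall kinetics are 20→80% (pre-peak) and 80→20% (post-peak) threshold
  crossings of the peak amplitude, located by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie_io import MovieStack, ROIMask, Trace

__all__ = [
    "BinnedScatter",
    "KineticsSummary",
    "compute_dff0",
    "roi_trace",
    "sd_vs_dff_scatter",
    "puff_activity_integral",
    "activity_ratio",
    "kinetics",
]


@dataclass
class BinnedScatter:
    """Per-bin mean SD against binned ΔF/F₀ (contiguous 0.1-wide bins)."""

    bin_edges: np.ndarray
    mean_sd: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def argmax_center(self) -> float:
        """Centre of the occupied bin with the largest mean SD."""
        if not np.any(np.isfinite(self.mean_sd)):
            raise ValueError("no occupied bins")
        return float(self.bin_centers[np.nanargmax(self.mean_sd)])


@dataclass
class KineticsSummary:
    """Peak amplitude and 20–80% rise / 80–20% fall times of a trace.

    Undefined quantities (flat trace, monotone tail) are NaN rather than
    errors.
    """

    peak_dff0: float
    t_peak: float
    rise_20_80: float
    fall_80_20: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.peak_dff0) and self.peak_dff0 > 0


def _baseline_window(obj, baseline_frames: int):
    """Frame range used for F0: the `baseline_frames` frames immediately
    before the stimulus when t0_stimulus is set, else the leading frames."""
    t0 = getattr(obj, "t0_stimulus", None)
    if t0 is not None:
        stop = int(t0)
        start = max(0, stop - baseline_frames)
    else:
        start, stop = 0, baseline_frames
    if stop - start < 1:
        raise ValueError("empty baseline window")
    return start, stop


def compute_dff0(obj, baseline_frames: int = 100, f0_floor: float = 0.0):
    """Fluorescence change relative to the pre-stimulus baseline, (F−F₀)/F₀.

    Applied pixel-wise to movies (F₀ is a per-pixel baseline image) and
    sample-wise to traces (F₀ is a scalar).  Raises if the baseline window is
    empty or any evaluated F₀ is at or below ``f0_floor``.
    """
    if isinstance(obj, MovieStack):
        start, stop = _baseline_window(obj, baseline_frames)
        if stop > obj.n_frames:
            raise ValueError("baseline window exceeds record")
        x = obj.data - obj.black_level
        f0 = x[start:stop].mean(axis=0)
        if np.min(f0) <= f0_floor:
            raise ValueError(
                f"baseline F0 reaches {np.min(f0):.3g} <= floor {f0_floor}"
            )
        return obj.with_data((x - f0) / f0, black_level=0.0)
    if isinstance(obj, Trace):
        start, stop = _baseline_window(obj, baseline_frames)
        if stop > len(obj):
            raise ValueError("baseline window exceeds record")
        f0 = obj.values[start:stop].mean()
        if f0 <= f0_floor:
            raise ValueError(f"baseline F0 {f0:.3g} <= floor {f0_floor}")
        return obj.with_values((obj.values - f0) / f0, units="dF/F0")
    raise TypeError(f"expected MovieStack or Trace, got {type(obj).__name__}")


def roi_trace(stack, roi: ROIMask | np.ndarray, name: str | None = None) -> Trace:
    """Per-frame mean over the masked pixels of a movie or SD stack."""
    roi = roi if isinstance(roi, ROIMask) else ROIMask(roi)
    roi.check_compatible(stack)
    data = stack.data
    times = stack.times
    values = data[:, roi.mask].mean(axis=1)
    finite = np.isfinite(values)
    return Trace(times[finite], values[finite],
                 name=name if name is not None else (roi.label or "roi"))


def sd_vs_dff_scatter(
    sd_trace: Trace,
    dff_trace: Trace,
    t_start: float | None = None,
    t_peak: float | None = None,
    bin_width: float = 0.1,
    normalize: bool = False,
    min_count: int = 3,
) -> BinnedScatter:
    """Bin SD samples by concurrent ΔF/F₀ over the rising phase.

    The window defaults to [first sample, time of the ΔF/F₀ maximum].  Traces
    must share a time base (the SD trace may be the shorter valid-window
    segment of it).  Bins with fewer than ``min_count`` samples report NaN.
    """
    # align on the SD trace's times (its valid window is a subset)
    idx = np.searchsorted(dff_trace.times, sd_trace.times)
    idx = np.clip(idx, 0, len(dff_trace) - 1)
    if not np.allclose(dff_trace.times[idx], sd_trace.times, rtol=1e-9, atol=1e-9):
        raise ValueError("SD and dF/F0 traces do not share a time base")
    dff = dff_trace.values[idx]
    times = sd_trace.times
    if t_peak is None:
        t_peak = float(dff_trace.times[np.argmax(dff_trace.values)])
    if t_start is None:
        t_start = float(times[0])
    if not (t_start < t_peak):
        raise ValueError(f"need t_start < t_peak, got {t_start} >= {t_peak}")
    sel = (times >= t_start) & (times <= t_peak)
    if not sel.any():
        raise ValueError("no samples in the rising-phase window")
    dff = dff[sel]
    sd = sd_trace.values[sel]

    lo = np.floor(dff.min() / bin_width) * bin_width
    hi = np.ceil(dff.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    which = np.clip(((dff - lo) / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sd, minlength=n_bins)
    mean_sd = np.full(n_bins, np.nan)
    ok = counts >= min_count
    mean_sd[ok] = sums[ok] / counts[ok]
    if normalize:
        peak = np.nanmax(np.abs(mean_sd)) if np.any(ok) else np.nan
        if peak and np.isfinite(peak):
            mean_sd = mean_sd / peak
    return BinnedScatter(edges, mean_sd, counts, normalized=normalize)


def _integrate(trace: Trace, t0: float, t1: float) -> float:
    """Trapezoidal integral over [t0, t1] with interpolated endpoints."""
    times, values = trace.times, trace.values
    if t0 >= t1:
        raise ValueError(f"need t0 < t1, got {t0} >= {t1}")
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError(
            f"window [{t0}, {t1}] outside record [{times[0]}, {times[-1]}]"
        )
    inner = (times > t0) & (times < t1)
    ts = np.concatenate(([t0], times[inner], [t1]))
    vs = np.concatenate((
        [np.interp(t0, times, values)],
        values[inner],
        [np.interp(t1, times, values)],
    ))
    return float(np.trapezoid(vs, ts))


def puff_activity_integral(sd_trace: Trace, t0: float, t1: float) -> float:
    """Integral under the SD trace over [t0, t1] (A.U.·s); a measure of total
    puff activity.  Negative excursions are included as-is."""
    return _integrate(sd_trace, t0, t1)


def activity_ratio(sd_integral: float, peak_dff0: float,
                   reference: tuple[float, float] | None = None) -> float:
    """Puff activity per unit global signal: ``sd_integral / peak_dff0``.

    With ``reference=(ref_integral, ref_peak)`` the ratio is normalized to
    that reference response (e.g. the initial stimulus of a train).
    """
    if peak_dff0 <= 0:
        raise ValueError(f"peak dF/F0 must be > 0, got {peak_dff0}")
    ratio = sd_integral / peak_dff0
    if reference is not None:
        ref_int, ref_peak = reference
        if ref_peak <= 0:
            raise ValueError("reference peak must be > 0")
        ref_ratio = ref_int / ref_peak
        if ref_ratio == 0:
            raise ValueError("reference ratio is zero")
        ratio = ratio / ref_ratio
    return float(ratio)


def _cross_time(times, values, level, i_from, i_to):
    """Linear-interpolated crossing of `level` scanning from i_from toward
    i_to (inclusive); returns NaN if never crossed."""
    step = 1 if i_to >= i_from else -1
    prev = i_from
    for i in range(i_from + step, i_to + step, step):
        a, b = values[prev], values[i]
        if (a - level) * (b - level) <= 0 and a != b:
            frac = (level - a) / (b - a)
            return float(times[prev] + frac * (times[i] - times[prev]))
        if a == level:
            return float(times[prev])
        prev = i
    return np.nan


def kinetics(trace: Trace, t_stimulus: float = 0.0) -> KineticsSummary:
    """20–80% rise and 80–20% fall times of the post-stimulus peak.

    Threshold levels are fractions of the peak value (ΔF/F₀ baseline is 0).
    A trace without a positive post-stimulus peak yields NaN kinetics; a tail
    that never falls back below 20% leaves the fall undefined (NaN).
    """
    sel = trace.times >= t_stimulus
    if not sel.any():
        raise ValueError("no samples at or after t_stimulus")
    times = trace.times[sel]
    values = trace.values[sel]
    i_peak = int(np.argmax(values))
    peak = float(values[i_peak])
    if peak <= 0 or np.ptp(values) == 0:
        return KineticsSummary(np.nan, np.nan, np.nan, np.nan)
    t_peak = float(times[i_peak])
    lvl20, lvl80 = 0.2 * peak, 0.8 * peak
    # rise: scan backwards from the peak for the 80% then 20% crossings
    t80_up = _cross_time(times, values, lvl80, i_peak, 0)
    t20_up = _cross_time(times, values, lvl20, i_peak, 0)
    rise = t80_up - t20_up if np.isfinite(t80_up) and np.isfinite(t20_up) else np.nan
    # fall: scan forward from the peak
    last = len(times) - 1
    t80_dn = _cross_time(times, values, lvl80, i_peak, last)
    t20_dn = _cross_time(times, values, lvl20, i_peak, last)
    fall = t20_dn - t80_dn if np.isfinite(t80_dn) and np.isfinite(t20_dn) else np.nan
    return KineticsSummary(peak_dff0=peak, t_peak=t_peak,
                           rise_20_80=rise, fall_80_20=fall)
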