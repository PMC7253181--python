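"""Ground-truthed synthetic recordings for the fluctuation pipeline.

The generator emulates the *phenomenology* of a Cal520-loaded HEK cell imaged
on an EMCCD at ~125 frames/s: a smooth global ΔF/F₀ rise of a few units over
seconds, stationary puff sites that emit transients lasting tens to a couple
of hundred ms and confined to ~1 µm, and camera noise (gain × Poisson photon
noise + Gaussian read noise + black offset).  It is an imaging-statistics
emulator, not a reaction–diffusion model of IP₃ receptor gating.

Model
-----
Photon rate per pixel and frame::

    lambda(t, y, x) = baseline_photons * (1 + g(t) + sum_events a_e * s(y,x) * h(t - t_e))

with ``g`` the global-rise profile, ``s`` a unit-peak 2-D Gaussian of the
site's spatial sigma, and ``h`` a unit-peak (1 − e^(−u/τr)) · e^(−u/τd)
kernel.  Counts are ``gain * Poisson(lambda) + black + N(0, read²)``.  The
global rise uses a C¹-smooth onset, (1 − e^(−u/τr))² · e^(−k·u), normalized
to the requested peak: global elevations rise smoothly, with no intrinsic
content in the 3–20 Hz fluctuation band.

Puff timing is an inhomogeneous Poisson process whose rate follows an
inverted-U in the concurrent global ΔF/F₀ (puff activity is maximal when the
global signal is around 2 ΔF/F₀ and terminates before the peak) — a test
fixture mirroring the empirical shape, not a mechanistic claim.  Sites can
also be given explicit event times for fully deterministic fixtures.

Every stochastic choice derives from a single seed; identical seeds give
bit-identical movies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .movie_io import MovieStack, Trace

__all__ = [
    "CameraModel",
    "GlobalRise",
    "PuffSite",
    "SyntheticConfig",
    "GroundTruth",
    "FluxPairTruth",
    "simulate_movie",
    "simulate_noise_series",
    "simulate_decay_trace",
    "simulate_flux_pair",
]


@dataclass
class CameraModel:
    """EMCCD-style count model: counts = gain·Poisson(photons) + offset + read."""

    gain: float = 5.0            # counts per detected photon
    black_level: float = 100.0   # counts
    read_noise: float = 1.5      # counts, Gaussian sigma

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.black_level < 0 or self.read_noise < 0:
            raise ValueError("invalid camera model")


@dataclass
class GlobalRise:
    """Smooth global ΔF/F₀ elevation: C¹ onset, first-order removal decay."""

    amplitude: float = 6.9       # peak dF/F0
    onset_s: float = 1.0
    rise_tau_s: float = 1.0
    removal_k_per_s: float = 0.22

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.rise_tau_s <= 0 or self.removal_k_per_s <= 0:
            raise ValueError("invalid global-rise parameters")

    def profile(self, times: np.ndarray) -> np.ndarray:
        """ΔF/F₀ versus time, normalized so the sampled maximum equals
        ``amplitude`` (zero before onset)."""
        u = np.asarray(times, dtype=np.float64) - self.onset_s
        shape = np.where(
            u > 0,
            (1.0 - np.exp(-np.clip(u, 0, None) / self.rise_tau_s)) ** 2
            * np.exp(-self.removal_k_per_s * np.clip(u, 0, None)),
            0.0,
        )
        peak = shape.max()
        if peak > 0:
            shape = shape * (self.amplitude / peak)
        return shape


@dataclass
class PuffSite:
    """A stationary puff site.

    Events are either drawn from an inhomogeneous Poisson process
    (``rate_mode='inverted_u'`` peaking where the global ΔF/F₀ crosses
    ``u_center``, or ``'constant'``), gated to the rising phase of the global
    signal, or supplied explicitly as ``events=[(onset_s, amplitude), ...]``.
    """

    y: int
    x: int
    sigma_um: float = 1.0
    amplitude: float = 0.5       # local peak dF/F0 per event
    rise_tau_s: float = 0.020
    decay_tau_s: float = 0.060
    rate_max_hz: float = 8.0
    rate_mode: str = "inverted_u"
    u_center: float = 2.0        # global dF/F0 at which the rate peaks
    u_width: float = 1.0
    events: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.sigma_um <= 0 or self.amplitude < 0:
            raise ValueError("invalid puff-site geometry/amplitude")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("puff time constants must be > 0")
        if self.rate_mode not in ("inverted_u", "constant"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")

    def kernel_peak_time(self) -> float:
        tr, td = self.rise_tau_s, self.decay_tau_s
        return tr * np.log((tr + td) / tr)

    def temporal_kernel(self, u: np.ndarray) -> np.ndarray:
        """Unit-peak rise-and-decay kernel evaluated at lags ``u`` (s)."""
        tr, td = self.rise_tau_s, self.decay_tau_s
        up = np.clip(u, 0.0, None)
        h = (1.0 - np.exp(-up / tr)) * np.exp(-up / td)
        h[u < 0] = 0.0
        u_pk = self.kernel_peak_time()
        h_pk = (1.0 - np.exp(-u_pk / tr)) * np.exp(-u_pk / td)
        return h / h_pk

    def duration_s(self, threshold: float = 0.05) -> float:
        """Event duration: time the kernel exceeds ``threshold`` of its peak."""
        u = np.linspace(0.0, 20.0 * self.decay_tau_s, 4096)
        h = self.temporal_kernel(u)
        above = np.flatnonzero(h >= threshold)
        return float(u[above[-1]] - u[above[0]]) if above.size else 0.0


@dataclass
class SyntheticConfig:
    """Full generative description of a simulated recording.

    Defaults correspond to a TIRF-style recording: 125 frames/s, 0.53 µm
    binned pixels, baseline of 80 photons/frame/pixel (~400 counts at the
    default gain of 5), global rise to 6.9 ΔF/F₀, EMCCD-like noise.
    """

    shape: tuple[int, int, int] = (1000, 48, 48)
    frame_interval: float = 0.008
    pixel_size: float = 0.53
    baseline_photons: float | np.ndarray = 80.0
    global_rise: GlobalRise | None = field(default_factory=GlobalRise)
    puff_sites: list[PuffSite] = field(default_factory=list)
    camera: CameraModel = field(default_factory=CameraModel)
    sat_dff_half: float | None = None   # optional dye-saturation half point
    seed: int | None = None

    def __post_init__(self) -> None:
        T, Y, X = self.shape
        if T < 1 or Y < 1 or X < 1:
            raise ValueError(f"invalid shape {self.shape}")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        base = np.asarray(self.baseline_photons, dtype=np.float64)
        if np.any(base <= 0):
            raise ValueError("baseline_photons must be > 0")
        if base.ndim == 2 and base.shape != (Y, X):
            raise ValueError("baseline map does not match frame shape")
        for site in self.puff_sites:
            if not (0 <= site.y < Y and 0 <= site.x < X):
                raise ValueError(f"puff site ({site.y}, {site.x}) out of bounds")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.shape[0]) * self.frame_interval

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["baseline_photons"] = (
            self.baseline_photons.tolist()
            if isinstance(self.baseline_photons, np.ndarray)
            else self.baseline_photons
        )
        payload["shape"] = list(self.shape)
        return payload

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        payload = dict(payload)
        payload["shape"] = tuple(payload["shape"])
        if payload.get("global_rise") is not None:
            payload["global_rise"] = GlobalRise(**payload["global_rise"])
        sites = []
        for entry in payload.get("puff_sites", []):
            entry = dict(entry)
            if entry.get("events") is not None:
                entry["events"] = [tuple(e) for e in entry["events"]]
            sites.append(PuffSite(**entry))
        payload["puff_sites"] = sites
        if payload.get("camera") is not None:
            payload["camera"] = CameraModel(**payload["camera"])
        if isinstance(payload.get("baseline_photons"), list):
            payload["baseline_photons"] = np.asarray(payload["baseline_photons"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Everything the analyzer should recover from a simulated movie."""

    events: pd.DataFrame            # site, t_onset_s, duration_s, amplitude, y, x
    true_k: float | None
    true_gain: float
    global_dff: Trace
    true_release_rate: Trace | None

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(directory / "events.csv", index=False)
        payload = {"true_k": self.true_k, "true_gain": self.true_gain}
        (directory / "truth.json").write_text(json.dumps(payload, indent=2))


@dataclass
class FluxPairTruth:
    """Exact construction parameters of a control/suppressed flux pair."""

    fraction: float
    t_end_s: float
    k: float


def _draw_events(site: PuffSite, times: np.ndarray, global_dff: np.ndarray,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    if site.events is not None:
        return [(float(t), float(a)) for t, a in site.events]
    dt = times[1] - times[0] if times.size > 1 else 1.0
    if site.rate_mode == "inverted_u":
        rate = site.rate_max_hz * np.exp(
            -((global_dff - site.u_center) ** 2) / (2.0 * site.u_width**2)
        )
    else:
        rate = np.full_like(times, site.rate_max_hz)
    # gate the flurry to the rising phase of the global signal, if there is one
    if global_dff.max() > 0:
        i_peak = int(np.argmax(global_dff))
        active = np.zeros_like(times, dtype=bool)
        active[: i_peak + 1] = global_dff[: i_peak + 1] > 0
        rate = np.where(active, rate, 0.0)
    cum = np.cumsum(rate) * dt
    total = cum[-1]
    if total <= 0:
        return []
    n = rng.poisson(total)
    if n == 0:
        return []
    draws = np.sort(rng.uniform(0.0, total, size=n))
    onsets = np.interp(draws, cum, times)
    return [(float(t), float(site.amplitude)) for t in onsets]


def simulate_movie(config: SyntheticConfig, seed: int | None = None,
                   ) -> tuple[MovieStack, GroundTruth]:
    """Generate a movie and its ground truth.

    The same ``seed`` always yields a bit-identical movie.  Returns the movie
    in camera counts (float64, values are what a 16-bit camera would deliver)
    plus the true event table, global ΔF/F₀, removal constant, camera gain and
    the true release-rate trace implied by the global component.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    T, Y, X = config.shape
    times = config.times
    dt = config.frame_interval

    global_dff = (config.global_rise.profile(times)
                  if config.global_rise is not None else np.zeros(T))

    dff = np.tile(global_dff[:, None, None], (1, Y, X))
    yy, xx = np.mgrid[0:Y, 0:X]
    rows = []
    for i_site, site in enumerate(config.puff_sites):
        sigma_px = site.sigma_um / config.pixel_size
        footprint = np.exp(-((yy - site.y) ** 2 + (xx - site.x) ** 2)
                           / (2.0 * sigma_px**2))
        duration = site.duration_s()
        for onset, amplitude in _draw_events(site, times, global_dff, rng):
            h = site.temporal_kernel(times - onset)
            if amplitude > 0 and h.max() > 0:
                dff += (amplitude * h)[:, None, None] * footprint[None, :, :]
            rows.append({
                "site": i_site, "t_onset_s": onset, "duration_s": duration,
                "amplitude": amplitude, "y": site.y, "x": site.x,
            })
    events = pd.DataFrame(
        rows, columns=["site", "t_onset_s", "duration_s", "amplitude", "y", "x"]
    )

    if config.sat_dff_half is not None:
        # phenomenological dye saturation: response compresses toward high dF/F0
        dff = dff * config.sat_dff_half / (config.sat_dff_half + dff)

    base = np.asarray(config.baseline_photons, dtype=np.float64)
    lam = base * (1.0 + dff) if base.ndim == 2 else base * (1.0 + dff)
    cam = config.camera
    counts = (cam.gain * rng.poisson(lam).astype(np.float64)
              + cam.black_level
              + rng.normal(0.0, cam.read_noise, size=lam.shape))

    t0 = (int(round(config.global_rise.onset_s / dt))
          if config.global_rise is not None else None)
    movie = MovieStack(counts, frame_interval=dt, pixel_size=config.pixel_size,
                       black_level=cam.black_level, t0_stimulus=t0)

    true_k = (config.global_rise.removal_k_per_s
              if config.global_rise is not None else None)
    global_trace = Trace(times, global_dff, units="dF/F0", name="global_dff")
    release = None
    if true_k is not None:
        r = np.gradient(global_dff, dt, edge_order=1) + true_k * global_dff
        release = Trace(times, r, units="dF/F0 per s", name="true_release_rate")
    truth = GroundTruth(events=events, true_k=true_k, true_gain=cam.gain,
                        global_dff=global_trace, true_release_rate=release)
    return movie, truth


def simulate_noise_series(
    gain: float,
    offset: float,
    read_sigma: float,
    levels: Sequence[float],
    shape: tuple[int, int, int] = (200, 48, 48),
    seed: int = 0,
    frame_interval: float = 0.008,
    pixel_size: float = 0.53,
) -> list[MovieStack]:
    """Uniform-intensity stationary stacks at each photon level — the
    synthetic counterpart of a fluorescein dilution ladder for shot-noise
    calibration.  ``levels`` are mean photons/frame/pixel."""
    if len(levels) < 3:
        raise ValueError(f"need >= 3 levels, got {len(levels)}")
    rng = np.random.default_rng(seed)
    stacks = []
    for level in levels:
        if level < 0:
            raise ValueError("levels must be >= 0")
        if level == 0:
            counts = np.full(shape, float(offset))
        else:
            counts = (gain * rng.poisson(level, size=shape).astype(np.float64)
                      + offset + rng.normal(0.0, read_sigma, size=shape))
        stacks.append(MovieStack(counts, frame_interval=frame_interval,
                                 pixel_size=pixel_size, black_level=offset))
    return stacks


def simulate_decay_trace(a: float, k: float, c: float, noise_sigma: float,
                         duration: float, dt: float, seed: int = 0) -> Trace:
    """A·exp(−k·t) + C plus Gaussian noise; test input for removal-rate fits."""
    if k <= 0:
        raise ValueError("k must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, dt)
    values = a * np.exp(-k * times) + c
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=times.shape)
    return Trace(times, values, units="dF/F0", name="decay")


def integrate_removal_ode(release: np.ndarray, k: float, dt: float) -> np.ndarray:
    """Integrate dF/dt = r(t) − k·F with F(0)=0 (exponential trapezoidal
    stepping, O(dt²))."""
    decay = np.exp(-k * dt)
    f = np.zeros_like(release, dtype=np.float64)
    for i in range(1, release.size):
        f[i] = f[i - 1] * decay + 0.5 * dt * (release[i] + release[i - 1] * decay)
    return f


def simulate_flux_pair(control_flux: np.ndarray, puff_fraction: float, k: float,
                       dt: float) -> tuple[Trace, Trace, FluxPairTruth]:
    """Build a control / puff-suppressed ΔF/F₀ pair with a known early-flux
    excess.

    ``control_flux`` is the control release rate sampled at ``dt``.  The
    suppressed flux equals ``(1 − puff_fraction) · control`` up to the time
    the control ΔF/F₀ peaks and the control flux thereafter, so the exact area
    fraction missing from the suppressed trace over [0, t_peak] equals
    ``puff_fraction``.
    """
    if not (0.0 <= puff_fraction <= 1.0):
        raise ValueError("puff_fraction must lie in [0, 1]")
    if k <= 0 or dt <= 0:
        raise ValueError("k and dt must be > 0")
    r_control = np.asarray(control_flux, dtype=np.float64)
    if r_control.ndim != 1 or r_control.size < 3:
        raise ValueError("control_flux must be a 1-D array of >= 3 samples")
    times = np.arange(r_control.size) * dt
    f_control = integrate_removal_ode(r_control, k, dt)
    i_end = int(np.argmax(f_control))
    t_end = float(times[i_end])
    r_suppressed = r_control.copy()
    r_suppressed[: i_end + 1] *= 1.0 - puff_fraction
    f_suppressed = integrate_removal_ode(r_suppressed, k, dt)
    truth = FluxPairTruth(fraction=float(puff_fraction), t_end_s=t_end, k=float(k))
    return (
        Trace(times, f_control, units="dF/F0", name="dff_control"),
        Trace(times, f_suppressed, units="dF/F0", name="dff_suppressed"),
        truth,
    )
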