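"""Image-stack and trace I/O with acquisition metadata.

Movies are carried as :class:`MovieStack` objects: a ``T x Y x X`` array of
camera counts plus the acquisition metadata (frame interval, pixel size,
camera black level, optional stimulus frame) that every downstream stage
needs.  TIFF reading/writing goes through :mod:`tifffile`; MetaMorph ``.stk``
files are plain multi-page TIFFs for our purposes and are read the same way.

Pixel coordinates are 0-based, row-major ``(frame, row, col)``; physical
conversions always go through ``pixel_size`` (µm/pixel) and
``frame_interval`` (s/frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "ROIMask",
    "Trace",
    "read_movie",
    "write_stack",
    "read_mask",
    "write_mask",
    "save_traces",
    "load_traces",
]


@dataclass
class MovieStack:
    """A fluorescence movie in camera units with acquisition metadata.

    Parameters
    ----------
    data:
        ``T x Y x X`` array.  Integer input is promoted to float64 without
        value change; all processing is done in floating point.
    frame_interval:
        Seconds per frame (e.g. ``0.008`` for ~125 frames/s TIRF).
    pixel_size:
        µm per pixel at the specimen (e.g. ``0.53`` for 2x2-binned EMCCD).
    black_level:
        Camera black offset in counts; subtracted before any analysis.
    t0_stimulus:
        Frame index of stimulus onset (photolysis flash / agonist), if known.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    black_level: float = 0.0
    t0_stimulus: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise ValueError(f"movie data must be T x Y x X, got shape {data.shape}")
        if data.shape[0] < 1 or data.shape[1] < 1 or data.shape[2] < 1:
            raise ValueError(f"empty movie of shape {data.shape}")
        data = data.astype(np.float64, copy=False)
        if not np.all(np.isfinite(data)):
            raise ValueError("movie contains non-finite values")
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.black_level < 0:
            raise ValueError(f"black_level must be >= 0, got {self.black_level}")
        self.data = data

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def fs(self) -> float:
        """Sampling rate in frames per second."""
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, **overrides) -> "MovieStack":
        """Return a copy carrying ``data`` with metadata propagated."""
        out = replace(self, data=data)
        for key, value in overrides.items():
            setattr(out, key, value)
        return out


@dataclass
class ROIMask:
    """Boolean region-of-interest mask over a movie's spatial frame."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError(f"mask {self.label!r} has no true pixels")
        self.mask = mask

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def check_compatible(self, stack_like) -> None:
        shape = getattr(stack_like, "frame_shape", None)
        if shape is None:
            shape = np.asarray(stack_like).shape[-2:]
        if tuple(shape) != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match frame shape {tuple(shape)}"
            )


@dataclass
class Trace:
    """A sampled time series (times in seconds, strictly increasing)."""

    times: np.ndarray
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("trace times and values must be 1-D")
        if times.shape != values.shape:
            raise ValueError(
                f"times ({times.shape}) and values ({values.shape}) differ in length"
            )
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        self.times = times
        self.values = values

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sampling interval; raises if sampling is not uniform."""
        if len(self) < 2:
            raise ValueError("trace too short to define a sampling interval")
        steps = np.diff(self.times)
        dt = float(steps[0])
        if not np.allclose(steps, dt, rtol=1e-6, atol=1e-12):
            raise ValueError("trace is not uniformly sampled")
        return dt

    def with_values(self, values: np.ndarray, units: str | None = None,
                    name: str | None = None) -> "Trace":
        return Trace(
            self.times.copy(),
            values,
            self.units if units is None else units,
            self.name if name is None else name,
        )

    def crop(self, t0: float, t1: float) -> "Trace":
        sel = (self.times >= t0) & (self.times <= t1)
        if not sel.any():
            raise ValueError(f"no samples in [{t0}, {t1}]")
        return Trace(self.times[sel], self.values[sel], self.units, self.name)


def read_movie(
    path,
    frame_interval: float,
    pixel_size: float,
    black_level: float = 0.0,
    t0_stimulus: int | None = None,
) -> MovieStack:
    """Read a single- or multi-page TIFF (or MetaMorph .stk) as a MovieStack.

    Raises ``ValueError`` on ragged page shapes or non-positive metadata and
    ``FileNotFoundError``/``tifffile`` errors on unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such movie file: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(
                f"{path.name}: pages have inconsistent shapes {sorted(shapes)}"
            )
        data = tif.asarray()
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 2-D/3-D stack, got {data.shape}")
    return MovieStack(
        data=data,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        black_level=black_level,
        t0_stimulus=t0_stimulus,
    )


def write_stack(stack, path) -> Path:
    """Write a stack (MovieStack, SD stack, or bare array) as float32 TIFF.

    Values (including negatives, e.g. shot-noise-corrected SD) are preserved;
    ``read_movie(write_stack(x))`` reproduces the float32 values bit-exactly.
    """
    data = np.asarray(getattr(stack, "data", stack))
    if data.size == 0:
        raise ValueError("refusing to write an empty stack")
    if data.ndim == 2:
        data = data[np.newaxis]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")
    return path


def read_mask(path, label: str | None = None) -> ROIMask:
    """Read an ROI mask from an 8-bit TIFF (non-zero = inside) or a run-length
    JSON file ``{"shape": [Y, X], "runs": [[start, length], ...]}`` with runs
    indexing the row-major flattened frame."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        shape = tuple(payload["shape"])
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        for start, length in payload["runs"]:
            flat[start : start + length] = True
        mask = flat.reshape(shape)
    else:
        mask = tifffile.imread(path)
        if mask.ndim == 3 and mask.shape[0] == 1:
            mask = mask[0]
        mask = np.asarray(mask) != 0
    return ROIMask(mask, label=label if label is not None else path.stem)


def write_mask(roi: ROIMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        flat = roi.mask.ravel()
        edges = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.uint8), [0]))))
        runs = [[int(s), int(e - s)] for s, e in zip(edges[::2], edges[1::2])]
        path.write_text(json.dumps({"shape": list(roi.mask.shape), "runs": runs}))
    else:
        tifffile.imwrite(path, roi.mask.astype(np.uint8) * 255)
    return path


def save_traces(traces: Mapping[str, Trace] | Sequence[Trace], path,
                long_form: bool = False) -> Path:
    """Save traces to CSV.

    Wide form (default) requires all traces to share one time base and writes
    columns ``time_s,<name>,...``; ``long_form=True`` stores heterogeneous
    traces as ``time_s,trace,value`` rows.  Raises on duplicate names or, in
    wide form, on mismatched time bases.
    """
    if not isinstance(traces, Mapping):
        named = {}
        for i, tr in enumerate(traces):
            name = tr.name or f"trace{i}"
            if name in named:
                raise ValueError(f"duplicate trace name {name!r}")
            named[name] = tr
        traces = named
    if not traces:
        raise ValueError("no traces to save")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if long_form:
        frames = [
            pd.DataFrame({"time_s": tr.times, "trace": name, "value": tr.values})
            for name, tr in traces.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return path
    items = list(traces.items())
    base = items[0][1].times
    for name, tr in items[1:]:
        if tr.times.shape != base.shape or not np.array_equal(tr.times, base):
            raise ValueError(
                f"trace {name!r} does not share the common time base; "
                "use long_form=True for heterogeneous traces"
            )
    frame = pd.DataFrame({"time_s": base})
    for name, tr in items:
        frame[name] = tr.values
    frame.to_csv(path, index=False)
    return path


def load_traces(path) -> dict[str, Trace]:
    """Inverse of :func:`save_traces` (wide form)."""
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing time_s column")
    times = frame["time_s"].to_numpy()
    return {
        name: Trace(times, frame[name].to_numpy(), name=name)
        for name in frame.columns
        if name != "time_s"
    }
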