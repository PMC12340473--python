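"""Containers and I/O for image series and physiological traces.

The package works with three clocks: a spirometry clock (typically 125 Hz),
an imaging clock (typically ~30 frames/s) and, implicitly, a shared wall
clock starting at t = 0 s.  All times are seconds, airflow is L/s and volume
is mL throughout.

Image series travel as NIfTI (time as 4th dimension) with a YAML sidecar for
acquisition metadata; traces travel as 2-column CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import CoverageError, FormatError, ValidationError

__all__ = [
    "FlowTrace",
    "VolumeTrace",
    "FrameSeries",
    "SliceStack",
    "resample_flow_to_frames",
    "read_series",
    "write_series",
    "read_trace",
    "write_trace",
]


@dataclass
class FlowTrace:
    """Uniformly sampled airflow trace in L/s.

    ``values[i]`` is the sample at time ``t0 + i / rate``.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("trace values must be one-dimensional")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        """Span covered by the samples, treating each as a 1/rate interval."""
        return len(self.values) / self.rate


@dataclass
class VolumeTrace:
    """Uniformly sampled volume trace in mL (same layout as FlowTrace)."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("trace values must be one-dimensional")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate


@dataclass
class FrameSeries:
    """One slice's image sequence: (T, H, W) intensities on a uniform frame clock."""

    frames: np.ndarray
    frame_period: float
    slice_index: int = 0
    orientation_deg: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (T, H, W) array")
        if not self.frame_period > 0:
            raise ValidationError("frame_period must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return len(self) * self.frame_period

    def window(self, start: int, stop: int) -> "FrameSeries":
        """Contiguous sub-series [start, stop) keeping the wall clock consistent."""
        if not (0 <= start < stop <= len(self)):
            raise ValidationError(f"invalid frame window [{start}, {stop})")
        return FrameSeries(
            frames=self.frames[start:stop],
            frame_period=self.frame_period,
            slice_index=self.slice_index,
            orientation_deg=self.orientation_deg,
            t0=self.t0 + start * self.frame_period,
        )


@dataclass
class SliceStack:
    """Ordered multi-slice short-axis stack."""

    series: list[FrameSeries]
    gap_mm: float = 8.0

    def __post_init__(self) -> None:
        if not self.series:
            raise ValidationError("stack must contain at least one slice")
        shapes = {s.frame_shape for s in self.series}
        if len(shapes) != 1:
            raise ValidationError(f"inconsistent frame geometry across slices: {shapes}")

    def __len__(self) -> int:
        return len(self.series)


def resample_flow_to_frames(flow: FlowTrace, series: FrameSeries) -> FlowTrace:
    """Average the high-rate spirometry trace onto the frame clock.

    Each frame l owns the half-open interval
    ``[t0 + l*dt, t0 + (l+1)*dt)`` and receives the mean of all flow samples
    whose timestamps fall inside it.  This is exactly linear in the input and
    anti-aliases the 125 Hz signal down to the frame rate.
    """
    dt = series.frame_period
    n_frames = len(series)
    start, stop = series.t0, series.t0 + n_frames * dt
    tol = 0.5 / flow.rate
    flow_end = flow.t0 + len(flow) / flow.rate
    if flow.t0 > start + tol or flow_end < stop - tol:
        raise CoverageError(
            f"flow trace covers [{flow.t0:.4f}, {flow_end:.4f}) s but frames require "
            f"[{start:.4f}, {stop:.4f}) s"
        )
    edges = start + np.arange(n_frames + 1) * dt
    # index of first sample with time >= edge
    idx = np.ceil((edges - flow.t0) * flow.rate - 1e-9).astype(int)
    idx = np.clip(idx, 0, len(flow))
    counts = np.diff(idx)
    if np.any(counts == 0):
        bad = int(np.argmax(counts == 0))
        raise CoverageError(
            f"no flow sample falls inside frame {bad} "
            f"([{edges[bad]:.4f}, {edges[bad + 1]:.4f}) s)"
        )
    cs = np.concatenate([[0.0], np.cumsum(flow.values)])
    means = (cs[idx[1:]] - cs[idx[:-1]]) / counts
    return FlowTrace(values=means, rate=1.0 / dt, t0=series.t0)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + ".yaml")


def write_series(series: FrameSeries, path: str | Path) -> Path:
    """Write one slice as NIfTI (H, W, 1, T) plus a YAML metadata sidecar."""
    path = Path(path)
    data = np.transpose(series.frames, (1, 2, 0))[:, :, np.newaxis, :]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    meta = {
        "frame_period": float(series.frame_period),
        "slice_index": int(series.slice_index),
        "orientation_deg": float(series.orientation_deg),
        "t0": float(series.t0),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_series(path: str | Path) -> FrameSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[2] != 1:
        raise FormatError(f"expected (H, W, 1, T) NIfTI, got shape {data.shape}")
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1))
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    try:
        return FrameSeries(
            frames=frames,
            frame_period=float(meta["frame_period"]),
            slice_index=int(meta["slice_index"]),
            orientation_deg=float(meta["orientation_deg"]),
            t0=float(meta.get("t0", 0.0)),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"sidecar {sidecar} lacks required key {exc}") from exc


def read_stack(paths: list[str | Path], gap_mm: float = 8.0) -> SliceStack:
    """Read an ordered list of per-slice NIfTI files into a stack."""
    return SliceStack(series=[read_series(p) for p in paths], gap_mm=gap_mm)


_FLOW_HEADER = ("time_s", "flow_l_per_s")
_VOL_HEADER = ("time_s", "volume_ml")


def write_trace(trace: FlowTrace | VolumeTrace, path: str | Path) -> Path:
    path = Path(path)
    header = _FLOW_HEADER if isinstance(trace, FlowTrace) else _VOL_HEADER
    df = pd.DataFrame({header[0]: trace.times, header[1]: trace.values})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace(path: str | Path) -> FlowTrace | VolumeTrace:
    path = Path(path)
    df = pd.read_csv(path)
    cols = tuple(df.columns)
    if cols == _FLOW_HEADER:
        cls = FlowTrace
    elif cols == _VOL_HEADER:
        cls = VolumeTrace
    else:
        raise FormatError(f"unrecognized trace header {cols} in {path}")
    t = df[cols[0]].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"trace {path} has fewer than two samples")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise FormatError(f"non-monotone time column in {path}")
    dt = np.median(dts)
    if np.max(np.abs(dts - dt)) > 1e-4 * dt + 1e-9:
        raise FormatError(f"non-uniform sampling in {path}")
    return cls(values=df[cols[1]].to_numpy(dtype=float), rate=1.0 / dt, t0=float(t[0]))
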