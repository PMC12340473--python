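"""Masking, downsampling and iterative Lucas-Kanade optical flow.

The pipeline order is fixed: ROI mask at full resolution, then block-mean
downsampling to a coarse working grid (default 40x40), then 10 iterations of
windowed Lucas-Kanade between consecutive frames.  The per-frame output is a
flow tensor X(l) of shape (grid, grid, 2) holding (row, col) displacements
of features from frame l-1 to frame l; X(0) is defined as the zero tensor so
tensors stay index-aligned with frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter

from .dataio import FrameSeries
from .errors import ValidationError

__all__ = [
    "RoiMask",
    "FlowTensorSeries",
    "apply_mask",
    "downsample",
    "lucas_kanade_iterative",
    "flow_series",
    "mask_from_motion",
    "read_mask",
    "write_mask",
    "save_flow",
    "load_flow",
]

DEFAULT_GRID = 40
DEFAULT_N_ITER = 10
DEFAULT_RADIUS = 7


@dataclass
class RoiMask:
    """Binary region-of-interest mask matching the full frame shape."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValidationError("mask must be two-dimensional")
        if not self.data.any():
            raise ValidationError("mask must contain at least one true pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class FlowTensorSeries:
    """Per-frame optical-flow tensors, shape (L, grid, grid, 2)."""

    tensors: np.ndarray
    grid_size: int = DEFAULT_GRID
    frame_period: float | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[-1] != 2:
            raise ValidationError("flow tensors must have shape (L, grid, grid, 2)")
        if not np.all(np.isfinite(self.tensors)):
            raise ValidationError("flow tensors contain non-finite entries")

    def __len__(self) -> int:
        return self.tensors.shape[0]


def apply_mask(series: FrameSeries, mask: RoiMask) -> FrameSeries:
    """Zero everything outside the ROI; inside-pixels pass unchanged."""
    if mask.shape != series.frame_shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match frame shape {series.frame_shape}"
        )
    return FrameSeries(
        frames=series.frames * mask.data,
        frame_period=series.frame_period,
        slice_index=series.slice_index,
        orientation_deg=series.orientation_deg,
        t0=series.t0,
    )


def downsample(series: FrameSeries, target: int = DEFAULT_GRID) -> FrameSeries:
    """Reduce each frame to ``target`` pixels per side.

    When the side length is divisible by ``target`` every output pixel is the
    exact mean of its source block; otherwise an anti-aliased resampling
    fallback (skimage) is used.
    """
    if target <= 0:
        raise ValidationError("downsampling target must be positive")
    h, w = series.frame_shape
    if h == w and h % target == 0:
        k = h // target
        t = len(series)
        frames = (
            series.frames.reshape(t, target, k, target, k).mean(axis=(2, 4))
        )
    else:
        from skimage.transform import resize

        frames = np.stack(
            [
                resize(f, (target, target), anti_aliasing=True, preserve_range=True)
                for f in series.frames
            ]
        )
    return FrameSeries(
        frames=frames,
        frame_period=series.frame_period,
        slice_index=series.slice_index,
        orientation_deg=series.orientation_deg,
        t0=series.t0,
    )


def lucas_kanade_iterative(
    ref: np.ndarray,
    mov: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """Dense per-pixel displacement from ``ref`` to ``mov``.

    Each of the ``n_iter`` warps re-solves the *total* flow: ``mov`` is
    warped by the current estimate, spatial gradients are taken from the
    warped image, and the windowed least-squares system is solved for the
    full displacement (not an increment), which keeps the iteration from
    accumulating drift in weakly conditioned regions.  Single scale, no
    pyramid.  Locally singular 2x2 systems yield zero flow.  Returns
    (H, W, 2) with channel 0 the row (vertical) and channel 1 the column
    (horizontal) displacement.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2:
        raise ValidationError(f"frame shapes differ: {ref.shape} vs {mov.shape}")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    size = 2 * radius + 1
    rows, cols = np.meshgrid(
        np.arange(ref.shape[0], dtype=float),
        np.arange(ref.shape[1], dtype=float),
        indexing="ij",
    )
    v = np.zeros_like(ref)  # row displacement
    u = np.zeros_like(ref)  # col displacement
    for _ in range(n_iter):
        warped = map_coordinates(mov, [rows + v, cols + u], order=1, mode="nearest")
        gy, gx = np.gradient(warped)
        err = gy * v + gx * u + ref - warped
        a11 = uniform_filter(gx * gx, size)
        a12 = uniform_filter(gx * gy, size)
        a22 = uniform_filter(gy * gy, size)
        b1 = uniform_filter(gx * err, size)
        b2 = uniform_filter(gy * err, size)
        det = a11 * a22 - a12 * a12
        good = np.abs(det) >= 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            u_new = (a22 * b1 - a12 * b2) / det
            v_new = (a11 * b2 - a12 * b1) / det
        u = np.where(good, u_new, 0.0)
        v = np.where(good, v_new, 0.0)
    return np.stack([v, u], axis=-1)


def flow_series(
    series: FrameSeries,
    mask: RoiMask,
    grid: int = DEFAULT_GRID,
    n_iter: int = DEFAULT_N_ITER,
    radius: int = DEFAULT_RADIUS,
) -> FlowTensorSeries:
    """Flow tensors between consecutive masked+downsampled frames.

    X(l) is computed from the pair (l-1, l) for l >= 1; X(0) := 0 so the
    series has exactly one tensor per frame.
    """
    if len(series) < 2:
        raise ValidationError("flow estimation requires at least two frames")
    small = downsample(apply_mask(series, mask), grid)
    frames = np.asarray(small.frames, dtype=float)
    tensors = np.zeros((len(series), grid, grid, 2))
    for l in range(1, len(series)):
        tensors[l] = lucas_kanade_iterative(frames[l - 1], frames[l], n_iter, radius)
    return FlowTensorSeries(
        tensors=tensors, grid_size=grid, frame_period=series.frame_period, t0=series.t0
    )


def mask_from_motion(series: FrameSeries, q: float = 75.0) -> RoiMask:
    """Derive an ROI by thresholding the temporal standard-deviation image.

    Pixels whose temporal SD reaches the q-th percentile of the SD image are
    kept.  A stand-in for the hand-drawn breathing-affected ROI a reader
    would otherwise supply.
    """
    if len(series) < 2:
        raise ValidationError("need at least two frames to estimate motion")
    sd = series.frames.std(axis=0)
    thr = np.percentile(sd, q)
    mask = sd >= thr
    if not mask.any():  # constant series: fall back to everything
        mask = np.ones_like(sd, dtype=bool)
    return RoiMask(data=mask)


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    """Write a mask as PNG (0/255) or single-frame NIfTI, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (mask.data * 255).astype(np.uint8))
    else:
        from .dataio import FrameSeries, write_series

        write_series(
            FrameSeries(frames=mask.data[np.newaxis].astype(np.float32), frame_period=1.0),
            path,
        )
    return path


def read_mask(path: str | Path) -> RoiMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return RoiMask(data=np.asarray(iio.imread(path)) > 127)
    from .dataio import read_series

    return RoiMask(data=read_series(path).frames[0] > 0.5)


def save_flow(path: str | Path, **series: FlowTensorSeries) -> Path:
    """Cache one or more tensor series to NPZ, keyed by name."""
    path = Path(path)
    arrays = {name: fs.tensors for name, fs in series.items()}
    np.savez_compressed(path, **arrays)
    return path


def load_flow(path: str | Path) -> dict[str, FlowTensorSeries]:
    with np.load(Path(path)) as data:
        return {
            name: FlowTensorSeries(tensors=data[name], grid_size=data[name].shape[1])
            for name in data.files
        }
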