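"""From normalized predictions to physical airflow and lung volume.

Pipeline: denormalize with the training statistics, Savitzky-Golay smooth,
cumulatively integrate to volume with the magnitude constant c, then apply a
baseline correction that removes the slow drift accumulated from small flow
biases.

Note on units: with per-frame airflow in L/s, exact physical integration
over 33 ms frames would use a scale of frame_period * 1000 ~= 33 mL per
unit flow.  The conventional constant is c = 10, which yields volumes on a
consistent (if rescaled) mL-magnitude axis for both measured and predicted
traces; since every agreement statistic compares the two on the same axis
the choice cancels out of relative measures.  ``physical_c`` is provided
for readers who want litres-true integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend, find_peaks, savgol_filter

from .dataio import FlowTrace, FrameSeries, VolumeTrace
from .errors import ValidationError
from .flowfield import RoiMask, flow_series
from .respmodel import RidgeModel, denormalize_flow, predict_normalized

__all__ = [
    "SmootherConfig",
    "IntegrationConfig",
    "denormalize",
    "smooth",
    "integrate_volume",
    "predict_respiration",
    "physical_c",
]


@dataclass(frozen=True)
class SmootherConfig:
    """Savitzky-Golay parameters; defaults span ~0.5 s at 30 frames/s."""

    window_frames: int = 15
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window_frames % 2 == 0:
            raise ValidationError(f"window_frames must be odd, got {self.window_frames}")
        if self.window_frames <= self.polyorder:
            raise ValidationError(
                f"window_frames ({self.window_frames}) must exceed polyorder ({self.polyorder})"
            )


BASELINE_MODES = ("linear_detrend", "breath_anchor", "none")


@dataclass(frozen=True)
class IntegrationConfig:
    c: float = 10.0
    baseline_mode: str = "linear_detrend"

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValidationError(f"volume scale c must be positive, got {self.c}")
        if self.baseline_mode not in BASELINE_MODES:
            raise ValidationError(
                f"baseline_mode must be one of {BASELINE_MODES}, got {self.baseline_mode!r}"
            )


def physical_c(frame_period: float) -> float:
    """Integration constant for litres-true volumes in mL: frame_period * 1000."""
    return frame_period * 1000.0


def denormalize(f_norm_pred: np.ndarray, stats) -> np.ndarray:
    """sigma_f * f_norm + mu_f (exact inverse of training normalization)."""
    return denormalize_flow(f_norm_pred, stats)


def smooth(flow: FlowTrace | np.ndarray, cfg: SmootherConfig = SmootherConfig()):
    """Savitzky-Golay smoothing; length-preserving, polynomial edge fit."""
    values = flow.values if isinstance(flow, FlowTrace) else np.asarray(flow, dtype=float)
    if len(values) < cfg.window_frames:
        raise ValidationError(
            f"trace length {len(values)} shorter than smoother window {cfg.window_frames}"
        )
    out = savgol_filter(values, cfg.window_frames, cfg.polyorder, mode="interp")
    if isinstance(flow, FlowTrace):
        return FlowTrace(values=out, rate=flow.rate, t0=flow.t0)
    return out


def _anchor_baseline(values: np.ndarray, rate: float, min_breath_s: float = 1.0) -> np.ndarray:
    """Fit a line through end-expiratory troughs and subtract it."""
    distance = max(1, int(round(min_breath_s * rate)))
    troughs, _ = find_peaks(-values, distance=distance)
    if len(troughs) < 2:
        return detrend(values, type="linear")
    coeffs = np.polyfit(troughs, values[troughs], 1)
    return values - np.polyval(coeffs, np.arange(len(values)))


def integrate_volume(flow: FlowTrace, cfg: IntegrationConfig = IntegrationConfig()) -> VolumeTrace:
    """v(t) = c * cumulative sum of per-frame airflow, then baseline correction.

    ``linear_detrend`` removes the least-squares line; ``breath_anchor``
    instead anchors on detected end-expiratory troughs (falling back to a
    plain detrend when fewer than two troughs are found); ``none`` returns
    the raw running sum.
    """
    if len(flow) == 0:
        raise ValidationError("cannot integrate an empty trace")
    values = cfg.c * np.cumsum(flow.values)
    if cfg.baseline_mode == "linear_detrend":
        values = detrend(values, type="linear")
    elif cfg.baseline_mode == "breath_anchor":
        values = _anchor_baseline(values, flow.rate)
    return VolumeTrace(values=values, rate=flow.rate, t0=flow.t0)


def predict_respiration(
    series: FrameSeries,
    mask: RoiMask,
    model: RidgeModel,
    smoother: SmootherConfig = SmootherConfig(),
    integ: IntegrationConfig = IntegrationConfig(),
    flow_kwargs: dict | None = None,
) -> tuple[FlowTrace, VolumeTrace]:
    """Single inference entry point: images in, airflow + volume out.

    Composes flow_series -> predict_normalized -> denormalize -> smooth ->
    integrate_volume.  The frame geometry must match the model's grid.
    """
    Xs = flow_series(series, mask, grid=model.grid_size, **(flow_kwargs or {}))
    f_norm = predict_normalized(Xs, model)
    f_denorm = denormalize(f_norm, model.norm)
    flow = FlowTrace(values=f_denorm, rate=1.0 / series.frame_period, t0=series.t0)
    flow = smooth(flow, smoother)
    volume = integrate_volume(flow, integ)
    return flow, volume
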