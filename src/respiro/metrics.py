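"""Evaluation statistics: rMSE, R^2, per-breath aTVD/aMFD, Bland-Altman, QC.

Relative MSE normalizes squared error by mean squared signal, so perfect
prediction scores 0 and a constant-zero prediction scores 1.  Breath-wise
statistics segment the *measured* spirometry trace at negative-to-positive
zero crossings and compare per-breath extrema: aTVD is the absolute
difference of tidal volumes (peak-to-trough ranges), aMFD the absolute
difference of peak inspiratory flows.  Agreement is summarized Bland-Altman
style (bias and 1.96-SD limits of agreement, sample SD).

Quality criteria: QC_volume passes when the mean aTVD is strictly below
20 mL; QC_flow is reported at a strict (50 mL/s) and a lenient (100 mL/s)
level, the lenient level acting as the pass/fail gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import FlowTrace, VolumeTrace
from .errors import DegenerateSignalError, ValidationError
from .postproc import IntegrationConfig, SmootherConfig, integrate_volume, smooth
from .respmodel import RidgeModel

__all__ = [
    "rmse_rel",
    "r_squared",
    "segment_breaths",
    "atvd",
    "amfd",
    "bland_altman",
    "select_pairs_per_slice",
    "qc_check",
    "sign_agreement",
    "QCResult",
    "MetricsReport",
    "evaluate_pair",
    "export_weight_map",
]

QC_VOLUME_ML = 20.0
QC_FLOW_STRICT_L_S = 0.05
QC_FLOW_LENIENT_L_S = 0.10


def _paired(measured, predicted, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValidationError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size < min_len:
        raise ValidationError(f"need at least {min_len} samples, got {m.size}")
    return m, p


def rmse_rel(measured, predicted) -> float:
    """mean((f - fhat)^2) / mean(f^2)."""
    m, p = _paired(measured, predicted, 1)
    denom = float(np.mean(m**2))
    if denom == 0.0:
        raise DegenerateSignalError("all-zero measured signal: relative MSE undefined")
    return float(np.mean((m - p) ** 2)) / denom


def r_squared(measured, predicted) -> float:
    """1 - sum((f - fhat)^2) / sum((f - fbar)^2); <= 1, may be negative."""
    m, p = _paired(measured, predicted, 2)
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateSignalError("constant measured signal: R^2 undefined")
    return 1.0 - float(np.sum((m - p) ** 2)) / ss_tot


def segment_breaths(
    flow: FlowTrace | np.ndarray,
    rate: float | None = None,
    min_duration_s: float = 1.0,
    presmooth: SmootherConfig | None = SmootherConfig(),
) -> list[tuple[int, int]]:
    """Half-open [start, stop) breath windows on the measured flow.

    Boundaries sit at negative-to-positive zero crossings of the (lightly
    smoothed) trace; a crossing landing exactly on a sample is assigned to
    that sample.  Segments shorter than ``min_duration_s`` are merged with
    their successor.  Returns [] with a warning when no crossing exists.
    """
    if isinstance(flow, FlowTrace):
        values, rate = flow.values, flow.rate
    else:
        values = np.asarray(flow, dtype=float)
        if rate is None:
            raise ValidationError("rate is required when flow is a bare array")
    if presmooth is not None and len(values) >= presmooth.window_frames:
        values = smooth(values, presmooth)
    pos = values >= 0
    crossings = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    if len(crossings) < 2:
        warnings.warn("no complete breath found: fewer than two zero crossings")
        return []
    min_len = int(round(min_duration_s * rate))
    bounds = [int(crossings[0])]
    for c in crossings[1:]:
        if c - bounds[-1] >= min_len:
            bounds.append(int(c))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def atvd(measured_seg, predicted_seg) -> float:
    """|TV(v) - TV(vhat)| with TV the peak-to-trough range of a breath (mL)."""
    m, p = np.asarray(measured_seg, float), np.asarray(predicted_seg, float)
    if m.size == 0 or p.size == 0:
        raise ValidationError("breath segments must be non-empty")
    return abs(float(m.max() - m.min()) - float(p.max() - p.min()))


def amfd(measured_seg, predicted_seg) -> float:
    """|max f - max fhat| over one breath (L/s); value-only comparison."""
    m, p = np.asarray(measured_seg, float), np.asarray(predicted_seg, float)
    if m.size == 0 or p.size == 0:
        raise ValidationError("breath segments must be non-empty")
    return abs(float(m.max()) - float(p.max()))


def bland_altman(pairs, seed: int | None = None) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) for predicted-minus-measured differences.

    ``pairs`` is either a flat sequence of (measured, predicted) scalars, or
    a per-slice list of such sequences from which one pair per slice is
    drawn with the explicit ``seed`` (mirroring one random breath per slice).
    Limits of agreement use the sample SD (ddof 1).
    """
    pairs = list(pairs)
    if pairs and not np.isscalar(pairs[0][0]):
        pairs = select_pairs_per_slice(pairs, seed=seed if seed is not None else 0)
    if len(pairs) < 2:
        raise ValidationError("Bland-Altman analysis requires at least two pairs")
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 1] - arr[:, 0]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def select_pairs_per_slice(per_slice_pairs, seed: int = 0) -> list[tuple[float, float]]:
    """Pick one (measured, predicted) pair per slice, reproducibly."""
    rng = np.random.default_rng(seed)
    chosen = []
    for slice_pairs in per_slice_pairs:
        slice_pairs = list(slice_pairs)
        if not slice_pairs:
            continue
        chosen.append(tuple(slice_pairs[rng.integers(len(slice_pairs))]))
    return chosen


@dataclass(frozen=True)
class QCResult:
    qc_volume_pass: bool
    qc_flow_strict_pass: bool
    qc_flow_pass: bool  # lenient gate
    mean_atvd_ml: float
    mean_amfd_l_s: float


def qc_check(atvd_ml, amfd_l_s) -> QCResult:
    """Apply the volume and airflow quality criteria to per-breath lists."""
    atvd_ml = np.asarray(atvd_ml, dtype=float)
    amfd_l_s = np.asarray(amfd_l_s, dtype=float)
    if atvd_ml.size == 0 or amfd_l_s.size == 0:
        raise ValidationError("aTVD/aMFD lists must be non-empty")
    mean_atvd = float(atvd_ml.mean())
    mean_amfd = float(amfd_l_s.mean())
    return QCResult(
        qc_volume_pass=mean_atvd < QC_VOLUME_ML,
        qc_flow_strict_pass=mean_amfd <= QC_FLOW_STRICT_L_S,
        qc_flow_pass=mean_amfd <= QC_FLOW_LENIENT_L_S,
        mean_atvd_ml=mean_atvd,
        mean_amfd_l_s=mean_amfd,
    )


def sign_agreement(measured, predicted) -> float:
    """Fraction of samples on which predicted and measured flow agree in sign.

    The coarsest usable readout: it distinguishes inspiration from
    expiration even when amplitudes are badly scaled.
    """
    m, p = _paired(measured, predicted, 1)
    return float(np.mean(np.sign(m) == np.sign(p)))


@dataclass
class MetricsReport:
    rmse_flow: float
    rmse_volume: float
    r2_flow: float
    r2_volume: float
    atvd_ml: list[float]
    amfd_l_s: list[float]
    tv_pairs: list[tuple[float, float]]  # per-breath (measured, predicted) tidal volumes
    mf_pairs: list[tuple[float, float]]  # per-breath (measured, predicted) peak flows
    ba_tv: tuple[float, float, float] | None
    ba_mf: tuple[float, float, float] | None
    qc: QCResult | None
    measured: FlowTrace | None = None
    predicted: FlowTrace | None = None

    def to_dict(self) -> dict:
        return {
            "rmse_flow": self.rmse_flow,
            "rmse_volume": self.rmse_volume,
            "r2_flow": self.r2_flow,
            "r2_volume": self.r2_volume,
            "atvd_ml": list(self.atvd_ml),
            "amfd_l_s": list(self.amfd_l_s),
            "ba_tv": self.ba_tv,
            "ba_mf": self.ba_mf,
            "qc": None if self.qc is None else vars(self.qc),
        }


def evaluate_pair(
    measured: FlowTrace,
    predicted: FlowTrace,
    integ: IntegrationConfig = IntegrationConfig(),
    min_breath_s: float = 1.0,
    ba_seed: int | None = None,
) -> MetricsReport:
    """Full per-slice evaluation of a predicted against a measured flow trace.

    Volumes are integrated from both traces with the same configuration so
    measured and predicted live on the same axis.  Breaths are segmented on
    the measured trace only.
    """
    if len(measured) != len(predicted):
        raise ValidationError("measured and predicted traces differ in length")
    v_m = integrate_volume(measured, integ)
    v_p = integrate_volume(predicted, integ)
    segs = segment_breaths(measured, min_duration_s=min_breath_s)
    atvds, amfds, tv_pairs, mf_pairs = [], [], [], []
    for a, b in segs:
        atvds.append(atvd(v_m.values[a:b], v_p.values[a:b]))
        amfds.append(amfd(measured.values[a:b], predicted.values[a:b]))
        tv_pairs.append(
            (
                float(v_m.values[a:b].max() - v_m.values[a:b].min()),
                float(v_p.values[a:b].max() - v_p.values[a:b].min()),
            )
        )
        mf_pairs.append((float(measured.values[a:b].max()), float(predicted.values[a:b].max())))
    ba_tv = bland_altman(tv_pairs, seed=ba_seed) if len(tv_pairs) >= 2 else None
    ba_mf = bland_altman(mf_pairs, seed=ba_seed) if len(mf_pairs) >= 2 else None
    qc = qc_check(atvds, amfds) if atvds else None
    return MetricsReport(
        rmse_flow=rmse_rel(measured.values, predicted.values),
        rmse_volume=rmse_rel(v_m.values, v_p.values),
        r2_flow=r_squared(measured.values, predicted.values),
        r2_volume=r_squared(v_m.values, v_p.values),
        atvd_ml=atvds,
        amfd_l_s=amfds,
        tv_pairs=tv_pairs,
        mf_pairs=mf_pairs,
        ba_tv=ba_tv,
        ba_mf=ba_mf,
        qc=qc,
        measured=measured,
        predicted=predicted,
    )


def export_weight_map(model: RidgeModel, upsample_to: int | None = None) -> np.ndarray:
    """Per-pixel weight magnitude sqrt(W_mn1^2 + W_mn2^2) on the flow grid."""
    mag = np.sqrt(model.W[..., 0] ** 2 + model.W[..., 1] ** 2)
    if upsample_to is not None:
        if upsample_to % mag.shape[0] != 0:
            raise ValidationError(
                f"upsample_to {upsample_to} not a multiple of grid {mag.shape[0]}"
            )
        k = upsample_to // mag.shape[0]
        mag = np.kron(mag, np.ones((k, k)))
    return mag


def breath_table(report: MetricsReport) -> "pd.DataFrame":
    """Per-breath measured/predicted tidal volumes, peak flows and errors."""
    import pandas as pd

    return pd.DataFrame(
        {
            "breath": np.arange(len(report.atvd_ml)),
            "tv_measured_ml": [m for m, _ in report.tv_pairs],
            "tv_predicted_ml": [p for _, p in report.tv_pairs],
            "atvd_ml": report.atvd_ml,
            "mf_measured_l_s": [m for m, _ in report.mf_pairs],
            "mf_predicted_l_s": [p for _, p in report.mf_pairs],
            "amfd_l_s": report.amfd_l_s,
        }
    )


def save_bland_altman_png(pairs, path, seed: int | None = None, units: str = ""):
    """Bland-Altman scatter with bias and 1.96-SD limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = list(pairs)
    if pairs and not np.isscalar(pairs[0][0]):
        pairs = select_pairs_per_slice(pairs, seed=seed if seed is not None else 0)
    bias, lo, hi = bland_altman(pairs)
    arr = np.asarray(pairs, dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 1] - arr[:, 0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.axhline(0.0, color="grey", linewidth=0.5)
    ax.set_xlabel(f"mean of measured and predicted {units}".strip())
    ax.set_ylabel(f"predicted - measured {units}".strip())
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_weight_map_png(model: RidgeModel, path, upsample_to: int | None = None):
    """Optional matplotlib rendering of the weight-magnitude map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mag = export_weight_map(model, upsample_to)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(mag, cmap="magma")
    fig.colorbar(im, ax=ax, label="|W|")
    ax.set_title("model weight magnitude")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
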