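"""Training-protocol experiments on multi-slice scenes.

A protocol fixes, per slice, a training block (default: the first 300
frames) and a held-out test block (default: the following 600 frames).  The
training block is then thinned two ways: a *breath budget* keeps only whole
breaths of a given pattern/count (down to a single inspiratory phase), and
a *slice stride* trains only every k-th slice, with untrained slices
predicted by the model of their nearest trained neighbour (ties broken
toward the basal direction, i.e. the lower slice index).

The test block is byte-identical across protocol variants for a given
scene, so variants are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as _nd_rotate

from .dataio import FlowTrace, FrameSeries, resample_flow_to_frames
from .errors import ValidationError
from .flowfield import (
    DEFAULT_GRID,
    DEFAULT_N_ITER,
    DEFAULT_RADIUS,
    FlowTensorSeries,
    RoiMask,
    flow_series,
    mask_from_motion,
)
from .metrics import MetricsReport, bland_altman, evaluate_pair, qc_check, segment_breaths
from .phantom import PhantomScene
from .postproc import IntegrationConfig, SmootherConfig, denormalize, smooth
from .respmodel import (
    NormStats,
    RidgeModel,
    normalize_flow,
    predict_normalized,
    select_lambda,
)

__all__ = [
    "ProtocolSpec",
    "SliceAssignment",
    "BREATH_BUDGETS",
    "SLICE_STRIDES",
    "select_training_indices",
    "split_train_test",
    "assign_slices",
    "run_protocol",
    "cross_subject_transfer",
    "test_retest",
    "ProtocolResult",
]

SLICE_STRIDES = (1, 2, 3, 6)
BREATH_BUDGETS = (
    "4_deep_4_normal",
    "4_deep",
    "4_normal",
    "3_normal",
    "2_normal",
    "1_normal",
    "1_inspiration",
)


@dataclass
class ProtocolSpec:
    train_frames_per_slice: int = 300
    test_frames_per_slice: int = 600
    slice_stride: int = 2
    breath_budget: str = "2_normal"
    rotation_align: bool = False
    seed: int = 0
    grid: int = DEFAULT_GRID
    n_iter: int = DEFAULT_N_ITER
    radius: int = DEFAULT_RADIUS
    mask_quantile: float = 75.0
    lam_grid: np.ndarray | None = None
    smoother: SmootherConfig = field(default_factory=SmootherConfig)
    integ: IntegrationConfig = field(default_factory=IntegrationConfig)
    min_breath_s: float = 1.0

    def __post_init__(self) -> None:
        if self.slice_stride not in SLICE_STRIDES:
            raise ValidationError(f"slice_stride must be one of {SLICE_STRIDES}")
        if self.breath_budget not in BREATH_BUDGETS:
            raise ValidationError(f"breath_budget must be one of {BREATH_BUDGETS}")
        if self.train_frames_per_slice < 2 or self.test_frames_per_slice < 2:
            raise ValidationError("train/test frame counts must be >= 2")


@dataclass
class SliceAssignment:
    """Map from every slice to the trained slice whose model predicts it."""

    mapping: dict[int, int]

    def __getitem__(self, s: int) -> int:
        return self.mapping[s]


def assign_slices(n_slices: int, trained_indices) -> SliceAssignment:
    """Nearest-trained-slice map; ties go to the lower (basal) index."""
    trained = sorted(set(int(i) for i in trained_indices))
    if not trained:
        raise ValidationError("trained slice set must be non-empty")
    if trained[0] < 0 or trained[-1] >= n_slices:
        raise ValidationError("trained indices out of range")
    mapping = {}
    for s in range(n_slices):
        best = min(trained, key=lambda t: (abs(t - s), t))
        mapping[s] = best
    return SliceAssignment(mapping=mapping)


def _classify_breaths(flow_vals: np.ndarray, rate: float, segs) -> list[str]:
    """Label each breath normal/deep by its inspired volume."""
    tvs = np.array([np.sum(np.clip(flow_vals[a:b], 0, None)) / rate for a, b in segs])
    if tvs.size == 0:
        return []
    if tvs.max() > 1.8 * tvs.min():
        thr = 0.5 * (tvs.min() + tvs.max())
        return ["deep" if tv > thr else "normal" for tv in tvs]
    return ["normal"] * len(tvs)


def select_training_indices(
    flow_vals: np.ndarray,
    rate: float,
    budget: str,
    min_breath_s: float = 1.0,
) -> np.ndarray:
    """Frame indices (within the training block) that the budget retains.

    Whole breaths are kept from the start of the block; ``1_inspiration``
    keeps only the inspiratory (positive-flow) limb of the first normal
    breath.
    """
    if budget not in BREATH_BUDGETS:
        raise ValidationError(f"unknown breath budget {budget!r}")
    segs = segment_breaths(flow_vals, rate=rate, min_duration_s=min_breath_s)
    if not segs:
        raise ValidationError("no complete breath inside the training block")
    kinds = _classify_breaths(flow_vals, rate, segs)

    def _take(kind: str, count: int) -> list[tuple[int, int]]:
        sel = [seg for seg, k in zip(segs, kinds) if k == kind][:count]
        if len(sel) < count:
            raise ValidationError(
                f"budget {budget!r} needs {count} {kind} breath(s); "
                f"only {len(sel)} found in the training block"
            )
        return sel

    if budget == "4_deep_4_normal":
        chosen = _take("deep", 4) + _take("normal", 4)
    elif budget == "4_deep":
        chosen = _take("deep", 4)
    elif budget == "1_inspiration":
        a, b = _take("normal", 1)[0]
        seg_vals = flow_vals[a:b]
        neg = np.flatnonzero(seg_vals < 0)
        stop = a + (int(neg[0]) if neg.size else len(seg_vals))
        if stop - a < 2:
            raise ValidationError("inspiratory phase too short to train on")
        return np.arange(a, stop)
    else:
        n = int(budget.split("_")[0])
        chosen = _take("normal", n)
    idx = np.concatenate([np.arange(a, b) for a, b in sorted(chosen)])
    return np.unique(idx)


def split_train_test(
    series: FrameSeries,
    frame_flow: FlowTrace,
    spec: ProtocolSpec,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Per-slice split: budgeted training indices and the fixed test window.

    Enforces the design rule that at most one third of the acquired frames
    is ever used for training.
    """
    ntr, nte = spec.train_frames_per_slice, spec.test_frames_per_slice
    total = len(series)
    if ntr + nte > total:
        raise ValidationError(
            f"train ({ntr}) + test ({nte}) frames exceed the {total} acquired"
        )
    if 3 * ntr > total:
        raise ValidationError(
            f"training block ({ntr} frames) exceeds one third of the {total} acquired"
        )
    if len(frame_flow) != total:
        raise ValidationError("per-frame flow and series lengths differ")
    idx = select_training_indices(
        frame_flow.values[:ntr], frame_flow.rate, spec.breath_budget, spec.min_breath_s
    )
    return idx, (ntr, ntr + nte)


def _predict_block(
    tensors: np.ndarray,
    model: RidgeModel,
    rate: float,
    t0: float,
    smoother: SmootherConfig,
) -> FlowTrace:
    f_norm = np.tensordot(tensors, model.W, axes=3) + model.b
    flow = FlowTrace(values=denormalize(f_norm, model.norm), rate=rate, t0=t0)
    return smooth(flow, smoother)


@dataclass
class _TrainedSlice:
    model: RidgeModel
    mask: RoiMask
    tensors: FlowTensorSeries  # full-series flow with this slice's mask
    frame_flow: FlowTrace


def _train_slice(scene: PhantomScene, s: int, spec: ProtocolSpec) -> _TrainedSlice:
    ser = scene.series(s)
    fframes = resample_flow_to_frames(scene.flow, ser)
    idx, _ = split_train_test(ser, fframes, spec)
    mask = mask_from_motion(ser.window(0, spec.train_frames_per_slice), q=spec.mask_quantile)
    Xfull = flow_series(ser, mask, grid=spec.grid, n_iter=spec.n_iter, radius=spec.radius)
    f_norm, stats = normalize_flow(fframes.values[idx])
    model = select_lambda(Xfull.tensors[idx], f_norm, lam_grid=spec.lam_grid, stats=stats)
    return _TrainedSlice(model=model, mask=mask, tensors=Xfull, frame_flow=fframes)


@dataclass
class ProtocolResult:
    spec: ProtocolSpec
    assignment: SliceAssignment
    per_slice: dict[int, MetricsReport]
    trained_slices: list[int]
    models: dict[int, RidgeModel]
    pooled: dict

    def table(self) -> pd.DataFrame:
        """Per-slice R^2/rMSE table (the slice-variability view)."""
        rows = []
        for s, rep in sorted(self.per_slice.items()):
            rows.append(
                {
                    "slice": s,
                    "trained": s in self.trained_slices,
                    "assigned_model": self.assignment[s],
                    "r2_flow": rep.r2_flow,
                    "r2_volume": rep.r2_volume,
                    "rmse_flow": rep.rmse_flow,
                    "rmse_volume": rep.rmse_volume,
                    "mean_atvd_ml": float(np.mean(rep.atvd_ml)) if rep.atvd_ml else np.nan,
                    "mean_amfd_l_s": float(np.mean(rep.amfd_l_s)) if rep.amfd_l_s else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _pool(per_slice: dict[int, MetricsReport], seed: int) -> dict:
    reports = [per_slice[s] for s in sorted(per_slice)]
    atvds = [a for r in reports for a in r.atvd_ml]
    amfds = [a for r in reports for a in r.amfd_l_s]
    pooled = {
        "mean_r2_flow": float(np.mean([r.r2_flow for r in reports])),
        "mean_r2_volume": float(np.mean([r.r2_volume for r in reports])),
        "mean_rmse_flow": float(np.mean([r.rmse_flow for r in reports])),
        "mean_rmse_volume": float(np.mean([r.rmse_volume for r in reports])),
        "mean_atvd_ml": float(np.mean(atvds)) if atvds else np.nan,
        "mean_amfd_l_s": float(np.mean(amfds)) if amfds else np.nan,
        "n_breaths": len(atvds),
    }
    if atvds and amfds:
        qc = qc_check(atvds, amfds)
        pooled["qc_volume_pass"] = qc.qc_volume_pass
        pooled["qc_flow_pass"] = qc.qc_flow_pass
        pooled["qc_flow_strict_pass"] = qc.qc_flow_strict_pass
    tv_lists = [r.tv_pairs for r in reports if r.tv_pairs]
    mf_lists = [r.mf_pairs for r in reports if r.mf_pairs]
    if len(tv_lists) >= 2:
        pooled["ba_tv"] = bland_altman(tv_lists, seed=seed)
        pooled["ba_mf"] = bland_altman(mf_lists, seed=seed)
    return pooled


def run_protocol(scene: PhantomScene, spec: ProtocolSpec) -> ProtocolResult:
    """Train per-slice models under ``spec`` and evaluate every test slice.

    One ridge model per trained slice; untrained slices are predicted with
    their assigned neighbour's model (and that neighbour's ROI mask, since
    the weight tensor is tied to the mask geometry it was trained with).
    """
    n_slices = scene.config.n_slices
    trained_idx = list(range(0, n_slices, spec.slice_stride))
    assignment = assign_slices(n_slices, trained_idx)
    ntr, nte = spec.train_frames_per_slice, spec.test_frames_per_slice
    rate = 1.0 / scene.config.frame_period

    trained: dict[int, _TrainedSlice] = {}
    per_slice: dict[int, MetricsReport] = {}
    for s in trained_idx:
        ts = _train_slice(scene, s, spec)
        measured = FlowTrace(
            values=ts.frame_flow.values[ntr : ntr + nte], rate=rate, t0=ts.frame_flow.t0 + ntr / rate
        )
        predicted = _predict_block(
            ts.tensors.tensors[ntr : ntr + nte], ts.model, rate, measured.t0, spec.smoother
        )
        per_slice[s] = evaluate_pair(
            measured, predicted, spec.integ, spec.min_breath_s, ba_seed=spec.seed
        )
        trained[s] = ts
        ts.tensors = FlowTensorSeries(tensors=np.zeros((1, spec.grid, spec.grid, 2)))  # release

    for s in range(n_slices):
        if s in trained:
            continue
        tau = assignment[s]
        ser = scene.series(s)
        fframes = resample_flow_to_frames(scene.flow, ser)
        sub = ser.window(ntr - 1, ntr + nte)
        Xsub = flow_series(
            sub, trained[tau].mask, grid=spec.grid, n_iter=spec.n_iter, radius=spec.radius
        )
        measured = FlowTrace(values=fframes.values[ntr : ntr + nte], rate=rate, t0=fframes.t0 + ntr / rate)
        predicted = _predict_block(
            Xsub.tensors[1:], trained[tau].model, rate, measured.t0, spec.smoother
        )
        per_slice[s] = evaluate_pair(
            measured, predicted, spec.integ, spec.min_breath_s, ba_seed=spec.seed
        )

    return ProtocolResult(
        spec=spec,
        assignment=assignment,
        per_slice=per_slice,
        trained_slices=trained_idx,
        models={s: trained[s].model for s in trained_idx},
        pooled=_pool(per_slice, spec.seed),
    )


def _rotate_frames(frames: np.ndarray, angle_deg: float) -> np.ndarray:
    if abs(angle_deg) < 1e-12:
        return frames
    return _nd_rotate(frames, angle_deg, axes=(1, 2), reshape=False, order=1, mode="constant")


def cross_subject_transfer(
    train_scenes: list[PhantomScene],
    test_scene: PhantomScene,
    spec: ProtocolSpec,
    rotate: bool = False,
    adaptive_norm: FlowTrace | None = None,
) -> ProtocolResult:
    """Train index-matched per-slice models on pooled subjects, test unseen one.

    With ``rotate`` the test frames are rigidly rotated by the orientation
    difference to the (first) training scene before optical flow.  The
    experimental ``adaptive_norm`` mode replaces the pooled training
    NormStats with statistics from a short spirometry snippet of the test
    subject at denormalization time.
    """
    if not train_scenes:
        raise ValidationError("at least one training scene is required")
    n_slices = test_scene.config.n_slices
    for sc in train_scenes:
        if sc.config.n_slices != n_slices:
            raise ValidationError("slice counts differ between training and test scenes")
    ntr, nte = spec.train_frames_per_slice, spec.test_frames_per_slice
    rate = 1.0 / test_scene.config.frame_period
    train_orient = train_scenes[0].config.rotation_deg
    # ndimage.rotate by (test - train) maps the test anatomy onto the
    # training orientation (verified against the phantom's own convention)
    angle = test_scene.config.rotation_deg - train_orient if rotate else 0.0

    per_slice: dict[int, MetricsReport] = {}
    models: dict[int, RidgeModel] = {}
    for s in range(n_slices):
        mask_union = None
        pooled_X, pooled_f = [], []
        per_scene = []
        for sc in train_scenes:
            ser = sc.series(s)
            fframes = resample_flow_to_frames(sc.flow, ser)
            idx, _ = split_train_test(ser, fframes, spec)
            m = mask_from_motion(ser.window(0, ntr), q=spec.mask_quantile).data
            mask_union = m if mask_union is None else (mask_union | m)
            per_scene.append((ser, fframes, idx))
        mask = RoiMask(data=mask_union)
        for ser, fframes, idx in per_scene:
            Xfull = flow_series(ser, mask, grid=spec.grid, n_iter=spec.n_iter, radius=spec.radius)
            pooled_X.append(Xfull.tensors[idx])
            pooled_f.append(fframes.values[idx])
        X = np.concatenate(pooled_X)
        f = np.concatenate(pooled_f)
        f_norm, stats = normalize_flow(f)
        model = select_lambda(X, f_norm, lam_grid=spec.lam_grid, stats=stats)
        if adaptive_norm is not None:
            _, adapted = normalize_flow(adaptive_norm.values)
            model.norm = adapted
        models[s] = model

        ser_t = test_scene.series(s)
        fframes_t = resample_flow_to_frames(test_scene.flow, ser_t)
        sub = ser_t.window(ntr - 1, ntr + nte)
        frames = _rotate_frames(np.asarray(sub.frames, dtype=float), angle)
        sub = FrameSeries(
            frames=frames,
            frame_period=sub.frame_period,
            slice_index=sub.slice_index,
            orientation_deg=sub.orientation_deg + angle,
            t0=sub.t0,
        )
        Xsub = flow_series(sub, mask, grid=spec.grid, n_iter=spec.n_iter, radius=spec.radius)
        measured = FlowTrace(values=fframes_t.values[ntr : ntr + nte], rate=rate, t0=fframes_t.t0 + ntr / rate)
        predicted = _predict_block(Xsub.tensors[1:], model, rate, measured.t0, spec.smoother)
        per_slice[s] = evaluate_pair(
            measured, predicted, spec.integ, spec.min_breath_s, ba_seed=spec.seed
        )

    trained_idx = list(range(n_slices))
    return ProtocolResult(
        spec=spec,
        assignment=assign_slices(n_slices, trained_idx),
        per_slice=per_slice,
        trained_slices=trained_idx,
        models=models,
        pooled=_pool(per_slice, spec.seed),
    )


def test_retest(
    train_scene: PhantomScene,
    retest_scene: PhantomScene,
    spec: ProtocolSpec | None = None,
    rotate: bool = False,
) -> ProtocolResult:
    """Reuse scan-1 models (optimized protocol) on an independent scan 2.

    The retest scene is treated purely as test data: every slice of the
    second scan is predicted with the model its index is assigned to in the
    first scan's protocol, optionally after rotating the second scan to the
    first scan's image orientation.
    """
    if spec is None:
        spec = ProtocolSpec()
    if retest_scene.config.n_slices != train_scene.config.n_slices:
        raise ValidationError("scan 1 and scan 2 must share the slice count")
    n_slices = train_scene.config.n_slices
    trained_idx = list(range(0, n_slices, spec.slice_stride))
    assignment = assign_slices(n_slices, trained_idx)
    rate = 1.0 / retest_scene.config.frame_period
    angle = (
        retest_scene.config.rotation_deg - train_scene.config.rotation_deg if rotate else 0.0
    )

    trained: dict[int, _TrainedSlice] = {}
    for s in trained_idx:
        ts = _train_slice(train_scene, s, spec)
        ts.tensors = FlowTensorSeries(tensors=np.zeros((1, spec.grid, spec.grid, 2)))
        trained[s] = ts

    per_slice: dict[int, MetricsReport] = {}
    for s in range(n_slices):
        tau = assignment[s]
        ser = retest_scene.series(s)
        fframes = resample_flow_to_frames(retest_scene.flow, ser)
        frames = _rotate_frames(np.asarray(ser.frames, dtype=float), angle)
        ser = FrameSeries(
            frames=frames,
            frame_period=ser.frame_period,
            slice_index=ser.slice_index,
            orientation_deg=ser.orientation_deg + angle,
            t0=ser.t0,
        )
        Xs = flow_series(ser, trained[tau].mask, grid=spec.grid, n_iter=spec.n_iter, radius=spec.radius)
        measured = FlowTrace(values=fframes.values[1:], rate=rate, t0=fframes.t0 + 1.0 / rate)
        predicted = _predict_block(Xs.tensors[1:], trained[tau].model, rate, measured.t0, spec.smoother)
        per_slice[s] = evaluate_pair(
            measured, predicted, spec.integ, spec.min_breath_s, ba_seed=spec.seed
        )

    return ProtocolResult(
        spec=spec,
        assignment=assignment,
        per_slice=per_slice,
        trained_slices=trained_idx,
        models={s: trained[s].model for s in trained_idx},
        pooled=_pool(per_slice, spec.seed),
    )
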