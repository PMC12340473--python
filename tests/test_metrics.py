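"""Agreement statistics: rMSE, R^2, breath segmentation, aTVD/aMFD, BA, QC."""

import warnings

import numpy as np
import pytest

from respiro.dataio import FlowTrace
from respiro.errors import DegenerateSignalError, ValidationError
from respiro.metrics import (
    amfd,
    atvd,
    bland_altman,
    evaluate_pair,
    export_weight_map,
    qc_check,
    r_squared,
    rmse_rel,
    segment_breaths,
    select_pairs_per_slice,
    sign_agreement,
)
from respiro.postproc import IntegrationConfig
from respiro.respmodel import NormStats, RidgeModel


class TestRmseR2:
    def test_perfect_prediction(self):
        f = np.array([0.5, -0.2, 0.8])
        assert rmse_rel(f, f) == 0.0
        assert r_squared(f, f) == 1.0

    def test_zero_prediction_scores_one(self):
        f = np.array([1.0, -2.0, 0.5])
        assert rmse_rel(f, np.zeros(3)) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero_r2(self):
        f = np.array([0.0, 1.0, 2.0])
        assert r_squared(f, np.full(3, f.mean())) == pytest.approx(0.0)

    def test_hand_computed_values(self):
        assert rmse_rel([1.0, 2.0], [1.0, 1.0]) == pytest.approx(0.2)
        assert r_squared([0.0, 1.0, 2.0], [0.0, 1.0, 3.0]) == pytest.approx(0.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateSignalError):
            rmse_rel(np.zeros(3), np.ones(3))
        with pytest.raises(DegenerateSignalError):
            r_squared(np.full(3, 2.0), np.ones(3))

    def test_tandem_permutation_invariance(self):
        rng = np.random.default_rng(0)
        f, p = rng.normal(size=50), rng.normal(size=50)
        perm = rng.permutation(50)
        assert rmse_rel(f, p) == pytest.approx(rmse_rel(f[perm], p[perm]))
        assert r_squared(f, p) == pytest.approx(r_squared(f[perm], p[perm]))

    def test_r2_rmse_consistency_identity(self):
        """R^2 = 1 - rMSE * T * mean(f^2) / sum((f - fbar)^2)."""
        rng = np.random.default_rng(1)
        f, p = rng.normal(size=40), rng.normal(size=40)
        t = len(f)
        lhs = r_squared(f, p)
        rhs = 1.0 - rmse_rel(f, p) * t * np.mean(f**2) / np.sum((f - f.mean()) ** 2)
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestSegmentBreaths:
    def test_sinusoid_boundaries_at_zero_crossings(self):
        """Two clean breaths: boundaries within one frame of analytic crossings."""
        rate = 30.0
        t = np.arange(315) / rate  # three and a half 3-s cycles
        flow = FlowTrace(values=0.5 * np.sin(2 * np.pi * t / 3.0), rate=rate)
        segs = segment_breaths(flow, presmooth=None)
        assert len(segs) == 2
        for (a, b), expected_start in zip(segs, [90, 180]):
            assert abs(a - expected_start) <= 1

    def test_all_positive_flow_yields_no_segments(self):
        flow = FlowTrace(values=np.full(100, 0.4), rate=30.0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            segs = segment_breaths(flow, presmooth=None)
        assert segs == []
        assert any("breath" in str(w.message) for w in caught)

    def test_short_segments_merged(self):
        rate = 30.0
        t = np.arange(300) / rate
        # 0.5-s wiggles: every crossing closer than the 1-s minimum is merged
        flow = FlowTrace(values=np.sin(2 * np.pi * t / 0.5), rate=rate)
        segs = segment_breaths(flow, presmooth=None, min_duration_s=1.0)
        assert all(b - a >= 30 for a, b in segs)


class TestBreathStatistics:
    def test_atvd_identical_segments_zero(self):
        v = np.array([0.0, 250.0, 500.0, 100.0])
        assert atvd(v, v) == 0.0

    def test_atvd_hand_computed(self):
        measured = np.array([0.0, 500.0])
        predicted = np.array([10.0, 490.0])
        assert atvd(measured, predicted) == pytest.approx(20.0)

    def test_atvd_constant_prediction_equals_measured_tv(self):
        measured = np.array([0.0, 420.0, 30.0])
        assert atvd(measured, np.full(3, 7.0)) == pytest.approx(420.0)

    def test_amfd_hand_computed(self):
        assert amfd([0.1, 0.62, 0.2], [0.55, 0.1, 0.3]) == pytest.approx(0.07)

    def test_amfd_equal_maxima_at_different_times(self):
        assert amfd([0.6, 0.1], [0.1, 0.6]) == 0.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValidationError):
            atvd(np.array([]), np.array([1.0]))


class TestBlandAltman:
    def test_all_zero_differences(self):
        bias, lo, hi = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_computed_limits(self):
        """Differences +10/-10: bias 0, LoA = +-1.96 * 10 * sqrt(2) (ddof 1)."""
        bias, lo, hi = bland_altman([(0.0, 10.0), (0.0, -10.0)])
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * 10.0 * np.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * 10.0 * np.sqrt(2.0))

    def test_per_slice_selection_deterministic(self):
        per_slice = [[(0.0, 1.0), (0.0, 2.0)], [(0.0, 3.0), (0.0, 4.0)], [(0.0, 5.0)]]
        a = select_pairs_per_slice(per_slice, seed=42)
        b = select_pairs_per_slice(per_slice, seed=42)
        assert a == b and len(a) == 3

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([(1.0, 2.0)])


class TestQC:
    def test_paper_scale_mean_atvd_passes(self):
        qc = qc_check([4.27], [0.01])
        assert qc.qc_volume_pass

    def test_boundary_exactly_20_fails(self):
        assert not qc_check([20.0], [0.01]).qc_volume_pass

    def test_flow_between_levels(self):
        qc = qc_check([1.0], [0.07])
        assert not qc.qc_flow_strict_pass
        assert qc.qc_flow_pass


class TestSignAgreement:
    def test_perfect_and_inverted(self):
        f = np.array([1.0, -1.0, 2.0, -2.0])
        assert sign_agreement(f, f) == 1.0
        assert sign_agreement(f, -f) == 0.0


class TestWeightMap:
    def test_zero_model_zero_map(self):
        m = RidgeModel(W=np.zeros((8, 8, 2)), b=0.0, lam=1.0, norm=NormStats(0.0, 1.0))
        assert np.all(export_weight_map(m) == 0.0)

    def test_single_entry_magnitude(self):
        W = np.zeros((8, 8, 2))
        W[3, 5, 0] = 0.1
        m = RidgeModel(W=W, b=0.0, lam=1.0, norm=NormStats(0.0, 1.0))
        mag = export_weight_map(m)
        assert mag[3, 5] == pytest.approx(0.1)
        assert mag.sum() == pytest.approx(0.1)

    def test_upsampled_overlay_shape(self):
        m = RidgeModel(W=np.ones((8, 8, 2)), b=0.0, lam=1.0, norm=NormStats(0.0, 1.0))
        assert export_weight_map(m, upsample_to=32).shape == (32, 32)

    def test_trained_weights_concentrate_in_moving_band(self, tiny_scene):
        """Top-decile weight mass localizes to the moving-diaphragm region.

        The region is the temporal-SD band dilated by the Lucas-Kanade
        window: every pixel whose 15x15 window overlaps the moving edge
        carries diaphragm-motion information and may legitimately receive
        weight.
        """
        from scipy.ndimage import binary_dilation

        from respiro.dataio import resample_flow_to_frames
        from respiro.flowfield import apply_mask, downsample, flow_series, mask_from_motion
        from respiro.respmodel import normalize_flow, select_lambda

        scene = tiny_scene
        ser = scene.series(0)
        fframes = resample_flow_to_frames(scene.flow, ser)
        mask = mask_from_motion(ser.window(0, 80))
        X = flow_series(ser, mask)
        f_norm, stats = normalize_flow(fframes.values)
        model = select_lambda(X.tensors, f_norm, stats=stats)

        mag = export_weight_map(model)
        top = mag >= np.quantile(mag, 0.9)
        sd = downsample(apply_mask(ser, mask), 40).frames.std(axis=0)
        band = sd >= np.percentile(sd, 75)
        moving = binary_dilation(band, structure=np.ones((15, 15), dtype=bool))
        frac = mag[top & moving].sum() / mag[top].sum()
        assert frac >= 0.6


class TestEvaluatePair:
    def test_report_fields_consistent(self):
        rate = 30.0
        t = np.arange(450) / rate
        measured = FlowTrace(values=0.5 * np.sin(2 * np.pi * t / 3.0), rate=rate)
        predicted = FlowTrace(values=0.48 * np.sin(2 * np.pi * t / 3.0), rate=rate)
        rep = evaluate_pair(measured, predicted, IntegrationConfig())
        assert 0.9 < rep.r2_flow <= 1.0
        assert rep.rmse_flow >= 0.0
        assert len(rep.atvd_ml) == len(rep.amfd_l_s) > 0
        bias, lo, hi = rep.ba_tv
        assert lo <= bias <= hi
        assert rep.qc is not None and rep.qc.qc_volume_pass

    def test_length_mismatch_rejected(self):
        a = FlowTrace(values=np.zeros(10), rate=30.0)
        b = FlowTrace(values=np.zeros(11), rate=30.0)
        with pytest.raises(ValidationError):
            evaluate_pair(a, b)
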