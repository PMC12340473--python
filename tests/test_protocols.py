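"""Protocol machinery: splits, budgets, slice assignment, transfer, retest."""

import dataclasses

import numpy as np
import pytest

from respiro.dataio import FlowTrace, FrameSeries
from respiro.errors import ValidationError
from respiro.metrics import sign_agreement
from respiro.phantom import breath_pattern_for_duration
from respiro.protocols import (
    ProtocolSpec,
    assign_slices,
    cross_subject_transfer,
    run_protocol,
    select_training_indices,
    split_train_test,
)
from respiro.protocols import test_retest as run_test_retest

from conftest import make_scene

RATE = 1 / 0.033


def _sine_flow(n, period_s=1.5, amp=0.5, rate=RATE, phase=np.pi):
    """Sinusoidal breathing starting mid-expiration (phase pi) so the block
    begins with a partial breath, as an arbitrary acquisition start would."""
    t = np.arange(n) / rate
    return amp * np.sin(2 * np.pi * t / period_s + phase)


class TestAssignSlices:
    def test_all_trained_identity(self):
        a = assign_slices(5, range(5))
        assert all(a[s] == s for s in range(5))

    def test_tie_breaks_toward_basal(self):
        a = assign_slices(5, [0, 2, 4])
        assert a[1] == 0  # equidistant from 0 and 2

    def test_nearest_distance(self):
        a = assign_slices(19, [0, 6, 12, 18])
        assert a[9] == 6  # tie 6 vs 12 resolved basally
        assert a[10] == 12

    def test_stride_counts_on_19_slices(self):
        assert len(range(0, 19, 2)) == 10
        assert len(range(0, 19, 3)) == 7
        assert len(range(0, 19, 6)) == 4

    def test_empty_trained_set_rejected(self):
        with pytest.raises(ValidationError):
            assign_slices(5, [])


class TestBreathBudgets:
    def test_two_normal_breaths_selected(self):
        flow = _sine_flow(300)
        idx = select_training_indices(flow, RATE, "2_normal")
        # whole breaths: contiguous block spanning two periods (~91 frames)
        assert idx.min() >= 15  # leading partial breath discarded
        assert 80 <= len(idx) <= 100
        np.testing.assert_array_equal(idx, np.arange(idx.min(), idx.max() + 1))

    def test_inspiration_only_positive_flow(self):
        flow = _sine_flow(300)
        idx = select_training_indices(flow, RATE, "1_inspiration")
        assert np.all(flow[idx] >= -1e-9)
        # roughly half a breath
        assert len(idx) < 40

    def test_deep_budget_requires_deep_breaths(self):
        flow = _sine_flow(300)
        with pytest.raises(ValidationError):
            select_training_indices(flow, RATE, "4_deep")

    def test_deep_and_normal_classification(self):
        rate = RATE
        t1 = np.arange(int(4 * 3.0 * rate)) / rate
        deep = 1.2 * np.sin(2 * np.pi * t1 / 3.0)
        t2 = np.arange(int(5 * 1.5 * rate)) / rate
        normal = 0.5 * np.sin(2 * np.pi * t2 / 1.5)
        flow = np.concatenate([deep, normal])
        idx = select_training_indices(flow, rate, "2_normal", min_breath_s=1.0)
        assert idx.min() > len(deep) - 50  # normal breaths live in the tail

    def test_unknown_budget_rejected(self):
        with pytest.raises(ValidationError):
            select_training_indices(_sine_flow(300), RATE, "5_normal")


class TestSplitTrainTest:
    def _series(self, n):
        return FrameSeries(frames=np.zeros((n, 8, 8)), frame_period=0.033)

    def test_budget_indices_confined_to_training_block(self):
        n = 600
        flow = FlowTrace(values=_sine_flow(n), rate=RATE)
        spec = ProtocolSpec(train_frames_per_slice=200, test_frames_per_slice=300)
        idx, (a, b) = split_train_test(self._series(n), flow, spec)
        assert idx.max() < 200
        assert (a, b) == (200, 500)

    def test_training_fraction_capped_at_one_third(self):
        flow = FlowTrace(values=_sine_flow(300), rate=RATE)
        spec = ProtocolSpec(train_frames_per_slice=150, test_frames_per_slice=100)
        with pytest.raises(ValidationError, match="one third"):
            split_train_test(self._series(300), flow, spec)

    def test_blocks_must_fit(self):
        flow = FlowTrace(values=_sine_flow(300), rate=RATE)
        spec = ProtocolSpec(train_frames_per_slice=100, test_frames_per_slice=300)
        with pytest.raises(ValidationError, match="exceed"):
            split_train_test(self._series(300), flow, spec)

    def test_invalid_stride_and_budget_rejected(self):
        with pytest.raises(ValidationError):
            ProtocolSpec(slice_stride=4)
        with pytest.raises(ValidationError):
            ProtocolSpec(breath_budget="0_normal")


@pytest.fixture(scope="module")
def protocol_scene():
    return make_scene(seed=310, n_slices=3, frames_per_slice=450, image_size=80)


@pytest.fixture(scope="module")
def stride1_result(protocol_scene):
    spec = ProtocolSpec(
        train_frames_per_slice=150, test_frames_per_slice=300, slice_stride=1, seed=9
    )
    return run_protocol(protocol_scene, spec)


class TestRunProtocol:
    def test_per_slice_reports_and_pooling(self, stride1_result):
        res = stride1_result
        assert sorted(res.per_slice) == [0, 1, 2]
        r2s = [rep.r2_flow for rep in res.per_slice.values()]
        assert res.pooled["mean_r2_flow"] == pytest.approx(np.mean(r2s))
        assert res.pooled["mean_r2_flow"] > 0.95  # trained-on-self slices

    def test_table_shape(self, stride1_result):
        tab = stride1_result.table()
        assert len(tab) == 3
        assert set(["slice", "trained", "r2_flow"]).issubset(tab.columns)

    def test_fixed_test_block_identical_across_strides(self, protocol_scene, stride1_result):
        spec3 = ProtocolSpec(
            train_frames_per_slice=150, test_frames_per_slice=300, slice_stride=3, seed=9
        )
        res3 = run_protocol(protocol_scene, spec3)
        np.testing.assert_array_equal(
            stride1_result.per_slice[0].measured.values, res3.per_slice[0].measured.values
        )

    def test_untrained_slice_uses_neighbor_model(self, protocol_scene):
        spec3 = ProtocolSpec(
            train_frames_per_slice=150, test_frames_per_slice=300, slice_stride=3, seed=9
        )
        res = run_protocol(protocol_scene, spec3)
        assert res.trained_slices == [0]
        assert res.assignment[2] == 0
        assert 2 in res.per_slice


@pytest.fixture(scope="module")
def transfer_scenes():
    train = make_scene(seed=21, n_slices=2, frames_per_slice=450, image_size=80)
    test_aligned = make_scene(seed=22, n_slices=2, frames_per_slice=450, image_size=80)
    return train, test_aligned


class TestCrossSubjectTransfer:
    def test_rotate_is_noop_when_orientations_match(self, transfer_scenes):
        train, test = transfer_scenes
        spec = ProtocolSpec(
            train_frames_per_slice=150, test_frames_per_slice=300, slice_stride=1, seed=5
        )
        res_a = cross_subject_transfer([train], test, spec, rotate=False)
        res_b = cross_subject_transfer([train], test, spec, rotate=True)
        for s in res_a.per_slice:
            np.testing.assert_allclose(
                res_a.per_slice[s].predicted.values,
                res_b.per_slice[s].predicted.values,
                atol=1e-6,
            )

    def test_similar_anatomy_transfers_well(self, transfer_scenes):
        train, test = transfer_scenes
        spec = ProtocolSpec(
            train_frames_per_slice=150, test_frames_per_slice=300, slice_stride=1, seed=5
        )
        res = cross_subject_transfer([train], test, spec)
        assert res.pooled["mean_r2_flow"] > 0.9


@pytest.fixture(scope="module")
def retest_results():
    n_slices, fps = 8, 450
    base = make_scene(seed=31, n_slices=n_slices, frames_per_slice=fps, image_size=80)
    dur = n_slices * fps * 0.033
    pattern2 = breath_pattern_for_duration(
        dur, tidal_volume_l=0.5, period_s=1.5, jitter=0.05,
        rng=np.random.default_rng(32),
    )
    cfg2 = dataclasses.replace(base.config, breath_pattern=pattern2, noise_seed=931)
    cfg2r = dataclasses.replace(cfg2, rotation_deg=15.0)
    from respiro.phantom import render_scene

    scan2 = render_scene(cfg2)
    scan2r = render_scene(cfg2r)
    spec = ProtocolSpec(
        train_frames_per_slice=150, test_frames_per_slice=300,
        slice_stride=2, breath_budget="2_normal", seed=7,
    )
    return {
        "same": run_test_retest(base, scan2, spec),
        "rotated": run_test_retest(base, scan2r, spec, rotate=False),
        "realigned": run_test_retest(base, scan2r, spec, rotate=True),
    }


class TestTestRetest:

    def test_identical_orientation_retest_passes_volume_qc(self, retest_results):
        assert retest_results["same"].pooled["qc_volume_pass"]

    def test_rotated_retest_keeps_breath_phase_but_degrades(self, retest_results):
        """Rotation misalignment still separates inspiration from expiration."""
        res = retest_results["rotated"]
        agreements = [
            sign_agreement(rep.measured.values, rep.predicted.values)
            for rep in res.per_slice.values()
        ]
        assert np.mean(agreements) > 0.8
        assert res.pooled["mean_r2_flow"] < retest_results["same"].pooled["mean_r2_flow"]

    def test_realignment_improves_metrics(self, retest_results):
        assert (
            retest_results["realigned"].pooled["mean_r2_flow"]
            > retest_results["rotated"].pooled["mean_r2_flow"]
        )
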