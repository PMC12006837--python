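"""Spine-volume quantification: projection, registration, ROI correction,
drift QC and shrinkage summaries."""

import numpy as np
import pytest

from spineburst import synth
from spineburst.spines import (
    RoiSpec,
    SpineTrace,
    drift_qc,
    measure_roi_series,
    project_zseries,
    quantify_series,
    register_series,
    spine_density,
    summarize_shrinkage,
)

from oracles import ols_line


class TestProjection:
    def test_single_voxel(self):
        stack = np.zeros((8, 8, 3))
        stack[2, 5, 1] = 7.0
        proj = project_zseries(stack)
        assert proj[2, 5] == 7.0
        assert proj.sum() == 7.0

    def test_constant_stack(self):
        assert np.all(project_zseries(np.full((4, 4, 5), 3.0)) == 3.0)

    def test_max_and_sum_conventions(self):
        stack = np.zeros((2, 2, 2))
        stack[0, 0] = [3.0, 7.0]
        assert project_zseries(stack, "max")[0, 0] == 7.0
        assert project_zseries(stack, "sum")[0, 0] == 10.0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            project_zseries(np.zeros((0, 4, 4)))


class TestRegistration:
    def _scene(self, rng):
        img = np.zeros((64, 64))
        img[20:28, 30:40] = rng.uniform(50, 100, (8, 10))
        return img

    def test_identical_images_zero_shift(self, rng):
        img = self._scene(rng)
        _, shifts = register_series([img, img.copy(), img.copy()])
        assert np.all(shifts == 0)

    def test_known_translation_recovered(self, rng):
        img = self._scene(rng)
        moved = np.roll(img, (3, -2), axis=(0, 1))
        aligned, shifts = register_series([img, moved])
        assert tuple(shifts[1]) == (3, -2)
        assert np.array_equal(aligned[1][5:-5, 5:-5], img[5:-5, 5:-5])

    def test_exhaustive_shift_search_agreement(self, rng):
        """Phase correlation matches an exhaustive integer-shift search."""
        img = self._scene(rng)
        for dy, dx in [(-7, 4), (0, 9), (10, -10)]:
            moved = np.roll(img, (dy, dx), axis=(0, 1))
            _, shifts = register_series([img, moved])
            best, best_err = None, np.inf
            for sy in range(-10, 11):
                for sx in range(-10, 11):
                    err = np.sum((np.roll(moved, (-sy, -sx), axis=(0, 1)) - img) ** 2)
                    if err < best_err:
                        best, best_err = (sy, sx), err
            assert tuple(shifts[1]) == best == (dy, dx)

    def test_idempotence(self, rng):
        img = self._scene(rng)
        aligned, _ = register_series([img, np.roll(img, (2, 2), axis=(0, 1))])
        _, again = register_series(aligned)
        assert np.all(again == 0)

    def test_all_zero_image_warns(self, rng):
        img = self._scene(rng)
        with pytest.warns(RuntimeWarning, match="all-zero"):
            _, shifts = register_series([img, np.zeros_like(img)])
        assert tuple(shifts[1]) == (0, 0)


def _uniform_rois():
    rois = [RoiSpec((30.0, 30.0), role="spine")]
    rois += [RoiSpec((30.0, 70.0 + 24 * k), role="background") for k in range(3)]
    rois += [RoiSpec((70.0, 30.0 + 24 * k), role="reference") for k in range(4)]
    return rois


class TestRoiMeasurement:
    def test_background_subtraction_arithmetic(self):
        """Uniform image of 10 with background reading 2 per pixel:
        corrected ROI = (10 - 2) * 400 = 3200."""
        rois = _uniform_rois()
        imgs = []
        for _ in range(4):
            img = np.full((128, 128), 2.0)
            for r in rois:
                if r.role != "background":
                    r0, r1, c0, c1 = r.bounds()
                    img[r0:r1, c0:c1] = 10.0
            imgs.append(img)
        traces = measure_roi_series(imgs, rois, np.arange(4) * 4.0, baseline_minutes=30.0)
        assert np.allclose(traces[0].corrected, 3200.0)
        assert np.allclose(traces[0].normalized, 100.0)

    def test_global_gain_cancels_exactly(self, small_stack_series):
        series, truth = small_stack_series
        imgs = [project_zseries(s) for s in series.stacks]
        base = measure_roi_series(imgs, truth["rois"], series.timestamps_min)
        scaled = [im * (1.3 if t == 20 else 1.0) for t, im in enumerate(imgs)]
        out = measure_roi_series(scaled, truth["rois"], series.timestamps_min)
        assert np.allclose(out[0].normalized, base[0].normalized, rtol=1e-12)

    def test_uniform_offset_cancels_exactly(self, small_stack_series):
        series, truth = small_stack_series
        imgs = [project_zseries(s) for s in series.stacks]
        base = measure_roi_series(imgs, truth["rois"], series.timestamps_min)
        shifted = [im + (37.0 if t == 5 else 0.0) for t, im in enumerate(imgs)]
        out = measure_roi_series(shifted, truth["rois"], series.timestamps_min)
        assert np.allclose(out[0].corrected, base[0].corrected, rtol=1e-12)

    def test_bleaching_fully_corrected(self):
        p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=3, shrink_fraction=1.0,
                                 bleach_per_timepoint=0.2, jitter_px=0, shot_noise=False, seed=3)
        series, truth = synth.gen_spine_stack_series(p)
        traces, _, _ = quantify_series(series, truth["rois"])
        for tr in traces:
            assert np.allclose(tr.normalized, 100.0, atol=1e-6)

    def test_roi_outside_frame_rejected(self):
        rois = _uniform_rois() + [RoiSpec((5.0, 5.0), role="spine")]
        with pytest.raises(ValueError, match="not fully inside"):
            measure_roi_series([np.ones((128, 128))] * 3, rois, np.arange(3) * 4.0)

    def test_roi_role_counts_enforced(self):
        rois = [RoiSpec((30.0, 30.0), role="spine"), RoiSpec((30.0, 70.0), role="background")]
        with pytest.raises(ValueError, match="3 background"):
            measure_roi_series([np.ones((128, 128))] * 3, rois, np.arange(3) * 4.0)


def _trace_from(values, dt_min=4.0):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * dt_min
    return SpineTrace(values, values, values, np.ones(values.size, bool), t)


class TestDriftQC:
    def test_constant_baseline_passes_with_zero_drift(self):
        qc = drift_qc(_trace_from([100.0] * 10))
        assert qc.drift_percent == pytest.approx(0.0, abs=1e-9)
        assert qc.passed

    @pytest.mark.parametrize("rise, should_pass", [(10.0, False), (5.0, True)])
    def test_linear_ramp_against_closed_form(self, rise, should_pass):
        t = np.arange(0.0, 30.0, 4.0)
        y = 100.0 + rise * t / 30.0
        qc = drift_qc(_trace_from(y))
        slope, icept = ols_line(t, y)
        fit = slope * t + icept
        expected = abs(fit[-1] - fit[0]) / fit.mean() * 100.0
        assert qc.drift_percent == pytest.approx(expected, rel=1e-9)
        assert qc.passed is should_pass

    def test_too_few_points_flagged(self):
        with pytest.warns(RuntimeWarning, match="fewer than 3"):
            qc = drift_qc(_trace_from([100.0, 101.0]))
        assert not qc.passed and np.isnan(qc.drift_percent)

    def test_injected_drift_flagged_and_clean_passes(self):
        from spineburst.spines import session_drift_qc

        for frac, expect in [(0.10, False), (0.04, True)]:
            p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=3,
                                     baseline_drift_fraction=frac, seed=8)
            series, truth = synth.gen_spine_stack_series(p)
            traces, _, _ = quantify_series(series, truth["rois"])
            assert session_drift_qc(traces).passed is expect


class TestShrinkageSummary:
    def test_constant_traces_give_100(self):
        exps = [[_trace_from([100.0] * 25)] * 3, [_trace_from([100.0] * 25)] * 2]
        mean, sem, n, _ = summarize_shrinkage(exps, (80.0, 96.0))
        assert mean == 100.0 and n == 2

    def test_noise_free_recovery_is_exact(self, small_stack_series):
        series, truth = small_stack_series
        traces, _, _ = quantify_series(series, truth["rois"])
        mean, _, _, _ = summarize_shrinkage([traces], (80.0, 96.0))
        assert mean == pytest.approx(80.0, abs=1e-6)

    def test_shot_noise_recovery_within_tolerance(self):
        errs = []
        for seed in range(5):
            p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=3, seed=seed)
            series, truth = synth.gen_spine_stack_series(p)
            traces, _, qc = quantify_series(series, truth["rois"])
            kept = [tr for tr, q in zip(traces, qc) if q.passed]
            mean, _, _, _ = summarize_shrinkage([kept], (80.0, 96.0))
            errs.append(abs(mean - 80.0))
        assert np.mean(errs) <= 3.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            summarize_shrinkage([[_trace_from([100.0] * 5)]], (200.0, 300.0))


class TestSpineDensity:
    def test_arithmetic(self):
        assert spine_density(23, 50.0) == pytest.approx(4.6)

    def test_zero_spines(self):
        assert spine_density(0, 30.0) == 0.0

    def test_homogeneity(self):
        assert spine_density(10, 25.0) == spine_density(20, 50.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            spine_density(5, 0.0)
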