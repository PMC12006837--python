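"""Generators: determinism, silent cases, counting oracles, scaling."""

import numpy as np
import pytest

from spineburst import fepsp, spines, synth


class TestExtracellular:
    def test_silent_case(self):
        p = synth.EphysSimParams(duration=1.0, noise_sd=0.0, background_rate=0.0, seed=0)
        tr, truth = synth.gen_extracellular_trace(p)
        assert np.all(tr.samples == 0)
        assert truth["spike_times"].size == 0

    def test_seed_determinism_bitwise(self):
        p = synth.EphysSimParams(duration=5.0, burst_intervals=((1.0, 2.0),), seed=7)
        t1, g1 = synth.gen_extracellular_trace(p)
        t2, g2 = synth.gen_extracellular_trace(p)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1["spike_times"], g2["spike_times"])

    def test_poisson_burst_count_oracle(self):
        """40 Hz Poisson bursting over 2 s: the ground-truth count inside the
        interval is ~80, within 4*sqrt(80) (Poisson counting oracle)."""
        p = synth.EphysSimParams(
            duration=10.0, burst_rate=40.0, background_rate=0.5,
            burst_intervals=((4.0, 6.0),), intra_burst="poisson", seed=3,
        )
        _, truth = synth.gen_extracellular_trace(p)
        t = truth["spike_times"]
        inside = np.sum((t >= 4.0) & (t < 6.0))
        assert abs(inside - 80) <= 4 * np.sqrt(80)

    def test_rhythmic_burst_count_is_tight(self):
        p = synth.EphysSimParams(duration=10.0, burst_rate=12.0, background_rate=0.0,
                                 burst_intervals=((2.0, 7.0),), seed=5)
        _, truth = synth.gen_extracellular_trace(p)
        assert abs(truth["spike_times"].size - 60) <= 3

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.EphysSimParams(duration=10.0, burst_intervals=((1.0, 3.0), (2.5, 4.0)))

    def test_amplitude_scaling(self):
        base = synth.EphysSimParams(duration=2.0, noise_sd=0.0, background_rate=2.0, seed=9)
        t1, _ = synth.gen_extracellular_trace(base)
        t2, _ = synth.gen_extracellular_trace(
            synth.EphysSimParams(duration=2.0, noise_sd=0.0, background_rate=2.0,
                                 spike_amplitude=-160.0, seed=9)
        )
        assert np.allclose(t2.samples, 2.0 * t1.samples)

    def test_plan_burst_intervals_disjoint_and_classed(self, rng):
        plan = synth.plan_burst_intervals(600.0, rng=rng)
        assert all(b > a for a, b in plan)
        assert all(a2 - b1 >= 8.0 for (_, b1), (a2, _) in zip(plan, plan[1:]))
        durs = np.array([b - a for a, b in plan])
        assert np.all(((durs >= 0.6) & (durs <= 0.8)) | ((durs >= 2.2) & (durs <= 3.0)))


class TestFepsp:
    def test_no_depression_no_noise_identical_sweeps(self):
        p = synth.FepspSimParams(depression_fraction=1.0, noise_cv=0.0, seed=0)
        s, _ = synth.gen_fepsp_session(p)
        assert np.all(s.sweeps == s.sweeps[0])

    def test_depression_forces_slope_ratio(self):
        p = synth.FepspSimParams(depression_fraction=0.46, noise_cv=0.0, seed=0)
        s, truth = synth.gen_fepsp_session(p)
        slopes = fepsp.measure_slopes(s)
        pre = slopes[truth["strength"] == 1.0].mean()
        post = slopes[truth["strength"] != 1.0].mean()
        assert post / pre == pytest.approx(0.46, rel=1e-6)

    def test_amplitude_linearity_through_measured_slope(self):
        s1, _ = synth.gen_fepsp_session(synth.FepspSimParams(noise_cv=0.0, seed=0))
        s2, _ = synth.gen_fepsp_session(synth.FepspSimParams(noise_cv=0.0, amplitude_mv=2.0, seed=0))
        r1 = fepsp.measure_slope(s1.time_ms, s1.sweeps[0], s1.stim_ms)
        r2 = fepsp.measure_slope(s2.time_ms, s2.sweeps[0], s2.stim_ms)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-9)

    def test_bad_durations_rejected(self):
        with pytest.raises(ValueError):
            synth.FepspSimParams(baseline_min=0.0)


class TestSpineStacks:
    def test_static_scene_identical_timepoints(self):
        p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=1, shrink_fraction=1.0,
                                 bleach_per_timepoint=0.0, jitter_px=0, shot_noise=False,
                                 n_timepoints=5, seed=1)
        s, _ = synth.gen_spine_stack_series(p)
        for stack in s.stacks[1:]:
            assert np.array_equal(stack, s.stacks[0])

    def test_blob_integral_tracks_volume_step(self):
        p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=1, shrink_fraction=0.8,
                                 shrink_onset=2, bleach_per_timepoint=0.0, jitter_px=0,
                                 shot_noise=False, background_level=0.0, ridge_intensity=0.0,
                                 n_timepoints=4, seed=1)
        s, truth = synth.gen_spine_stack_series(p)
        cy, cx, _ = truth["spine_centers"][0]
        r0, c0 = int(cy) - 10, int(cx) - 10
        pre = s.stacks[0][r0 : r0 + 20, c0 : c0 + 20].sum()
        post = s.stacks[3][r0 : r0 + 20, c0 : c0 + 20].sum()
        # references contribute nothing inside this ROI; ratio is the step
        assert post / pre == pytest.approx(0.8, rel=1e-3)

    def test_seed_determinism(self):
        p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=1, n_timepoints=3, seed=4)
        s1, _ = synth.gen_spine_stack_series(p)
        s2, _ = synth.gen_spine_stack_series(p)
        for a, b in zip(s1.stacks, s2.stacks):
            assert np.array_equal(a, b)

    def test_volume_scaling(self):
        kw = dict(frame_shape=(128, 128, 8), n_spines=1, n_timepoints=2, shot_noise=False,
                  background_level=0.0, ridge_intensity=0.0, seed=2)
        s1, _ = synth.gen_spine_stack_series(synth.SpineSimParams(baseline_volume=20000.0, **kw))
        s2, _ = synth.gen_spine_stack_series(synth.SpineSimParams(baseline_volume=40000.0, **kw))
        assert np.allclose(s2.stacks[0], 2.0 * s1.stacks[0])

    def test_jitter_recovered_by_registration(self):
        p = synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=1, jitter_px=3,
                                 shot_noise=False, n_timepoints=5, seed=6)
        s, truth = synth.gen_spine_stack_series(p)
        proj = [spines.project_zseries(st) for st in s.stacks]
        _, shifts = spines.register_series(proj)
        assert np.array_equal(shifts, truth["jitters"])

    def test_overfull_frame_rejected(self):
        with pytest.raises(ValueError, match="cannot host"):
            synth.gen_spine_stack_series(synth.SpineSimParams(frame_shape=(64, 64, 6), n_spines=15))


class TestLabeling:
    def test_no_noise_no_effect_all_equal(self):
        from spineburst.metabolic import normalize_batch
        p = synth.LabelingSimParams(group_effects={"A": 1.0, "B": 1.0}, cv=0.0,
                                    protein_cv=0.0, triplicate_cv=0.0, seed=0)
        out = normalize_batch(synth.gen_labeling_experiment(p)[0])
        assert np.allclose(out["normalized_percent"], 100.0)

    def test_exact_effect_without_noise(self):
        from spineburst.metabolic import normalize_batch
        p = synth.LabelingSimParams(cv=0.0, protein_cv=0.0, triplicate_cv=0.0, seed=0)
        out = normalize_batch(synth.gen_labeling_experiment(p)[0])
        means = out.groupby("group")["normalized_percent"].mean()
        assert means["KO"] / means["WT"] == pytest.approx(1.15, rel=1e-12)

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synth.LabelingSimParams(group_effects={"WT": 1.0, "KO": 0.0})


class TestAgsCohort:
    @pytest.mark.parametrize("p, expected", [(0.0, 0), (1.0, 10)])
    def test_degenerate_probabilities(self, p, expected):
        params = synth.AgsSimParams(groups=(("WT", "saline", p, 10),), seed=0)
        table, _ = synth.gen_ags_cohort(params)
        assert int(table["seized"].sum()) == expected

    def test_binomial_tail_oracle(self):
        params = synth.AgsSimParams(groups=(("KO", "saline", 0.8, 1000),), seed=1)
        table, _ = synth.gen_ags_cohort(params)
        assert 0.75 <= table["seized"].mean() <= 0.85

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            synth.AgsSimParams(groups=(("WT", "saline", 1.2, 5),))
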