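"""End-to-end runs: configuration validation, stage execution, manifests.

A run is described by a YAML/dict config with per-stage blocks; every
constant of the analysis (filter band, MAD factor, bin and window widths,
hysteresis rates, ROI geometry, drift threshold, analysis windows, the
+/-2 SD outlier rule) is surfaced as a named default rather than being
hard-coded. Reruns with the same config and seed write byte-identical
outputs, which the manifest certifies with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import inspect
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, synth
from .bursts import DetectorConfig, analyze_trace
from .fepsp import measure_slopes, normalize_series, plasticity_magnitude
from .metabolic import normalize_batch
from .spines import quantify_series, session_drift_qc, summarize_shrinkage
from .stats import ContingencyTable2x2, fisher_exact

log = logging.getLogger("spineburst")

_STAGES = ("trace", "bursts", "fepsp", "stacks", "spines", "labeling", "ags", "fisher")

_DEFAULTS = {
    "seed": 0,
    "stages": ["trace", "bursts"],
    "detector": {k.name: getattr(DetectorConfig(), k.name) for k in dataclasses.fields(DetectorConfig)},
    "trace": {},  # EphysSimParams overrides
    "burst_plan": {"n_bursts": 12},
    "fepsp": {},  # FepspSimParams overrides
    "fepsp_windows": {"baseline_min": [0.0, 10.0], "post_min": [60.0, 70.0]},
    "stacks": {},  # SpineSimParams overrides
    "spines": {"baseline_minutes": 30.0, "analysis_window_min": [80.0, 96.0], "projection": "max"},
    "labeling": {},
    "ags": {},
}


_PARAM_BLOCKS = {
    "trace": synth.EphysSimParams,
    "fepsp": synth.FepspSimParams,
    "stacks": synth.SpineSimParams,
    "labeling": synth.LabelingSimParams,
    "ags": synth.AgsSimParams,
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for k, v in user.items():
        if k not in defaults:
            raise ValueError(f"unknown config key {path + k!r}")
        if k in _PARAM_BLOCKS and not path:
            fields = {f.name for f in dataclasses.fields(_PARAM_BLOCKS[k])} - {"seed"}
            bad = set(v) - fields
            if bad:
                raise ValueError(f"unknown config key(s) {sorted(bad)} in block {k!r}")
            out[k] = dict(v)
        elif k == "burst_plan" and not path:
            allowed = set(inspect.signature(synth.plan_burst_intervals).parameters) - {"duration", "rng"}
            bad = set(v) - allowed
            if bad:
                raise ValueError(f"unknown config key(s) {sorted(bad)} in block 'burst_plan'")
            out[k] = dict(v)
        elif isinstance(defaults[k], dict) and isinstance(v, dict) and defaults[k]:
            out[k] = _merge(defaults[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Fill defaults, reject unknown keys, and sanity-check constants."""
    cfg = _merge(_DEFAULTS, config or {})
    det = dict(_DEFAULTS["detector"])
    det.update(cfg["detector"] if isinstance(cfg["detector"], dict) else {})
    unknown = set(det) - set(_DEFAULTS["detector"])
    if unknown:
        raise ValueError(f"unknown detector keys {sorted(unknown)}")
    for key in ("band", "analysis_span"):
        if det.get(key) is not None:
            det[key] = tuple(det[key])
    DetectorConfig(**det)  # raises on bad hysteresis/band
    cfg["detector"] = det
    for s in cfg["stages"]:
        if s not in _STAGES:
            raise ValueError(f"unknown stage {s!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the requested stages in dependency order; write a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    det = DetectorConfig(**cfg["detector"])
    written: list[Path] = []

    trace = truth = None
    if "trace" in stages or "bursts" in stages:
        rng = np.random.default_rng(seed)
        plan = synth.plan_burst_intervals(
            cfg["trace"].get("duration", synth.EphysSimParams().duration), rng=rng, **cfg["burst_plan"]
        )
        params = synth.EphysSimParams(seed=seed, burst_intervals=plan, **cfg["trace"])
        trace, truth = synth.gen_extracellular_trace(params)
        io.write_trace_npz(out / "trace.npz", trace)
        io.write_ground_truth(out / "trace_truth.json", truth)
        written += [out / "trace.npz", out / "trace_truth.json"]
        log.info("trace: %.0f s at %.0f Hz, %d true bursts", params.duration, params.fs, len(plan))

    if "bursts" in stages:
        events, summary = analyze_trace(trace, det)
        io.write_events_csv(out / "events.csv", events)
        io.write_summary_json(out / "burst_summary.json", summary)
        written += [out / "events.csv", out / "burst_summary.json"]
        log.info("bursts: %d events (%d short, %d long)", len(events), summary.n_short, summary.n_long)

    if "fepsp" in stages:
        params = synth.FepspSimParams(seed=seed, **cfg["fepsp"])
        series, ftruth = synth.gen_fepsp_session(params)
        slopes = measure_slopes(series)
        norm = normalize_series(slopes, series.timestamps_min, tuple(cfg["fepsp_windows"]["baseline_min"]))
        mag = plasticity_magnitude(norm, tuple(cfg["fepsp_windows"]["post_min"]))
        io.write_sweeps_csv(out / "sweeps.csv", series)
        pd.DataFrame(
            {"timestamp_min": norm.timestamps_min, "slope_mV_per_ms": norm.slopes, "normalized_pct": norm.normalized}
        ).to_csv(out / "slopes.csv", index=False, float_format="%.6f")
        (out / "ltd_summary.json").write_text(
            json.dumps({"magnitude_percent": mag.magnitude_percent, "window_min": mag.window_min, "n_sweeps": mag.n_sweeps}, indent=1)
        )
        written += [out / "sweeps.csv", out / "slopes.csv", out / "ltd_summary.json"]
        log.info("fepsp: LTD magnitude %.1f%% of baseline", mag.magnitude_percent)

    series = None
    if "stacks" in stages or "spines" in stages:
        params = synth.SpineSimParams(seed=seed, **cfg["stacks"])
        series, struth = synth.gen_spine_stack_series(params)
        io.write_stack_series(out / "stacks", series)
        io.write_rois_csv(out / "rois.csv", struth["rois"])
        io.write_ground_truth(out / "stacks_truth.json", struth)
        written += sorted((out / "stacks").glob("*.tif")) + [out / "stacks" / "tp_meta.json", out / "rois.csv", out / "stacks_truth.json"]

    if "spines" in stages:
        rois = io.read_rois_csv(out / "rois.csv")
        traces, shifts, qc = quantify_series(
            series, rois, cfg["spines"]["baseline_minutes"], cfg["spines"]["projection"]
        )
        session = session_drift_qc(traces, cfg["spines"]["baseline_minutes"])
        if session.passed:
            mean, _, _, _ = summarize_shrinkage([traces], tuple(cfg["spines"]["analysis_window_min"]))
        else:
            mean = float("nan")
        rows = []
        for i, tr in enumerate(traces):
            for t, v in zip(tr.timestamps_min, tr.normalized):
                rows.append({"spine": i, "timestamp_min": t, "normalized_pct": v})
        pd.DataFrame(rows).to_csv(out / "spine_traces.csv", index=False, float_format="%.4f")
        (out / "spine_qc.json").write_text(
            json.dumps(
                {
                    "n_spines": len(traces),
                    "session_drift_percent": session.drift_percent,
                    "session_passed": session.passed,
                    "spine_drift_percent": [q.drift_percent for q in qc],
                    "volume_percent_mean": mean,
                },
                indent=1,
            )
        )
        written += [out / "spine_traces.csv", out / "spine_qc.json"]
        log.info("spines: session drift %.2f%% (passed=%s), volume %.1f%%",
                 session.drift_percent, session.passed, mean)

    if "labeling" in stages:
        params = synth.LabelingSimParams(seed=seed, **cfg["labeling"])
        table, _ = synth.gen_labeling_experiment(params)
        normalize_batch(table).to_csv(out / "labeling.csv", index=False, float_format="%.4f")
        written.append(out / "labeling.csv")

    if "ags" in stages or "fisher" in stages:
        params = synth.AgsSimParams(seed=seed, **cfg["ags"])
        cohort, _ = synth.gen_ags_cohort(params)
        cohort.to_csv(out / "ags_cohort.csv", index=False)
        written.append(out / "ags_cohort.csv")
        if "fisher" in stages:
            results = {}
            groups = cohort.groupby(["genotype", "treatment"])["seized"].agg(["sum", "count"])
            keys = list(groups.index)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    s1, n1 = groups.loc[keys[i]]
                    s2, n2 = groups.loc[keys[j]]
                    r = fisher_exact(ContingencyTable2x2.from_incidence(int(s1), int(n1), int(s2), int(n2)))
                    results["{}:{} vs {}:{}".format(*keys[i], *keys[j])] = r.p_two_sided
            (out / "fisher.json").write_text(json.dumps(results, indent=1))
            written.append(out / "fisher.json")

    manifest = {
        "config": cfg,
        "seed": seed,
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the canonical small test dataset.

    Contents: a 10-min extracellular trace with 12 known bursts; a
    25-timepoint spine stack series (128x128x8 frames, 3 spines); one
    fEPSP session; a labeling table; and the audiogenic-seizure cohort
    with the published incidence counts (2/15 WT-saline, 9/11 KO-saline,
    2/15 WT-Glyx, 5/16 KO-Glyx) written verbatim, not sampled.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    plan = synth.plan_burst_intervals(600.0, n_bursts=12, rng=rng)
    trace, truth = synth.gen_extracellular_trace(
        synth.EphysSimParams(duration=600.0, burst_intervals=plan, seed=seed)
    )
    io.write_trace_npz(out / "trace.npz", trace)
    io.write_ground_truth(out / "trace_truth.json", truth)

    series, struth = synth.gen_spine_stack_series(
        synth.SpineSimParams(frame_shape=(128, 128, 8), n_spines=3, seed=seed)
    )
    io.write_stack_series(out / "stacks", series)
    io.write_rois_csv(out / "rois.csv", struth["rois"])
    io.write_ground_truth(out / "stacks_truth.json", struth)

    fsess, ftruth = synth.gen_fepsp_session(synth.FepspSimParams(seed=seed))
    io.write_sweeps_csv(out / "sweeps.csv", fsess)
    io.write_ground_truth(out / "sweeps_truth.json", ftruth)

    table, _ = synth.gen_labeling_experiment(synth.LabelingSimParams(seed=seed))
    table.to_csv(out / "labeling.csv", index=False, float_format="%.4f")

    rows = []
    for genotype, treatment, seized, n in (
        ("WT", "saline", 2, 15),
        ("KO", "saline", 9, 11),
        ("WT", "glyx13", 2, 15),
        ("KO", "glyx13", 5, 16),
    ):
        for i in range(n):
            rows.append(
                {
                    "animal_id": f"{genotype}_{treatment}_{i:02d}",
                    "genotype": genotype,
                    "treatment": treatment,
                    "seized": i < seized,
                }
            )
    pd.DataFrame(rows).to_csv(out / "ags_cohort.csv", index=False)

    paths = sorted(p for p in out.rglob("*") if p.is_file())
    return {str(p.relative_to(out)): _sha256(p) for p in paths}


__all__ = ["validate_config", "run_pipeline", "make_fixtures"]
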