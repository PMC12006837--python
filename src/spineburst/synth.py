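"""Synthetic data with known ground truth for every analysis stage.

Each generator emulates the statistical structure of one experimental
readout — extracellular CA3 recordings with embedded epileptiform bursts,
Schaffer-collateral fEPSP sweeps with a step depression, two-photon spine
z-series with photobleaching and stage jitter, 35S metabolic-labeling
count tables, and audiogenic-seizure cohorts — and returns the data
together with an immutable :class:`GroundTruth` record describing exactly
what was generated. All randomness flows from a single seeded
``numpy.random.Generator`` per call; identical parameters and seed give
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .bursts import VoltageTrace
from .fepsp import SweepSeries
from .spines import RoiSpec, StackSeries


@dataclass(frozen=True)
class GroundTruth:
    """Immutable record of what a generator actually produced."""

    kind: str
    data: Mapping[str, Any]

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", MappingProxyType(dict(self.data)))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, (list, tuple)):
                return [conv(u) for u in v]
            if isinstance(v, Mapping):
                return {k: conv(u) for k, u in v.items()}
            return v

        return {"kind": self.kind, "data": {k: conv(v) for k, v in self.data.items()}}


# ---------------------------------------------------------------------------
# extracellular CA3 traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EphysSimParams:
    """Conditions for a synthetic extracellular CA3 recording.

    The defaults are the study conditions used throughout the analysis:
    25 kHz sampling, 10 uV Gaussian noise, -80 uV spikes, sparse (0.05 Hz)
    background multi-unit activity, and rhythmic 12 Hz discharge inside
    declared burst intervals.
    """

    duration: float = 600.0
    fs: float = 25000.0
    noise_sd: float = 10.0
    spike_amplitude: float = -80.0
    background_rate: float = 0.05
    burst_rate: float = 12.0
    burst_intervals: tuple[tuple[float, float], ...] = ()
    intra_burst: str = "rhythmic"  # or "poisson"
    isi_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 2000.0:
            raise ValueError("sampling rate must exceed 2 kHz to support the 300-1000 Hz band")
        if self.intra_burst not in ("rhythmic", "poisson"):
            raise ValueError("intra_burst must be 'rhythmic' or 'poisson'")
        ivals = sorted(tuple(map(float, iv)) for iv in self.burst_intervals)
        for (a, b) in ivals:
            if not (0.0 <= a < b <= self.duration):
                raise ValueError(f"burst interval ({a}, {b}) outside [0, {self.duration}]")
        for (_, b), (a2, _) in zip(ivals, ivals[1:]):
            if a2 < b:
                raise ValueError("burst intervals must not overlap")
        object.__setattr__(self, "burst_intervals", tuple(ivals))


def spike_template(fs: float, amplitude: float = -1.0) -> np.ndarray:
    """Biphasic extracellular spike: 0.45-ms negative lobe then a 0.75-ms
    positive lobe at 40% amplitude (1.2 ms total); peak equals ``amplitude``."""
    n_neg = max(int(round(0.00045 * fs)), 2)
    n_pos = max(int(round(0.00075 * fs)), 2)
    w = np.concatenate(
        [-np.sin(np.linspace(0.0, np.pi, n_neg)), 0.4 * np.sin(np.linspace(0.0, np.pi, n_pos))]
    )
    return w / np.abs(w).max() * -amplitude * -1.0


def plan_burst_intervals(
    duration: float,
    n_bursts: int = 12,
    short_range: tuple[float, float] = (0.6, 0.8),
    long_range: tuple[float, float] = (2.2, 3.0),
    p_short: float = 0.6,
    min_gap: float = 8.0,
    edge_margin: float = 10.0,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[float, float], ...]:
    """Draw non-overlapping burst intervals of two duration classes.

    Short interictal-like events and prolonged discharges are drawn from
    separate ranges, mirroring the bimodal short/long event structure of
    disinhibited CA3, with a minimum quiet gap between events.
    """
    rng = rng or np.random.default_rng()
    durations = np.where(
        rng.random(n_bursts) < p_short,
        rng.uniform(*short_range, n_bursts),
        rng.uniform(*long_range, n_bursts),
    )
    for _ in range(10000):
        starts = np.sort(rng.uniform(edge_margin, duration - edge_margin - durations.max(), n_bursts))
        ends = starts + durations
        if np.all(starts[1:] - ends[:-1] >= min_gap):
            return tuple((float(a), float(b)) for a, b in zip(starts, ends))
    raise RuntimeError("could not place burst intervals; reduce n_bursts or min_gap")


def gen_extracellular_trace(params: EphysSimParams) -> tuple[VoltageTrace, GroundTruth]:
    """Gaussian noise plus biphasic spike templates.

    Background spikes are Poisson at ``background_rate`` outside the burst
    intervals; inside each interval spikes fire at ``burst_rate``, by
    default as a jittered clock (rhythmic discharge), optionally as a
    Poisson process.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    x = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)

    spike_times: list[float] = []
    # background: Poisson over the whole record, thinned out of burst windows
    n_bg = rng.poisson(params.background_rate * params.duration)
    for t in np.sort(rng.uniform(0.0, params.duration, n_bg)):
        if not any(a <= t < b for a, b in params.burst_intervals):
            spike_times.append(float(t))
    for (a, b) in params.burst_intervals:
        if params.intra_burst == "poisson":
            k = rng.poisson(params.burst_rate * (b - a))
            spike_times.extend(np.sort(rng.uniform(a, b, k)).tolist())
        else:
            isi = 1.0 / params.burst_rate
            t = a + rng.uniform(0.0, isi)
            while t < b:
                spike_times.append(float(t))
                t += isi * (1.0 + params.isi_jitter * rng.uniform(-1.0, 1.0))
    spike_times.sort()

    tmpl = spike_template(params.fs, params.spike_amplitude)
    for t in spike_times:
        i = int(round(t * params.fs))
        j = min(n, i + tmpl.size)
        if i < n:
            x[i:j] += tmpl[: j - i]

    truth = GroundTruth(
        "extracellular_trace",
        {
            "spike_times": np.asarray(spike_times),
            "burst_intervals": params.burst_intervals,
            "params": params,
        },
    )
    return VoltageTrace(x, params.fs), truth


# ---------------------------------------------------------------------------
# fEPSP sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FepspSimParams:
    """Conditions for a synthetic Schaffer-collateral fEPSP session.

    One sweep per 30 s (0.033 Hz stimulation); synaptic strength is 1.0
    through the baseline and steps to ``depression_fraction`` at induction,
    with multiplicative per-sweep noise of coefficient of variation
    ``noise_cv`` on the response.
    """

    baseline_min: float = 10.0
    post_min: float = 60.0
    sweep_interval_s: float = 30.0
    depression_fraction: float = 0.35
    noise_cv: float = 0.05
    sweep_ms: float = 80.0
    fs_khz: float = 10.0
    stim_ms: float = 5.0
    amplitude_mv: float = 1.0
    tau_rise_ms: float = 1.5
    tau_decay_ms: float = 8.0
    additive_noise_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_min <= 0 or self.post_min <= 0:
            raise ValueError("baseline and post durations must be positive")
        if not 0.0 < self.depression_fraction <= 1.0:
            raise ValueError("depression_fraction must lie in (0, 1]")


def fepsp_waveform(t_ms: np.ndarray, params: FepspSimParams) -> np.ndarray:
    """Difference-of-exponentials field potential (negative-going), unit peak."""
    onset = params.stim_ms + 1.5
    tau = np.maximum(t_ms - onset, 0.0)
    shape = np.exp(-tau / params.tau_decay_ms) - np.exp(-tau / params.tau_rise_ms)
    shape[t_ms < onset] = 0.0
    peak = shape.max()
    return -shape / peak if peak > 0 else shape


def _stim_artifact(t_ms: np.ndarray, stim_ms: float) -> np.ndarray:
    a = np.zeros_like(t_ms)
    w = (t_ms >= stim_ms) & (t_ms < stim_ms + 0.4)
    a[w] = 2.0 * np.sin((t_ms[w] - stim_ms) / 0.4 * 2 * np.pi)
    return a


def gen_fepsp_session(params: FepspSimParams) -> tuple[SweepSeries, GroundTruth]:
    rng = np.random.default_rng(params.seed)
    n_samp = int(round(params.sweep_ms * params.fs_khz))
    t_ms = np.arange(n_samp) / params.fs_khz
    total_s = (params.baseline_min + params.post_min) * 60.0
    stamps_min = np.arange(0.0, total_s, params.sweep_interval_s) / 60.0
    strength = np.where(stamps_min < params.baseline_min, 1.0, params.depression_fraction)

    wave = fepsp_waveform(t_ms, params) * params.amplitude_mv
    artifact = _stim_artifact(t_ms, params.stim_ms)
    sweeps = np.empty((stamps_min.size, n_samp))
    for k, s in enumerate(strength):
        gain = s * (1.0 + params.noise_cv * rng.standard_normal()) if params.noise_cv > 0 else s
        sweeps[k] = artifact + gain * wave
        if params.additive_noise_mv > 0:
            sweeps[k] += rng.normal(0.0, params.additive_noise_mv, n_samp)

    series = SweepSeries(t_ms, sweeps, params.stim_ms, stamps_min)
    truth = GroundTruth(
        "fepsp_session",
        {"strength": strength, "timestamps_min": stamps_min, "params": params},
    )
    return series, truth


# ---------------------------------------------------------------------------
# spine stack series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineSimParams:
    """Conditions for a synthetic two-photon spine imaging session.

    Each timepoint (4-min spacing) is a z-series containing a dendrite
    ridge, ``n_spines`` Gaussian-blob spines whose integrated intensity
    follows the true relative-volume course (a step to ``shrink_fraction``
    at ``shrink_onset``), four stable reference blobs, a uniform background
    offset, global multiplicative bleaching, integer-pixel stage jitter and
    optional shot noise. ``baseline_drift_fraction`` injects a residual
    linear ramp into the spine volumes across the baseline for QC testing.
    """

    n_timepoints: int = 25
    frame_shape: tuple[int, int, int] = (512, 512, 15)  # (y, x, z)
    n_spines: int = 15
    spine_sigma: float = 1.6
    sigma_z: float = 1.2
    baseline_volume: float = 60000.0
    shrink_fraction: float = 0.8
    shrink_onset: int = 8
    bleach_per_timepoint: float = 0.02
    jitter_px: int = 3
    shot_noise: bool = True
    background_level: float = 5.0
    ridge_intensity: float = 120.0
    timepoint_min: float = 4.0
    baseline_drift_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.shrink_fraction <= 1.0:
            raise ValueError("shrink_fraction must lie in (0, 1]")
        if self.shrink_onset < 0:
            raise ValueError("shrink_onset must be non-negative (>= n_timepoints means no shrink)")


def _gaussian_blob(shape, cy, cx, cz, sy, sx, sz, integral):
    yy = np.arange(shape[0])[:, None, None]
    xx = np.arange(shape[1])[None, :, None]
    zz = np.arange(shape[2])[None, None, :]
    g = np.exp(
        -((yy - cy) ** 2) / (2 * sy**2)
        - ((xx - cx) ** 2) / (2 * sx**2)
        - ((zz - cz) ** 2) / (2 * sz**2)
    )
    return g * (integral / ((2 * np.pi) ** 1.5 * sy * sx * sz))


def gen_spine_stack_series(params: SpineSimParams) -> tuple[StackSeries, GroundTruth]:
    """Synthesize the z-series time course and its ground truth.

    Spine and reference blob centers sit alongside a diagonal dendrite
    ridge, spaced so that every 20x20 ROI contains a single structure.
    Raises ``ValueError`` if the requested number of structures cannot be
    placed fully inside the frame.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx, nz = params.frame_shape
    n_struct = params.n_spines + 4  # spines + reference locations
    margin = 14 + params.jitter_px
    pitch = 26  # keeps 20x20 ROIs disjoint

    # dendrite ridge: a gently sloped band across the frame
    def ridge_y(x):
        return 0.3 * ny + 0.2 * x

    # candidate centers on a grid, excluding cells near the background ROI
    # locations; spine cells additionally keep their whole 20x20 ROI clear
    # of the dendrite ridge (constant ridge fluorescence inside a spine ROI
    # would bias the relative-volume ratio), while reference ROIs tolerate
    # ridge overlap because they are normalized to their own baseline
    bg_centers = [(ny - margin + 2.0, margin + 2.0 + 24.0 * k) for k in range(3)]
    gy = np.arange(margin, ny - margin + 1, pitch, dtype=float)
    gx = np.arange(margin, nx - margin + 1, pitch, dtype=float)
    cells = [
        (y, x)
        for y in gy
        for x in gx
        if abs(y - ridge_y(x)) > 11.0
        and all(abs(y - by) >= 22.0 or abs(x - bx) >= 22.0 for by, bx in bg_centers)
    ]
    safe = [c for c in cells if abs(c[0] - ridge_y(c[1])) > 19.0]
    other = [c for c in cells if c not in safe]
    if len(safe) < params.n_spines or len(cells) < n_struct:
        raise ValueError(
            f"frame {(ny, nx)} cannot host {params.n_spines} spines plus 4 "
            f"references at {pitch}-px spacing; enlarge the frame or reduce n_spines"
        )
    spine_cells = [safe[i] for i in rng.choice(len(safe), params.n_spines, replace=False)]
    rest = [c for c in safe if c not in spine_cells] + other
    ref_cells = [rest[i] for i in rng.choice(len(rest), 4, replace=False)]
    chosen = spine_cells + ref_cells
    cy = np.array([c[0] for c in chosen]) + rng.uniform(-2.0, 2.0, n_struct)
    cx = np.array([c[1] for c in chosen]) + rng.uniform(-2.0, 2.0, n_struct)
    cz = np.clip(nz / 2 + rng.uniform(-1.0, 1.0, n_struct), 1.5, nz - 2.5)
    spine_centers = np.stack([cy[: params.n_spines], cx[: params.n_spines], cz[: params.n_spines]], 1)
    ref_centers = np.stack([cy[params.n_spines :], cx[params.n_spines :], cz[params.n_spines :]], 1)

    t_idx = np.arange(params.n_timepoints)
    volumes = np.where(t_idx >= params.shrink_onset, params.shrink_fraction, 1.0)
    volumes = np.tile(volumes, (params.n_spines, 1)).astype(float)
    if params.baseline_drift_fraction != 0.0 and params.shrink_onset > 1:
        ramp = 1.0 + params.baseline_drift_fraction * (t_idx / max(params.shrink_onset - 1, 1))
        volumes[:, : params.shrink_onset] *= ramp[: params.shrink_onset]

    bleach = (1.0 - params.bleach_per_timepoint) ** t_idx
    jitters = (
        rng.integers(-params.jitter_px, params.jitter_px + 1, size=(params.n_timepoints, 2))
        if params.jitter_px > 0
        else np.zeros((params.n_timepoints, 2), dtype=int)
    )
    jitters[0] = 0

    # static fluorescent scene components
    yy = np.arange(ny)[:, None, None]
    xx = np.arange(nx)[None, :, None]
    zz = np.arange(nz)[None, None, :]
    ridge = params.ridge_intensity * np.exp(
        -((yy - ridge_y(xx)) ** 2) / (2 * 2.0**2) - ((zz - nz / 2) ** 2) / (2 * 1.5**2)
    )
    ref_scene = np.zeros((ny, nx, nz))
    for (ry, rx, rz) in ref_centers:
        ref_scene += _gaussian_blob(
            (ny, nx, nz), ry, rx, rz, params.spine_sigma, params.spine_sigma, params.sigma_z, params.baseline_volume
        )
    spine_blobs = [
        _gaussian_blob(
            (ny, nx, nz), sy_, sx_, sz_, params.spine_sigma, params.spine_sigma, params.sigma_z, params.baseline_volume
        )
        for (sy_, sx_, sz_) in spine_centers
    ]

    stacks = []
    for t in t_idx:
        scene = ridge + ref_scene
        for s, blob in enumerate(spine_blobs):
            scene = scene + blob * volumes[s, t]
        frame = bleach[t] * scene + params.background_level
        frame = np.roll(frame, tuple(jitters[t]), axis=(0, 1))
        if params.shot_noise:
            frame = rng.poisson(frame).astype(float)
        stacks.append(frame)

    series = StackSeries(stacks, timestamps_min=t_idx * params.timepoint_min)
    rois = [RoiSpec((float(c[0]), float(c[1])), role="spine") for c in spine_centers]
    rois += [RoiSpec((float(c[0]), float(c[1])), role="reference") for c in ref_centers]
    # background ROIs in structure-free locations along the bottom edge
    for by, bx in bg_centers:
        rois.append(RoiSpec((by, bx), role="background"))
    truth = GroundTruth(
        "spine_stack_series",
        {
            "volumes": volumes,
            "spine_centers": spine_centers,
            "reference_centers": ref_centers,
            "jitters": jitters,
            "bleach": bleach,
            "rois": rois,
            "params": params,
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# metabolic labeling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelingSimParams:
    """Conditions for a synthetic 35S-Met/Cys labeling experiment.

    ``group_effects`` maps group label to a multiplicative effect on the
    true incorporation rate (e.g. ``{"WT": 1.0, "KO": 1.15}``); ``cv`` is
    the lognormal coefficient of variation across slices.
    """

    group_effects: Mapping[str, float] = field(default_factory=lambda: {"WT": 1.0, "KO": 1.15})
    n_per_group: int = 12
    cv: float = 0.1
    base_rate_cpm_per_mg: float = 20000.0
    protein_mg: float = 0.5
    protein_cv: float = 0.15
    triplicate_cv: float = 0.01
    dose_cpm: float = 1.0e6
    batch_id: str = "batch1"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, e in self.group_effects.items():
            if e <= 0:
                raise ValueError(f"group effect for {g!r} must be positive")


def gen_labeling_experiment(params: LabelingSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Triplicate CPM draws per slice with a multiplicative group effect."""
    rng = np.random.default_rng(params.seed)
    sigma = np.sqrt(np.log(1.0 + params.cv**2))
    rows = []
    for group, effect in params.group_effects.items():
        for i in range(params.n_per_group):
            noise = rng.lognormal(-sigma**2 / 2, sigma) if params.cv > 0 else 1.0
            rate = params.base_rate_cpm_per_mg * effect * noise
            protein = (
                params.protein_mg * rng.lognormal(0.0, np.sqrt(np.log(1 + params.protein_cv**2)))
                if params.protein_cv > 0
                else params.protein_mg
            )
            cpm_mean = rate * protein
            trip = (
                cpm_mean * (1.0 + params.triplicate_cv * rng.standard_normal(3))
                if params.triplicate_cv > 0
                else np.full(3, cpm_mean)
            )
            rows.append(
                {
                    "sample_id": f"{group}_{i:02d}",
                    "group": group,
                    "batch_id": params.batch_id,
                    "cpm1": trip[0],
                    "cpm2": trip[1],
                    "cpm3": trip[2],
                    "protein_mg": protein,
                    "dose_cpm": params.dose_cpm,
                }
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth("labeling_experiment", {"effects": dict(params.group_effects), "params": params})
    return table, truth


# ---------------------------------------------------------------------------
# audiogenic seizure cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgsSimParams:
    """Per-(genotype, treatment) seizure probability and cohort size."""

    groups: tuple[tuple[str, str, float, int], ...] = (
        ("WT", "saline", 0.13, 15),
        ("KO", "saline", 0.82, 11),
        ("WT", "glyx13", 0.13, 15),
        ("KO", "glyx13", 0.31, 16),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, tr, p, n in self.groups:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"seizure probability for {(g, tr)} outside [0, 1]")
            if n < 1:
                raise ValueError("cohort size must be >= 1")


def gen_ags_cohort(params: AgsSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """One Bernoulli seizure outcome row per animal."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for genotype, treatment, p, n in params.groups:
        outcomes = rng.random(n) < p
        for i, seized in enumerate(outcomes):
            rows.append(
                {
                    "animal_id": f"{genotype}_{treatment}_{i:02d}",
                    "genotype": genotype,
                    "treatment": treatment,
                    "seized": bool(seized),
                }
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        "ags_cohort",
        {"probabilities": {f"{g}:{t}": p for g, t, p, _ in params.groups}, "params": params},
    )
    return table, truth


__all__ = [
    "GroundTruth",
    "EphysSimParams",
    "FepspSimParams",
    "SpineSimParams",
    "LabelingSimParams",
    "AgsSimParams",
    "spike_template",
    "plan_burst_intervals",
    "fepsp_waveform",
    "gen_extracellular_trace",
    "gen_fepsp_session",
    "gen_spine_stack_series",
    "gen_labeling_experiment",
    "gen_ags_cohort",
]
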