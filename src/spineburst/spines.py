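"""Relative spine-volume quantification from two-photon z-series.

The measurement chain follows the standard time-lapse ROI workflow:
project each z-series (maximum-intensity by default), register the
projections to the first timepoint by integer-pixel translation, integrate
fluorescence in 20x20-pixel ROIs, subtract background estimated at three
structure-free locations, divide out global fluorescence fluctuations
(laser power, bleaching) estimated at four stable reference locations, and
normalize each spine to its own baseline mean. Sessions whose baseline
drifts by more than 7% (linear fit over the 30-min baseline) are excluded.

Integrated, corrected ROI intensity is taken as proportional to spine
volume; all outputs are expressed as percent of the baseline mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.registration import phase_cross_correlation


@dataclass(frozen=True)
class StackSeries:
    """Ordered z-series, one 3-D array (y, x, z) per timepoint."""

    stacks: Sequence[np.ndarray]
    timestamps_min: np.ndarray
    pixel_um: float = 0.1
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        stacks = [np.asarray(s, dtype=float) for s in self.stacks]
        if not stacks:
            raise ValueError("stack series is empty")
        shape = stacks[0].shape
        if any(s.shape != shape for s in stacks):
            raise ValueError("all timepoints must share one frame shape")
        ts = np.asarray(self.timestamps_min, dtype=float)
        if ts.size != len(stacks):
            raise ValueError("one timestamp per stack required")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly ascending")
        object.__setattr__(self, "stacks", stacks)
        object.__setattr__(self, "timestamps_min", ts)

    def __len__(self) -> int:
        return len(self.stacks)


@dataclass(frozen=True)
class RoiSpec:
    """A square ROI given by its center (row, col) and role."""

    center: tuple[float, float]
    size: int = 20
    role: Literal["spine", "background", "reference"] = "spine"

    def bounds(self) -> tuple[int, int, int, int]:
        r0 = int(round(self.center[0] - self.size / 2))
        c0 = int(round(self.center[1] - self.size / 2))
        return r0, r0 + self.size, c0, c0 + self.size

    def validate(self, shape: tuple[int, int]) -> None:
        r0, r1, c0, c1 = self.bounds()
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError(f"ROI {self.center} ({self.size}x{self.size}) not fully inside frame {shape}")


@dataclass(frozen=True)
class SpineTrace:
    """Per-timepoint intensities for one spine ROI."""

    raw: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray  # percent of baseline mean
    valid: np.ndarray  # per-timepoint flag (False where the global factor degenerated)
    timestamps_min: np.ndarray


@dataclass(frozen=True)
class DriftQC:
    drift_percent: float
    passed: bool
    slope: float
    intercept: float
    n_baseline: int


def project_zseries(stack: np.ndarray, method: Literal["max", "sum"] = "max") -> np.ndarray:
    """Collapse a (y, x, z) series to 2-D, by maximum intensity (default) or sum."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a non-empty 3-D (y, x, z) stack")
    return stack.max(axis=2) if method == "max" else stack.sum(axis=2)


def _shift_int(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero padding outside the overlap."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = img[ys, xs]
    return out


def register_series(images: Sequence[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Align projections to the first image by integer-pixel translation.

    Returns the aligned images (zero-padded outside the overlap) and the
    estimated per-timepoint displacement of each image relative to the
    first, as integer (dy, dx); the inverse shift is applied to align.
    Displacements are estimated by phase cross-correlation.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if len(images) < 2:
        raise ValueError("registration needs at least two images")
    ref = images[0]
    shifts = np.zeros((len(images), 2), dtype=int)
    aligned = [images[0].copy()]
    for t, img in enumerate(images[1:], start=1):
        if not np.any(img):
            warnings.warn(f"timepoint {t}: all-zero image, assuming zero shift", RuntimeWarning, stacklevel=2)
            aligned.append(img.copy())
            continue
        est, _, _ = phase_cross_correlation(ref, img, upsample_factor=1, normalization=None)
        dy, dx = int(round(est[0])), int(round(est[1]))
        # est is the shift that maps img onto ref; displacement of img is its negation
        shifts[t] = (-dy, -dx)
        aligned.append(_shift_int(img, dy, dx))
    return aligned, shifts


def measure_roi_series(
    images: Sequence[np.ndarray],
    rois: Sequence[RoiSpec],
    timestamps_min: np.ndarray,
    baseline_minutes: float = 30.0,
) -> list[SpineTrace]:
    """Integrate, background-subtract, globally correct and normalize ROIs.

    Per timepoint t:

    * raw_s(t)      = sum of the 20x20 spine ROI;
    * b(t)          = mean per-pixel intensity over the three background ROIs;
    * corrected_s(t)= raw_s(t) - area * b(t);
    * g(t)          = mean over the four reference ROIs of their corrected
      intensity divided by its own baseline mean (so g == 1 throughout the
      baseline on average), and spine values are divided by g(t);
    * normalized_s(t) = corrected_s(t) / g(t) as percent of its baseline mean.

    Timepoints where g(t) <= 0 are flagged invalid. Exactly three background
    and four reference ROIs are required.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    timestamps_min = np.asarray(timestamps_min, dtype=float)
    shape = images[0].shape
    for roi in rois:
        roi.validate(shape)
    spines = [r for r in rois if r.role == "spine"]
    bgs = [r for r in rois if r.role == "background"]
    refs = [r for r in rois if r.role == "reference"]
    if len(bgs) != 3 or len(refs) != 4:
        raise ValueError(f"expected 3 background and 4 reference ROIs, got {len(bgs)} and {len(refs)}")
    if not spines:
        raise ValueError("no spine ROIs supplied")
    baseline = timestamps_min < baseline_minutes
    if not np.any(baseline):
        raise ValueError("no timepoints fall inside the baseline window")

    def roi_sums(roi: RoiSpec) -> np.ndarray:
        r0, r1, c0, c1 = roi.bounds()
        return np.array([im[r0:r1, c0:c1].sum() for im in images])

    area = float(rois[0].size ** 2)
    b = np.mean([roi_sums(r) / area for r in bgs], axis=0)  # per-pixel background
    ref_corr = np.stack([roi_sums(r) - area * b for r in refs])
    ref_base = ref_corr[:, baseline].mean(axis=1)
    if np.any(ref_base <= 0):
        raise ValueError("a reference ROI has non-positive baseline intensity")
    g = (ref_corr / ref_base[:, None]).mean(axis=0)
    valid = g > 0
    if not np.all(valid):
        warnings.warn("timepoints with non-positive global factor flagged invalid", RuntimeWarning, stacklevel=2)

    traces = []
    g_safe = np.where(valid, g, np.nan)
    for roi in spines:
        raw = roi_sums(roi)
        corrected = (raw - area * b) / g_safe
        base_mean = corrected[baseline & valid].mean()
        normalized = corrected / base_mean * 100.0
        traces.append(SpineTrace(raw, corrected, normalized, valid.copy(), timestamps_min.copy()))
    return traces


def drift_qc(trace: SpineTrace, baseline_minutes: float = 30.0, max_drift_percent: float = 7.0) -> DriftQC:
    """Baseline-stability check by linear regression over the baseline.

    Drift is the absolute difference of the fitted line between the first
    and last baseline timepoints, as a percentage of the mean fitted value;
    sessions with drift above ``max_drift_percent`` fail.
    """
    sel = (trace.timestamps_min < baseline_minutes) & trace.valid
    t = trace.timestamps_min[sel]
    y = trace.normalized[sel]
    if t.size < 3:
        warnings.warn("fewer than 3 baseline points: drift QC undefined, series flagged", RuntimeWarning, stacklevel=2)
        return DriftQC(float("nan"), False, float("nan"), float("nan"), int(t.size))
    slope, intercept = np.polyfit(t, y, 1)
    fit = slope * t + intercept
    drift = abs(fit[-1] - fit[0]) / fit.mean() * 100.0
    return DriftQC(float(drift), bool(drift <= max_drift_percent), float(slope), float(intercept), int(t.size))


def session_drift_qc(
    traces: Sequence[SpineTrace], baseline_minutes: float = 30.0, max_drift_percent: float = 7.0
) -> DriftQC:
    """Experiment-level drift QC on the mean normalized trace.

    The exclusion rule operates on whole imaging sessions: the normalized
    spine traces of one experiment are averaged per timepoint and the
    linear-fit drift of that mean trace decides whether the session is
    kept. Averaging across spines suppresses single-ROI shot noise, so the
    decision reflects genuine preparation drift.
    """
    if not traces:
        raise ValueError("no spine traces supplied")
    stamps = traces[0].timestamps_min
    valid = np.logical_and.reduce([tr.valid for tr in traces])
    mean_trace = SpineTrace(
        raw=np.mean([tr.raw for tr in traces], axis=0),
        corrected=np.mean([tr.corrected for tr in traces], axis=0),
        normalized=np.mean([tr.normalized for tr in traces], axis=0),
        valid=valid,
        timestamps_min=stamps,
    )
    return drift_qc(mean_trace, baseline_minutes, max_drift_percent)


def summarize_shrinkage(
    experiments: Sequence[Sequence[SpineTrace]],
    analysis_window_min: tuple[float, float],
) -> tuple[float, float, int, list[float]]:
    """Group-level percent-of-baseline volume in an analysis window.

    Per spine: mean normalized volume over the window; per experiment
    (slice/animal): mean across its spines; group value: mean +/- SEM
    across experiments, with N the number of experiments.

    Returns ``(mean, sem, n, per_experiment_means)``.
    """
    lo, hi = analysis_window_min
    per_exp = []
    for traces in experiments:
        vals = []
        for tr in traces:
            sel = (tr.timestamps_min >= lo) & (tr.timestamps_min <= hi) & tr.valid
            if not np.any(sel):
                raise ValueError(f"analysis window ({lo}, {hi}) min contains no timepoints")
            vals.append(tr.normalized[sel].mean())
        per_exp.append(float(np.mean(vals)))
    arr = np.asarray(per_exp)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sem, arr.size, per_exp


def spine_density(spine_count: int, dendrite_length_um: float, unit_length_um: float = 10.0) -> float:
    """Spines per ``unit_length_um`` of dendrite."""
    if dendrite_length_um <= 0:
        raise ValueError("dendrite length must be positive")
    return spine_count / dendrite_length_um * unit_length_um


def quantify_series(
    series: StackSeries,
    rois: Sequence[RoiSpec],
    baseline_minutes: float = 30.0,
    projection: Literal["max", "sum"] = "max",
) -> tuple[list[SpineTrace], np.ndarray, list[DriftQC]]:
    """Project, register, measure and QC one imaging session."""
    projections = [project_zseries(s, projection) for s in series.stacks]
    aligned, shifts = register_series(projections)
    traces = measure_roi_series(aligned, rois, series.timestamps_min, baseline_minutes)
    qc = [drift_qc(tr, baseline_minutes) for tr in traces]
    return traces, shifts, qc


__all__ = [
    "StackSeries",
    "RoiSpec",
    "SpineTrace",
    "DriftQC",
    "project_zseries",
    "register_series",
    "measure_roi_series",
    "drift_qc",
    "session_drift_qc",
    "summarize_shrinkage",
    "spine_density",
    "quantify_series",
]
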