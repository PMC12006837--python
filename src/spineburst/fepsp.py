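"""Field-potential quantification: initial slope, normalization, LTD.

Synaptic strength is indexed by the initial slope of the fEPSP: an
ordinary-least-squares fit of voltage against time over the samples lying
between 20% and 80% of peak negativity on the initial falling phase,
skipping a 1-ms stimulus-artifact blanking window. Slopes are expressed as
percent of the baseline-window mean; LTD magnitude is the mean normalized
slope over a post-induction window (50-60 min after induction against the
last 10 min of baseline, by default). Percent block of pharmacologically
isolated responses is computed from response means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SweepSeries:
    """Per-stimulus sweeps: one row per sweep, common time base in ms."""

    time_ms: np.ndarray
    sweeps: np.ndarray  # (n_sweeps, n_samples), mV
    stim_ms: float
    timestamps_min: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        v = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        ts = np.asarray(self.timestamps_min, dtype=float)
        if v.shape[1] != t.size:
            raise ValueError("sweeps and time base disagree in length")
        if ts.size != v.shape[0]:
            raise ValueError("one timestamp per sweep required")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("sweeps must be uniformly sampled")
        if not (t[0] <= self.stim_ms <= t[-1]):
            raise ValueError("stimulus time outside the sweep record")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "sweeps", v)
        object.__setattr__(self, "timestamps_min", ts)


@dataclass(frozen=True)
class SlopeConfig:
    """Fit-window conventions for the initial slope."""

    frac_lo: float = 0.2
    frac_hi: float = 0.8
    blank_ms: float = 1.0
    noise_floor_sd: float = 5.0  # minimum peak amplitude, in baseline SDs

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_lo < self.frac_hi <= 1.0:
            raise ValueError("require 0 <= frac_lo < frac_hi <= 1")


@dataclass(frozen=True)
class SlopeSeries:
    slopes: np.ndarray  # mV/ms, NaN where missing
    timestamps_min: np.ndarray
    normalized: np.ndarray  # percent of baseline mean
    baseline_window_min: tuple[float, float]


@dataclass(frozen=True)
class PlasticitySummary:
    magnitude_percent: float
    window_min: tuple[float, float]
    n_sweeps: int


def measure_slope(time_ms: np.ndarray, voltage_mv: np.ndarray, stim_ms: float, cfg: SlopeConfig = SlopeConfig()) -> float:
    """Initial slope (mV/ms) of one sweep; NaN if no deflection is found.

    The pre-stimulus segment defines the baseline level and noise floor.
    The peak of negativity is located after the blanking window; the fit
    runs over the contiguous samples of the falling phase whose amplitude
    lies between ``frac_lo`` and ``frac_hi`` of the peak.
    """
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(voltage_mv, dtype=float)
    pre = t < stim_ms
    if not np.any(pre):
        raise ValueError("no pre-stimulus samples to define the baseline")
    base = v[pre].mean()
    noise_sd = v[pre].std()
    rel = v - base
    search = t >= stim_ms + cfg.blank_ms
    if not np.any(search):
        return float("nan")
    seg = np.flatnonzero(search)
    peak_i = seg[np.argmin(rel[seg])]
    amp = rel[peak_i]
    if amp >= 0 or (noise_sd > 0 and -amp < cfg.noise_floor_sd * noise_sd):
        warnings.warn("no deflection beyond the noise floor; slope flagged missing", RuntimeWarning, stacklevel=2)
        return float("nan")
    lo, hi = cfg.frac_lo * amp, cfg.frac_hi * amp  # both negative
    # walk the falling phase backwards from the peak
    sel = []
    for i in range(peak_i, seg[0] - 1, -1):
        if rel[i] > lo:  # risen above the 20% level: past the start of the deflection
            break
        if rel[i] <= lo and rel[i] >= hi:
            sel.append(i)
    if len(sel) < 2:
        return float("nan")
    sel = np.array(sorted(sel))
    slope = np.polyfit(t[sel], v[sel], 1)[0]
    return float(slope)


def measure_slopes(series: SweepSeries, cfg: SlopeConfig = SlopeConfig()) -> np.ndarray:
    return np.array([measure_slope(series.time_ms, sw, series.stim_ms, cfg) for sw in series.sweeps])


def normalize_series(
    slopes: np.ndarray,
    timestamps_min: np.ndarray,
    baseline_window_min: tuple[float, float],
) -> SlopeSeries:
    """Express slopes as percent of the baseline-window mean."""
    slopes = np.asarray(slopes, dtype=float)
    timestamps_min = np.asarray(timestamps_min, dtype=float)
    lo, hi = baseline_window_min
    sel = (timestamps_min >= lo) & (timestamps_min < hi) & ~np.isnan(slopes)
    if not np.any(sel):
        raise ValueError("baseline window contains no measurable sweeps")
    base = slopes[sel].mean()
    if base == 0:
        raise ValueError("baseline mean slope is zero; cannot normalize")
    return SlopeSeries(slopes, timestamps_min, slopes / base * 100.0, (lo, hi))


def plasticity_magnitude(series: SlopeSeries, post_window_min: tuple[float, float]) -> PlasticitySummary:
    """Mean normalized slope over a post-induction window, % of baseline."""
    lo, hi = post_window_min
    sel = (series.timestamps_min >= lo) & (series.timestamps_min < hi) & ~np.isnan(series.normalized)
    if not np.any(sel):
        raise ValueError("post window contains no measurable sweeps")
    return PlasticitySummary(float(series.normalized[sel].mean()), (lo, hi), int(sel.sum()))


def percent_block(control_mean: float, drug_mean: float) -> float:
    """Percent of the isolated response eliminated by a drug."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return (1.0 - drug_mean / control_mean) * 100.0


__all__ = [
    "SweepSeries",
    "SlopeConfig",
    "SlopeSeries",
    "PlasticitySummary",
    "measure_slope",
    "measure_slopes",
    "normalize_series",
    "plasticity_magnitude",
    "percent_block",
]
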