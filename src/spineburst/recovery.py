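"""Ground-truth matching and recovery metrics for synthetic experiments."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bursts import BurstEvent


@dataclass(frozen=True)
class BurstRecovery:
    """Event-level agreement between detected and true bursts."""

    n_true: int
    n_detected: int
    n_matched: int
    n_false: int
    duration_errors: np.ndarray  # detected - true, matched events only
    class_correct: int  # among matched events with |true - 1.5| > class_margin
    class_checked: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_detected if self.n_detected else 0.0

    @property
    def duration_mae(self) -> float:
        return float(np.abs(self.duration_errors).mean()) if self.duration_errors.size else float("nan")


def match_bursts(
    true_intervals: Sequence[tuple[float, float]],
    events: Sequence[BurstEvent],
    class_threshold: float = 1.5,
    class_margin: float = 0.3,
) -> BurstRecovery:
    """Greedy overlap matching of detected events to true burst intervals.

    Each true interval is matched to the detected event with which it
    shares the most overlap (if any); detected events matched by no true
    interval are false positives. Duration errors and short/long agreement
    are evaluated on matched pairs; classification is only scored for true
    durations further than ``class_margin`` from the class threshold.
    """
    matched: dict[int, int] = {}
    for ti, (a, b) in enumerate(true_intervals):
        best, best_ov = None, 0.0
        for ei, ev in enumerate(events):
            ov = min(b, ev.offset) - max(a, ev.onset)
            if ov > best_ov:
                best_ov, best = ov, ei
        if best is not None:
            matched[ti] = best
    errors, cls_ok, cls_tot = [], 0, 0
    for ti, ei in matched.items():
        a, b = true_intervals[ti]
        ev = events[ei]
        errors.append(ev.duration - (b - a))
        if abs((b - a) - class_threshold) > class_margin:
            cls_tot += 1
            cls_ok += int((ev.duration >= class_threshold) == ((b - a) >= class_threshold))
    n_false = len(events) - len(set(matched.values()))
    return BurstRecovery(
        len(true_intervals), len(events), len(matched), n_false, np.asarray(errors), cls_ok, cls_tot
    )


def pool_recoveries(parts: Sequence[BurstRecovery]) -> BurstRecovery:
    """Combine per-trace recoveries into one overall record."""
    return BurstRecovery(
        sum(p.n_true for p in parts),
        sum(p.n_detected for p in parts),
        sum(p.n_matched for p in parts),
        sum(p.n_false for p in parts),
        np.concatenate([p.duration_errors for p in parts]) if parts else np.empty(0),
        sum(p.class_correct for p in parts),
        sum(p.class_checked for p in parts),
    )


__all__ = ["BurstRecovery", "match_bursts", "pool_recoveries"]
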