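"""Independent oracles, deliberately written on different code paths from
the implementations they check."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_bursts(counts, t_start=0.0, bin_width=0.1, window_bins=5, on=8.0, off=4.0):
    """Enumerate every window position with explicit Python sums and walk
    the hysteresis state machine; returns (onset, offset) pairs."""
    counts = list(counts)
    n_windows = len(counts) - window_bins + 1
    if n_windows <= 0:
        return []
    window_len = window_bins * bin_width
    rates = []
    for i in range(n_windows):
        s = 0
        for k in range(window_bins):
            s += counts[i + k]
        rates.append(s / window_len)
    events = []
    i = 0
    while i < n_windows:
        if rates[i] > on:
            j = i
            while j + 1 < n_windows and rates[j + 1] >= off:
                j += 1
            events.append((t_start + i * bin_width, t_start + j * bin_width + window_len))
            i = j + window_bins
        else:
            i += 1
    return events


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct rational-arithmetic enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return 1.0
    denom = comb(n, c1)
    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(x)
        if p <= p_obs:
            total += p
    return float(total)


def ols_line(x, y):
    """Closed-form least-squares line (slope, intercept) via the textbook
    covariance formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope, ym - slope * xm


def pooled_t(a, b):
    """Classical pooled-variance two-sample t statistic and df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2
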