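"""Group statistics: outlier rule, summaries, t-tests, one-way ANOVA with
Bonferroni post hoc comparisons, and an exact two-sided Fisher test.

The Fisher test uses the point-probability rule: the two-sided p-value is
the sum of hypergeometric probabilities, over all tables with the observed
margins, that do not exceed the probability of the observed table (ties
included). Probabilities are evaluated with log-factorials, so large
margins are handled without overflow; the test suite checks the result
against an exact rational-arithmetic enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (rows = groups, columns = outcome yes/no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @classmethod
    def from_incidence(cls, seized1: int, n1: int, seized2: int, n2: int) -> "ContingencyTable2x2":
        return cls(seized1, n1 - seized1, seized2, n2 - seized2)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float | None
    p_two_sided: float
    summaries: tuple = ()
    pairwise: dict = field(default_factory=dict)


def mean_sem(values) -> tuple[float, float, int]:
    """Mean, SEM (sample SD / sqrt(n); NaN for n = 1) and n."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.size == 1:
        warnings.warn("SEM undefined for a single observation", RuntimeWarning, stacklevel=2)
        return float(x[0]), float("nan"), 1
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size)


def remove_outliers(values, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass +/- k*SD rule on the full input; order preserved.

    Returns (retained values, removed indices). Values exactly at
    mean +/- k*SD are retained (strict inequality removes). With fewer
    than 3 values the rule is skipped.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("outlier rule needs n >= 3; returning input unchanged", RuntimeWarning, stacklevel=2)
        return x.copy(), np.empty(0, dtype=int)
    sd = x.std(ddof=1)
    removed = np.flatnonzero(np.abs(x - x.mean()) > k * sd)
    return np.delete(x, removed), removed


def t_test(a, b, paired: bool = False) -> TestResult:
    """Student's t: pooled-variance two-sample (unpaired) or paired."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        d = a - b
        if np.all(d == d[0]) and d[0] == 0:
            return TestResult("paired t", 0.0, float(a.size - 1), 1.0, _summaries(a, b))
        r = sps.ttest_rel(a, b)
        df = float(a.size - 1)
        return TestResult("paired t", float(r.statistic), df, float(r.pvalue), _summaries(a, b))
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult("unpaired t", 0.0, float(a.size + b.size - 2), 1.0, _summaries(a, b))
    r = sps.ttest_ind(a, b, equal_var=True)
    df = float(a.size + b.size - 2)
    return TestResult("unpaired t", float(r.statistic), df, float(r.pvalue), _summaries(a, b))


def _summaries(*groups) -> tuple:
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        sem = float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan")
        out.append((float(g.mean()), sem, int(g.size)))
    return tuple(out)


def anova_oneway(groups, labels=None) -> TestResult:
    """One-way ANOVA with Bonferroni-corrected pairwise (pooled t) p-values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    labels = labels or [f"group{i}" for i in range(len(groups))]
    if all(np.ptp(g) == 0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        r = sps.f_oneway(*groups)
        f_stat, p = float(r.statistic), float(r.pvalue)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    m = k * (k - 1) // 2
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            raw = t_test(groups[i], groups[j]).p_two_sided
            pairwise[(labels[i], labels[j])] = min(raw * m, 1.0)
    return TestResult(
        "one-way ANOVA",
        f_stat,
        float(k - 1),  # numerator df; denominator is n_total - k
        p,
        _summaries(*groups),
        pairwise,
    )


def _log_hypergeom_pmf(x: int, r1: int, r2: int, c1: int) -> float:
    n = r1 + r2

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(r1, x) + lchoose(r2, c1 - x) - lchoose(n, c1)


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by point-probability enumeration.

    Degenerate tables (an all-zero row or column) return p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return TestResult("fisher exact", float("nan"), None, 1.0)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    logp = np.array([_log_hypergeom_pmf(int(x), r1, r2, c1) for x in xs])
    logp_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    # include ties up to the same relative tolerance scipy uses
    keep = logp <= logp_obs + np.log1p(1e-7)
    p = float(np.exp(logp[keep]).sum())
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult("fisher exact", odds, None, min(p, 1.0))


__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "mean_sem",
    "remove_outliers",
    "t_test",
    "anova_oneway",
    "fisher_exact",
]
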