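"""Reproducibility statistics for registration and targeting experiments.

Implements the analysis applied to repeated registration/targeting trials:
two-tailed unpaired Student t-tests for day-to-day differences in directional
targeting error, two-tailed variance-ratio F-tests comparing multi-user
against single-user variability (after subtracting each day's mean to remove
day bias), the Benjamini-Hochberg step-up procedure for the correlated robot
pose tests, and pooled mean ± SD summaries across experiment days.

Degrees-of-freedom convention for the F-tests: ``N - 1`` per experiment, where
N counts all observations across days, even though day centering removes one
mean per day. This yields F(15, 11) for the reference design of 16 single-user
and 12 multi-user trials; the df inflation from centering is deliberate, not
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

__all__ = [
    "GroupSummary",
    "TestResult",
    "unpaired_t_test",
    "centered_variance_f_test",
    "benjamini_hochberg",
    "pooled_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group (e.g. one experiment day)."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise UndefinedStatisticError("group summaries need n >= 2")
        if self.sd < 0:
            raise UndefinedStatisticError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    ci95: tuple[float, float] | None = None


def _as_summary(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise UndefinedStatisticError("samples need n >= 2")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def unpaired_t_test(a, b) -> TestResult:
    """Two-tailed pooled-variance (Student) two-sample t-test.

    Accepts raw samples or :class:`GroupSummary` objects. Returns the t
    statistic, ``df = n1 + n2 - 2``, the two-tailed p-value and the 95%
    confidence interval of the mean difference ``a - b``.
    """
    ga, gb = _as_summary(a), _as_summary(b)
    df = ga.n + gb.n - 2
    pooled_var = ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / df
    diff = ga.mean - gb.mean
    if pooled_var == 0.0:
        if diff == 0.0:
            return TestResult(statistic=0.0, df=(float(df),), p_value=1.0, ci95=(0.0, 0.0))
        t = float(np.inf) if diff > 0 else float(-np.inf)
        return TestResult(statistic=t, df=(float(df),), p_value=0.0, ci95=(diff, diff))
    se = np.sqrt(pooled_var * (1.0 / ga.n + 1.0 / gb.n))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * se
    return TestResult(
        statistic=float(t),
        df=(float(df),),
        p_value=float(p),
        ci95=(float(diff - half), float(diff + half)),
    )


def _center_by_day(groups) -> np.ndarray:
    """Subtract each day's mean from its members; returns pooled residuals."""
    if isinstance(groups, Mapping):
        days: Iterable = groups.values()
    elif isinstance(groups, np.ndarray) and groups.ndim == 1:
        days = [groups]
    elif len(groups) > 0 and np.isscalar(groups[0]):
        days = [np.asarray(groups, dtype=float)]
    else:
        days = groups
    centered = []
    for day in days:
        arr = np.asarray(day, dtype=float)
        if arr.size < 2:
            raise UndefinedStatisticError("each day needs n >= 2")
        centered.append(arr - arr.mean())
    return np.concatenate(centered)


def centered_variance_f_test(multi, single) -> TestResult:
    """Two-tailed F-test of single- vs multi-user variance after day centering.

    ``multi`` and ``single`` are collections of per-day samples (a mapping
    day -> values, a list of arrays, or a single flat array treated as one
    day). Each day's mean is removed before pooling. The statistic is
    ``F = var(single, centered) / var(multi, centered)`` with degrees of
    freedom ``(N_single - 1, N_multi - 1)`` and two-tailed p-value
    ``2 * min(P(F <= f), P(F >= f))``.
    """
    multi_c = _center_by_day(multi)
    single_c = _center_by_day(single)
    var_multi = float(np.var(multi_c, ddof=1))
    var_single = float(np.var(single_c, ddof=1))
    if var_multi == 0.0:
        raise UndefinedStatisticError("multi-user variance is zero; F undefined")
    f = var_single / var_multi
    dfn, dfd = single_c.size - 1, multi_c.size - 1
    p = 2.0 * min(sps.f.cdf(f, dfn, dfd), sps.f.sf(f, dfn, dfd))
    return TestResult(statistic=float(f), df=(float(dfn), float(dfd)), p_value=float(min(p, 1.0)))


def benjamini_hochberg(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Sorts the p-values ascending and rejects all hypotheses up to the largest
    rank i with ``p_(i) <= i * alpha / m``. Returns rejection flags in the
    input order and the adjusted threshold ``i* * alpha / m`` (0.0 if nothing
    is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise UndefinedStatisticError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) * alpha) / m
    passing = np.flatnonzero(ranked <= crit)
    reject = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return reject, 0.0
    k = passing[-1]  # largest rank satisfying the step-up condition
    reject[order[: k + 1]] = True
    return reject, float(crit[k])


def pooled_summary(groups: Sequence[GroupSummary], label: str = "pooled") -> GroupSummary:
    """Combine per-day summaries into one mean ± SD.

    The pooled mean is the n-weighted mean of group means (equal to the flat
    mean of all underlying observations); the pooled SD combines within- and
    between-group variation with an N-1 denominator, exactly reconstructing
    the SD of the concatenated observations.
    """
    if not groups:
        raise UndefinedStatisticError("pooled_summary needs at least one group")
    n_total = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n_total
    ss = sum((g.n - 1) * g.sd**2 + g.n * (g.mean - mean) ** 2 for g in groups)
    sd = float(np.sqrt(ss / (n_total - 1)))
    return GroupSummary(n=n_total, mean=float(mean), sd=sd, label=label)
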