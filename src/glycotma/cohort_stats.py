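"""Nonparametric outcome statistics for the marker cohort.

Implements the study's comparisons: Wilcoxon signed-rank tests of paired
tumor-vs-adjacent elevation with Benjamini-Hochberg FDR across the five
markers, Wilcoxon rank-sum comparisons between short- and long-TTP groups,
2-year TTP dichotomization, median splits, Kaplan-Meier estimation and the
Mantel-Cox log-rank test.

Small-sample conventions (logged for reproducibility): signed-rank zero
differences are discarded (classic Wilcoxon) with the discarded count
reported; exact p-values are used whenever SciPy can compute them (no
ties/zeros, moderate n), falling back to the tie-corrected normal
approximation; rank-sum p-values are exact for min(n) <= 10 without ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "MARKERS",
    "paired_elevation_tests",
    "bh_fdr",
    "rank_sum_test",
    "signed_rank_test",
    "dichotomize_ttp",
    "median_split",
    "km_estimate",
    "logrank_test",
    "TTP_CUTOFF_MONTHS",
]

MARKERS = ("ca199", "stra", "ca199_only", "stra_only", "dual")

#: 2-year TTP dichotomy
TTP_CUTOFF_MONTHS = 24.0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_used: int
    q_value: float | None = None
    flag: str | None = None

    def with_q(self, q: float) -> "TestResult":
        return TestResult(self.statistic, self.p_value, self.n_used, q_value=q, flag=self.flag)


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; if every difference is zero the test is
    degenerate and reported as p = 1 with a flag.  Exact when SciPy's exact
    path applies (no ties among nonzero |differences|), otherwise the
    tie-corrected normal approximation.
    """

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, n_used=0, flag="all differences zero")
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), n_used=int(nonzero.size))


def paired_elevation_tests(
    paired: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    min_pairs: int = 6,
) -> pd.DataFrame:
    """Signed-rank elevation test per marker, BH-adjusted across the markers.

    ``paired`` maps marker name -> (tumor values, adjacent values); pairs
    with a missing member are dropped.  Returns a tidy frame with columns
    marker, statistic, p, q, n.
    """

    rows = []
    for marker, (tumor, adjacent) in paired.items():
        t = np.asarray(tumor, dtype=float)
        a = np.asarray(adjacent, dtype=float)
        keep = ~(np.isnan(t) | np.isnan(a))
        t, a = t[keep], a[keep]
        if t.size < min_pairs:
            raise ValueError(f"marker {marker!r}: fewer than {min_pairs} complete pairs")
        res = signed_rank_test(t, a)
        rows.append({"marker": marker, "statistic": res.statistic, "p": res.p_value,
                     "n": res.n_used, "flag": res.flag})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["marker", "statistic", "p", "q", "n", "flag"]]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when the smaller group has <= 10 observations and there are no
    ties across the pooled sample; otherwise the tie-corrected normal
    approximation with continuity correction.
    """

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), n_used=int(pooled.size))


def dichotomize_ttp(
    times: Sequence[float],
    events: Sequence[int],
    cutoff_months: float = TTP_CUTOFF_MONTHS,
) -> np.ndarray:
    """Label patients short / long / indeterminate at the TTP cutoff.

    Progression before the cutoff -> ``short``; follow-up reaching the
    cutoff (with or without an event) -> ``long``; censoring before the
    cutoff -> ``indeterminate`` (excluded from classification analyses).
    A time exactly at the cutoff is ``long`` (short is strictly < cutoff).
    """

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    return np.where(t >= cutoff_months, "long", np.where(e == 1, "short", "indeterminate"))


def median_split(values: Sequence[float]) -> np.ndarray:
    """Label values ``low`` (< median) or ``high`` (>= median)."""

    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to split")
    med = np.median(v)
    return np.where(v < med, "low", "high")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a step table.

    Returns one row per distinct observed time with columns ``time``,
    ``n_at_risk``, ``n_events``, ``n_censored`` and ``survival`` (the value
    of the right-continuous estimator at that time).  The curve starts at 1.
    """

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "n_at_risk": table["at_risk"].to_numpy(dtype=int),
            "n_events": table["observed"].to_numpy(dtype=int),
            "n_censored": table["censored"].to_numpy(dtype=int),
        }
    )
    out["survival"] = [float(kmf.predict(tt)) for tt in out["time"]]
    return out


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> TestResult:
    """Two-group Mantel-Cox log-rank test (1 df, two-sided).

    With no events in either group the test is undefined and reported as
    p = 1 with a flag.
    """

    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must have at least one record")
    n_events = int(ea.sum() + eb.sum())
    if n_events == 0:
        return TestResult(statistic=0.0, p_value=1.0, n_used=int(ta.size + tb.size),
                          flag="no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    p = float(res.p_value)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return TestResult(statistic=0.0, p_value=1.0, n_used=int(ta.size + tb.size),
                          flag="degenerate log-rank")
    return TestResult(statistic=stat, p_value=p, n_used=int(ta.size + tb.size))
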