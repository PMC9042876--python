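"""Survival-statistics kernel: Kaplan-Meier curves, the two-group log-rank
test, Benjamini-Hochberg FDR adjustment, and a restricted-mean comparator
used to decide which expression class survives better.

Kaplan-Meier estimation and restricted-mean survival areas are delegated to
``lifelines``; the log-rank test is computed directly so that the observed
and expected event decomposition for group A is available on the result
object (the screening stages report it), and is cross-checked against
``lifelines`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalSample",
    "LogrankResult",
    "KaplanMeierCurve",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "better_survival_class",
]


@dataclass(frozen=True)
class SurvivalSample:
    """One subject's follow-up: time in days, event=1 for death, 0 censored."""

    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"survival time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class LogrankResult:
    """Unweighted two-group log-rank outcome (chi-square, 1 df).

    ``degenerate`` marks tests with zero events or zero variance, which are
    reported with statistic 0 and p-value 1 rather than raising.
    """

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    observed_a: float
    expected_a: float
    degenerate: bool = False


def _times_events(samples: Iterable[SurvivalSample]) -> tuple[np.ndarray, np.ndarray]:
    pairs = [(s.time, s.event) for s in samples]
    if not pairs:
        return np.empty(0), np.empty(0, dtype=int)
    t, e = zip(*pairs)
    return np.asarray(t, dtype=float), np.asarray(e, dtype=int)


class KaplanMeierCurve:
    """Product-limit survival curve: right-continuous, nonincreasing step
    function with S(0)=1 that drops only at event times."""

    def __init__(self, times: np.ndarray, survival: np.ndarray, n_at_risk: np.ndarray):
        self.times = times  # drop locations, ascending, excludes 0
        self.survival = survival  # S just after each drop
        self.n_at_risk = n_at_risk

    def survival_at(self, t):
        """S(t); vectorised over t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx] if t.shape else float(vals[idx])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "n_at_risk": self.n_at_risk}
        )


def km_estimate(samples: Iterable[SurvivalSample]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimate for one group of subjects."""
    times, events = _times_events(samples)
    if times.size == 0:
        raise ValueError("km_estimate requires a nonempty sample set")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    # keep only rows where the curve actually drops (event times)
    surv = sf.iloc[:, 0].to_numpy()
    tgrid = sf.index.to_numpy(dtype=float)
    drops = np.concatenate([[False], np.diff(surv) < 0])
    ev_times = tgrid[drops]
    ev_surv = surv[drops]
    at_risk = np.array([(times >= t).sum() for t in ev_times], dtype=int)
    return KaplanMeierCurve(ev_times, ev_surv, at_risk)


def logrank_test(
    group_a: Iterable[SurvivalSample], group_b: Iterable[SurvivalSample]
) -> LogrankResult:
    """Standard (unweighted) log-rank test between two groups.

    At each distinct event time the observed-minus-expected event count for
    group A is accumulated under the conditional hypergeometric model;
    censored subjects at time t remain at risk for events at t.
    """
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    return _logrank_arrays(ta, ea, tb, eb)


def _logrank_arrays(ta, ea, tb, eb) -> LogrankResult:
    """Vectorised log-rank on raw (time, event) arrays."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    n_a, n_b = ta.size, tb.size
    if e.sum() == 0:
        return LogrankResult(0.0, 1.0, n_a, n_b, 0.0, 0.0, degenerate=True)

    ev_times = np.unique(t[e == 1])
    ta_sorted = np.sort(ta)
    t_sorted = np.sort(t)
    # at-risk counts just before each event time (>= t convention)
    r_tot = t.size - np.searchsorted(t_sorted, ev_times, side="left")
    r_a = n_a - np.searchsorted(ta_sorted, ev_times, side="left")
    # event counts at each event time
    d_tot = _counts_at(t[e == 1], ev_times)
    d_a = _counts_at(ta[ea == 1], ev_times)

    with np.errstate(divide="ignore", invalid="ignore"):
        exp_a = d_tot * r_a / r_tot
        var = np.where(
            r_tot > 1,
            d_tot * (r_a / r_tot) * (1 - r_a / r_tot) * (r_tot - d_tot) / np.maximum(r_tot - 1, 1),
            0.0,
        )
    observed = float(d_a.sum())
    expected = float(exp_a.sum())
    v = float(var.sum())
    if v <= 0:
        return LogrankResult(0.0, 1.0, n_a, n_b, observed, expected, degenerate=True)
    stat = (observed - expected) ** 2 / v
    p = float(_sps.chi2.sf(stat, 1))
    return LogrankResult(float(stat), max(p, np.finfo(float).tiny), n_a, n_b, observed, expected)


def _counts_at(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Number of entries of ``values`` equal to each grid point (grid sorted unique)."""
    counts = np.zeros(grid.size, dtype=float)
    pos = np.searchsorted(grid, values)
    ok = pos < grid.size
    pos = pos[ok]
    match = grid[pos] == values[ok]
    np.add.at(counts, pos[match], 1.0)
    return counts


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, returned in input order.

    q_(i) = min_{j>=i} p_(j) * n / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _km_arrays(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit drop points and survival values (fast path for the
    screening loops; agrees with :func:`km_estimate`)."""
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        return ev_times, np.empty(0)
    t_sorted = np.sort(times)
    at_risk = times.size - np.searchsorted(t_sorted, ev_times, side="left")
    deaths = _counts_at(times[events == 1], ev_times)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return ev_times, surv


def restricted_mean(times: np.ndarray, events: np.ndarray, tau: float) -> float:
    """Area under the Kaplan-Meier curve up to ``tau``."""
    ev_times, surv = _km_arrays(np.asarray(times, float), np.asarray(events, int))
    grid = np.concatenate([[0.0], ev_times, [tau]])
    vals = np.concatenate([[1.0], surv])  # S on [grid_i, grid_{i+1})
    grid = np.clip(grid, 0.0, tau)
    widths = np.diff(grid)
    return float(np.sum(vals[: widths.size] * widths))


def better_survival_class(
    low: Iterable[SurvivalSample], high: Iterable[SurvivalSample]
) -> str:
    """Which expression class survives better: 'high' or 'low'.

    Compares restricted-mean survival (area under each Kaplan-Meier curve)
    up to the shorter group's last observed time, so the comparison covers
    only the follow-up window common to both classes. Exact ties resolve to
    'low' for determinism.
    """
    tl, el = _times_events(low)
    th, eh = _times_events(high)
    if tl.size == 0 or th.size == 0:
        raise ValueError("both classes must be nonempty")
    return _better_class_arrays(tl, el, th, eh)


def _better_class_arrays(tl, el, th, eh) -> str:
    tau = min(tl.max(), th.max())
    if tau <= 0:
        return "low"
    return "high" if restricted_mean(th, eh, tau) > restricted_mean(tl, el, tau) else "low"
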