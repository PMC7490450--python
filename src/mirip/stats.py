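"""Cohort statistics implemented from first principles.

Pearson correlation (with its exact t-based two-sided p-value), the classic
equal-variance two-sample Student's t test, the Kaplan-Meier product-limit
estimator, and the two-group log-rank test. The statistics themselves are
computed from their defining formulas; only the t and chi-square tail
probabilities come from scipy.

Conventions: p-values are two-sided throughout; at tied times, events are
processed before censorings (the standard convention); no multiple-testing
correction is applied anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _spstats

from .exceptions import DegenerateInputError, MissingDataError, SampleSizeError

__all__ = [
    "TestResult",
    "KmCurve",
    "pearson_test",
    "student_t_test",
    "km_estimate",
    "logrank_test",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``estimate`` carries the effect measure where one exists (Pearson r,
    difference of means); ``n`` is the per-group sample size(s).
    """

    statistic: float
    p_value: float
    df: float
    n: tuple[int, ...]
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class KmCurve:
    """Kaplan-Meier step curve: survival evaluated at the distinct event times."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        """Step-function value of S(t); 1 before the first event time."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DegenerateInputError(f"{name} contains non-finite values")
    return arr


def pearson_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the exact two-sided t-distribution p-value.

    r is the sample correlation; the statistic is
    ``t = r * sqrt((n - 2) / (1 - r**2))`` on n - 2 degrees of freedom.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise SampleSizeError(f"Pearson test requires n >= 3, got n = {n}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateInputError("constant input vector: correlation undefined")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t_stat = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t_stat = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(_spstats.t.sf(abs(t_stat), df))
    return TestResult(statistic=t_stat, p_value=min(p, 1.0), df=float(df),
                      n=(n,), estimate=r)


def student_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Classic equal-variance two-sample Student's t test (two-sided).

    Pooled variance on n_a + n_b - 2 degrees of freedom. Welch's correction
    is deliberately not applied.
    """
    aa = _as_float_array(a, "a")
    ba = _as_float_array(b, "b")
    na, nb = aa.size, ba.size
    if na < 2 or nb < 2:
        raise SampleSizeError(
            f"each group needs n >= 2, got n_a = {na}, n_b = {nb}"
        )
    df = na + nb - 2
    va = float(np.var(aa, ddof=1))
    vb = float(np.var(ba, ddof=1))
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    if pooled <= 0.0:
        raise DegenerateInputError("zero pooled variance: t statistic undefined")
    diff = float(aa.mean() - ba.mean())
    se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t_stat = diff / se
    p = 2.0 * float(_spstats.t.sf(abs(t_stat), df))
    return TestResult(statistic=t_stat, p_value=min(p, 1.0), df=float(df),
                      n=(na, nb), estimate=diff)


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t_i with d_i events among r_i subjects at
    risk, survival multiplies by (1 - d_i / r_i). Censored subjects leave
    the risk set strictly after their censoring time, so an event tied with
    a censoring counts the censored subject as still at risk (events before
    censorings).
    """
    t = _as_float_array(times, "times")
    e = np.asarray(events, dtype=bool)
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise MissingDataError("empty survival data")
    if np.any(t <= 0):
        raise DegenerateInputError("survival times must be > 0")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    out_t: list[float] = []
    out_s: list[float] = []
    out_r: list[int] = []
    out_d: list[int] = []
    s = 1.0
    i, n = 0, t.size
    while i < n:
        ti = t[i]
        j = i
        d = 0
        while j < n and t[j] == ti:
            d += int(e[j])
            j += 1
        if d > 0:
            r = n - i  # everyone with time >= ti, censored ties included
            s *= 1.0 - d / r
            out_t.append(float(ti))
            out_s.append(s)
            out_r.append(r)
            out_d.append(d)
        i = j
    return KmCurve(
        times=tuple(out_t),
        survival=tuple(out_s),
        at_risk=tuple(out_r),
        n_events=tuple(out_d),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df, two-sided).

    At every distinct pooled event time the observed events in arm A are
    compared with their hypergeometric expectation given the margins of the
    per-time 2x2 table; the squared standardized sum is referred to the
    chi-square distribution with one degree of freedom.
    """
    ta = _as_float_array(times_a, "times_a")
    ea = np.asarray(events_a, dtype=bool)
    tb = _as_float_array(times_b, "times_b")
    eb = np.asarray(events_b, dtype=bool)
    if ta.size != ea.size or tb.size != eb.size:
        raise ValueError("times and events must have equal length per arm")
    if ta.size == 0 or tb.size == 0:
        raise MissingDataError("both arms must be nonempty")
    if not (ea.any() or eb.any()):
        raise DegenerateInputError("no events in either arm: log-rank undefined")

    event_times = np.unique(
        np.concatenate([ta[ea], tb[eb]])
    )
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        n1 = int(np.sum(ta >= ti))
        n2 = int(np.sum(tb >= ti))
        nj = n1 + n2
        d1 = int(np.sum((ta == ti) & ea))
        d2 = int(np.sum((tb == ti) & eb))
        dj = d1 + d2
        if nj == 0 or dj == 0:
            continue
        expected = dj * n1 / nj
        o_minus_e += d1 - expected
        if nj > 1:
            var += dj * (n1 / nj) * (n2 / nj) * (nj - dj) / (nj - 1)
    if var == 0.0:
        # all events concentrated where one arm is exhausted; no information
        return TestResult(statistic=0.0, p_value=1.0, df=1.0,
                          n=(int(ta.size), int(tb.size)), estimate=o_minus_e)
    chi2 = o_minus_e * o_minus_e / var
    p = float(_spstats.chi2.sf(chi2, 1))
    return TestResult(statistic=chi2, p_value=min(p, 1.0), df=1.0,
                      n=(int(ta.size), int(tb.size)), estimate=o_minus_e)
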