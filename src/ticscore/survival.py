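"""Kaplan-Meier estimation and the log-rank test.

Own vectorized implementations (the log-rank is called many times inside the
maximally selected cutpoint scan); cross-checked against lifelines in the
test suite.  Tie convention: at equal times, events precede censorings, i.e.
censored subjects at time t are still in the risk set for events at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "n_risk": self.at_risk, "n_events": self.n_events}
        )


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with d_i events among n_i at risk.  S(0) = 1 by the empty product.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if len(time) == 0:
        raise ValueError("need at least one record")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event == 1])
    n = len(time)
    surv = np.empty(len(ev_times))
    at_risk = np.empty(len(ev_times), dtype=int)
    d_cnt = np.empty(len(ev_times), dtype=int)
    s = 1.0
    for i, t in enumerate(ev_times):
        ni = int((time >= t).sum())  # censored at t still at risk (events first)
        di = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - di / ni
        surv[i], at_risk[i], d_cnt[i] = s, ni, di
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk, n_events=d_cnt)


@dataclass
class LogrankResult:
    chi2: float
    df: int
    pvalue: float


def logrank_test(time, event, groups) -> LogrankResult:
    """K-sample log-rank test.

    At each distinct event time, the observed events per group are compared
    with their hypergeometric expectation given the risk sets; the quadratic
    form over the first k-1 groups with the hypergeometric covariance gives a
    chi-square statistic with k-1 degrees of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise ValueError(f"empty group {lab!r}")
    if (event == 1).sum() == 0:
        raise ValueError("no events")

    gidx = np.searchsorted(labels, groups)
    ev_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int(((time == t) & (event == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(time == t) & (event == 1)], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            V += v
    u = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        chi2 = float(u @ np.linalg.solve(Vr, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(Vr) @ u)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, pvalue=p)


def km_by_group(time, event, groups) -> dict:
    """Convenience: one KM curve per group label."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    groups = np.asarray(groups)
    return {lab: km_estimate(time[groups == lab], event[groups == lab])
            for lab in np.unique(groups)}
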