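"""Kaplan-Meier estimation and the two-group log-rank test.

Both are implemented from the standard formulas (product-limit estimator and
the observed-minus-expected chi-square with hypergeometric variance) so the
prognostic comparison between ISC groups is fully transparent; established
survival libraries serve as independent oracles in the test suite. Ties between
events and censorings at the same time are resolved events-first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns a frame with one row per distinct event time: ``time``,
    ``n_at_risk``, ``n_events``, ``n_censored`` (censorings in (previous time,
    time]) and ``survival`` = the right-continuous estimate just after ``time``.
    S(0) = 1; subjects censored at an event time are still at risk for it.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if (t < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    rows = []
    surv = 1.0
    for et in event_times:
        n_at_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        c = int(((t == et) & ~e).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append((float(et), n_at_risk, d, c, surv))
    if not rows:  # no events: flat curve at 1
        rows.append((float(t.max()), int(t.size), 0, int(t.size), 1.0))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "n_censored", "survival"])


def km_survival_at(curve: pd.DataFrame, time: float) -> float:
    """Evaluate a :func:`km_estimate` curve at ``time`` (right-continuous)."""
    past = curve[curve["time"] <= time]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared to
    the expectation under the null of a common hazard; the statistic
    ``(O - E)^2 / V`` is chi-square with 1 df. Symmetric in group order.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    if not e.any():
        raise ValueError("no events observed")
    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & grp_a).sum())
        d = int(((t == et) & e).sum())
        d_a = int(((t == et) & e & grp_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p
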