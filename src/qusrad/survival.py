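"""Kaplan-Meier product-limit estimation and log-rank comparison.

Survival times are months from the treatment-start baseline.  The KM
estimator is S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event
times, with Greenwood's formula for the variance; censored records leave
the risk set after their censoring time (events precede censorings at tied
times, the standard convention).  The two-group log-rank test compares
observed and hypergeometric-expected events over the pooled event times
(chi-square, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "survival_at",
    "logrank",
    "stratify_by_prediction",
]


@dataclass
class KMCurve:
    """Product-limit curve: steps at distinct event times.

    ``variance`` is Greenwood's estimate of Var[S(t)] at each step.
    """

    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "variance": self.variance,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p outside [0, 1]")


def _clean(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need >= 1 record")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``events`` is 1 for an observed event, 0 for right-censoring.  With no
    events the curve is identically 1 (no steps).
    """
    t, e = _clean(times, events)
    ev_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= u).sum() for u in ev_times], dtype=float)
    d = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=float)
    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf))
        var = np.where(np.isfinite(gw), surv**2 * np.minimum(gw, 1e300), 0.0)
    return KMCurve(
        event_times=ev_times,
        n_risk=n_risk.astype(int),
        n_events=d.astype(int),
        survival=surv,
        variance=var,
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t); S(0) = 1."""
    if t < 0:
        raise ValueError("t must be non-negative")
    k = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if k == 0 else float(curve.survival[k - 1])


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (1 df) over pooled distinct event times."""
    ta, ea = _clean(times_a, events_a)
    tb, eb = _clean(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        raise ValueError("no events in either group")
    O = np.zeros(2)
    E = np.zeros(2)
    V = 0.0
    for u in ev_times:
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (g == 1)).sum()
        O[1] += d1
        O[0] += d - d1
        E[1] += d * n1 / n
        E[0] += d * (n - n1) / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = float((O[1] - E[1]) ** 2 / V)
        p = float(sps.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi_square=chi2,
        p_value=p,
        observed=(float(O[0]), float(O[1])),
        expected=(float(E[0]), float(E[1])),
    )


def stratify_by_prediction(
    outcomes: pd.DataFrame,
    predictions: pd.Series,
    endpoint: str = "RFS",
) -> dict:
    """KM curves and log-rank test for predicted-R vs predicted-NR groups.

    ``outcomes`` must carry the cohort columns (patient_id, time/event per
    endpoint); ``predictions`` maps patient_id to a predicted label in
    {"R", "NR"} and must cover every patient.  Returns the two curves, the
    log-rank result, and the 5-year survival of each predicted group.
    """
    if endpoint not in ("RFS", "OS"):
        raise ValueError("endpoint must be 'RFS' or 'OS'")
    tcol = f"time_{endpoint.lower()}_months"
    ecol = f"event_{endpoint.lower()}"
    df = outcomes.set_index("patient_id") if "patient_id" in outcomes else outcomes
    missing = df.index.difference(predictions.index)
    if len(missing):
        raise ValueError(f"predictions missing for patients: {list(missing)[:5]}")
    pred = predictions.loc[df.index]
    grp_r = df[pred == "R"]
    grp_nr = df[pred == "NR"]
    if len(grp_r) == 0 or len(grp_nr) == 0:
        raise ValueError("one predicted group is empty")
    curve_r = km_estimate(grp_r[tcol], grp_r[ecol])
    curve_nr = km_estimate(grp_nr[tcol], grp_nr[ecol])
    lr = logrank(grp_r[tcol], grp_r[ecol], grp_nr[tcol], grp_nr[ecol])
    return {
        "endpoint": endpoint,
        "curve_predicted_R": curve_r,
        "curve_predicted_NR": curve_nr,
        "logrank": lr,
        "five_year": {
            "predicted_R": survival_at(curve_r, 60.0),
            "predicted_NR": survival_at(curve_nr, 60.0),
        },
    }
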