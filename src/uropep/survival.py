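"""Kaplan–Meier estimation, log-rank testing and O/E hazard ratios.

The product-limit estimator and the Mantel–Haenszel log-rank table are
implemented directly (the hazard-ratio estimator needs the observed and
expected event counts of the log-rank table, which packaged tests do not
expose); a Cox proportional-hazards fit is available as an independent
cross-check.  Administrative censoring at a fixed follow-up horizon
(default 500 days) is applied with :func:`apply_horizon`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalCurve:
    """Kaplan–Meier curve: event times, risk-set sizes, survival
    probabilities (step function evaluated just after each event time),
    and censoring times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "survival": self.survival,
            }
        )


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if (times < 0).any() or not np.all(np.isfinite(times)):
        raise ValueError("survival times must be finite and >= 0")
    return times


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) estimator.

    ``events[i]`` is True for an observed death at ``times[i]`` and False
    for right-censoring; censored subjects leave the risk set after their
    censoring time (same-time deaths are counted before censorings).
    """
    times = _check_times(times)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must align")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    uniq = np.unique(t_sorted[e_sorted]) if e_sorted.any() else np.array([])
    n = len(times)
    s = 1.0
    at_risk, surv = [], []
    for t in uniq:
        r = int((t_sorted >= t).sum())
        d = int(((t_sorted == t) & e_sorted).sum())
        s *= 1.0 - d / r
        at_risk.append(r)
        surv.append(s)
    return SurvivalCurve(
        event_times=uniq,
        at_risk=np.array(at_risk, dtype=int),
        survival=np.array(surv),
        censor_times=np.sort(t_sorted[~e_sorted]),
    )


def _logrank_table(
    times_a, events_a, times_b, events_b
) -> tuple[float, float, float, float, float]:
    """Pooled Mantel–Haenszel table: (O_A, E_A, O_B, E_B, V)."""
    ta, ea = _check_times(times_a), np.asarray(events_a, dtype=bool)
    tb, eb = _check_times(times_b), np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O_a = float(ea.sum())
    O_b = float(eb.sum())
    E_a = E_b = V = 0.0
    for t in all_event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & ea).sum())
        d_b = int(((tb == t) & eb).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n == 0:
            continue
        E_a += d * n_a / n
        E_b += d * n_b / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return O_a, E_a, O_b, E_b, V


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Mantel–Haenszel log-rank statistic over the pooled event times and
    its 1-df chi-square p-value.  With no events at all, returns (0, 1)
    with a warning."""
    O_a, E_a, O_b, E_b, V = _logrank_table(times_a, events_a, times_b, events_b)
    if O_a + O_b == 0 or V == 0:
        warnings.warn("no events (or no variance); log-rank test is uninformative")
        return 0.0, 1.0
    chi2 = (O_a - E_a) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class HazardResult:
    hazard_ratio: float
    ci_95: tuple[float, float]
    logrank_chi2: float
    logrank_p: float
    o_a: float
    e_a: float
    o_b: float
    e_b: float
    horizon_days: float = 500.0


def hazard_ratio(
    times_a, events_a, times_b, events_b, horizon_days: float = 500.0
) -> HazardResult:
    """O/E hazard ratio of group A relative to group B.

    HR = (O_A/E_A) / (O_B/E_B) from the log-rank table, with the classical
    CI exp(ln HR +/- 1.96 sqrt(1/E_A + 1/E_B)).  Requires at least one
    event per group.
    """
    O_a, E_a, O_b, E_b, V = _logrank_table(times_a, events_a, times_b, events_b)
    if O_a < 1 or O_b < 1:
        raise ValueError("need at least one event per group for the O/E estimator")
    if E_a == 0 or E_b == 0:
        raise ValueError("zero expected events; hazard ratio undefined")
    hr = (O_a / E_a) / (O_b / E_b)
    half = 1.96 * np.sqrt(1.0 / E_a + 1.0 / E_b)
    ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    if V > 0 and (O_a + O_b) > 0:
        chi2 = (O_a - E_a) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    return HazardResult(
        hazard_ratio=float(hr),
        ci_95=ci,
        logrank_chi2=float(chi2),
        logrank_p=p,
        o_a=O_a,
        e_a=E_a,
        o_b=O_b,
        e_b=E_b,
        horizon_days=horizon_days,
    )


def cox_hazard_ratio(times_a, events_a, times_b, events_b) -> tuple[float, tuple[float, float]]:
    """Single-covariate Cox PH cross-check: HR of group A vs B with 95% CI."""
    from lifelines import CoxPHFitter

    frame = pd.DataFrame(
        {
            "time": np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)]),
            "event": np.concatenate(
                [np.asarray(events_a, bool), np.asarray(events_b, bool)]
            ).astype(int),
            "group_a": np.concatenate(
                [np.ones(len(times_a)), np.zeros(len(times_b))]
            ),
        }
    )
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["group_a"]))
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.loc["group_a"].iloc[0]))
    hi = float(np.exp(ci.loc["group_a"].iloc[1]))
    return hr, (lo, hi)


def apply_horizon(
    times: Sequence[float], events: Sequence[bool], horizon_days: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring: no event strictly after the horizon counts."""
    t = _check_times(times)
    e = np.asarray(events, dtype=bool)
    capped = np.minimum(t, horizon_days)
    return capped, e & (t <= horizon_days)
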