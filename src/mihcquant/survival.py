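"""Kaplan–Meier estimation, log-rank comparison and single-covariate hazard
ratios for the three endpoints: OS (diagnosis → death/last follow-up), irOS
(start of immunotherapy → death/last follow-up) and irPFS (start of
immunotherapy → progression/last follow-up).

Estimation is delegated to lifelines: the product-limit estimator for the
curves, the Mantel–Cox log-rank test for two-group comparison, and a
proportional-hazards fit on the group indicator (Efron tie handling) for
the hazard ratio and its 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

ENDPOINTS = ("OS", "irOS", "irPFS")


@dataclass
class SurvivalSummary:
    endpoint: str
    group: str
    n: int
    n_events: int
    median_months: Optional[float]  # None ⇒ median not reached
    km_curve: list[tuple[float, float]]  # (time, S(t)) steps, starts at (0, 1)


@dataclass
class LogRankResult:
    statistic: float  # Mantel–Cox chi-square, 1 df
    p_value: float
    hazard_ratio: float
    ci95: tuple[float, float]


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    endpoint: str = "OS",
    group: str = "",
) -> SurvivalSummary:
    """Product-limit survival curve with median (first t where S(t) ≤ 0.5)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("no subjects")
    if t.shape != e.shape:
        raise ValueError("times and events differ in length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    med = kmf.median_survival_time_
    median: Optional[float] = None if math.isinf(med) else float(med)
    curve = [
        (float(ti), float(si))
        for ti, si in zip(kmf.survival_function_.index, kmf.survival_function_.iloc[:, 0])
    ]
    return SurvivalSummary(
        endpoint=endpoint,
        group=group,
        n=len(t),
        n_events=int(e.sum()),
        median_months=median,
        km_curve=curve,
    )


def logrank_compare(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogRankResult:
    """Mantel–Cox log-rank test plus hazard ratio of group A relative to B.

    The hazard ratio comes from a single-covariate proportional-hazards
    regression on the group indicator (1 = group A), with Efron handling of
    tied event times; its 95% CI is the Wald interval on the log scale.
    Identical groups return statistic 0, p = 1, HR = 1.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if int(ea.sum()) + int(eb.sum()) == 0:
        raise ValueError("no events")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    df = pd.DataFrame(
        {
            "time": np.concatenate([ta, tb]),
            "event": np.concatenate([ea, eb]).astype(int),
            "group_a": np.concatenate([np.ones(len(ta)), np.zeros(len(tb))]),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group_a"])
    se = float(cph.standard_errors_["group_a"])
    z = 1.959963984540054
    # np.exp: a degenerate fit (monotone likelihood on tiny groups) yields
    # inf rather than raising
    with np.errstate(over="ignore"):
        hr = float(np.exp(beta))
        ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        hazard_ratio=hr,
        ci95=ci,
    )


def derive_endpoints(patient) -> dict[str, tuple[float, bool]]:
    """Extract the (time, event) pairs available for one patient.

    Only endpoints whose time and event flag are both present are returned;
    immunotherapy endpoints are simply absent for patients without them.
    """
    out: dict[str, tuple[float, bool]] = {}
    for endpoint, prefix in (("OS", "os"), ("irOS", "iros"), ("irPFS", "irpfs")):
        t = getattr(patient, f"{prefix}_months")
        e = getattr(patient, f"{prefix}_event")
        if t is None or e is None:
            continue
        if t < 0:
            raise ValueError(f"patient {patient.patient_id!r}: negative {endpoint} time")
        out[endpoint] = (float(t), bool(e))
    return out


def survival_report(
    patients: Sequence,
    group_field: str = "cldn_status",
    groups: tuple[str, str] = ("positive", "negative"),
    endpoints: Sequence[str] = ENDPOINTS,
) -> pd.DataFrame:
    """Per-endpoint two-group survival comparison over a patient list.

    Returns one row per endpoint × group with n, events and median, plus the
    shared log-rank p, hazard ratio (first group vs second) and 95% CI.
    Endpoints with no events or an empty group are skipped.
    """
    rows = []
    for endpoint in endpoints:
        data: dict[str, tuple[list[float], list[bool]]] = {g: ([], []) for g in groups}
        for p in patients:
            g = getattr(p, group_field, None) or p.covariates.get(group_field)
            if g not in data:
                continue
            ep = derive_endpoints(p)
            if endpoint in ep:
                t, e = ep[endpoint]
                data[g][0].append(t)
                data[g][1].append(e)
        (ta, ea), (tb, eb) = data[groups[0]], data[groups[1]]
        if not ta or not tb or (sum(ea) + sum(eb)) == 0:
            continue
        lr = logrank_compare(ta, ea, tb, eb)
        for g, (tt, ee) in data.items():
            summ = km_estimate(tt, ee, endpoint=endpoint, group=g)
            rows.append(
                {
                    "endpoint": endpoint,
                    "group": g,
                    "n": summ.n,
                    "events": summ.n_events,
                    "median_months": (
                        "" if summ.median_months is None else summ.median_months
                    ),
                    "hr": lr.hazard_ratio,
                    "ci_lo": lr.ci95[0],
                    "ci_hi": lr.ci95[1],
                    "logrank_stat": lr.statistic,
                    "logrank_p": lr.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "endpoint",
            "group",
            "n",
            "events",
            "median_months",
            "hr",
            "ci_lo",
            "ci_hi",
            "logrank_stat",
            "logrank_p",
        ],
    )


def km_curve_table(
    patients: Sequence,
    group_field: str = "cldn_status",
    groups: tuple[str, str] = ("positive", "negative"),
    endpoints: Sequence[str] = ENDPOINTS,
) -> pd.DataFrame:
    """Step-curve coordinates per endpoint × group, for external plotting."""
    rows = []
    for endpoint in endpoints:
        for g in groups:
            times, events = [], []
            for p in patients:
                gv = getattr(p, group_field, None) or p.covariates.get(group_field)
                if gv != g:
                    continue
                ep = derive_endpoints(p)
                if endpoint in ep:
                    times.append(ep[endpoint][0])
                    events.append(ep[endpoint][1])
            if not times:
                continue
            summ = km_estimate(times, events, endpoint=endpoint, group=g)
            for t, s in summ.km_curve:
                rows.append(
                    {"endpoint": endpoint, "group": g, "time_months": t, "survival": s}
                )
    return pd.DataFrame(rows, columns=["endpoint", "group", "time_months", "survival"])
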