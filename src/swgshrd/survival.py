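"""Survival analysis by HRD class: Kaplan-Meier, log-rank, univariate Cox.

Kaplan-Meier estimation and the k-group log-rank test delegate to
lifelines.  "Mean survival" is reported as the KM **restricted mean** —
the area under the survival step function up to the largest observed time —
because an unrestricted mean is undefined whenever the curve does not reach
zero; with no censoring the restricted mean reduces to the arithmetic mean
of the event times.  The median is the earliest time at which S(t) drops to
0.5 or below, reported as not reached (inf) otherwise.

The univariate Cox proportional-hazards model is fitted here directly by
Newton-Raphson on the Breslow partial likelihood (ties enter the risk set
of their own event time); iteration stops when the score falls below 1e-8.
Monotone likelihoods (complete separation, e.g. one group entirely
outliving the other) are detected and refused rather than reported as a
huge hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "SeparationError",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "survival_report",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # days
    event: int  # 1 = progression/death observed, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event flag must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit survival estimate with its summary functionals."""

    times: np.ndarray          # distinct event times
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # subjects at risk at each event time
    restricted_mean: float     # area under S up to the largest observed time
    median: float              # inf when S never reaches 0.5
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


class SeparationError(RuntimeError):
    """Cox partial likelihood is monotone (complete separation)."""


def _as_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival times")
    return t, e


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier estimate of one group's survival function."""
    if not records:
        raise ValueError("km_estimate needs at least one record")
    t, e = _as_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tmax = float(t.max())
    rmean = float(restricted_mean_survival_time(kmf, t=tmax))
    med = float(kmf.median_survival_time_)

    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    return KMCurve(times, surv, at_risk, rmean, med, len(records))


def logrank_test(groups: dict[str, list[SurvivalRecord]]) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = {g: r for g, r in groups.items() if r}
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    times, events, labels = [], [], []
    for g, recs in groups.items():
        t, e = _as_arrays(recs)
        times.append(t)
        events.append(e)
        labels += [g] * len(recs)
    t = np.concatenate(times)
    e = np.concatenate(events)
    if e.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(t, labels, e)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(
    records: list[SurvivalRecord],
    covariate: np.ndarray | list[float],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Univariate Cox PH fit by Newton-Raphson on the Breslow partial
    likelihood.

    Returns ``{"hr", "ci_low", "ci_high", "p_value", "beta", "se"}`` with a
    Wald 95% interval.  Raises :class:`SeparationError` on monotone
    likelihood.
    """
    t, e = _as_arrays(records)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(t):
        raise ValueError("covariate length must match records")
    if e.sum() == 0:
        raise ValueError("Cox model needs at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate must have at least two levels")

    order = np.argsort(-t, kind="stable")  # descending time
    t, e, x = t[order], e[order], x[order]

    beta = 0.0
    for _ in range(max_iter):
        score = 0.0
        info = 0.0
        s0 = s1 = s2 = 0.0
        i = 0
        n = len(t)
        while i < n:
            # extend the risk set with everything at time >= current time
            j = i
            while j < n and t[j] == t[i]:
                j += 1
            for k in range(i, j):
                w = math.exp(beta * x[k])
                s0 += w
                s1 += w * x[k]
                s2 += w * x[k] * x[k]
            for k in range(i, j):
                if e[k]:
                    m = s1 / s0
                    score += x[k] - m
                    info += s2 / s0 - m * m
            i = j
        if info <= 0:
            raise SeparationError("non-positive information: likelihood is flat")
        step = score / info
        beta += step
        if abs(beta) > 15:
            raise SeparationError(
                "monotone partial likelihood (complete separation); "
                "hazard ratio not estimable"
            )
        if abs(score) < tol:
            break
    else:
        if abs(score) > 1e-4:
            raise SeparationError("Newton iteration did not converge")

    se = 1.0 / math.sqrt(info)
    from scipy import stats

    z = beta / se
    return {
        "beta": beta,
        "se": se,
        "hr": math.exp(beta),
        "ci_low": math.exp(beta - 1.959963984540054 * se),
        "ci_high": math.exp(beta + 1.959963984540054 * se),
        "p_value": float(2.0 * stats.norm.sf(abs(z))),
    }


def survival_report(
    cohort: pd.DataFrame,
    time_col: str = "pfs_days",
    event_col: str = "pfs_event",
    group_col: str = "hrd_class",
) -> dict:
    """Per-group KM summaries plus log-rank and a two-group Cox fit.

    Groups are summarised even when only one is present; the log-rank test
    and the Cox fit require at least two.  Means and medians are reported
    in days and months (30.4375 days/month).
    """
    groups: dict[str, list[SurvivalRecord]] = {}
    for _, row in cohort.iterrows():
        rec = SurvivalRecord(
            str(row.get("sample_id", "?")),
            float(row[time_col]),
            int(row[event_col]),
            str(row[group_col]),
        )
        groups.setdefault(rec.group, []).append(rec)

    report: dict = {"groups": {}}
    for g in sorted(groups):
        curve = km_estimate(groups[g])
        report["groups"][g] = {
            "n": curve.n,
            "events": int(sum(r.event for r in groups[g])),
            "restricted_mean_days": curve.restricted_mean,
            "restricted_mean_months": curve.restricted_mean / DAYS_PER_MONTH,
            "median_days": None if math.isinf(curve.median) else curve.median,
        }
    if len(groups) >= 2:
        try:
            stat, p = logrank_test(groups)
            report["logrank"] = {"statistic": stat, "p_value": p}
        except ValueError as exc:
            report["logrank"] = {"error": str(exc)}
        # Cox on HRD-positive (non-HRN) vs HRN when both sides exist,
        # otherwise on the two largest groups
        all_recs = [r for recs in groups.values() for r in recs]
        if "HRN" in groups and len(groups["HRN"]) < len(all_recs):
            x = [0.0 if r.group == "HRN" else 1.0 for r in all_recs]
        else:
            big = sorted(groups, key=lambda g: -len(groups[g]))[:2]
            all_recs = [r for g in big for r in groups[g]]
            x = [1.0 if r.group == big[0] else 0.0 for r in all_recs]
        try:
            report["cox"] = cox_univariate(all_recs, x)
        except (SeparationError, ValueError) as exc:
            report["cox"] = {"error": str(exc)}
    else:
        report["logrank"] = {"error": "single group: test undefined"}
    return report
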