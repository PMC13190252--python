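"""Time-to-event machinery: Kaplan–Meier curves, landmark rates, medians,
reverse-KM follow-up, duration of response and stratified Cox regression.

The product-limit estimator and Greenwood variance are computed directly so
that the complementary log-log pointwise interval and the Brookmeyer–Crowley
style median interval (obtained by inverting that pointwise band) are fully
specified.  Ties follow the standard convention that events precede
censorings at equal times (censored subjects remain at risk for events at
their censoring time).  Stratified proportional-hazards fits are delegated to
``statsmodels`` (Breslow or Efron tie handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .design import ProportionInterval

__all__ = [
    "KMCurve",
    "MedianSurvival",
    "CoxResult",
    "km_fit",
    "km_rate_at",
    "km_median",
    "reverse_km_followup",
    "duration_of_response",
    "cox_stratified",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: distinct event times, survival, Greenwood SE,
    numbers at risk and event counts at each event time."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup S(t)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_se[idx] ** 2)


@dataclass(frozen=True)
class MedianSurvival:
    """Median survival time with confidence bounds; ``None`` marks a quantity
    that is not reached within follow-up."""

    median: float | None
    lower: float | None
    upper: float | None
    level: float


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate hazard ratios with Wald intervals from a stratified fit."""

    table: pd.DataFrame  # index: covariate; columns: coef, hr, se, hr_lower, hr_upper, p
    ties: str
    level: float


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_fit(time, event) -> KMCurve:
    """Kaplan–Meier product-limit fit with Greenwood standard errors."""
    t, e = _as_arrays(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    event_times = np.unique(t[e == 1])
    surv, se, at_risk, d_out = [], [], [], []
    s = 1.0
    gw = 0.0  # running sum of d / (n (n - d))
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= (n_risk - d) / n_risk
        if n_risk - d > 0:
            gw += d / (n_risk * (n_risk - d))
            se.append(s * np.sqrt(gw))
        else:
            se.append(0.0)  # S hits zero; variance degenerate
        surv.append(s)
        at_risk.append(n_risk)
        d_out.append(d)
    return KMCurve(
        event_times=event_times,
        survival=np.asarray(surv),
        greenwood_se=np.asarray(se),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_out, dtype=int),
        n_total=n,
    )


def _cloglog_bounds(s: float, var: float, level: float) -> tuple[float, float]:
    """Pointwise CI for S via the complementary log-log transform."""
    if s <= 0.0:
        return 0.0, 0.0
    if s >= 1.0 or var == 0.0:
        return s, s
    z = stats.norm.ppf(0.5 + level / 2.0)
    # SE on the log(-log S) scale by the delta method
    se_cll = np.sqrt(var) / abs(s * np.log(s))
    lo = s ** np.exp(z * se_cll)
    hi = s ** np.exp(-z * se_cll)
    return float(lo), float(hi)


def km_rate_at(curve: KMCurve, t: float, level: float = 0.95) -> ProportionInterval:
    """Survival probability at time ``t`` with a complementary log-log
    Greenwood interval; degenerate at t=0 and before the first event."""
    if t < 0:
        raise ValueError("t must be non-negative")
    s = curve.survival_at(t)
    lo, hi = _cloglog_bounds(s, curve.variance_at(t), level)
    return ProportionInterval(point=s, lower=lo, upper=hi, level=level)


def km_median(curve: KMCurve, level: float = 0.95) -> MedianSurvival:
    """Median survival: smallest event time with S(t) <= 0.5.

    The confidence interval inverts the pointwise complementary log-log band
    (Brookmeyer–Crowley flavor): the lower limit is the first event time at
    which the band's lower bound drops to 0.5, the upper limit the first time
    its upper bound does.  ``None`` marks bounds (or the median itself) not
    reached within follow-up.
    """
    median = lower = upper = None
    for et, s, se in zip(curve.event_times, curve.survival, curve.greenwood_se):
        lo, hi = _cloglog_bounds(float(s), float(se) ** 2, level)
        if median is None and s <= 0.5:
            median = float(et)
        if lower is None and lo <= 0.5:
            lower = float(et)
        if upper is None and hi <= 0.5:
            upper = float(et)
    return MedianSurvival(median=median, lower=lower, upper=upper, level=level)


def reverse_km_followup(time, event, level: float = 0.95) -> MedianSurvival:
    """Median follow-up by the reverse Kaplan–Meier method: flip the event
    indicator (censoring becomes the event of interest) and take the KM
    median."""
    t, e = _as_arrays(time, event)
    return km_median(km_fit(t, 1 - e), level=level)


def duration_of_response(
    response_start, end_time, event, level: float = 0.95
) -> MedianSurvival:
    """KM median duration of response among responders.

    Each responder contributes ``end_time - response_start`` (progression or
    death as the event, otherwise censored).  Callers must pass responders
    only; a start time after the end time is rejected.
    """
    start = np.asarray(response_start, dtype=float)
    end = np.asarray(end_time, dtype=float)
    if start.size == 0:
        raise ValueError("no responders supplied")
    if np.any(np.isnan(start)):
        raise ValueError("non-responder (missing response start) passed")
    dur = end - start
    if np.any(dur < 0):
        raise ValueError("response start after end time")
    return km_median(km_fit(dur, event), level=level)


def cox_stratified(
    records: pd.DataFrame,
    covariates: list[str],
    strata: str | None = None,
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
    level: float = 0.95,
) -> CoxResult:
    """Stratified Cox proportional-hazards fit.

    Maximizes the stratified partial likelihood (Breslow tie handling by
    default, Efron optional) and reports hazard ratios with Wald intervals.
    Constant covariates are rejected (zero information).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    X = records[covariates].to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant (zero information)")
    t, e = _as_arrays(records[time_col], records[event_col])
    strata_vals = records[strata].to_numpy() if strata is not None else None
    if strata_vals is not None:
        for s in np.unique(strata_vals):
            if int(e[strata_vals == s].sum()) < 2:
                raise ValueError(f"stratum {s!r} has fewer than 2 events")
    model = PHReg(t, X, status=e, strata=strata_vals, ties=ties)
    fit = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    coef = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    table = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "se": se,
            "hr_lower": np.exp(coef - z * se),
            "hr_upper": np.exp(coef + z * se),
            "p": 2 * stats.norm.sf(np.abs(coef / se)),
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return CoxResult(table=table, ties=ties, level=level)
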