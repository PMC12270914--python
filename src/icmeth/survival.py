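"""Mortality analyses: Cox proportional hazards per s.d. of age
acceleration, Kaplan-Meier curves for extreme groups, log-rank tests and
restricted-mean survival contrasts.

Model fitting is delegated to lifelines (Efron tie handling, Newton
optimization); this module owns the interfaces, validation and the
restricted-mean contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import ContractError, ConvergenceError, DegenerateDomainError, RangeError

__all__ = ["CoxFit", "KMCurve", "cox_fit", "kaplan_meier", "logrank_test", "rmst_difference"]


@dataclass
class CoxFit:
    coefs: pd.Series  # log-hazard coefficients, all predictors
    hr: float  # focal predictor, per s.d.
    ci: tuple[float, float]
    p: float  # two-sided Wald
    n_events: int
    log_likelihood: float


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # event-time grid (includes 0)
    survival: np.ndarray  # S(t) at each grid time
    at_risk: np.ndarray
    max_time: float

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])

    def area(self, tau: float) -> float:
        """Exact rectangle integral of the step function on [0, tau]."""
        if tau > self.max_time:
            raise RangeError(f"tau={tau} beyond last observed time {self.max_time}")
        ts = np.concatenate([self.times[self.times < tau], [tau]])
        widths = np.diff(ts)
        heights = self.survival[: widths.size]
        return float(np.sum(widths * heights))


def cox_fit(
    time,
    event,
    focal,
    covariates: pd.DataFrame | None = None,
    standardize_focal: bool = True,
    focal_name: str = "acceleration",
) -> CoxFit:
    """Cox proportional hazards fit (Efron ties) with the focal predictor
    reported per standard deviation.

    ``covariates`` (typically age and sex) enter unstandardized; the focal
    predictor is standardized to unit s.d. unless already so.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    focal = np.asarray(focal, dtype=float)
    if event.sum() < 2:
        raise ContractError("need at least 2 events")
    if np.ptp(focal) == 0:
        raise DegenerateDomainError("focal predictor is constant")
    if standardize_focal:
        focal = (focal - focal.mean()) / focal.std(ddof=1)
    df = pd.DataFrame({"time": time, "event": event, focal_name: focal})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).copy()
        for c in cov.columns:
            if cov[c].dtype.kind in "OUS":
                cov[c] = (cov[c] == "male").astype(float)
        df = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-12, "max_steps": 500})
    except _LLConvergenceError as exc:
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
    summ = cph.summary
    return CoxFit(
        coefs=cph.params_.copy(),
        hr=float(summ.loc[focal_name, "exp(coef)"]),
        ci=(
            float(summ.loc[focal_name, "exp(coef) lower 95%"]),
            float(summ.loc[focal_name, "exp(coef) upper 95%"]),
        ),
        p=float(summ.loc[focal_name, "p"]),
        n_events=int(event.sum()),
        log_likelihood=float(cph.log_likelihood_),
    )


def _km_one(time: np.ndarray, event: np.ndarray) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    table = kmf.event_table
    at_risk = table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk, max_time=float(time.max()))


def kaplan_meier(time, event, group=None) -> KMCurve | dict[str, KMCurve]:
    """Kaplan-Meier curve(s); one per group label when ``group`` is given."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if group is None:
        return _km_one(time, event)
    group = np.asarray(group)
    out = {}
    for g in pd.unique(group):
        m = group == g
        if not m.any():
            raise ContractError(f"empty group {g!r}")
        out[g] = _km_one(time[m], event[m])
    return out


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ContractError(f"need exactly two groups, got {list(levels)}")
    m = group == levels[0]
    if not (m.any() and (~m).any()):
        raise ContractError("both groups must be nonempty")
    if event.sum() < 1:
        raise ContractError("need at least one event")
    res = _ll_logrank(time[m], time[~m], event[m], event[~m])
    return float(res.test_statistic), float(res.p_value)


def rmst_difference(km_high: KMCurve, km_low: KMCurve, tau: float) -> float:
    """Restricted-mean survival difference (high minus low) on [0, tau]."""
    if tau > min(km_high.max_time, km_low.max_time):
        raise RangeError(
            f"tau={tau} exceeds the support of at least one curve "
            f"({km_high.max_time}, {km_low.max_time})"
        )
    return km_high.area(tau) - km_low.area(tau)
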