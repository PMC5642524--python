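"""Survival analysis: Kaplan-Meier curves, log-rank tests, Cox regression.

Endpoints follow the study's definitions: relapse-free survival (RFS)
events are loco-regional recurrence, distant metastasis, or death from any
cause; gastric-cancer-specific survival (GCSS) events are deaths from a
GC-related cause. Times are in days from surgery to last follow-up.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
Cox proportional-hazards fitting uses the Breslow tie approximation via
statsmodels' PHReg, wrapped to report hazard ratios with Wald confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed to converge."""


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    time: float  # days
    rfs_event: bool
    gcss_event: bool
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.gcss_event and not self.rfs_event:
            # a GC-specific death is also an any-cause-death RFS event
            raise ValueError("gcss_event implies an RFS event")


def km_curve(
    times: Sequence[float], events: Sequence[bool]
) -> pd.DataFrame:
    """Product-limit survival estimate with at-risk counts.

    Returns a DataFrame with columns (time, survival, at_risk, events);
    censored times reduce the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": tbl.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
        }
    )


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]],
) -> tuple[float, int, float]:
    """Log-rank comparison of >=2 groups -> (chi2 statistic, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = list(t)
        if not t:
            raise ValueError(f"group {gi} has zero observations")
        times.extend(float(x) for x in t)
        events.extend(bool(x) for x in e)
        labels.extend([gi] * len(t))
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate Cox PH estimates (Breslow ties)."""

    summary: pd.DataFrame  # columns: coef, hr, hr_lower, hr_upper, se, p
    n: int
    n_events: int
    converged: bool
    separation_flagged: tuple[str, ...] = ()


def _records_to_arrays(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str],
    endpoint: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    status = np.array(
        [getattr(r, endpoint) for r in records], dtype=float
    )
    X = np.array(
        [[float(r.covariates[c]) for c in covariate_names] for r in records],
        dtype=float,
    )
    return times, status, X


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str],
    endpoint: str = "rfs_event",
    level: float = 0.95,
) -> CoxResult:
    """Cox proportional-hazards regression with Breslow tie handling.

    Returns hazard ratios with Wald confidence intervals and p-values.
    Zero-variance covariates get coef 0 / HR 1 with NA inference; a
    coefficient exceeding |5| on standardized inputs is flagged as
    potential complete separation.
    """
    if not records:
        raise ValueError("no records")
    times, status, X = _records_to_arrays(records, covariate_names, endpoint)
    n_events = int(status.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")

    variable = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    rows = {
        name: {"coef": 0.0, "hr": 1.0, "hr_lower": np.nan, "hr_upper": np.nan,
               "se": np.nan, "p": np.nan}
        for name in covariate_names
    }
    converged = True
    flagged: list[str] = []
    if variable:
        model = PHReg(times, X[:, variable], status=status, ties="breslow")
        try:
            fit = model.fit(maxiter=100, disp=False)
        except Exception as exc:  # pragma: no cover - statsmodels raises rarely
            raise ConvergenceError(str(exc)) from exc
        grad = np.asarray(model.score(fit.params))
        if np.linalg.norm(grad) > 1e-4 * max(1, n_events):
            raise ConvergenceError(
                f"gradient norm {np.linalg.norm(grad):.3g} after fitting"
            )
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        for idx, name in zip(variable, [covariate_names[i] for i in variable]):
            j = variable.index(idx)
            coef = float(fit.params[j])
            se = float(fit.bse[j])
            rows[name] = {
                "coef": coef,
                "hr": float(np.exp(coef)),
                "hr_lower": float(np.exp(coef - z * se)),
                "hr_upper": float(np.exp(coef + z * se)),
                "se": se,
                "p": float(fit.pvalues[j]),
            }
            scale = np.std(X[:, idx])
            if abs(coef) * scale > 5:
                flagged.append(name)
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "covariate"
    return CoxResult(
        summary=summary,
        n=len(records),
        n_events=n_events,
        converged=converged,
        separation_flagged=tuple(flagged),
    )


def cox_score_test(
    records: Sequence[SurvivalRecord],
    covariate: str,
    endpoint: str = "rfs_event",
) -> float:
    """Score (Rao) test statistic of the Cox model at beta = 0.

    With a single group-indicator covariate and Breslow ties this equals
    the log-rank chi-square statistic.
    """
    times, status, X = _records_to_arrays(records, [covariate], endpoint)
    model = PHReg(times, X, status=status, ties="breslow")
    beta0 = np.zeros(X.shape[1])
    score = np.asarray(model.score(beta0))
    info = -np.asarray(model.hessian(beta0))
    return float(score @ np.linalg.solve(info, score))


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "time_days": r.time,
            "rfs_event": int(r.rfs_event),
            "gcss_event": int(r.gcss_event),
        }
        row.update({k: v for k, v in r.covariates.items()})
        rows.append(row)
    return pd.DataFrame(rows)
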