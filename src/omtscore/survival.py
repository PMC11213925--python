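"""Transformation-free survival evaluation.

Kaplan-Meier curves, log-rank tests, Harrell's concordance index and a
multivariate Cox proportional-hazards model (Efron tie handling), with all
transformations right-censored at eight years so internal and external
cohorts are comparable.  Statistical machinery is delegated to ``lifelines``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

CENSOR_HORIZON_YEARS = 8.0
_TIME_EPS = 1e-6

COX_COVARIATES = ["omt_risk", "binary_grade", "who_grade", "age", "sex", "site"]


@dataclass(frozen=True)
class SurvivalInput:
    time: float
    event: int
    group: object = None


def apply_censoring(
    times: Sequence[float],
    events: Sequence[int],
    horizon: float = CENSOR_HORIZON_YEARS,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-censor at ``horizon`` years: later times become (horizon, 0).

    Zero times are clamped to a small epsilon (with a warning) so that
    downstream partial-likelihood fits remain well defined.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    over = times > horizon
    out_t = np.where(over, horizon, times)
    out_e = np.where(over, 0, events)
    if (out_t <= 0).any():
        warnings.warn("zero survival times clamped to epsilon", stacklevel=2)
        out_t = np.where(out_t <= 0, _TIME_EPS, out_t)
    return out_t, out_e


def kaplan_meier(
    times: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """Product-limit survival estimate: columns time, survival, at_risk."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=int))
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=float),
        }
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> float:
    """Log-rank chi-square p-value across >=2 groups."""
    groups = np.asarray(groups)
    if len(set(groups.tolist())) < 2:
        raise ValueError("log-rank test needs >=2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=int)
    )
    return float(res.p_value)


def concordance_index(
    scores: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> float:
    """Harrell's C between a risk score and observed event ordering.

    Higher scores should mean earlier events; score ties count 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no comparable pairs (no events)")
    # lifelines expects higher = longer survival, so negate the risk score
    return float(_lifelines_cindex(times, -np.asarray(scores, dtype=float), events))


def cox_ph(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: Sequence[str] = COX_COVARIATES,
) -> pd.DataFrame:
    """Multivariate Cox PH fit (Efron ties): HR, Wald 95% CI and p per covariate.

    Returns a forest-table DataFrame indexed by covariate with columns
    ``p, HR, HR_lower_95, HR_upper_95, coef, se``.
    """
    covariates = list(covariates)
    x = data[covariates].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc) if len(covariates) > 1 else int((xc != 0).any())
    if rank < len(covariates):
        sd = xc.std(axis=0)
        flat = [c for c, s in zip(covariates, sd) if s == 0]
        raise ValueError(
            f"singular design matrix; constant/collinear columns: {flat or covariates}"
        )
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates", stacklevel=2
        )
    cph = CoxPHFitter()
    cph.fit(
        data[[duration_col, event_col, *covariates]],
        duration_col=duration_col,
        event_col=event_col,
    )
    s = cph.summary
    return pd.DataFrame(
        {
            "p": s["p"],
            "HR": s["exp(coef)"],
            "HR_lower_95": s["exp(coef) lower 95%"],
            "HR_upper_95": s["exp(coef) upper 95%"],
            "coef": s["coef"],
            "se": s["se(coef)"],
        }
    )


def survival_summary(
    cohort_frame: pd.DataFrame,
    risk_group: Mapping[str, int],
    horizon: float = CENSOR_HORIZON_YEARS,
) -> dict:
    """KM per risk group, log-rank p, C-index and Cox forest table.

    ``cohort_frame`` is the cohort as a DataFrame (see ``io.cohort_to_frame``);
    ``risk_group`` maps slide_id to the thresholded OMT prediction (1 = high
    risk).  WHO grade is coded ordinally 0/1/2 and the binary grade 0/1.
    """
    df = cohort_frame.copy()
    df["omt_risk"] = df["slide_id"].map(risk_group).astype(int)
    who_code = {"mild": 0, "moderate": 1, "severe": 2}
    bin_code = {"low_risk": 0, "high_risk": 1}
    df["who_grade_code"] = df["who_grade"].map(who_code)
    df["binary_grade_code"] = df["binary_grade"].map(bin_code)
    t, e = apply_censoring(
        df["time_to_event_years"], df["transformed"], horizon=horizon
    )
    df["time"], df["event"] = t, e

    km = {
        int(g): kaplan_meier(sub["time"], sub["event"])
        for g, sub in df.groupby("omt_risk")
    }
    p_logrank = logrank_test(df["time"], df["event"], df["omt_risk"])
    cindex = concordance_index(df["omt_risk"], df["time"], df["event"])
    cox_df = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"],
            "omt_risk": df["omt_risk"],
            "binary_grade": df["binary_grade_code"],
            "who_grade": df["who_grade_code"],
            "age": df["age"],
            "sex": df["sex"],
            "site": df["site"],
        }
    )
    forest = cox_ph(cox_df)
    return {
        "km_curves": km,
        "logrank_p": p_logrank,
        "c_index": cindex,
        "cox_table": forest,
    }
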