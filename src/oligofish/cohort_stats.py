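"""Association and survival statistics over patient cohorts.

Covers the statistical toolbox of a clinico-pathological FISH study:
Pearson chi-square on contingency tables (optionally Yates-corrected
for 2x2), Kaplan-Meier product-limit curves with median survival and
fixed-horizon survival probabilities, the unweighted log-rank test, and
Cox proportional-hazards regression (Efron tie handling) with the
classical two-stage selection — multivariate entry only for covariates
with univariate log-rank p < 0.05.

Survival estimation and Cox fitting are delegated to lifelines; the
chi-square to scipy.  Records with an unknown value for a covariate
are excluded listwise from any analysis that uses it.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2_contingency

from .io_formats import PatientRecord

__all__ = [
    "ContingencyResult",
    "SurvivalCurve",
    "CoxResult",
    "ModelScope",
    "SURVIVAL_HORIZONS_MONTHS",
    "chisq_test",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "survival_table",
    "records_to_frame",
]

#: 1 / 5 / 10 / 15 / 20 year horizons, in months.
SURVIVAL_HORIZONS_MONTHS = (12, 60, 120, 180, 240)


class ModelScope(enum.Enum):
    UNIVARIATE = "univariate"
    MULTIVARIATE = "multivariate"


@dataclass(frozen=True)
class ContingencyResult:
    observed: tuple[tuple[int, ...], ...]
    statistic: float
    df: int
    p_value: float
    corrected: bool


@dataclass(frozen=True)
class SurvivalCurve:
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median_months: float | None

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t) (right-continuous)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    scope: ModelScope


def chisq_test(table: Sequence[Sequence[int]], yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence on a contingency table.

    ``yates`` applies the continuity correction (2x2 tables only, as in
    scipy).  All row and column margins must be positive.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = chi2_contingency(obs, correction=yates)
    return ContingencyResult(
        observed=tuple(tuple(int(v) for v in row) for row in obs),
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        corrected=yates,
    )


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Tied events at the same time point are handled simultaneously; the
    median is undefined (None) when the curve never drops below 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("times must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # lifelines event table gives at-risk counts on the same grid
    at_risk = kmf.event_table["at_risk"].reindex(grid).ffill().to_numpy()
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    return SurvivalCurve(
        times=tuple(float(x) for x in grid),
        survival=tuple(float(s) for s in surv),
        at_risk=tuple(int(r) for r in at_risk),
        median_months=median,
    )


def logrank_test(
    group_labels: Sequence, times: Sequence[float], events: Sequence[bool]
) -> float:
    """Unweighted log-rank test across >= 2 groups; returns the p-value."""
    labels = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(set(labels.tolist())) < 2:
        raise ValueError("log-rank requires at least two groups")
    res = multivariate_logrank_test(t, labels, e)
    return float(res.p_value)


_RECORD_COVARIATE_LEVELS = {
    # covariate -> (field, level coded as 1)
    "grade_O3": ("grade", "O3"),
    "sex_female": ("sex", "female"),
    "mitoses_gt5": ("mitoses_class", "gt5"),
    "mvp_glomeruloid": ("mvp", "glomeruloid"),
    "mib1_gt17": ("mib1_class", "gt17"),
}
_RECORD_BOOL_COVARIATES = {
    "necrosis": "necrosis",
    "calcification": "calcification",
    "recurrent": "recurrent_flag",
}


def records_to_frame(
    records: Sequence[PatientRecord],
    extra: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Encode patient records as an analysis DataFrame of 0/1 indicators.

    ``extra`` maps covariate name -> {patient_id: value} for covariates
    that live outside the record (e.g. the FISH polysomy call).  Unknown
    values become NaN and are dropped listwise per analysis.
    """
    rows = []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id,
            "efs_months": r.efs_months,
            "efs_event": int(r.efs_event),
            "os_months": r.os_months,
            "os_event": int(r.os_event),
            "age_years": r.age_years if r.age_years is not None else np.nan,
        }
        for cov, (field_name, hot) in _RECORD_COVARIATE_LEVELS.items():
            v = getattr(r, field_name)
            row[cov] = np.nan if v is None else int(v == hot)
        for cov, field_name in _RECORD_BOOL_COVARIATES.items():
            v = getattr(r, field_name)
            row[cov] = np.nan if v is None else int(v)
        if extra:
            for cov, mapping in extra.items():
                row[cov] = mapping.get(r.patient_id, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def _fit_cox(df: pd.DataFrame, duration: str, event: str, covariates: list[str],
             scope: ModelScope) -> list[CoxResult]:
    sub = df[[duration, event, *covariates]].dropna()
    if sub[event].sum() == 0:
        raise ValueError("no events in the data")
    for cov in covariates:
        if sub[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant: hazard ratio non-identifiable")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(sub, duration_col=duration, event_col=event)
    out = []
    # near-separable covariates give huge CI bounds; exp overflow -> inf is fine
    with np.errstate(over="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for cov in covariates:
            out.append(CoxResult(
                covariate=cov,
                hazard_ratio=float(np.exp(cph.params_[cov])),
                ci_low=float(np.exp(cph.confidence_intervals_.loc[cov].iloc[0])),
                ci_high=float(np.exp(cph.confidence_intervals_.loc[cov].iloc[1])),
                p_value=float(cph.summary.loc[cov, "p"]),
                scope=scope,
            ))
    return out


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    *,
    duration_col: str = "os_months",
    event_col: str = "os_event",
    scope: ModelScope = ModelScope.UNIVARIATE,
    selection_alpha: float = 0.05,
) -> list[CoxResult]:
    """Cox proportional-hazards regression (Efron ties).

    ``scope=UNIVARIATE`` fits one single-covariate model per covariate.
    ``scope=MULTIVARIATE`` first screens each binary covariate with a
    univariate log-rank test and fits one joint model on those with
    p < ``selection_alpha`` (the classical two-stage procedure).
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates supplied")

    if scope is ModelScope.UNIVARIATE:
        results = []
        for cov in covariates:
            results.extend(_fit_cox(df, duration_col, event_col, [cov], scope))
        return results

    selected = []
    for cov in covariates:
        sub = df[[duration_col, event_col, cov]].dropna()
        if sub[cov].nunique() < 2:
            continue
        p = logrank_test(sub[cov].to_numpy(), sub[duration_col].to_numpy(),
                         sub[event_col].to_numpy(dtype=bool))
        if p < selection_alpha:
            selected.append(cov)
    if not selected:
        raise ValueError("no covariate passed univariate selection")
    return _fit_cox(df, duration_col, event_col, selected, ModelScope.MULTIVARIATE)


def survival_table(
    df: pd.DataFrame,
    stratifier: str,
    *,
    duration_col: str = "os_months",
    event_col: str = "os_event",
    horizons: Sequence[float] = SURVIVAL_HORIZONS_MONTHS,
) -> pd.DataFrame:
    """Per-stratum median survival and survival at fixed horizons.

    Returns a DataFrame indexed by stratum with columns ``median_months``
    and ``s_<h>m`` (survival probability at each horizon, in [0, 1]).
    """
    sub = df[[duration_col, event_col, stratifier]].dropna()
    if sub.empty:
        raise ValueError("no usable records")
    rows = {}
    for level, grp in sub.groupby(stratifier):
        if grp.empty:
            raise ValueError(f"empty stratum {level!r}")
        curve = km_estimate(grp[duration_col].to_numpy(), grp[event_col].to_numpy(dtype=bool))
        row = {"n": len(grp), "median_months": curve.median_months}
        for h in horizons:
            row[f"s_{int(h)}m"] = curve.survival_at(h)
        rows[level] = row
    return pd.DataFrame.from_dict(rows, orient="index")
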