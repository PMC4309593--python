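"""Association stages: logistic ORs, Kaplan-Meier risk curves, Cox HRs.

Dosage (the expected mutation-allele count per individual, from imputation
or tree prediction) enters every model additively.  Survival analyses use
age as the time scale — age at diagnosis for cases, age at last observation
for censored individuals — matching a cohort design where age-specific risk
is the estimand.  One-sided p-values are oriented toward increased risk;
confidence intervals are two-sided Wald intervals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .core import EffectEstimate, RiskCurve

Z975 = stats.norm.ppf(0.975)


def logistic_assoc(
    dosage: np.ndarray,
    case_status: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> EffectEstimate:
    """Maximum-likelihood logistic regression of case status on dosage.

    Returns the odds ratio per dosage unit with a two-sided 95% Wald CI and
    a one-sided p-value toward OR > 1.  Complete or quasi-complete
    separation is flagged on the result rather than raised.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(case_status, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    if np.std(dosage) == 0:
        raise ValueError("dosage has zero variance")
    X = pd.DataFrame({"dosage": dosage})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    X = sm.add_constant(X, prepend=True)
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as err:
            raise RuntimeError(f"logistic fit failed: {err}") from err
        for w in caught:
            if "separation" in str(w.message).lower() or "convergence" in str(
                w.message
            ).lower():
                flags.append("separation_or_nonconvergence")
                break
    beta = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    z = beta / se if se > 0 else np.inf
    return EffectEstimate(
        w=float(np.exp(beta)),
        beta=beta,
        se_beta=se,
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p_one_sided=float(stats.norm.sf(z)),
        kind="OR",
        flags=flags,
    )


def km_logrank(
    ages: np.ndarray,
    events: np.ndarray,
    carrier_group: np.ndarray,
) -> tuple[dict[str, RiskCurve], float | None, float | None]:
    """Cumulative-risk (1 - KM) curves per group and a log-rank test.

    Curves are evaluated on the pooled grid of observed ages so groups are
    directly comparable (and correctable) pointwise.  With a single group
    only curves are returned (no test).
    """
    ages = np.asarray(ages, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(carrier_group)
    if events.sum() == 0:
        raise ValueError("no events observed")
    grid = np.unique(ages)
    curves: dict[str, RiskCurve] = {}
    for g in pd.unique(groups):
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(ages[m], events[m])
        surv = kmf.survival_function_at_times(grid).to_numpy()
        curves[str(g)] = RiskCurve(age=grid, risk=1.0 - surv, label=str(g))
    if len(curves) < 2:
        return curves, None, None
    res = multivariate_logrank_test(ages, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_hr(
    ages: np.ndarray,
    events: np.ndarray,
    dosage: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> EffectEstimate:
    """Cox proportional-hazards HR per dosage unit (Efron tie handling)."""
    df = pd.DataFrame(
        {
            "age": np.asarray(ages, dtype=float),
            "event": np.asarray(events, dtype=int),
            "dosage": np.asarray(dosage, dtype=float),
        }
    )
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], dtype=float)
    cph = CoxPHFitter()
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="age", event_col="event")
        for w in caught:
            if "converg" in str(w.message).lower():
                flags.append("nonconvergence")
                break
    beta = float(cph.params_["dosage"])
    se = float(cph.standard_errors_["dosage"])
    z = beta / se if se > 0 else np.inf
    return EffectEstimate(
        w=float(np.exp(beta)),
        beta=beta,
        se_beta=se,
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p_one_sided=float(stats.norm.sf(z)),
        kind="HR",
        flags=flags,
    )


def cox_score_statistic(
    ages: np.ndarray, events: np.ndarray, group: np.ndarray
) -> float:
    """Cox partial-likelihood score test statistic at beta = 0 (binary group).

    Without ties this equals the two-group log-rank chi-square; used as an
    independent cross-check of the survival machinery.
    """
    ages = np.asarray(ages, dtype=float)
    events = np.asarray(events, dtype=int)
    z = np.asarray(group, dtype=float)
    order = np.argsort(ages, kind="stable")
    ages, events, z = ages[order], events[order], z[order]
    u = 0.0
    info = 0.0
    n = len(ages)
    for i in range(n):
        if not events[i]:
            continue
        risk = ages >= ages[i]
        zr = z[risk]
        zbar = zr.mean()
        u += z[i] - zbar
        info += zr.var()
    if info <= 0:
        raise ValueError("no information for score test")
    return float(u * u / info)


def prevalent_incident_split(
    table: pd.DataFrame,
    age_col: str,
    event_col: str,
    survey_col: str = "survey_age",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split follow-up at the survey age to probe survivor bias.

    Prevalent subset: event information truncated at the survey — events
    after the survey are censored there.  Incident subset: individuals with
    an event before the survey are excluded; the rest keep their full
    follow-up.  Both subsets reuse the original column names.
    """
    if survey_col not in table.columns:
        raise KeyError(f"missing column {survey_col!r}")
    age = table[age_col].to_numpy(dtype=float)
    event = table[event_col].to_numpy(dtype=int)
    survey = table[survey_col].to_numpy(dtype=float)

    prevalent = table.copy()
    prevalent[age_col] = np.minimum(age, survey)
    prevalent[event_col] = ((event == 1) & (age <= survey)).astype(int)

    prevalent_case = (event == 1) & (age <= survey)
    incident = table.loc[~prevalent_case].copy()
    return prevalent, incident
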