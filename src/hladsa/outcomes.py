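"""Time-to-event and regression comparisons across dnDSA groups.

The comparison plan mirrors routine transplant-cohort practice: Kaplan-Meier
curves with global and pairwise log-rank tests for antibody-mediated
rejection (ABMR) and death-censored graft loss, univariate and multivariate
Cox models for graft loss, and logistic models for ABMR.  Numerics are
delegated to lifelines (Efron handling of tied event times) and
statsmodels; this module owns the group encodings, the collinearity rule
for overlapping exposure definitions (LR_dnDSA+ contains LR+/HR+, so those
terms are fitted in independent models), and the NA flagging of strata
with no events or separated outcomes, which are reported as flagged rows
rather than crashes.

Times are months since transplant.  Significance is two-tailed at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

#: outcome name -> (event flag column, event/censor time column)
EVENTS = {
    "ABMR": ("abmr", "abmr_months"),
    "graft_loss": ("graft_loss", "graft_loss_months"),
}

#: columns every cohort table must carry
COHORT_REQUIRED = [
    "patient_id", "group",
    "abmr", "abmr_months", "graft_loss", "graft_loss_months",
]

ALPHA = 0.05


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient record {dup!r}")
    for _, (flag, time) in EVENTS.items():
        if (df[time] < 0).any():
            raise ValueError(f"negative times in {time}")
        if not df[flag].isin((0, 1, True, False)).all():
            raise ValueError(f"{flag} must be a 0/1 event indicator")
    return df


@dataclass
class SurvivalComparison:
    event: str
    #: group -> step-function DataFrame with columns time, survival
    curves: dict
    global_statistic: float
    global_p: float
    pairwise_p: dict = dc_field(default_factory=dict)


def km_logrank(df: pd.DataFrame, event: str,
               grouping: str = "group") -> SurvivalComparison:
    """Product-limit curves per group plus global and pairwise log-rank tests.

    All-censored groups yield a curve flat at 1 and simply contribute
    at-risk time to the tests.
    """
    flag, time = EVENTS[event]
    groups = [g for g, sub in df.groupby(grouping) if len(sub)]
    if len(groups) < 2:
        raise ValueError("log-rank comparison needs at least two non-empty groups")
    curves = {}
    for g, sub in df.groupby(grouping):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time], event_observed=sub[flag])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    res = multivariate_logrank_test(df[time], df[grouping], df[flag])
    pairwise = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            a = df[df[grouping] == g1]
            b = df[df[grouping] == g2]
            r = logrank_test(a[time], b[time], a[flag], b[flag])
            pairwise[(g1, g2)] = float(r.p_value)
    return SurvivalComparison(
        event=event,
        curves=curves,
        global_statistic=float(res.test_statistic),
        global_p=float(res.p_value),
        pairwise_p=pairwise,
    )


def _na_row(term: str, mode: str, note: str) -> dict:
    return {"term": term, "mode": mode, "estimate": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "note": note}


def _zero_event_stratum(df: pd.DataFrame, term: str, flag: str) -> str | None:
    """NA note when a binary exposure has a stratum without events/exposure."""
    values = df[term].dropna().unique()
    if len(values) > 2 or not set(np.unique(values)) <= {0, 1, True, False}:
        return None
    exposed = df[df[term].astype(bool)]
    if len(exposed) == 0:
        return "no exposed subjects"
    if exposed[flag].sum() == 0:
        return "no events in the exposed group"
    if df[~df[term].astype(bool)][flag].sum() == 0:
        return "no events in the unexposed group"
    return None


def cox_models(df: pd.DataFrame, event: str, terms: list[str],
               mode: str = "univariate",
               adjust: list[str] | None = None,
               collinear: list[str] | None = None) -> pd.DataFrame:
    """Hazard ratios with 95% CI per term.

    ``univariate`` fits one model per term.  ``multivariate`` fits the
    adjustment set plus each collinear exposure term in an independent
    model (overlapping dnDSA group definitions cannot share a model).
    Zero-event strata and non-convergence give NA-flagged rows.
    """
    flag, time = EVENTS[event]
    if df[flag].sum() < 1:
        raise ValueError(f"no {event} events in the cohort")
    rows = []
    if mode == "univariate":
        for term in terms:
            rows.append(_fit_cox(df, flag, time, [term], term, mode))
    elif mode == "multivariate":
        adjust = list(adjust or [])
        collinear = list(collinear if collinear is not None else terms)
        base = [t for t in terms if t not in collinear]
        if base:
            fitted = _fit_cox_frame(df, flag, time, adjust + base, mode)
            rows.extend(fitted if isinstance(fitted, list) else [fitted])
        for term in collinear:
            rows.append(_fit_cox(df, flag, time, adjust + [term], term, mode))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows,
                        columns=["term", "mode", "estimate", "ci_low",
                                 "ci_high", "p", "note"])


def _fit_cox(df, flag, time, covariates, report_term, mode) -> dict:
    note = _zero_event_stratum(df, report_term, flag)
    if note:
        return _na_row(report_term, mode, note)
    cph = CoxPHFitter()
    cols = [time, flag] + covariates
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[cols].dropna(), duration_col=time, event_col=flag)
    except ConvergenceError:
        return _na_row(report_term, mode, "model did not converge")
    s = cph.summary.loc[report_term]
    return {
        "term": report_term, "mode": mode,
        "estimate": float(np.exp(s["coef"])),
        "ci_low": float(np.exp(s["coef lower 95%"])),
        "ci_high": float(np.exp(s["coef upper 95%"])),
        "p": float(s["p"]), "note": "",
    }


def _fit_cox_frame(df, flag, time, covariates, mode) -> list[dict]:
    rows = []
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[[time, flag] + covariates].dropna(),
                    duration_col=time, event_col=flag)
    except ConvergenceError:
        return [_na_row(t, mode, "model did not converge") for t in covariates]
    for term in covariates:
        s = cph.summary.loc[term]
        rows.append({
            "term": term, "mode": mode,
            "estimate": float(np.exp(s["coef"])),
            "ci_low": float(np.exp(s["coef lower 95%"])),
            "ci_high": float(np.exp(s["coef upper 95%"])),
            "p": float(s["p"]), "note": "",
        })
    return rows


def logistic_models(df: pd.DataFrame, outcome: str, terms: list[str],
                    mode: str = "univariate",
                    adjust: list[str] | None = None) -> pd.DataFrame:
    """Odds ratios with 95% CI per term; separation gives NA-flagged rows."""
    import statsmodels.api as sm

    flag = EVENTS[outcome][0] if outcome in EVENTS else outcome
    rows = []
    term_sets = ([[t] for t in terms] if mode == "univariate"
                 else [list(adjust or []) + [t] for t in terms])
    for term, covariates in zip(terms, term_sets):
        note = _zero_event_stratum(df, term, flag)
        if note:
            rows.append(_na_row(term, mode, note))
            continue
        sub = df[[flag] + covariates].dropna()
        X = sm.add_constant(sub[covariates].astype(float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(sub[flag].astype(float), X).fit(disp=0)
        except Exception:
            rows.append(_na_row(term, mode, "model did not converge (separation?)"))
            continue
        coef = fit.params[term]
        se = fit.bse[term]
        if not np.isfinite(se) or abs(coef) > 15:
            rows.append(_na_row(term, mode, "quasi-complete separation"))
            continue
        rows.append({
            "term": term, "mode": mode,
            "estimate": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - 1.959964 * se)),
            "ci_high": float(np.exp(coef + 1.959964 * se)),
            "p": float(fit.pvalues[term]), "note": "",
        })
    return pd.DataFrame(rows,
                        columns=["term", "mode", "estimate", "ci_low",
                                 "ci_high", "p", "note"])
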