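"""Clinico-genomic association scans and survival analysis.

Kaplan-Meier curves with log-rank homogeneity tests, Cox proportional
hazards with Efron tie handling, and per-feature regression scans
(logistic / linear / negative binomial) adjusted for clinical
covariates, with Benjamini-Hochberg adjustment across scanned features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from somacohort.burden import bh_adjust


@dataclass
class SurvivalResult:
    feature: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    endpoint: str = "OS"


def km_logrank(time: np.ndarray, event: np.ndarray,
               group: np.ndarray) -> tuple[dict[str, KaplanMeierFitter], float]:
    """Product-limit curves per group plus a two-sided log-rank p.

    With a single group the p-value is NaN (curves only).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group)
    curves = {}
    for g in pd.unique(group):
        km = KaplanMeierFitter()
        mask = group == g
        km.fit(time[mask], event[mask], label=str(g))
        curves[str(g)] = km
    if len(curves) < 2:
        return curves, float("nan")
    res = multivariate_logrank_test(time, group, event)
    return curves, float(res.p_value)


def cox_fit(df: pd.DataFrame, time_col: str, event_col: str,
            covariates: list[str], adjusters: list[str] | None = None,
            endpoint: str = "OS") -> list[SurvivalResult]:
    """Cox partial-likelihood fit (Efron ties); one result per covariate.

    All covariates and adjusters enter one multivariable model; Wald CI
    and two-sided z p-value per covariate of interest. Constant columns
    and separation are flagged as errors / NaN results.
    """
    adjusters = adjusters or []
    cols = covariates + adjusters
    for c in cols:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c} is constant")
    n_events = int(df[event_col].sum())
    if n_events < 5 * len(cols):
        warnings.warn(f"only {n_events} events for {len(cols)} covariates",
                      stacklevel=2)
    data = df[[time_col, event_col] + cols].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:
        warnings.warn(f"Cox fit failed ({exc}); returning flagged results",
                      stacklevel=2)
        return [SurvivalResult(feature=c, hazard_ratio=float("nan"),
                               ci_low=float("nan"), ci_high=float("nan"),
                               p_value=float("nan"), n=len(df),
                               endpoint=endpoint) for c in covariates]
    out = []
    ci = cph.confidence_intervals_
    for c in covariates:
        beta = float(cph.params_[c])
        lo = float(np.exp(ci.loc[c].iloc[0]))
        hi = float(np.exp(ci.loc[c].iloc[1]))
        out.append(SurvivalResult(feature=c, hazard_ratio=float(np.exp(beta)),
                                  ci_low=lo, ci_high=hi,
                                  p_value=float(cph.summary.loc[c, "p"]),
                                  n=len(df), endpoint=endpoint))
    return out


def association_scan(features: pd.DataFrame, clinical: pd.DataFrame,
                     outcome: str, family: str,
                     adjusters: list[str] | None = None) -> pd.DataFrame:
    """Per-feature adjusted regression scan.

    family: 'logistic' (binary outcome, effect = odds ratio), 'linear'
    (effect = beta) or 'negative-binomial' (count outcome, effect = rate
    ratio). Each feature is fit in its own model together with the
    adjusters; BH across features.
    """
    if family not in ("logistic", "linear", "negative-binomial"):
        raise ValueError(f"unknown family {family!r}")
    adjusters = adjusters or []
    y = clinical[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome is constant")
    rows = []
    for feat in features.columns:
        x = pd.concat([features[feat].astype(float),
                       clinical[adjusters].astype(float)], axis=1)
        x = sm.add_constant(x)
        try:
            if family == "logistic":
                fit = sm.Logit(y, x).fit(disp=0)
            elif family == "linear":
                fit = sm.OLS(y, x).fit()
            else:
                alpha = _profile_nb_alpha(y, x)
                fit = sm.GLM(y, x,
                             family=sm.families.NegativeBinomial(alpha=alpha)
                             ).fit()
        except Exception as exc:
            warnings.warn(f"scan for {feat} failed: {exc}", stacklevel=2)
            rows.append(dict(feature=feat, effect=np.nan, ci_low=np.nan,
                             ci_high=np.nan, p_value=np.nan))
            continue
        beta = float(fit.params[feat])
        lo, hi = (float(v) for v in fit.conf_int().loc[feat])
        p = float(fit.pvalues[feat])
        if family == "linear":
            eff, elo, ehi = beta, lo, hi
        else:  # odds / rate ratio scale
            eff, elo, ehi = np.exp(beta), np.exp(lo), np.exp(hi)
        rows.append(dict(feature=feat, effect=eff, ci_low=elo, ci_high=ehi,
                         p_value=p))
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(df.loc[ok, "p_value"].to_numpy())
    df["q_value"] = q
    return df


def _profile_nb_alpha(y: pd.Series, x: pd.DataFrame) -> float:
    """Crude method-of-moments NB dispersion from a Poisson pre-fit."""
    pois = sm.GLM(y, x, family=sm.families.Poisson()).fit()
    mu = pois.fittedvalues
    resid = ((y - mu) ** 2 - mu) / mu ** 2
    alpha = float(np.clip(resid.mean(), 1e-6, 10.0))
    return alpha
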