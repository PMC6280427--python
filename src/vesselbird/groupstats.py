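"""Downstream group comparisons.

Flight-time vs VeDBA regression, linear mixed models (REML, random
intercept per bird) of the four foraging responses on sex and interaction
status, chi-square tests of gear preference and sex differences, and the
summary tables.  Model fitting is delegated to statsmodels; the F-test
bookkeeping uses a residual denominator-df convention (observations minus
fixed-effect parameters), documented rather than asserted as the only
defensible choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .geo import DomainError

RESPONSES = ("daily_vedba_sum", "daily_flight_time_h",
             "trip_length_km", "max_colony_distance_km")


@dataclass
class ModelResult:
    response: str
    transform: str                  # 'none' or 'log'
    effects: pd.DataFrame           # term, estimate, F, df_num, df_den, p
    random_variance: float
    method: str                     # 'lmm-reml' or 'ols-fallback'

    def effect(self, term: str) -> pd.Series:
        m = self.effects[self.effects["term"] == term]
        if len(m) == 0:
            raise KeyError(term)
        return m.iloc[0]


def regress_flight_on_vedba(records: pd.DataFrame):
    """OLS of daily flight time on the daily sum of VeDBA.

    Returns (slope, intercept, F, df_num, df_den, p).
    """
    if len(records) < 3:
        raise DomainError("need >= 3 records")
    x = records["daily_vedba_sum"].to_numpy(dtype=float)
    y = records["daily_flight_time_h"].to_numpy(dtype=float)
    if np.std(x) < 1e-12:
        raise DomainError("zero-variance covariate")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    F = float(fit.tvalues[1] ** 2)
    df_den = int(fit.df_resid)
    p = float(st.f.sf(F, 1, df_den))
    return slope, intercept, F, 1, df_den, p


def _needs_log(records: pd.DataFrame, response: str, formula_rhs: str,
               alpha: float = 0.05) -> bool:
    """Normality screen: Shapiro-Wilk on residuals of the untransformed OLS."""
    y = records[response].to_numpy(dtype=float)
    if np.min(y) <= 0:
        return False
    fit = smf.ols(f"{response} ~ {formula_rhs}", data=records).fit()
    resid = fit.resid
    if len(resid) < 8 or len(resid) > 4999:
        return False
    return st.shapiro(resid).pvalue < alpha


def fit_lmm(records: pd.DataFrame, response: str,
            include_interaction: bool = True,
            log_transform: str = "auto") -> ModelResult:
    """REML linear mixed model of one response on sex and INT status with a
    random intercept per bird.

    Marginal F statistics (Wald, 1 numerator df per term) are reported with
    denominator df = observations - fixed-effect parameters.  A log
    transform is applied when the Shapiro-Wilk screen on the untransformed
    residuals fails (``log_transform='auto'``); singular or non-convergent
    fits fall back to ordinary regression with a warning.
    """
    if records["bird_id"].nunique() < 2:
        raise DomainError("need >= 2 birds")
    rhs = "sex * int_flag" if include_interaction else "sex + int_flag"
    df = records.copy()
    if log_transform == "auto":
        use_log = _needs_log(df, response, rhs)
    else:
        use_log = bool(log_transform == "log" or log_transform is True)
    yname = response
    if use_log:
        yname = f"log_{response}"
        df[yname] = np.log(df[response].astype(float))
    formula = f"{yname} ~ {rhs}"
    n = len(df)
    method = "lmm-reml"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, df, groups=df["bird_id"])
            fit = md.fit(reml=True)
        if not np.isfinite(fit.params).all():
            raise np.linalg.LinAlgError("non-finite estimates")
        params = fit.fe_params
        cov = fit.cov_params().loc[params.index, params.index]
        rand_var = float(np.asarray(fit.cov_re)[0, 0])
    except Exception as exc:  # singular random effect, convergence failure
        warnings.warn(f"mixed model for {response} failed ({exc}); "
                      "falling back to ordinary regression")
        method = "ols-fallback"
        fit = smf.ols(formula, df).fit()
        params = fit.params
        cov = fit.cov_params()
        rand_var = 0.0
    k = len(params)
    df_den = n - k
    rows = []
    for term in params.index:
        if term == "Intercept":
            continue
        est = float(params[term])
        se = float(np.sqrt(cov.loc[term, term]))
        F = (est / se) ** 2 if se > 0 else np.inf
        rows.append({"term": term, "estimate": est, "se": se, "F": F,
                     "df_num": 1, "df_den": df_den,
                     "p": float(st.f.sf(F, 1, df_den))})
    return ModelResult(response, "log" if use_log else "none",
                       pd.DataFrame(rows), rand_var, method)


def gear_preference_test(observed_by_gear: dict, fleet_by_gear: dict):
    """1-df goodness of fit of trawler vs non-trawler interaction counts
    against fleet availability proportions.

    Returns (chi2, df, p, warning_flag) where the flag marks expected
    counts below 5.
    """
    gears = set(observed_by_gear) | set(fleet_by_gear)
    if len([g for g in gears if fleet_by_gear.get(g, 0) > 0]) < 2:
        raise DomainError("need >= 2 gear classes in the fleet")
    obs_trawl = float(observed_by_gear.get("trawl", 0))
    obs_other = float(sum(v for g, v in observed_by_gear.items() if g != "trawl"))
    fleet_trawl = float(fleet_by_gear.get("trawl", 0))
    fleet_total = float(sum(fleet_by_gear.values()))
    n = obs_trawl + obs_other
    exp = np.array([fleet_trawl / fleet_total, 1.0 - fleet_trawl / fleet_total]) * n
    obs = np.array([obs_trawl, obs_other])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    p = float(st.chi2.sf(chi2, 1))
    return chi2, 1, p, bool((exp < 5).any())


def sex_interaction_test(birds: pd.DataFrame, correction: bool = False):
    """Pearson chi-square on the sex x INT 2x2 table (one row per bird).

    No continuity correction by default.  Returns (chi2, df, p).
    """
    table = pd.crosstab(birds["sex"], birds["int_flag"])
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() \
            or (table.sum(axis=1) == 0).any():
        raise DomainError("degenerate 2x2 table")
    chi2, p, dof, _ = st.chi2_contingency(table.to_numpy(), correction=correction)
    return float(chi2), int(dof), float(p)


def gear_table(fleet_by_gear: dict) -> pd.DataFrame:
    """Fleet composition with integer-rounded percentages."""
    total = sum(fleet_by_gear.values())
    rows = [{"gear": g, "n_vessels": int(n),
             "pct": int(round(100.0 * n / total))}
            for g, n in fleet_by_gear.items()]
    rows.append({"gear": "total", "n_vessels": int(total), "pct": 100})
    return pd.DataFrame(rows)


def foraging_table(records: pd.DataFrame,
                   responses: tuple = RESPONSES) -> pd.DataFrame:
    """Mean +/- SD of each response split by INT flag."""
    rows = []
    for resp in responses:
        if resp not in records.columns:
            continue
        for flag, g in records.groupby("int_flag", sort=True):
            v = g[resp].dropna().to_numpy(dtype=float)
            rows.append({"response": resp, "int_flag": flag, "n": len(v),
                         "mean": float(np.mean(v)) if len(v) else np.nan,
                         "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0})
    return pd.DataFrame(rows)


def summary_tables(records: pd.DataFrame, events: list,
                   fleet_by_gear: dict) -> dict:
    """Gear-composition and foraging-variable tables plus the per-gear
    interaction counts."""
    ev_gear = {}
    for ev in events:
        g = getattr(ev, "gear", None)
        ev_gear[g] = ev_gear.get(g, 0) + 1
    return {
        "gear": gear_table(fleet_by_gear),
        "foraging": foraging_table(records),
        "interactions_by_gear": ev_gear,
    }
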