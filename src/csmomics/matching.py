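"""Propensity-score 1:1 nearest-neighbour matching with balance checks.

Controls (survivors) are matched to cases (nonsurvivors) on the logit
of a propensity score from a logistic regression of case status on age,
HIV status and MUAC. Matching is greedy without replacement, hardest
cases (highest propensity) first, ties broken by subject id; balance is
reported as standardized mean differences (SMD) and variance ratios
before and after matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datatypes import PairSet, ValidationError

__all__ = ["fit_propensity", "nearest_neighbor_match", "balance_diagnostics", "match_cohort"]

DEFAULT_COVARIATES = ("age_months", "hiv", "muac_cm")


def _design(subjects: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        col = subjects[c]
        if c == "hiv" or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc]
        elif col.dtype == bool:
            cols[c] = col.astype(float)
        else:
            cols[c] = col.astype(float)
    X = pd.DataFrame(cols, index=subjects.index)
    keep = X.std(ddof=0) > 0  # constant columns are absorbed by the intercept
    X = X.loc[:, keep[keep].index]
    return sm.add_constant(X, has_constant="add")


def fit_propensity(
    subjects: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    ridge: float = 0.0,
) -> pd.Series:
    """Fitted P(case | covariates) for every NS/S subject.

    Maximum-likelihood logistic regression; categorical covariates
    (HIV pos/neg/unknown) enter as dummies. Perfect separation raises
    with advice to refit with a small ridge penalty (``ridge`` > 0).
    """
    pool = subjects[subjects["outcome"].isin(["NS", "S"])]
    for c in covariates:
        if pool[c].isna().any():
            raise ValidationError(f"covariate {c} has missing values")
    y = (pool["outcome"] == "NS").astype(float)
    X = _design(pool, covariates)
    model = sm.Logit(y, X)
    try:
        if ridge > 0:
            res = model.fit_regularized(alpha=ridge, L1_wt=0.0, disp=0)
        else:
            res = model.fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValidationError(
            "perfect separation in the propensity model; refit with ridge > 0"
        ) from err
    params = np.asarray(res.params, float)
    if not np.isfinite(params).all() or np.abs(params).max() > 50:
        raise ValidationError(
            "propensity model diverged (separation); refit with ridge > 0"
        )
    score = pd.Series(res.predict(X), index=pool.index, name="propensity")
    return score.clip(1e-12, 1 - 1e-12)


def nearest_neighbor_match(
    scores: pd.Series,
    cases: list[str],
    controls: list[str],
    caliper: float | None = None,
) -> PairSet:
    """Greedy 1:1 matching on |logit(score_case) - logit(score_control)|.

    Cases are processed in descending propensity order; ties (equal
    scores, equal distances) resolve by lexicographic subject id. An
    optional caliper (on the logit scale) drops matches beyond it.
    """
    if not cases or not controls:
        raise ValidationError("empty case or control set")
    logit = np.log(scores / (1 - scores))
    case_order = sorted(cases, key=lambda s: (-scores[s], s))
    available = sorted(controls)
    pairs, unmatched = [], []
    for case in case_order:
        if not available:
            unmatched.append(case)
            continue
        dists = [(abs(logit[case] - logit[ctl]), ctl) for ctl in available]
        dist, best = min(dists)
        if caliper is not None and dist > caliper:
            unmatched.append(case)
            continue
        pairs.append((case, best, float(dist)))
        available.remove(best)
    unmatched.extend(available)
    return PairSet(pairs=pairs, unmatched=unmatched)


def _smd(case_vals: np.ndarray, control_vals: np.ndarray) -> float:
    m1, m0 = case_vals.mean(), control_vals.mean()
    v1 = case_vals.var(ddof=1) if len(case_vals) > 1 else 0.0
    v0 = control_vals.var(ddof=1) if len(control_vals) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0:
        return 0.0 if m1 == m0 else float("inf")
    return float((m1 - m0) / pooled)


def _variance_ratio(case_vals, control_vals) -> float:
    v1 = case_vals.var(ddof=1) if len(case_vals) > 1 else 0.0
    v0 = control_vals.var(ddof=1) if len(control_vals) > 1 else 0.0
    return float(v1 / v0) if v0 > 0 else float("nan")


def balance_diagnostics(
    pair_set: PairSet,
    subjects: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """SMD and variance ratio per covariate, before and after matching.

    Binary/categorical covariates are expanded to level proportions.
    """
    if not pair_set.pairs:
        raise ValidationError("empty pair set")
    pool = subjects[subjects["outcome"].isin(["NS", "S"])]
    all_cases = pool.index[pool["outcome"] == "NS"]
    all_controls = pool.index[pool["outcome"] == "S"]
    rows = []
    X = _design(pool, covariates).drop(columns=["const"])
    for c in X.columns:
        v = X[c]
        rows.append(
            {
                "covariate": c,
                "smd_before": _smd(v.loc[all_cases].to_numpy(), v.loc[all_controls].to_numpy()),
                "smd_after": _smd(
                    v.loc[pair_set.case_ids].to_numpy(), v.loc[pair_set.control_ids].to_numpy()
                ),
                "vr_before": _variance_ratio(v.loc[all_cases], v.loc[all_controls]),
                "vr_after": _variance_ratio(v.loc[pair_set.case_ids], v.loc[pair_set.control_ids]),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def match_cohort(
    subjects: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    caliper: float | None = None,
    ridge: float = 0.0,
) -> tuple[PairSet, pd.DataFrame]:
    """Fit propensity, match, and return (PairSet, balance table)."""
    scores = fit_propensity(subjects, covariates, ridge=ridge)
    pool = subjects.loc[scores.index]
    cases = list(pool.index[pool["outcome"] == "NS"])
    controls = list(pool.index[pool["outcome"] == "S"])
    pair_set = nearest_neighbor_match(scores, cases, controls, caliper=caliper)
    balance = balance_diagnostics(pair_set, subjects, covariates)
    return pair_set, balance
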