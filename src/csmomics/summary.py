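"""Table-1 style cohort summaries.

Continuous variables are summarized as mean ± SD (or median [IQR]) per
outcome group with a Welch t-test; binary/categorical variables as
n (%) with a chi-square test without continuity correction, falling
back to Fisher's exact test when a 2x2 cell is zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = ["summarize_cohort"]


def _continuous_row(v: pd.Series, g: pd.Series, style: str) -> dict:
    out = {}
    groups = []
    for label in ("NS", "S"):
        x = v[(g == label) & v.notna()].astype(float)
        groups.append(x)
        if style == "median":
            out[label] = f"{x.median():.1f} [{x.quantile(0.25):.1f}-{x.quantile(0.75):.1f}]"
        else:
            out[label] = f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"
    if groups[0].std(ddof=1) == 0 and groups[1].std(ddof=1) == 0:
        out["p"] = 1.0 if groups[0].mean() == groups[1].mean() else 0.0
    else:
        out["p"] = float(stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
    out["test"] = "welch_t"
    return out


def _categorical_row(v: pd.Series, g: pd.Series) -> list[dict]:
    """One row per level: n (%) per group plus one shared test p."""
    mask = v.notna() & g.isin(["NS", "S"])
    tab = pd.crosstab(v[mask].astype(str), g[mask])
    for label in ("NS", "S"):
        if label not in tab.columns:
            tab[label] = 0
    tab = tab[["NS", "S"]]
    if (tab.to_numpy() == 0).any() and tab.shape == (2, 2):
        p = float(stats.fisher_exact(tab.to_numpy()).pvalue)
        test = "fisher_exact"
    else:
        p = float(stats.chi2_contingency(tab.to_numpy(), correction=False).pvalue)
        test = "chi2"
    rows = []
    totals = tab.sum(axis=0)
    for level in tab.index:
        row = {"level": level}
        for label in ("NS", "S"):
            n = int(tab.loc[level, label])
            denom = int(totals[label])
            pct = 100.0 * n / denom if denom else float("nan")
            row[label] = f"{n} ({pct:.1f}%)"
            row[f"{label}_n"] = n
            row[f"{label}_pct"] = pct
        row["p"] = p
        row["test"] = test
        rows.append(row)
    return rows


def summarize_cohort(
    subjects: pd.DataFrame,
    variables: list[str] | None = None,
    style: str = "mean",
) -> pd.DataFrame:
    """Per-variable descriptive statistics by outcome group with tests.

    Boolean variables report the True level only; categorical variables
    report every level sharing one test p-value.
    """
    g = subjects["outcome"]
    if variables is None:
        variables = [c for c in subjects.columns
                     if c not in ("outcome", "pair_id", "batch", "time_to_event_days")]
    rows = []
    for var in variables:
        if var not in subjects.columns:
            raise ValidationError(f"unknown variable {var!r}")
        v = subjects[var]
        if v.notna().sum() == 0:
            raise ValidationError(f"variable {var!r} is all-missing")
        if v.dtype == bool or str(v.dtype) == "boolean":
            sub = _categorical_row(v.map({True: "yes", False: "no"}), g)
            for r in sub:
                if r["level"] == "yes":
                    r["variable"] = var
                    rows.append(r)
        elif np.issubdtype(v.dtype, np.number):
            r = _continuous_row(v, g, style)
            r["variable"] = var
            r["level"] = ""
            rows.append(r)
        else:
            for r in _categorical_row(v, g):
                r["variable"] = var
                rows.append(r)
    table = pd.DataFrame(rows).set_index(["variable", "level"])
    return table
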