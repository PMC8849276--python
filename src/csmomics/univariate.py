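"""Per-analyte matched screening: conditional logistic + BH-FDR + ratios.

Each analyte (autoscaled, log10 scale) is tested one at a time with a
1:1 conditional logistic regression on the case-control differences,
optionally adjusted for a covariate (edema or WHZ) entered as an
additional difference term. P-values are BH-adjusted within the block,
and fold changes are ratios of raw-concentration group means (NS/S).

Metabolite ratios (Fischer's ratio, urea-cycle total, C2/C0,
kynurenine/tryptophan, and any user-defined numerator/denominator sums)
are computed on the raw scale and screened exactly like analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .clogit import ConditionalLogit
from .datatypes import AnalyteMatrix, PairSet, ValidationError
from .preprocess import ProcessedMatrix

__all__ = [
    "RatioDefinition",
    "BUILTIN_RATIOS",
    "UNIT",
    "bh_adjust",
    "compute_ratios",
    "screen_analytes",
]

#: sentinel denominator entry meaning "divide by 1" (plain sums)
UNIT = "unit"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, ties preserved)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class RatioDefinition:
    """A named metabolite ratio: sum(numerator) / sum(denominator).

    A denominator of ``(UNIT,)`` divides by 1, expressing plain sums
    such as the urea-cycle total.
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValidationError(f"ratio {self.name}: numerator and denominator must be non-empty")
        if set(self.numerator) & set(self.denominator) - {UNIT}:
            raise ValidationError(f"ratio {self.name}: numerator and denominator must be disjoint")


BUILTIN_RATIOS: tuple[RatioDefinition, ...] = (
    RatioDefinition("fischer_ratio", ("valine", "leucine", "isoleucine"),
                    ("tyrosine", "phenylalanine")),
    RatioDefinition("urea_cycle_total", ("citrulline", "ornithine", "arginine", "aspartate"),
                    (UNIT,)),
    RatioDefinition("C2_C0", ("C2",), ("C0",)),
    RatioDefinition("kynurenine_tryptophan", ("kynurenine",), ("tryptophan",)),
)


def compute_ratios(
    raw: pd.DataFrame | AnalyteMatrix,
    definitions=BUILTIN_RATIOS,
) -> AnalyteMatrix:
    """Per-subject ratio values on the raw concentration scale."""
    df = raw.values if isinstance(raw, AnalyteMatrix) else raw
    cols = set(df.columns)
    out = {}
    for rd in definitions:
        missing = (set(rd.numerator) | set(rd.denominator)) - cols - {UNIT}
        if missing:
            raise ValidationError(f"ratio {rd.name}: missing analytes {sorted(missing)}")
        num = df[list(rd.numerator)].sum(axis=1)
        if tuple(rd.denominator) == (UNIT,):
            den = pd.Series(1.0, index=df.index)
        else:
            den = df[list(rd.denominator)].sum(axis=1)
        if (den == 0).any():
            bad = list(den.index[den == 0])
            raise ValidationError(f"ratio {rd.name}: zero denominator for subjects {bad[:5]}")
        out[rd.name] = num / den
    values = pd.DataFrame(out)
    return AnalyteMatrix(
        block="metabolite",
        values=values,
        mask=pd.DataFrame(False, index=values.index, columns=values.columns),
        classes=pd.Series("ratio", index=values.columns, name="class"),
    )


def _pair_diffs(values: pd.DataFrame, pairs: PairSet) -> pd.DataFrame:
    missing = [s for s in pairs.member_ids() if s not in values.index]
    if missing:
        raise ValidationError(f"paired subjects absent from matrix: {missing[:5]}")
    case = values.loc[pairs.case_ids].to_numpy(float)
    control = values.loc[pairs.control_ids].to_numpy(float)
    return pd.DataFrame(case - control, index=[p[0] for p in pairs.pairs], columns=values.columns)


def screen_analytes(
    processed: ProcessedMatrix,
    pairs: PairSet,
    raw: pd.DataFrame | AnalyteMatrix | None = None,
    adjust_for: pd.Series | None = None,
    sig_on: str = "q",
    sig_threshold: float = 0.01,
    fold_change_method: str = "arithmetic",
) -> pd.DataFrame:
    """Univariate conditional-logistic screen of every analyte.

    Parameters
    ----------
    processed : autoscaled matrix (subjects x analytes).
    pairs : the 1:1 matching structure.
    raw : raw concentrations for fold changes (NS/S ratio of group
        means); fold change is NaN when omitted.
    adjust_for : per-subject covariate (e.g. edema as 0/1, or WHZ); its
        case-control difference enters each model as a second term.
    sig_on, sig_threshold : the block's top-significance rule — ``q`` <
        0.01 for metabolites, ``p`` < 0.05 for proteins/cytokines.

    Returns a table with beta (log-odds per SD), se, wald_z, p, q,
    fold_change, separated and top_significant per analyte.
    """
    if sig_on not in ("p", "q"):
        raise ValidationError("sig_on must be 'p' or 'q'")
    diffs = _pair_diffs(processed.values, pairs)
    cov_diff = None
    if adjust_for is not None:
        cov = adjust_for.astype(float)
        cov_diff = (cov.loc[pairs.case_ids].to_numpy() - cov.loc[pairs.control_ids].to_numpy())

    rows = []
    for a in processed.values.columns:
        d = diffs[a].to_numpy()
        if np.abs(d).max() == 0:
            rows.append({"analyte": a, "beta": 0.0, "se": np.inf, "wald_z": 0.0,
                         "p": 1.0, "separated": False})
            continue
        if cov_diff is not None and np.abs(cov_diff).max() > 0:
            x = pd.DataFrame({a: d, "covariate": cov_diff})
        else:
            x = pd.DataFrame({a: d})
        res = ConditionalLogit(x).fit()
        rows.append(
            {
                "analyte": a,
                "beta": float(res.params[a]),
                "se": float(res.bse[a]),
                "wald_z": float(res.tvalues[a]),
                "p": float(res.pvalues[a]),
                "separated": res.separated,
            }
        )
    table = pd.DataFrame(rows).set_index("analyte")
    table["q"] = bh_adjust(table["p"].to_numpy())

    if raw is not None:
        raw_df = raw.values if isinstance(raw, AnalyteMatrix) else raw
        if fold_change_method == "geometric":
            ns_mean = np.exp(np.log(raw_df.loc[pairs.case_ids]).mean(axis=0))
            s_mean = np.exp(np.log(raw_df.loc[pairs.control_ids]).mean(axis=0))
        elif fold_change_method == "arithmetic":
            ns_mean = raw_df.loc[pairs.case_ids].mean(axis=0)
            s_mean = raw_df.loc[pairs.control_ids].mean(axis=0)
        else:
            raise ValidationError("fold_change_method must be 'arithmetic' or 'geometric'")
        table["fold_change"] = (ns_mean / s_mean).reindex(table.index)
    else:
        table["fold_change"] = np.nan

    crit = table["q"] if sig_on == "q" else table["p"]
    table["top_significant"] = crit < sig_threshold
    # volcano-plot-ready columns
    table["log2_fc"] = np.log2(table["fold_change"])
    table["neglog10_q"] = -np.log10(np.clip(table["q"], 1e-300, None))
    return table
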