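"""QC filtering, imputation, batch correction and transformation.

The preprocessing contract for each block mirrors targeted-metabolomics
and TMT-proteomics practice:

* metabolites: keep analytes with QC-replicate CV < 30% (sd/mean on the
  raw scale) that are detected in at least 80% of samples in either
  outcome group; impute remaining non-detects at LOD/2;
* proteins: drop analytes missing in > 20% of subjects, k-nearest-
  neighbour imputation of the rest, location/scale (ComBat-style) batch
  correction with parametric empirical-Bayes shrinkage;
* all blocks: log10-transform, mean-centre and scale each analyte to
  unit variance (autoscaling) before any model fitting.

Every removal is recorded in a :class:`QCReport` with a reason code so
that assayed = retained + reasoned removals always balances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .datatypes import AnalyteMatrix, ValidationError

__all__ = [
    "QCReport",
    "ProcessedMatrix",
    "cv_detection_filter",
    "impute_lod",
    "protein_missingness_filter",
    "knn_impute",
    "batch_correct",
    "transform_autoscale",
    "autoscale",
]

REASONS = ("cv_fail", "detection_fail", "missingness_fail")


@dataclass
class QCReport:
    """Per-analyte QC decisions for one block.

    ``table`` has one row per assayed analyte with columns ``cv``,
    ``detect_NS``, ``detect_S``, ``missing_frac`` (whichever apply),
    ``retained`` and ``reasons`` (comma-joined reason codes, empty when
    retained).
    """

    block: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        removed = self.table[~self.table["retained"]]
        if (removed["reasons"] == "").any():
            raise ValidationError("every removed analyte needs at least one reason")

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    @property
    def removed(self) -> list[str]:
        return list(self.table.index[~self.table["retained"]])

    def summary(self) -> dict:
        reasons = {}
        for r in REASONS:
            reasons[r] = int(self.table["reasons"].str.contains(r).sum())
        return {
            "block": self.block,
            "assayed": int(len(self.table)),
            "retained": len(self.retained),
            "removed": len(self.removed),
            "removed_by_reason": reasons,
        }


@dataclass
class ProcessedMatrix:
    """Autoscaled log10 analyte matrix ready for model fitting."""

    values: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("ProcessedMatrix must not contain missing values")
        v = self.values.to_numpy(float)
        if v.shape[1]:
            mu = np.abs(v.mean(axis=0)).max()
            sd = np.abs(v.std(axis=0, ddof=1) - 1).max()
            if mu > 1e-8 or sd > 1e-8:
                raise ValidationError(
                    f"ProcessedMatrix columns must be autoscaled (|mean|max={mu:.2e}, "
                    f"|sd-1|max={sd:.2e})"
                )

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)


def _as_group_series(groups, index: pd.Index) -> pd.Series:
    if isinstance(groups, pd.Series):
        g = groups.reindex(index)
    else:  # mapping group -> list of subject ids
        g = pd.Series(index=index, dtype=object)
        for label, ids in groups.items():
            g.loc[list(ids)] = label
    return g


def cv_detection_filter(
    matrix: AnalyteMatrix,
    qc: pd.DataFrame,
    groups,
    cv_max: float = 0.30,
    detect_min: float = 0.80,
) -> tuple[AnalyteMatrix, QCReport]:
    """Retain analytes with QC CV < ``cv_max`` and detection fraction
    >= ``detect_min`` in either outcome group.

    ``groups`` maps subjects to "NS"/"S" (a Series, or a dict of id
    lists); subjects outside both groups are ignored for detection.
    """
    missing_qc = [a for a in matrix.analyte_ids if a not in qc.columns]
    if missing_qc:
        raise ValidationError(f"analytes missing from QC matrix: {missing_qc[:5]}")
    g = _as_group_series(groups, matrix.values.index)
    sel_ns = (g == "NS").to_numpy()
    sel_s = (g == "S").to_numpy()
    detect_ns = 1.0 - matrix.mask.loc[sel_ns].mean(axis=0) if sel_ns.any() else pd.Series(1.0, index=matrix.values.columns)
    detect_s = 1.0 - matrix.mask.loc[sel_s].mean(axis=0) if sel_s.any() else pd.Series(1.0, index=matrix.values.columns)

    rows = []
    for a in matrix.analyte_ids:
        rep = qc[a].to_numpy(float)
        mean = rep.mean()
        cv = np.nan if mean == 0 else rep.std(ddof=1) / mean
        det = {"NS": float(detect_ns[a]), "S": float(detect_s[a])}
        reasons = []
        if not (np.isfinite(cv) and cv < cv_max):
            reasons.append("cv_fail")
        if not (det["NS"] >= detect_min or det["S"] >= detect_min):
            reasons.append("detection_fail")
        rows.append(
            {
                "analyte": a,
                "cv": cv,
                "detect_NS": det["NS"],
                "detect_S": det["S"],
                "retained": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    table = pd.DataFrame(rows).set_index("analyte")
    report = QCReport(block=matrix.block, table=table)
    return matrix.subset_analytes(report.retained), report


def impute_lod(matrix: AnalyteMatrix) -> AnalyteMatrix:
    """Replace non-detected cells by LOD/2; detected values untouched."""
    mask = matrix.mask.to_numpy()
    if not mask.any():
        return matrix
    if matrix.lod is None:
        raise ValidationError("LOD imputation requires per-analyte LODs")
    lod = matrix.lod.reindex(matrix.values.columns)
    need = mask.any(axis=0)
    bad = [a for a, n in zip(matrix.values.columns, need) if n and not np.isfinite(lod[a])]
    if bad:
        raise ValidationError(f"analytes with non-detects but no LOD: {bad[:5]}")
    values = matrix.values.copy()
    filled = np.where(mask, (lod / 2.0).to_numpy(float)[None, :], values.to_numpy(float))
    values.iloc[:, :] = filled
    return AnalyteMatrix(
        block=matrix.block,
        values=values,
        mask=pd.DataFrame(False, index=values.index, columns=values.columns),
        classes=matrix.classes.copy(),
        lod=matrix.lod.copy(),
    )


def protein_missingness_filter(
    matrix: AnalyteMatrix, max_missing: float = 0.20
) -> tuple[AnalyteMatrix, QCReport]:
    """Drop analytes whose missing fraction exceeds ``max_missing``."""
    frac = matrix.mask.mean(axis=0)
    table = pd.DataFrame(
        {
            "missing_frac": frac,
            "retained": frac <= max_missing,
            "reasons": np.where(frac <= max_missing, "", "missingness_fail"),
        }
    )
    table.index.name = "analyte"
    report = QCReport(block=matrix.block, table=table)
    if not report.retained:
        raise ValidationError("no analytes left after missingness filtering")
    return matrix.subset_analytes(report.retained), report


def knn_impute(matrix: AnalyteMatrix, k: int = 10) -> AnalyteMatrix:
    """Impute missing cells by the mean of the k nearest subjects.

    Neighbours by Euclidean distance over shared observed analytes
    (nan-Euclidean, sklearn convention); observed cells are untouched.
    """
    if k >= matrix.n_subjects:
        raise ValidationError(f"k={k} must be below the number of subjects ({matrix.n_subjects})")
    obs = matrix.observed()
    if obs.notna().sum(axis=1).min() == 0:
        empty = obs.index[obs.notna().sum(axis=1) == 0]
        raise ValidationError(f"subjects with no observed values: {list(empty[:5])}")
    if not matrix.mask.to_numpy().any():
        return matrix
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(obs.to_numpy(float))
    values = pd.DataFrame(filled, index=obs.index, columns=obs.columns)
    return AnalyteMatrix(
        block=matrix.block,
        values=values,
        mask=pd.DataFrame(False, index=values.index, columns=values.columns),
        classes=matrix.classes.copy(),
        lod=None if matrix.lod is None else matrix.lod.copy(),
    )


# ---------------------------------------------------------------------------
# ComBat-style batch correction


def _eb_shrink(gamma_hat, delta2_hat, n_b, tol=1e-6, max_iter=500):
    """Parametric empirical-Bayes shrinkage of one batch's location/scale
    parameters toward their across-analyte moments (ComBat iteration)."""
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    # inverse-gamma prior moments for delta2
    v = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1) if delta2_hat.size > 1 else 0.0
    lam = (v**2 + 2 * s2) / s2 if s2 > 0 else 2.0 + 1e6
    theta = (v**3 + v * s2) / s2 if s2 > 0 else v * (lam - 1.0)
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + delta2_star * gamma_bar) / (n_b * tau2 + delta2_star)
        ssr = delta2_hat * (n_b - 1) + n_b * (gamma_hat - g_new) ** 2
        d_new = (theta + 0.5 * ssr) / (n_b / 2.0 + lam - 1.0)
        change = max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta2_star).max())
        gamma_star, delta2_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta2_star


def combat_adjust(values: np.ndarray, batches: np.ndarray, shrinkage: bool = True) -> np.ndarray:
    """Location/scale batch adjustment of a subjects x analytes array
    (already on the modelling scale), ComBat-style."""
    values = np.asarray(values, float)
    batches = np.asarray(batches)
    labels = pd.unique(batches)
    if len(labels) == 1:
        return values.copy()
    sizes = {b: int((batches == b).sum()) for b in labels}
    if min(sizes.values()) < 2 and not shrinkage:
        small = [b for b, s in sizes.items() if s < 2]
        raise ValidationError(f"singleton batches {small} need shrinkage=True")

    alpha = values.mean(axis=0)
    resid = values.copy()
    for b in labels:
        sel = batches == b
        resid[sel] -= values[sel].mean(axis=0)
    sigma = np.sqrt((resid**2).sum(axis=0) / values.shape[0])
    sigma[sigma == 0] = 1.0
    z = (values - alpha) / sigma

    out = np.empty_like(z)
    for b in labels:
        sel = batches == b
        n_b = sel.sum()
        gamma_hat = z[sel].mean(axis=0)
        delta2_hat = z[sel].var(axis=0, ddof=1) if n_b > 1 else np.ones(z.shape[1])
        delta2_hat = np.clip(delta2_hat, 1e-8, None)
        if shrinkage:
            gamma, delta2 = _eb_shrink(gamma_hat, delta2_hat, n_b)
        else:
            gamma, delta2 = gamma_hat, delta2_hat
        out[sel] = (z[sel] - gamma) / np.sqrt(np.clip(delta2, 1e-8, None))
    return out * sigma + alpha


def batch_correct(
    matrix: AnalyteMatrix, batch_labels: pd.Series | None = None, shrinkage: bool = True
) -> AnalyteMatrix:
    """Batch-correct an analyte block on the log10 scale.

    Adjusts each analyte's per-batch location and scale against the
    pooled mean/variance (with optional empirical-Bayes shrinkage of the
    batch parameters), then back-transforms to the concentration scale.
    """
    if matrix.mask.to_numpy().any():
        raise ValidationError("impute missing values before batch correction")
    if batch_labels is None:
        raise ValidationError("batch labels required")
    batches = batch_labels.reindex(matrix.values.index).to_numpy()
    if pd.isna(batches).any():
        raise ValidationError("batch label missing for some subjects")
    vals = matrix.values.to_numpy(float)
    if np.any(vals <= 0):
        raise ValidationError("batch correction requires strictly positive concentrations")
    corrected = 10.0 ** combat_adjust(np.log10(vals), batches, shrinkage=shrinkage)
    values = pd.DataFrame(corrected, index=matrix.values.index, columns=matrix.values.columns)
    return AnalyteMatrix(
        block=matrix.block,
        values=values,
        mask=matrix.mask.copy(),
        classes=matrix.classes.copy(),
        lod=None if matrix.lod is None else matrix.lod.copy(),
    )


# ---------------------------------------------------------------------------
# transformation


def autoscale(df: pd.DataFrame, provenance: list[dict] | None = None) -> ProcessedMatrix:
    """Mean-centre and unit-variance scale each column (no log)."""
    v = df.to_numpy(float)
    sd = v.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(df.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped[:5]}", stacklevel=2)
        df = df.loc[:, df.columns[keep]]
        v, sd = v[:, keep], sd[keep]
    scaled = (v - v.mean(axis=0)) / sd
    steps = list(provenance or []) + [{"step": "autoscale", "ddof": 1}]
    return ProcessedMatrix(values=pd.DataFrame(scaled, index=df.index, columns=df.columns),
                           provenance=steps)


def transform_autoscale(matrix: AnalyteMatrix | pd.DataFrame) -> ProcessedMatrix:
    """log10-transform then autoscale every analyte."""
    df = matrix.values if isinstance(matrix, AnalyteMatrix) else matrix
    if isinstance(matrix, AnalyteMatrix) and matrix.mask.to_numpy().any():
        raise ValidationError("impute missing values before transformation")
    if df.isna().any().any():
        raise ValidationError("missing values present; impute first")
    v = df.to_numpy(float)
    if np.any(v <= 0):
        r, c = np.argwhere(v <= 0)[0]
        raise ValidationError(
            f"non-positive value at subject {df.index[r]!r}, analyte {df.columns[c]!r}; "
            "log10 undefined"
        )
    logged = pd.DataFrame(np.log10(v), index=df.index, columns=df.columns)
    return autoscale(logged, provenance=[{"step": "log10"}])
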