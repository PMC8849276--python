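"""Multilevel PLS-DA for 1:1 matched designs.

The within-pair (multilevel) transformation removes between-pair
variation: every subject's row is replaced by its deviation from the
pair mean, so each member carries plus/minus half the case-control
difference. PLS1 (NIPALS) is then fitted against the class response
y in {-1, +1}: iteratively extract a unit-norm weight w proportional to
X'y, score t = Xw, then deflate X by the rank-one component t p'.

Cross-validation assigns whole pairs to folds; held-out pairs are
decomposed with their own pair means (no labels needed). Performance
per repeat: pooled ROC AUC, misclassification at y_hat = 0, training
R-squared, and the discriminant Q-squared (DQ2) in which a held-out
residual is zeroed when the prediction is on the correct side of the
label with at least unit magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .datatypes import PairSet, ValidationError
from .preprocess import ProcessedMatrix

__all__ = ["within_pair_decompose", "MultilevelPLSDA", "PLSDAResults", "CVPerformance", "fit_plsda"]


def within_pair_decompose(X: pd.DataFrame | ProcessedMatrix, pairs: PairSet) -> pd.DataFrame:
    """Subtract each pair's mean row from both members."""
    df = X.values if isinstance(X, ProcessedMatrix) else X
    members = pairs.member_ids()
    missing = [s for s in members if s not in df.index]
    if missing:
        raise ValidationError(f"unpaired or absent subjects: {missing[:5]}")
    out = df.loc[members].copy().astype(float)
    v = out.to_numpy()
    half = (v[0::2] - v[1::2]) / 2.0
    v[0::2] = half
    v[1::2] = -half
    return out


def _nipals(X: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 NIPALS; returns (W, P, T, q, x_var_explained)."""
    n, p = X.shape
    Xd = X.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    total_ss = (X**2).sum()
    extracted = 0
    for k in range(n_components):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-24:
            break
        p_load = Xd.T @ t / tt
        q[k] = (y @ t) / tt
        Xd -= np.outer(t, p_load)
        W[:, k], P[:, k], T[:, k] = w, p_load, t
        extracted += 1
    W, P, T, q = W[:, :extracted], P[:, :extracted], T[:, :extracted], q[:extracted]
    comp_ss = (T**2).sum(axis=0) * (P**2).sum(axis=0)
    x_var = comp_ss / total_ss if total_ss > 0 else np.zeros(extracted)
    return W, P, T, q, x_var


@dataclass
class PLSDAResults:
    """Fitted multilevel PLS-DA: weights, loadings, scores and fit."""

    weights: pd.DataFrame        # analytes x components, unit-norm columns
    x_loadings: pd.DataFrame
    scores: pd.DataFrame         # subjects x components
    y_loadings: np.ndarray
    x_variance_explained: np.ndarray
    correlation_circle: pd.DataFrame  # corr(analyte, score) per component
    r2: float                    # training variance of y explained (DR2)
    analytes: list[str]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def coefficients(self) -> np.ndarray:
        """Regression vector b with y_hat = X_within b."""
        W, P, q = self.weights.to_numpy(), self.x_loadings.to_numpy(), self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X_within: pd.DataFrame | np.ndarray) -> np.ndarray:
        v = X_within.to_numpy(float) if isinstance(X_within, pd.DataFrame) else np.asarray(X_within, float)
        return v @ self.coefficients()

    def summary(self) -> dict:
        return {
            "n_components": self.n_components,
            "x_variance_explained": [round(float(v), 4) for v in self.x_variance_explained],
            "r2": round(float(self.r2), 4),
        }


@dataclass
class CVPerformance:
    """Mean +/- SD over repeats of the cross-validated metrics."""

    auc: np.ndarray
    misclassification: np.ndarray
    r2: np.ndarray
    dq2: np.ndarray

    def summary(self) -> dict:
        out = {}
        for name in ("auc", "misclassification", "r2", "dq2"):
            v = getattr(self, name)
            out[name] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        return out


def _discounted(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Residuals with no penalty beyond the correct class label."""
    correct = (np.sign(yhat) == np.sign(y)) & (np.abs(yhat) >= 1.0)
    return np.where(correct, 0.0, y - yhat)


def fit_plsda(X_within: pd.DataFrame, y: np.ndarray, n_components: int = 2) -> PLSDAResults:
    """Fit PLS1 on an already within-pair-decomposed matrix."""
    X = X_within.to_numpy(float)
    if X.shape[1] == 0 or np.allclose(X, 0):
        raise ValidationError("zero-variance X")
    y = np.asarray(y, float)
    W, P, T, q, x_var = _nipals(X, y, n_components)
    if W.shape[1] == 0:
        raise ValidationError("no PLS component could be extracted (y orthogonal to X)")
    comps = [f"comp{k + 1}" for k in range(W.shape[1])]
    yhat = T @ q
    ybar = y.mean()
    denom = ((y - ybar) ** 2).sum()
    # discriminant R2 (DR2): training residuals discounted exactly like
    # DQ2 — zero once the prediction is past the correct class label —
    # so that held-out DQ2 is comparable to (and bounded by) the fit
    r2 = float(1.0 - (_discounted(y, yhat) ** 2).sum() / denom) if denom > 0 else 0.0
    # correlation circle: analyte vs score correlations on the input X
    cc = np.zeros((X.shape[1], W.shape[1]))
    xs = X.std(axis=0, ddof=1)
    ts = T.std(axis=0, ddof=1)
    for k in range(W.shape[1]):
        ok = (xs > 0) & (ts[k] > 0)
        cc[ok, k] = ((X[:, ok] - X[:, ok].mean(0)) * (T[:, k] - T[:, k].mean())[:, None]).sum(0) / (
            (X.shape[0] - 1) * xs[ok] * ts[k]
        )
    analytes = list(X_within.columns)
    return PLSDAResults(
        weights=pd.DataFrame(W, index=analytes, columns=comps),
        x_loadings=pd.DataFrame(P, index=analytes, columns=comps),
        scores=pd.DataFrame(T, index=X_within.index, columns=comps),
        y_loadings=q,
        x_variance_explained=x_var,
        correlation_circle=pd.DataFrame(cc, index=analytes, columns=comps),
        r2=r2,
        analytes=analytes,
    )


class MultilevelPLSDA:
    """Model: multilevel PLS-DA on a processed matrix and its PairSet.

    ``fit()`` decomposes within pairs and fits PLS1 with cases coded +1,
    controls -1; ``cross_validate()`` reports the fold-held-out
    performance distribution.
    """

    def __init__(
        self,
        X: ProcessedMatrix | pd.DataFrame,
        pairs: PairSet,
        n_components: int = 2,
    ) -> None:
        self.Xdf = X.values if isinstance(X, ProcessedMatrix) else X
        self.pairs = pairs
        self.n_components = n_components

    def _y(self) -> np.ndarray:
        return np.tile([1.0, -1.0], self.pairs.n_pairs)

    def fit(self) -> PLSDAResults:
        Xw = within_pair_decompose(self.Xdf, self.pairs)
        return fit_plsda(Xw, self._y(), self.n_components)

    def cross_validate(
        self,
        n_folds: int = 10,
        n_repeats: int = 50,
        seed: int | None = None,
        n_components: int | None = None,
    ) -> CVPerformance:
        if seed is None:
            raise ValidationError("seed must be set")
        ncomp = n_components or self.n_components
        n_pairs = self.pairs.n_pairs
        if n_pairs < n_folds:
            raise ValidationError("fewer pairs than folds")
        Xw_all = within_pair_decompose(self.Xdf, self.pairs)
        X = Xw_all.to_numpy(float)
        y = self._y()
        rng = np.random.default_rng(seed)
        auc, mis, r2s, dq2s = [], [], [], []
        for _rep in range(n_repeats):
            fold_of_pair = np.arange(n_pairs) % n_folds
            rng.shuffle(fold_of_pair)
            fold = np.repeat(fold_of_pair, 2)
            yhat = np.zeros_like(y)
            fold_r2 = []
            for f in range(n_folds):
                test = fold == f
                train = ~test
                Wp = fit_plsda(Xw_all.iloc[train], y[train], ncomp)
                fold_r2.append(Wp.r2)
                yhat[test] = X[test] @ Wp.coefficients()
            auc.append(roc_auc_score((y > 0).astype(int), yhat))
            mis.append(float(((yhat >= 0) != (y > 0)).mean()))
            e_disc = _discounted(y, yhat)
            denom = ((y - y.mean()) ** 2).sum()
            dq2s.append(float(1.0 - (e_disc**2).sum() / denom))
            r2s.append(float(np.mean(fold_r2)))
        return CVPerformance(
            auc=np.array(auc),
            misclassification=np.array(mis),
            r2=np.array(r2s),
            dq2=np.array(dq2s),
        )
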