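"""Conditional logistic regression for 1:1 matched pairs.

For 1:1 case-control pairs the conditional likelihood reduces to an
intercept-free logistic regression on the within-pair covariate
differences d_i = x_case - x_control with all responses equal to 1:

    L(beta) = prod_i sigma(beta' d_i),    sigma(t) = 1/(1+e^-t)

which this module maximises by Newton-Raphson. Wald tests come from the
observed information; under separation (some linear combination of the
differences never changes sign) the MLE diverges, the affected
coefficients are flagged and the p-value falls back to the score test
at beta = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = ["ConditionalLogit", "ConditionalLogitResults", "fit_clogit_1to1"]

_BETA_DIVERGED = 15.0  # |beta| beyond this on autoscaled data means separation


class ConditionalLogit:
    """Model: 1:1 matched conditional logistic regression.

    Parameters
    ----------
    pair_diffs : (n_pairs, k) array or DataFrame of case-control
        covariate differences.
    """

    def __init__(self, pair_diffs) -> None:
        if isinstance(pair_diffs, pd.DataFrame):
            self.exog_names = list(pair_diffs.columns)
            d = pair_diffs.to_numpy(float)
        else:
            d = np.asarray(pair_diffs, float)
            if d.ndim == 1:
                d = d[:, None]
            self.exog_names = [f"x{j}" for j in range(d.shape[1])]
        if d.shape[0] < 2:
            raise ValidationError("need at least 2 pairs")
        if not np.isfinite(d).all():
            raise ValidationError("non-finite pair differences")
        zero_cols = np.where(np.abs(d).max(axis=0) == 0)[0]
        if zero_cols.size:
            raise ValidationError(
                f"all-zero difference columns: {[self.exog_names[j] for j in zero_cols]}"
            )
        self.diffs = d

    # -- likelihood pieces ---------------------------------------------------
    def loglike(self, beta: np.ndarray) -> float:
        eta = self.diffs @ beta
        return float(-np.logaddexp(0.0, -eta).sum())

    def score(self, beta: np.ndarray) -> np.ndarray:
        eta = self.diffs @ beta
        return self.diffs.T @ (1.0 - _sigmoid(eta))

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        p = _sigmoid(self.diffs @ beta)
        w = p * (1.0 - p)
        return -(self.diffs * w[:, None]).T @ self.diffs

    def score_test(self) -> tuple[float, float]:
        """Rao score test of beta = 0; returns (chi2, p)."""
        u = self.diffs.sum(axis=0) / 2.0
        info = self.diffs.T @ self.diffs / 4.0
        stat = float(u @ np.linalg.solve(info, u))
        p = float(stats.chi2.sf(stat, df=self.diffs.shape[1]))
        return stat, p

    def fit(self, maxiter: int = 50, tol: float = 1e-8) -> "ConditionalLogitResults":
        d = self.diffs
        beta = np.zeros(d.shape[1])
        converged = False
        for _ in range(maxiter):
            u = self.score(beta)
            if np.abs(u).max() < tol:
                converged = True
                break
            h = self.hessian(beta)
            try:
                step = np.linalg.solve(h, -u)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h, -u, rcond=None)[0]
            # dampen huge steps (separation drives beta to infinity)
            norm = np.abs(step).max()
            if norm > 5.0:
                step *= 5.0 / norm
            beta = beta + step
            if np.abs(beta).max() > _BETA_DIVERGED:
                break
        separated = (not converged) and np.abs(beta).max() >= _BETA_DIVERGED * 0.99
        h = self.hessian(beta)
        try:
            cov = np.linalg.inv(-h)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-h)
        return ConditionalLogitResults(self, beta, cov, converged, separated)


class ConditionalLogitResults:
    """Estimates, uncertainties and tests from :class:`ConditionalLogit`."""

    def __init__(self, model, beta, cov, converged, separated) -> None:
        self.model = model
        self._beta = np.asarray(beta, float)
        self._cov = np.asarray(cov, float)
        self.converged = bool(converged)
        self.separated = bool(separated)
        self.nobs = model.diffs.shape[0]

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=self.model.exog_names, name="coef")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov)), index=self.model.exog_names, name="se")

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.model.exog_names, columns=self.model.exog_names)

    @property
    def tvalues(self) -> pd.Series:
        return (self.params / self.bse).rename("z")

    @property
    def pvalues(self) -> pd.Series:
        """Wald p-values; under separation, the score-test p for every
        coefficient (the Wald statistic is meaningless there)."""
        if self.separated:
            _, p = self.model.score_test()
            return pd.Series(p, index=self.model.exog_names, name="p")
        z = self.tvalues.to_numpy()
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.model.exog_names, name="p")

    @property
    def llf(self) -> float:
        return self.model.loglike(self._beta)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.tvalues,
                "p": self.pvalues,
                "OR": np.exp(self.params),
            }
        )
        out.attrs["n_pairs"] = self.nobs
        out.attrs["converged"] = self.converged
        out.attrs["separated"] = self.separated
        return out


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fit_clogit_1to1(pair_diffs) -> ConditionalLogitResults:
    """Convenience wrapper: fit and return results in one call."""
    return ConditionalLogit(pair_diffs).fit()
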