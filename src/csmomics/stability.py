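"""Bootstrap elastic-net stability selection over matched pairs.

The multivariable arm of the screen: an elastic-net logistic model
(alpha = 0.75) is refitted on B = 200 bootstrap resamples of the matched
pairs; within each resample lambda is tuned by five-fold
cross-validated misclassification error (folds keep pairs together,
which also stratifies the outcome), the model is refitted at the chosen
lambda, and the nonzero support is recorded. Analytes selected in more
than 70% of resamples are "influential". The differential set is the
union of the univariate top-significant analytes and the influential
analytes.

The resampling unit is the matched pair, preserving the 1:1 design; the
elastic-net likelihood itself is unconditional logistic on the
case/control labels. Per-iteration RNG streams are spawned from the
master seed, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PairSet, ValidationError
from .enet import enet_logistic_path, fit_enet_logistic, lambda_grid, predict_proba
from .preprocess import ProcessedMatrix

__all__ = [
    "StabilitySelection",
    "SelectionProfile",
    "DifferentialSet",
    "tune_lambda_cv",
    "bootstrap_selection",
    "union_differential",
]


def _pair_folds(n_pairs: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per pair; whole pairs stay together, so every fold holds
    both classes as long as it holds at least one pair."""
    folds = np.arange(n_pairs) % n_folds
    rng.shuffle(folds)
    return folds


def tune_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    pair_index: np.ndarray,
    alpha: float,
    n_folds: int = 5,
    lambdas: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Pick lambda minimising mean CV misclassification (threshold 0.5).

    ``pair_index`` maps each row of X to its pair; folds are assigned at
    the pair level. Ties resolve to the largest (most parsimonious)
    lambda. Returns (lambda_opt, mean error per grid point).
    """
    rng = rng or np.random.default_rng(0)
    if lambdas is None:
        lambdas = lambda_grid(X, y, alpha)
    lambdas = np.asarray(lambdas, float)
    if np.any(np.diff(lambdas) > 0):
        raise ValidationError("lambda grid must be descending")
    pairs = np.unique(pair_index)
    if len(pairs) < n_folds:
        raise ValidationError("fewer pairs than folds")
    fold_of_pair = dict(zip(pairs, _pair_folds(len(pairs), n_folds, rng)))
    fold = np.array([fold_of_pair[p] for p in pair_index])

    errors = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        test = fold == f
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValidationError("degenerate single-class fold")
        betas, b0s = enet_logistic_path(X[train], y[train], alpha, lambdas, tol=tol)
        proba = predict_proba(X[test], betas.T, b0s)  # (n_test, n_lambda)
        pred = proba >= 0.5
        errors[f] = (pred != y[test, None]).mean(axis=0)
    mean_err = errors.mean(axis=0)
    best = int(np.argmin(mean_err))  # first index = largest lambda on ties
    return float(lambdas[best]), mean_err


@dataclass
class SelectionProfile:
    """Per-analyte bootstrap selection frequencies (the Results object)."""

    frequencies: pd.Series
    mean_coef: pd.Series
    B: int
    alpha: float
    threshold: float
    seed: int
    n_redrawn: int = 0

    @property
    def influential(self) -> pd.Series:
        return (self.frequencies > self.threshold).rename("influential")

    @property
    def influential_set(self) -> list[str]:
        return list(self.frequencies.index[self.frequencies > self.threshold])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "selection_frequency": self.frequencies,
                "mean_coef": self.mean_coef,
                "influential": self.influential,
            }
        ).sort_values("selection_frequency", ascending=False)


class StabilitySelection:
    """Model: bootstrap elastic-net selection on a processed block.

    Parameters
    ----------
    X : autoscaled subjects x analytes matrix (ProcessedMatrix or
        DataFrame) containing every paired subject.
    pairs : the matched PairSet; resampling and CV folds operate on
        whole pairs. Cases (NS) are coded y=1.
    """

    def __init__(
        self,
        X: ProcessedMatrix | pd.DataFrame,
        pairs: PairSet,
        B: int = 200,
        alpha: float = 0.75,
        threshold: float = 0.70,
        n_folds: int = 5,
        n_lambda: int = 100,
        cv_tol: float = 3e-3,
        seed: int | None = None,
    ) -> None:
        df = X.values if isinstance(X, ProcessedMatrix) else X
        missing = [s for s in pairs.member_ids() if s not in df.index]
        if missing:
            raise ValidationError(f"paired subjects absent from matrix: {missing[:5]}")
        if B < 1:
            raise ValidationError("B must be >= 1")
        if seed is None:
            raise ValidationError("seed must be set")
        self.analytes = list(df.columns)
        order = pairs.member_ids()  # case, control, case, control, ...
        self.X = np.ascontiguousarray(df.loc[order].to_numpy(float))
        self.y = np.tile([1.0, 0.0], pairs.n_pairs)
        self.pair_index = np.repeat(np.arange(pairs.n_pairs), 2)
        self.n_pairs = pairs.n_pairs
        self.B, self.alpha, self.threshold = B, alpha, threshold
        self.n_folds, self.n_lambda, self.seed = n_folds, n_lambda, seed
        # CV paths rank lambdas by misclassification counts, which are
        # insensitive to small coefficient perturbations; the final fit
        # per bootstrap uses the tight tolerance
        self.cv_tol = cv_tol

    def _one_bootstrap(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
        """Support indicator and coefficients for one pair resample."""
        redrawn = 0
        for _ in range(100):
            take = rng.integers(0, self.n_pairs, size=self.n_pairs)
            rows = np.empty(2 * self.n_pairs, dtype=np.int64)
            rows[0::2] = 2 * take
            rows[1::2] = 2 * take + 1
            Xb, yb = self.X[rows], self.y[rows]
            if len(np.unique(yb)) == 2:
                break
            redrawn += 1  # unreachable for pair resampling; kept for safety
        lambdas = lambda_grid(Xb, yb, self.alpha, n_lambda=self.n_lambda)
        pair_idx = np.repeat(np.arange(self.n_pairs), 2)
        try:
            lam, _ = tune_lambda_cv(
                Xb, yb, pair_idx, self.alpha, n_folds=self.n_folds, lambdas=lambdas,
                rng=rng, tol=self.cv_tol,
            )
        except ValidationError:
            redrawn += 1
            return self._one_bootstrap(rng)
        beta, _b0 = fit_enet_logistic(Xb, yb, self.alpha, lam)
        return (beta != 0.0), beta, redrawn

    def fit(self) -> SelectionProfile:
        """Run the B bootstrap fits and aggregate selection frequencies."""
        streams = [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(self.B)]
        p = len(self.analytes)
        counts = np.zeros(p)
        coef_sum = np.zeros(p)
        n_redrawn = 0
        for rng in streams:
            support, beta, redrawn = self._one_bootstrap(rng)
            counts += support
            coef_sum += beta
            n_redrawn += redrawn
        freq = pd.Series(counts / self.B, index=self.analytes, name="selection_frequency")
        mean_coef = pd.Series(coef_sum / self.B, index=self.analytes, name="mean_coef")
        return SelectionProfile(
            frequencies=freq,
            mean_coef=mean_coef,
            B=self.B,
            alpha=self.alpha,
            threshold=self.threshold,
            seed=self.seed,
            n_redrawn=n_redrawn,
        )


def bootstrap_selection(
    X, pairs: PairSet, B: int = 200, alpha: float = 0.75,
    threshold: float = 0.70, seed: int | None = None, **kw
) -> SelectionProfile:
    """Functional wrapper around :class:`StabilitySelection`."""
    return StabilitySelection(X, pairs, B=B, alpha=alpha, threshold=threshold,
                              seed=seed, **kw).fit()


@dataclass
class DifferentialSet:
    """Union of univariate top-significant and influential analytes."""

    analyte_ids: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.analyte_ids)


def union_differential(univ: pd.DataFrame, prof: SelectionProfile) -> DifferentialSet:
    """Differential analytes = top-significant ∪ influential, with per-
    analyte provenance ('univariate', 'multivariable' or 'both')."""
    if set(univ.index) != set(prof.frequencies.index):
        raise ValidationError("univariate table and selection profile cover different analytes")
    top = set(univ.index[univ["top_significant"]])
    infl = set(prof.influential_set)
    ids = [a for a in univ.index if a in top | infl]
    prov = {}
    for a in ids:
        prov[a] = "both" if a in top and a in infl else ("univariate" if a in top else "multivariable")
    return DifferentialSet(analyte_ids=ids, provenance=prov)
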