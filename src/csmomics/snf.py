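"""Similarity network fusion over clinical and omic views.

Each view (a subjects x features table) becomes a subject-similarity
matrix through the scaled-exponential kernel

    W(i,j) = exp(-d^2(i,j) / (mu * eps_ij)),
    eps_ij = (mean d(i, K-NN of i) + mean d(j, K-NN of j) + d(i,j)) / 3

with standardized-Euclidean distance for omic views and Gower distance
for the mixed-type clinical view. Fusion iterates the cross-diffusion

    P_v  <-  S_v . mean_{u != v}(P_u) . S_v'

where P is the full kernel row-normalized with half its mass on the
diagonal and S the row-normalized K-NN kernel; the fused network is the
mean of the final P's. Spectral clustering (normalized cuts) of the
fused matrix yields the patient clusters (k = 2 primary, k = 4
subgroups); per-view concordance is the normalized mutual information
between a view's own spectral labels and the fused labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score
from scipy.spatial.distance import pdist, squareform

from .datatypes import ValidationError
from .preprocess import ProcessedMatrix

__all__ = [
    "AffinityMatrix",
    "view_affinity",
    "snf_fuse",
    "spectral_cluster",
    "view_concordance",
    "deviation_zscores",
    "cluster_characterization",
    "SimilarityNetworkFusion",
    "SNFResults",
    "gower_distance",
]


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative subject-similarity matrix for one view."""

    matrix: pd.DataFrame
    view: str
    K: int
    mu: float

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(float)
        if np.abs(m - m.T).max() > 1e-10:
            raise ValidationError(f"view {self.view}: affinity not symmetric")
        if (m < 0).any():
            raise ValidationError(f"view {self.view}: negative affinities")
        if (np.diag(m) <= 0).any():
            raise ValidationError(f"view {self.view}: non-positive diagonal")

    @property
    def subjects(self) -> pd.Index:
        return self.matrix.index


def gower_distance(df: pd.DataFrame) -> np.ndarray:
    """Gower distance for mixed numeric/boolean/categorical features."""
    n = len(df)
    total = np.zeros((n, n))
    used = 0
    for c in df.columns:
        col = df[c]
        if col.dtype == bool or str(col.dtype) == "boolean":
            v = col.to_numpy(bool).astype(float)
            d = np.abs(v[:, None] - v[None, :])
        elif np.issubdtype(col.dtype, np.number):
            v = col.to_numpy(float)
            rng = np.nanmax(v) - np.nanmin(v)
            if rng == 0:
                continue
            d = np.abs(v[:, None] - v[None, :]) / rng
        else:
            v = col.to_numpy(object)
            d = (v[:, None] != v[None, :]).astype(float)
        total += d
        used += 1
    if used == 0:
        return total
    return total / used


def _knn_mean_dist(d: np.ndarray, K: int) -> np.ndarray:
    """Mean distance of each subject to its K nearest other subjects."""
    n = d.shape[0]
    masked = d + np.diag(np.full(n, np.inf))
    part = np.sort(masked, axis=1)[:, :K]
    return part.mean(axis=1)


def view_affinity(
    X: ProcessedMatrix | pd.DataFrame,
    K: int = 20,
    mu: float = 0.5,
    metric: str = "euclidean_scaled",
    view: str = "view",
) -> AffinityMatrix:
    """Scaled-exponential-kernel affinity for one view."""
    df = X.values if isinstance(X, ProcessedMatrix) else X
    if df.isna().any().any():
        raise ValidationError("affinity requires complete data")
    n = len(df)
    if K >= n:
        raise ValidationError(f"K={K} must be below n={n}")
    if metric == "euclidean_scaled":
        v = df.to_numpy(float)
        sd = v.std(axis=0, ddof=1)
        keep = sd > 0
        v = v[:, keep] / sd[keep]
        d = squareform(pdist(v, metric="euclidean")) / max(1, np.sqrt(keep.sum()))
    elif metric == "gower":
        d = gower_distance(df)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    if d.max() == 0:
        warnings.warn(f"view {view}: constant view, uniform affinity", stacklevel=2)
        w = np.ones((n, n))
    else:
        mean_knn = _knn_mean_dist(d, K)
        eps = (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0
        eps = np.clip(eps, 1e-12, None)
        w = np.exp(-(d**2) / (mu * eps))
    w = (w + w.T) / 2.0
    return AffinityMatrix(
        matrix=pd.DataFrame(w, index=df.index, columns=df.index), view=view, K=K, mu=mu
    )


def _p_normalize(w: np.ndarray) -> np.ndarray:
    """Full kernel, rows sum to 1 with half the mass on the diagonal."""
    p = w.copy().astype(float)
    np.fill_diagonal(p, 0.0)
    rs = p.sum(axis=1)
    rs[rs == 0] = 1.0
    p = p / (2.0 * rs[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _s_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized K-NN kernel (local similarity)."""
    n = w.shape[0]
    s = np.zeros_like(w, dtype=float)
    off = w - np.diag(np.diag(w))
    for i in range(n):
        idx = np.argsort(-off[i])[:K]
        s[i, idx] = off[i, idx]
    rs = s.sum(axis=1)
    rs[rs == 0] = 1.0
    return s / rs[:, None]


@dataclass
class SNFResults:
    """Fused similarity network and its cluster structure."""

    fused: pd.DataFrame
    labels: dict[int, pd.Series] = field(default_factory=dict)
    concordance: dict[str, float] = field(default_factory=dict)
    iterations: int = 0
    final_change: float = float("nan")
    #: max |row sum - 1| of any view's P at any iteration (normalization check)
    p_row_sum_max_dev: float = float("nan")

    def summary(self) -> dict:
        out = {
            "n_subjects": len(self.fused),
            "iterations": self.iterations,
            "final_change": self.final_change,
            "concordance": {k: round(v, 4) for k, v in self.concordance.items()},
        }
        for k, lab in self.labels.items():
            out[f"cluster_sizes_k{k}"] = lab.value_counts().sort_index().tolist()
        return out


def snf_fuse(affinities: list[AffinityMatrix], K: int = 20, t: int = 20) -> SNFResults:
    """Iterative cross-diffusion of the per-view kernels."""
    if len(affinities) < 2:
        raise ValidationError("fusion needs at least 2 views")
    idx = affinities[0].subjects
    for a in affinities[1:]:
        if not a.subjects.equals(idx):
            raise ValidationError("views cover different subject sets")
    ws = [a.matrix.to_numpy(float) for a in affinities]
    ps = [_p_normalize(w) for w in ws]
    ss = [_s_kernel(w, K) for w in ws]
    m = len(ps)
    fused_prev = sum(ps) / m
    change = np.nan
    row_dev = max(float(np.abs(p.sum(axis=1) - 1.0).max()) for p in ps)
    for _it in range(t):
        new_ps = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            p_new = ss[v] @ others @ ss[v].T
            p_new = (p_new + p_new.T) / 2.0
            new_ps.append(_p_normalize(p_new))
        ps = new_ps
        row_dev = max(row_dev,
                      max(float(np.abs(p.sum(axis=1) - 1.0).max()) for p in ps))
        fused = sum(ps) / m
        change = float(np.linalg.norm(fused - fused_prev))
        fused_prev = fused
    if not np.isnan(change) and change > 1e-4:
        warnings.warn(f"fusion change {change:.2e} > 1e-4 after {t} iterations", stacklevel=2)
    fused = (fused_prev + fused_prev.T) / 2.0
    return SNFResults(
        fused=pd.DataFrame(fused, index=idx, columns=idx),
        iterations=t,
        final_change=change,
        p_row_sum_max_dev=row_dev,
    )


def spectral_cluster(
    similarity: pd.DataFrame | np.ndarray, k: int, seed: int = 0, n_restarts: int = 50
) -> np.ndarray:
    """Normalized-cut spectral clustering; labels in 1..k."""
    w = similarity.to_numpy(float) if isinstance(similarity, pd.DataFrame) else np.asarray(similarity, float)
    n = w.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if k == 1:
        return np.ones(n, dtype=int)
    if np.abs(w - w.T).max() > 1e-8 or (w < 0).any():
        raise ValidationError("similarity must be symmetric nonnegative")
    d = w.sum(axis=1)
    d[d == 0] = 1.0
    d_isqrt = 1.0 / np.sqrt(d)
    lap = d_isqrt[:, None] * w * d_isqrt[None, :]
    vals, vecs = np.linalg.eigh((lap + lap.T) / 2.0)
    u = vecs[:, -k:]
    norms = np.linalg.norm(u, axis=1)
    norms[norms == 0] = 1.0
    u = u / norms[:, None]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(u) + 1


def view_concordance(
    view: AffinityMatrix, fused: pd.DataFrame | SNFResults, k: int = 2, seed: int = 0
) -> float:
    """NMI between a view's spectral labels and the fused labels."""
    fused_m = fused.fused if isinstance(fused, SNFResults) else fused
    if not view.subjects.equals(fused_m.index):
        raise ValidationError("view and fused network cover different subjects")
    lv = spectral_cluster(view.matrix, k, seed=seed)
    lf = spectral_cluster(fused_m, k, seed=seed)
    if len(np.unique(lv)) < 2 or len(np.unique(lf)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(lv, lf))


def deviation_zscores(
    X: ProcessedMatrix | pd.DataFrame,
    subjects: pd.DataFrame,
    strata: tuple[tuple[int, int], ...] = ((1, 3), (4, 7), (8, 10**6)),
) -> pd.DataFrame:
    """Per-analyte Z of NS time-to-death strata against the S group:
    Z = (mean NS-stratum - mean S) / SD S."""
    df = X.values if isinstance(X, ProcessedMatrix) else X
    meta = subjects.reindex(df.index)
    s_rows = df.loc[(meta["outcome"] == "S").to_numpy()]
    if s_rows.empty:
        raise ValidationError("no survivors present")
    s_mean = s_rows.mean(axis=0)
    s_sd = s_rows.std(axis=0, ddof=1)
    flagged = list(s_sd.index[s_sd == 0])
    if flagged:
        warnings.warn(f"zero survivor SD for analytes {flagged[:5]}", stacklevel=2)
    s_sd = s_sd.replace(0, np.nan)
    out = {}
    ns = meta["outcome"] == "NS"
    for lo, hi in strata:
        label = f"{lo}-{hi}d" if hi < 10**6 else f">{lo - 1}d"
        sel = (ns & meta["time_to_event_days"].between(lo, hi)).to_numpy()
        if sel.sum() == 0:
            raise ValidationError(f"empty NS stratum {label}")
        out[label] = (df.loc[sel].mean(axis=0) - s_mean) / s_sd
    return pd.DataFrame(out)


def cluster_characterization(
    X: ProcessedMatrix | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    outcome: pd.Series,
    n_top: int = 20,
) -> dict:
    """Outcome composition and top deviating features per cluster."""
    df = X.values if isinstance(X, ProcessedMatrix) else X
    lab = pd.Series(np.asarray(labels), index=df.index) if not isinstance(labels, pd.Series) else labels
    overall_mean = df.mean(axis=0)
    overall_sd = df.std(axis=0, ddof=1).replace(0, np.nan)
    out = {}
    for c in sorted(lab.unique()):
        sel = (lab == c).to_numpy()
        if sel.sum() == 0:
            raise ValidationError(f"empty cluster {c}")
        oc = outcome.reindex(df.index)[sel]
        comp = oc.value_counts(normalize=True).to_dict()
        dev = ((df.loc[sel].mean(axis=0) - overall_mean) / overall_sd).dropna()
        top = dev.reindex(dev.abs().sort_values(ascending=False).index)[:n_top]
        out[int(c)] = {"n": int(sel.sum()), "composition": comp, "top_features": top}
    return out


class SimilarityNetworkFusion:
    """Model: SNF over named views with clustering and concordance.

    ``views`` maps a view name to ``(table, metric)`` where metric is
    ``euclidean_scaled`` (omics) or ``gower`` (clinical).
    """

    def __init__(
        self,
        views: dict[str, tuple[pd.DataFrame, str]],
        K: int = 20,
        mu: float = 0.5,
        t: int = 20,
        ks: tuple[int, ...] = (2, 4),
        seed: int = 0,
    ) -> None:
        if len(views) < 2:
            raise ValidationError("need at least 2 views")
        self.views = views
        self.K, self.mu, self.t, self.ks, self.seed = K, mu, t, ks, seed

    def fit(self) -> SNFResults:
        affs = []
        for name, (table, metric) in self.views.items():
            df = table.values if isinstance(table, ProcessedMatrix) else table
            affs.append(view_affinity(df, K=self.K, mu=self.mu, metric=metric, view=name))
        res = snf_fuse(affs, K=self.K, t=self.t)
        for k in self.ks:
            lab = spectral_cluster(res.fused, k, seed=self.seed)
            res.labels[k] = pd.Series(lab, index=res.fused.index, name=f"cluster_k{k}")
        for aff in affs:
            res.concordance[aff.view] = view_concordance(aff, res, k=self.ks[0], seed=self.seed)
        return res
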