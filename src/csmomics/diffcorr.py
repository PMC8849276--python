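"""Group-wise correlation, Fisher-z differential testing and networks.

Pearson correlations over all analyte pairs are computed separately in
the NS and S groups, with within-group significance from the exact
t-distribution on n-2 df and BH-FDR over all pairs within each group.
A pair is a differential edge when its correlation is FDR-significant
(q < 0.05) in at least one group AND the two groups' correlations
differ by the two-sample Fisher-z test at p < 0.05. Edges carry the
direction (strengthened/weakened in NS), the sign of the significant
correlation, and a width attribute |r_NS - r_S| for rendering; node
degree counts differential edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

from .datatypes import ValidationError
from .preprocess import ProcessedMatrix
from .univariate import bh_adjust

__all__ = [
    "group_correlations",
    "fisher_z_test",
    "build_differential_network",
    "DifferentialNetwork",
    "cluster_heatmap",
    "pooled_scfa_analysis",
]

SCFA_ANALYTES = ("propionate", "isobutyrate", "butyrate")


def _corr_with_p(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
    """Pearson r, p and BH q matrices over all column pairs."""
    n = df.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 subjects per group")
    r = df.corr(method="pearson")
    rv = r.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices_from(p, k=1)
    q_flat = bh_adjust(p[iu])
    q = np.ones_like(p)
    q[iu] = q_flat
    q = np.minimum(q, q.T)
    np.fill_diagonal(q, 0.0)
    cols = df.columns
    return (
        r,
        pd.DataFrame(p, index=cols, columns=cols),
        pd.DataFrame(q, index=cols, columns=cols),
        n,
    )


def group_correlations(X: ProcessedMatrix | pd.DataFrame, groups: pd.Series) -> dict:
    """Per-group correlation/p/q matrices for the NS and S groups.

    Zero-variance analytes within a group are excluded (with a warning)
    from both groups so the matrices stay comparable.
    """
    df = X.values if isinstance(X, ProcessedMatrix) else X
    g = groups.reindex(df.index)
    out: dict = {}
    sub = {label: df.loc[(g == label).to_numpy()] for label in ("NS", "S")}
    drop: set = set()
    for label, d in sub.items():
        sd = d.std(ddof=1)
        zero = list(sd.index[sd == 0])
        if zero:
            warnings.warn(f"{label}: excluding zero-variance analytes {zero[:5]}", stacklevel=2)
            drop.update(zero)
    for label, d in sub.items():
        d = d.drop(columns=[c for c in drop if c in d.columns])
        r, p, q, n = _corr_with_p(d)
        out[label] = {"r": r, "p": p, "q": q, "n": n}
    return out


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of correlations after Fisher's
    z-transformation; returns (z statistic, two-sided normal p)."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValidationError("|r| = 1 has an infinite Fisher transform")
        if n < 4:
            raise ValidationError("need n >= 4 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class DifferentialNetwork:
    """Edges with group correlations and the node table with degrees."""

    edges: pd.DataFrame
    nodes: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def summary(self) -> dict:
        deg = self.nodes["degree"]
        return {
            "n_edges": self.n_edges,
            "n_nodes_connected": int((deg > 0).sum()),
            "max_degree": int(deg.max()) if len(deg) else 0,
            "direction_counts": self.edges["direction"].value_counts().to_dict()
            if len(self.edges)
            else {},
        }


def build_differential_network(
    corr: dict,
    classes: pd.Series | None = None,
    within_q: float = 0.05,
    delta_p: float = 0.05,
) -> DifferentialNetwork:
    """Differential edges from :func:`group_correlations` output."""
    r_ns, r_s = corr["NS"]["r"], corr["S"]["r"]
    q_ns, q_s = corr["NS"]["q"], corr["S"]["q"]
    n_ns, n_s = corr["NS"]["n"], corr["S"]["n"]
    analytes = sorted(r_ns.columns)
    if not analytes:
        raise ValidationError("empty analyte set")
    rows = []
    for i, a in enumerate(analytes):
        for b in analytes[i + 1:]:
            qa, qb = q_ns.loc[a, b], q_s.loc[a, b]
            if not (qa < within_q or qb < within_q):
                continue
            ra, rb = float(r_ns.loc[a, b]), float(r_s.loc[a, b])
            if abs(ra) >= 1 or abs(rb) >= 1:
                warnings.warn(f"edge ({a},{b}): |r|=1, skipped", stacklevel=2)
                continue
            z, p = fisher_z_test(rb, n_s, ra, n_ns)  # S vs NS; sign: + when S stronger
            if p >= delta_p:
                continue
            if qa < within_q and qb < within_q:
                sign_r = ra if abs(ra) >= abs(rb) else rb
            else:
                sign_r = ra if qa < within_q else rb
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "r_NS": ra,
                    "r_S": rb,
                    "z_stat": z,
                    "p_delta": p,
                    "delta": abs(ra - rb),
                    "direction": "strengthened" if abs(ra) > abs(rb) else "weakened",
                    "sign": "positive" if sign_r >= 0 else "negative",
                }
            )
    edges = pd.DataFrame(
        rows,
        columns=["source", "target", "r_NS", "r_S", "z_stat", "p_delta", "delta",
                 "direction", "sign"],
    )
    degree = pd.Series(0, index=analytes, dtype=int)
    for _, e in edges.iterrows():
        degree[e["source"]] += 1
        degree[e["target"]] += 1
    nodes = pd.DataFrame({"degree": degree})
    nodes.index.name = "id"
    if classes is not None:
        nodes["class"] = classes.reindex(nodes.index)
    return DifferentialNetwork(edges=edges, nodes=nodes)


def cluster_heatmap(
    X: ProcessedMatrix | pd.DataFrame,
    classes: pd.Series | None = None,
    method: str = "average",
) -> dict:
    """Hierarchical clustering of analytes with distance 1 - r.

    Returns the leaf order, the scipy linkage matrix (merge tree) and
    the pooled correlation matrix, ready for heatmap rendering.
    """
    df = X.values if isinstance(X, ProcessedMatrix) else X
    if df.shape[1] < 2:
        raise ValidationError("need at least 2 analytes to cluster")
    r = df.corr(method="pearson")
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    leaves = dendrogram(z, no_plot=True)["leaves"]
    order = [r.columns[i] for i in leaves]
    out = {"order": order, "linkage": z, "correlation": r}
    if classes is not None:
        out["classes"] = classes.reindex(r.columns)
    return out


def pooled_scfa_analysis(
    metabolites: pd.DataFrame,
    cytokines: pd.DataFrame | pd.Series,
    scfas=SCFA_ANALYTES,
    target: str = "IL8",
) -> dict:
    """Pooled short-chain fatty acids versus a cytokine.

    Sums the three SCFAs per subject, correlates with the target on the
    log10 scale, and cross-tabulates subjects above/below the two
    medians (raw scale).
    """
    missing = [a for a in scfas if a not in metabolites.columns]
    if missing:
        raise ValidationError(f"missing SCFA constituents: {missing}")
    pooled = metabolites[list(scfas)].sum(axis=1)
    t = cytokines if isinstance(cytokines, pd.Series) else cytokines[target]
    t = t.reindex(pooled.index)
    if t.isna().any():
        raise ValidationError("target cytokine missing for some subjects")
    if t.std(ddof=1) == 0 or pooled.std(ddof=1) == 0:
        return {"pooled": pooled, "r": np.nan, "p": np.nan, "flag": "constant input"}
    r, p = stats.pearsonr(np.log10(pooled), np.log10(t))
    med_s, med_t = pooled.median(), t.median()
    above = pd.crosstab(pooled > med_s, t > med_t)
    return {
        "pooled": pooled,
        "r": float(r),
        "p": float(p),
        "median_scfa": float(med_s),
        "median_target": float(med_t),
        "crosstab": above,
    }
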