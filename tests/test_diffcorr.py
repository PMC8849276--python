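"""Correlation estimation, Fisher-z testing, network building and the
clustered heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csmomics.datatypes import ValidationError
from csmomics.diffcorr import (
    build_differential_network,
    cluster_heatmap,
    fisher_z_test,
    group_correlations,
    pooled_scfa_analysis,
)


def _two_group_df(n=40, p=5, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(2 * n, p)),
                      index=[f"s{i}" for i in range(2 * n)],
                      columns=[f"A{j}" for j in range(p)])
    groups = pd.Series(["NS"] * n + ["S"] * n, index=df.index)
    return df, groups


class TestGroupCorrelations:
    def test_hand_computed_pearson(self):
        """x=(1..5), y=(2,1,4,3,5) has r = 0.8 exactly."""
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5] * 2, "y": [2, 1, 4, 3, 5] * 2},
                          dtype=float)
        df.index = [f"s{i}" for i in range(10)]
        groups = pd.Series(["NS"] * 5 + ["S"] * 5, index=df.index)
        out = group_correlations(df, groups)
        assert out["NS"]["r"].loc["x", "y"] == pytest.approx(0.8)
        assert out["S"]["r"].loc["x", "y"] == pytest.approx(0.8)

    def test_proportional_columns(self):
        df, groups = _two_group_df(seed=1)
        df["B"] = 3.0 * df["A0"]
        out = group_correlations(df, groups)
        assert out["NS"]["r"].loc["A0", "B"] == pytest.approx(1.0)
        assert out["NS"]["p"].loc["A0", "B"] < 1e-10

    def test_zero_variance_excluded_with_warning(self):
        df, groups = _two_group_df(seed=2)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            out = group_correlations(df, groups)
        assert "flat" not in out["NS"]["r"].columns

    def test_small_group_rejected(self):
        df, groups = _two_group_df(n=3)
        with pytest.raises(ValidationError):
            group_correlations(df, groups)


class TestFisherZ:
    def test_equal_correlations_null(self):
        z, p = fisher_z_test(0.42, 50, 0.42, 80)
        assert z == 0.0 and p == 1.0

    def test_printed_urea_cycle_pair(self):
        """r_S=0.7 vs r_NS=0.1 at n=92 per group is significant below 1e-4."""
        z, p = fisher_z_test(0.7, 92, 0.1, 92)
        assert p < 1e-4

    def test_antisymmetry(self):
        z1, p1 = fisher_z_test(0.6, 40, 0.2, 60)
        z2, p2 = fisher_z_test(0.2, 60, 0.6, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValidationError):
            fisher_z_test(1.0, 50, 0.2, 50)

    def test_permutation_oracle(self):
        """Fisher-z p agrees with a label-permutation p within
        Monte-Carlo error on a toy dataset."""
        rng = np.random.default_rng(3)
        n = 30
        x1 = rng.normal(size=n)
        y1 = 0.8 * x1 + 0.6 * rng.normal(size=n)   # strong correlation
        x2 = rng.normal(size=n)
        y2 = 0.1 * x2 + rng.normal(size=n)          # weak correlation
        r1, r2 = np.corrcoef(x1, y1)[0, 1], np.corrcoef(x2, y2)[0, 1]
        _, p_fisher = fisher_z_test(r1, n, r2, n)
        xs, ys = np.r_[x1, x2], np.r_[y1, y2]
        obs = abs(np.arctanh(r1) - np.arctanh(r2))
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            idx = rng.permutation(2 * n)
            g1, g2 = idx[:n], idx[n:]
            ra = np.corrcoef(xs[g1], ys[g1])[0, 1]
            rb = np.corrcoef(xs[g2], ys[g2])[0, 1]
            if abs(np.arctanh(ra) - np.arctanh(rb)) >= obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_fisher - p_perm) < max(0.02, mc_err + 0.01)


class TestNetwork:
    def test_identical_structure_no_edges(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(200, 4))
        df = pd.DataFrame(np.vstack([base, base]),
                          index=[f"s{i}" for i in range(400)],
                          columns=list("ABCD"))
        groups = pd.Series(["NS"] * 200 + ["S"] * 200, index=df.index)
        net = build_differential_network(group_correlations(df, groups))
        assert net.n_edges == 0

    def test_planted_shift_recovered(self, ):
        rng = np.random.default_rng(5)
        n = 90
        za = rng.normal(size=2 * n)
        noise = rng.normal(size=2 * n)
        zb = np.empty(2 * n)
        zb[:n] = 0.0 * za[:n] + noise[:n]                      # NS: r = 0
        zb[n:] = 0.7 * za[n:] + np.sqrt(1 - 0.49) * noise[n:]  # S: r = 0.7
        df = pd.DataFrame({"a": za, "b": zb, "c": rng.normal(size=2 * n)},
                          index=[f"s{i}" for i in range(2 * n)])
        groups = pd.Series(["NS"] * n + ["S"] * n, index=df.index)
        net = build_differential_network(group_correlations(df, groups))
        edge = net.edges[(net.edges["source"] == "a") & (net.edges["target"] == "b")]
        assert len(edge) == 1
        assert edge.iloc[0]["direction"] == "weakened"
        assert edge.iloc[0]["sign"] == "positive"
        assert net.nodes.loc["a", "degree"] >= 1

    def test_input_order_invariance(self):
        df, groups = _two_group_df(n=50, p=4, seed=6)
        df["B"] = 0.9 * df["A0"] + 0.3 * np.random.default_rng(1).normal(size=len(df))
        net1 = build_differential_network(group_correlations(df, groups))
        shuffled = df[list(df.columns[::-1])]
        net2 = build_differential_network(group_correlations(shuffled, groups))
        e1 = set(map(tuple, net1.edges[["source", "target"]].to_numpy()))
        e2 = set(map(tuple, net2.edges[["source", "target"]].to_numpy()))
        assert e1 == e2


class TestHeatmap:
    def test_perfect_pair_merges_first(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=30)
        out = cluster_heatmap(df)
        first = out["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_analyte_linkage_arithmetic(self):
        """r(A,B)=0.9, r(A,C)=r(B,C)=0: first merge is (A,B) at
        distance 0.1; C joins at the average distance 1.0."""
        corr = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        chol = np.linalg.cholesky(corr)
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(5000, 3)) @ chol.T, columns=list("ABC"))
        out = cluster_heatmap(df)
        z = out["linkage"]
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(0.1, abs=0.03)
        assert z[1, 2] == pytest.approx(1.0, abs=0.05)

    def test_block_structure_contiguous(self):
        rng = np.random.default_rng(9)
        n = 200
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for j in range(4):
            cols[f"x{j}"] = f1 + 0.3 * rng.normal(size=n)
        for j in range(4):
            cols[f"y{j}"] = f2 + 0.3 * rng.normal(size=n)
        out = cluster_heatmap(pd.DataFrame(cols))
        order = out["order"]
        first_block = {a[0] for a in order[:4]}
        assert first_block in ({"x"}, {"y"})

    def test_single_analyte_rejected(self):
        with pytest.raises(ValidationError):
            cluster_heatmap(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestPooledSCFA:
    def _mets(self, n=50, seed=10):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            10 ** rng.normal(1, 0.2, size=(n, 3)),
            columns=["propionate", "isobutyrate", "butyrate"],
            index=[f"s{i}" for i in range(n)],
        )

    def test_proportional_target_r1(self):
        mets = self._mets()
        target = mets.sum(axis=1) * 2.0
        out = pooled_scfa_analysis(mets, target.rename("IL8"))
        assert out["r"] == pytest.approx(1.0)

    def test_constant_target_flagged(self):
        mets = self._mets()
        out = pooled_scfa_analysis(mets, pd.Series(5.0, index=mets.index, name="IL8"))
        assert np.isnan(out["r"]) and out["flag"] == "constant input"

    def test_missing_constituent_rejected(self):
        mets = self._mets().drop(columns=["butyrate"])
        with pytest.raises(ValidationError):
            pooled_scfa_analysis(mets, pd.Series(1.0, index=mets.index, name="IL8"))

    def test_planted_r_recovered(self):
        """Planted r=0.3 at n=180: estimates within ±0.15 over 20 seeds."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 180
            z = rng.normal(size=n)
            mets = pd.DataFrame({
                "propionate": 10 ** (1 + 0.2 * z + 0.05 * rng.normal(size=n)),
                "isobutyrate": 10 ** (0.5 + 0.2 * z + 0.05 * rng.normal(size=n)),
                "butyrate": 10 ** (0.8 + 0.2 * z + 0.05 * rng.normal(size=n)),
            }, index=[f"s{i}" for i in range(n)])
            zs = np.log10(mets.sum(axis=1))
            zs = (zs - zs.mean()) / zs.std(ddof=1)
            il8 = 10 ** (1 + 0.3 * (0.3 * zs + np.sqrt(1 - 0.09) * rng.normal(size=n)))
            out = pooled_scfa_analysis(mets, pd.Series(il8.to_numpy(), index=mets.index, name="IL8"))
            errs.append(abs(out["r"] - 0.3))
        assert np.mean(np.array(errs) < 0.15) >= 0.95
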