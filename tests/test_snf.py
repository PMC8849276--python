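"""Affinity kernels, cross-diffusion fusion, spectral clustering,
concordance and deviation Z-scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from csmomics.datatypes import ValidationError
from csmomics.snf import (
    SimilarityNetworkFusion,
    _p_normalize,
    cluster_characterization,
    deviation_zscores,
    gower_distance,
    snf_fuse,
    spectral_cluster,
    view_affinity,
    view_concordance,
)


def _clustered_view(n_per=30, sep=2.0, noise=1.0, p=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p)) * noise
    X[n_per:] += sep
    return pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n_per)])


class TestAffinity:
    def test_duplicate_subjects_maximal(self):
        df = _clustered_view(n_per=10, seed=1)
        df.iloc[1] = df.iloc[0]
        aff = view_affinity(df, K=5)
        assert aff.matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        aff = view_affinity(_clustered_view(seed=2), K=10)
        m = aff.matrix.to_numpy()
        assert np.abs(m - m.T).max() < 1e-10
        assert m.min() >= 0 and m.max() <= 1 + 1e-12

    def test_scale_invariance(self):
        df = _clustered_view(seed=3)
        a1 = view_affinity(df, K=10).matrix.to_numpy()
        a2 = view_affinity(df * 7.0, K=10).matrix.to_numpy()
        np.testing.assert_allclose(a1, a2, atol=1e-8)

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            view_affinity(_clustered_view(n_per=3), K=10)

    def test_gower_mixed_types(self):
        df = pd.DataFrame({
            "age": [10.0, 20.0, 10.0],
            "flag": [True, True, False],
            "site": ["a", "b", "a"],
        })
        d = gower_distance(df)
        assert d[0, 2] == pytest.approx((0 + 1 + 0) / 3)
        assert d[0, 1] == pytest.approx((1 + 0 + 1) / 3)
        aff = view_affinity(df, K=2, metric="gower")
        assert aff.matrix.to_numpy().min() >= 0


class TestFusion:
    def test_p_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        w = np.abs(rng.normal(size=(12, 12)))
        w = (w + w.T) / 2
        p = _p_normalize(w)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(np.diag(p), 0.5)

    def test_p_normalized_every_iteration(self):
        views = [view_affinity(_clustered_view(seed=s), K=10, view=f"v{s}")
                 for s in (5, 6)]
        res = snf_fuse(views, K=10, t=10)
        assert res.p_row_sum_max_dev < 1e-8
        # the symmetrized fused average stays close to row-stochastic
        np.testing.assert_allclose(res.fused.sum(axis=1), 1.0, atol=0.05)

    def test_identical_views_self_consistent(self):
        df = _clustered_view(seed=7)
        views = [view_affinity(df, K=10, view=f"v{i}") for i in range(2)]
        res = snf_fuse(views, K=10, t=10)
        lab = spectral_cluster(res.fused, 2, seed=0)
        single = spectral_cluster(views[0].matrix, 2, seed=0)
        assert adjusted_rand_score(lab, single) == pytest.approx(1.0)

    def test_fusion_beats_or_matches_best_view(self):
        """Two noisy views of the same 2-cluster structure: fused ARI is
        within 0.05 of the best single view, across seeds."""
        wins = []
        for seed in range(10):
            truth = np.repeat([0, 1], 30)
            v1 = _clustered_view(sep=1.0, noise=1.0, seed=100 + seed)
            v2 = _clustered_view(sep=1.0, noise=1.0, seed=200 + seed)
            a1, a2 = (view_affinity(v, K=15, view=s) for v, s in ((v1, "a"), (v2, "b")))
            fused = snf_fuse([a1, a2], K=15, t=15)
            ari_f = adjusted_rand_score(truth, spectral_cluster(fused.fused, 2))
            ari_1 = adjusted_rand_score(truth, spectral_cluster(a1.matrix, 2))
            ari_2 = adjusted_rand_score(truth, spectral_cluster(a2.matrix, 2))
            wins.append(ari_f >= max(ari_1, ari_2) - 0.05)
        assert np.mean(wins) >= 0.9

    def test_permutation_equivariance(self):
        df = _clustered_view(n_per=15, seed=8)
        views = [view_affinity(df, K=8, view="a"),
                 view_affinity(df * 2 + 1, K=8, view="b")]
        res = snf_fuse(views, K=8, t=8)
        perm = np.random.default_rng(0).permutation(len(df))
        dfp = df.iloc[perm]
        viewsp = [view_affinity(dfp, K=8, view="a"),
                  view_affinity(dfp * 2 + 1, K=8, view="b")]
        resp = snf_fuse(viewsp, K=8, t=8)
        np.testing.assert_allclose(
            resp.fused.to_numpy(),
            res.fused.to_numpy()[np.ix_(perm, perm)],
            atol=1e-10,
        )

    def test_single_view_rejected(self):
        with pytest.raises(ValidationError):
            snf_fuse([view_affinity(_clustered_view(), K=10)])


class TestSpectral:
    def test_block_diagonal_exact(self):
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        lab = spectral_cluster(w, 2)
        assert len(set(lab[:5])) == 1 and len(set(lab[5:])) == 1
        assert lab[0] != lab[5]

    def test_k1_single_label(self):
        assert set(spectral_cluster(np.ones((4, 4)), 1)) == {1}

    def test_planted_four_clusters(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truth = np.repeat(np.arange(4), 15)
            X = rng.normal(size=(60, 8))
            for c in range(4):
                X[truth == c, c] += 8.0
                X[truth == c, c + 4] += 8.0
            aff = view_affinity(pd.DataFrame(X), K=10)
            lab = spectral_cluster(aff.matrix, 4, seed=seed)
            assert adjusted_rand_score(truth, lab) == 1.0

    def test_k_exceeds_n(self):
        with pytest.raises(ValidationError):
            spectral_cluster(np.ones((3, 3)), 5)


class TestConcordance:
    def test_view_equals_fused(self):
        df = _clustered_view(seed=9)
        aff = view_affinity(df, K=10, view="x")
        assert view_concordance(aff, aff.matrix) == pytest.approx(1.0)

    def test_unrelated_view_near_zero(self):
        vals = []
        for seed in range(10):
            df1 = _clustered_view(n_per=50, sep=3.0, seed=300 + seed)
            rng = np.random.default_rng(seed)
            df2 = pd.DataFrame(rng.normal(size=(100, 10)), index=df1.index)
            # structured but independent split: random half of subjects
            df2.iloc[rng.choice(100, 50, replace=False)] += 3.0
            a1 = view_affinity(df1, K=20, view="sig")
            a2 = view_affinity(df2, K=20, view="noise")
            vals.append(view_concordance(a2, a1.matrix))
        assert np.mean(vals) < 0.1

    def test_omic_beats_clinical_ordering(self):
        """Strong-signal omic view vs weak-signal clinical view: the
        omic concordance to the fused network is the larger one."""
        rng = np.random.default_rng(10)
        n = 60
        truth = np.repeat([0, 1], n // 2)
        omic = pd.DataFrame(rng.normal(size=(n, 20)),
                            index=[f"s{i}" for i in range(n)])
        omic.iloc[truth == 1] += 1.5
        clin = pd.DataFrame({
            "age": rng.normal(18, 5, n),
            "muac": rng.normal(11, 1, n),
            "flag": rng.random(n) < (0.35 + 0.1 * truth),
        }, index=omic.index)
        model = SimilarityNetworkFusion(
            {"omic": (omic, "euclidean_scaled"), "clinical": (clin, "gower")},
            K=15, t=15, seed=0,
        )
        res = model.fit()
        assert res.concordance["omic"] > res.concordance["clinical"]


class TestDeviationZ:
    def _data(self, shift_by_stratum, seed=0, n_s=60):
        rng = np.random.default_rng(seed)
        rows, meta = [], []
        sid = 0
        for stratum, (lo, hi, shift, n) in shift_by_stratum.items():
            for _ in range(n):
                rows.append(rng.normal(shift, 1.0, size=4))
                meta.append(("NS", int(rng.integers(lo, hi + 1))))
                sid += 1
        for _ in range(n_s):
            rows.append(rng.normal(0.0, 1.0, size=4))
            meta.append(("S", int(rng.integers(4, 15))))
            sid += 1
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        subjects = pd.DataFrame(meta, columns=["outcome", "time_to_event_days"],
                                index=df.index)
        return df, subjects

    def test_unit_shift_gives_z_one(self):
        df, subjects = self._data({"early": (1, 3, 1.0, 400)}, n_s=4000, seed=1)
        z = deviation_zscores(df, subjects, strata=((1, 3),))
        np.testing.assert_allclose(z["1-3d"], 1.0, atol=0.15)

    def test_null_stratum_near_zero(self):
        df, subjects = self._data({"early": (1, 3, 0.0, 400)}, n_s=4000, seed=2)
        z = deviation_zscores(df, subjects, strata=((1, 3),))
        np.testing.assert_allclose(z["1-3d"], 0.0, atol=0.2)

    def test_severity_gradient_ordering(self):
        df, subjects = self._data({
            "early": (1, 3, 1.5, 50), "mid": (4, 7, 1.0, 50), "late": (8, 20, 0.4, 50)
        }, seed=3)
        z = deviation_zscores(df, subjects)
        assert z["1-3d"].abs().mean() > z[">7d"].abs().mean()


class TestCharacterization:
    def test_labels_equal_outcome(self):
        df = _clustered_view(seed=11)
        outcome = pd.Series(["NS"] * 30 + ["S"] * 30, index=df.index)
        labels = pd.Series([1] * 30 + [2] * 30, index=df.index)
        out = cluster_characterization(df, labels, outcome)
        assert out[1]["composition"]["NS"] == pytest.approx(1.0)
        assert out[2]["composition"]["S"] == pytest.approx(1.0)
        assert len(out[1]["top_features"]) > 0
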