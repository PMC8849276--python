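"""QC filter, imputation, batch correction and autoscaling rules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csmomics.datatypes import AnalyteMatrix, ValidationError
from csmomics.preprocess import (
    autoscale,
    batch_correct,
    combat_adjust,
    cv_detection_filter,
    impute_lod,
    knn_impute,
    protein_missingness_filter,
    transform_autoscale,
)


def _mat(values, mask=None, block="metabolite", lod=None):
    df = pd.DataFrame(values)
    df.index = [f"S{i}" for i in range(len(df))]
    df.columns = [f"A{j}" for j in range(df.shape[1])]
    m = pd.DataFrame(False, index=df.index, columns=df.columns) if mask is None else \
        pd.DataFrame(mask, index=df.index, columns=df.columns)
    lod_s = None if lod is None else pd.Series(lod, index=df.columns)
    return AnalyteMatrix(block=block, values=df, mask=m,
                         classes=pd.Series("amino acid", index=df.columns), lod=lod_s)


def _groups(mat, n_ns=None):
    n = mat.n_subjects
    n_ns = n // 2 if n_ns is None else n_ns
    return pd.Series(["NS"] * n_ns + ["S"] * (n - n_ns), index=mat.values.index)


class TestCVDetectionFilter:
    def test_clean_analyte_retained(self):
        mat = _mat(np.ones((6, 1)) * 2.0)
        qc = pd.DataFrame({"A0": [1.0, 1.0, 1.0]})
        out, rep = cv_detection_filter(mat, qc, _groups(mat))
        assert rep.table.loc["A0", "cv"] == 0.0
        assert rep.retained == ["A0"]

    def test_high_cv_removed(self):
        """QC replicates (1,2,3): sd=1, mean=2, CV=0.5 > 0.30."""
        mat = _mat(np.ones((6, 1)))
        qc = pd.DataFrame({"A0": [1.0, 2.0, 3.0]})
        out, rep = cv_detection_filter(mat, qc, _groups(mat))
        assert rep.table.loc["A0", "cv"] == pytest.approx(0.5)
        assert rep.table.loc["A0", "reasons"] == "cv_fail"
        assert out.analyte_ids == []

    def test_either_group_detection_rule(self):
        """85% detection in NS but 10% in S still retains the analyte."""
        n_ns, n_s = 20, 20
        mask = np.zeros((40, 1), dtype=bool)
        mask[:n_ns][3:] = False
        mask[np.arange(3)] = True            # 17/20 = 85% detected in NS
        mask[n_ns + np.arange(18), 0] = True  # 2/20 = 10% detected in S
        mat = _mat(np.ones((40, 1)), mask=mask)
        qc = pd.DataFrame({"A0": [1.0, 1.0, 1.0]})
        out, rep = cv_detection_filter(mat, qc, _groups(mat, n_ns))
        assert rep.table.loc["A0", "detect_NS"] == pytest.approx(0.85)
        assert rep.table.loc["A0", "detect_S"] == pytest.approx(0.10)
        assert rep.retained == ["A0"]

    def test_zero_mean_qc_is_cv_fail(self):
        mat = _mat(np.ones((4, 1)))
        qc = pd.DataFrame({"A0": [1.0, -1.0, 0.0]})
        _, rep = cv_detection_filter(mat, qc, _groups(mat))
        assert "cv_fail" in rep.table.loc["A0", "reasons"]

    def test_missing_qc_analyte_errors(self):
        mat = _mat(np.ones((4, 2)))
        qc = pd.DataFrame({"A0": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="A1"):
            cv_detection_filter(mat, qc, _groups(mat))

    def test_audit_balance(self, small_cohort):
        mat = small_cohort.matrices["metabolite"]
        _, rep = cv_detection_filter(mat, small_cohort.qc_samples,
                                     small_cohort.subjects["outcome"])
        assert len(rep.retained) + len(rep.removed) == len(mat.analyte_ids)
        assert (rep.table.loc[rep.removed, "reasons"] != "").all()


class TestImputeLOD:
    def test_half_lod(self):
        mask = np.array([[True], [False]])
        mat = _mat([[0.5], [1.0]], mask=mask, lod=[0.2])
        out = impute_lod(mat)
        assert out.values.iloc[0, 0] == pytest.approx(0.1)
        assert out.values.iloc[1, 0] == pytest.approx(1.0)
        assert not out.mask.any().any()

    def test_identity_without_nondetects(self):
        mat = _mat([[1.0], [2.0]], lod=[0.2])
        assert impute_lod(mat) is mat

    def test_fully_censored_column_constant(self):
        mask = np.ones((3, 1), dtype=bool)
        mat = _mat([[1.0], [2.0], [3.0]], mask=mask, lod=[4.0])
        out = impute_lod(mat)
        assert (out.values["A0"] == 2.0).all()

    def test_missing_lod_errors(self):
        mat = _mat([[1.0], [2.0]], mask=[[True], [False]])
        with pytest.raises(ValidationError):
            impute_lod(mat)


class TestMissingnessFilter:
    @pytest.mark.parametrize("n_missing,kept", [(19, False), (18, True), (0, True)])
    def test_20pct_rule_at_92_subjects(self, n_missing, kept):
        mask = np.zeros((92, 1), dtype=bool)
        mask[:n_missing] = True
        mat = _mat(np.ones((92, 1)), mask=mask, block="protein")
        if not kept:
            with pytest.raises(ValidationError):
                protein_missingness_filter(mat)  # nothing left
            return
        out, rep = protein_missingness_filter(mat)
        assert out.analyte_ids == ["A0"]

    def test_mixed_columns(self):
        mask = np.zeros((10, 2), dtype=bool)
        mask[:3, 1] = True  # 30% missing
        mat = _mat(np.ones((10, 2)), mask=mask, block="protein")
        out, rep = protein_missingness_filter(mat)
        assert out.analyte_ids == ["A0"]
        assert rep.table.loc["A1", "reasons"] == "missingness_fail"


class TestKNNImpute:
    def test_identity_without_missing(self):
        mat = _mat(np.arange(12, dtype=float).reshape(4, 3), block="protein")
        assert knn_impute(mat, k=2) is mat

    def test_twin_subject(self):
        vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 99.0], [50.0, 60.0, 70.0]])
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        mat = _mat(vals, mask=mask, block="protein")
        out = knn_impute(mat, k=1)
        assert out.values.iloc[1, 2] == pytest.approx(3.0)

    def test_neighbor_mean_hand_computed(self):
        """k=2: the two nearest complete rows on the shared columns."""
        vals = np.array([
            [1.0, 1.0, 1.0],
            [1.0, 1.0, 2.0],
            [10.0, 10.0, 10.0],
            [0.0, 1.0, 0.0],   # last cell missing
        ])
        mask = np.zeros((4, 3), dtype=bool)
        mask[3, 2] = True
        mat = _mat(vals, mask=mask, block="protein")
        out = knn_impute(mat, k=2)
        # neighbours of row 3 on columns (0,1): rows 0 and 1 (dist 1 each)
        assert out.values.iloc[3, 2] == pytest.approx((1.0 + 2.0) / 2)

    def test_k_too_large(self):
        mat = _mat(np.ones((3, 2)), block="protein")
        with pytest.raises(ValidationError):
            knn_impute(mat, k=3)


class TestBatchCorrect:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        mat = _mat(10 ** rng.normal(1, 0.2, size=(8, 3)), block="protein")
        out = batch_correct(mat, pd.Series("B1", index=mat.values.index))
        np.testing.assert_allclose(out.values, mat.values, rtol=1e-10)

    def test_constant_multiplicative_shift_removed(self):
        rng = np.random.default_rng(1)
        base = 10 ** rng.normal(1, 0.2, size=(10, 4))
        vals = np.vstack([base, base * 3.0])  # second batch scaled by 3
        mat = _mat(vals, block="protein")
        batches = pd.Series(["B1"] * 10 + ["B2"] * 10, index=mat.values.index)
        out = batch_correct(mat, batches, shrinkage=False)
        logs = np.log10(out.values.to_numpy())
        m1, m2 = logs[:10].mean(axis=0), logs[10:].mean(axis=0)
        np.testing.assert_allclose(m1, m2, atol=1e-8)

    def test_planted_shift_f_statistic_suppressed(self):
        """After correction, the per-analyte batch F statistic drops to
        null-like levels."""
        from scipy import stats
        rng = np.random.default_rng(2)
        n_b, per, p = 4, 15, 30
        logs = rng.normal(2, 0.3, size=(n_b * per, p))
        shifts = rng.normal(0, 1.0, size=(n_b, p))
        for b in range(n_b):
            logs[b * per:(b + 1) * per] += shifts[b]
        mat = _mat(10**logs, block="protein")
        batches = pd.Series(np.repeat([f"B{i}" for i in range(n_b)], per),
                            index=mat.values.index)
        out = batch_correct(mat, batches, shrinkage=True)
        corrected = np.log10(out.values.to_numpy())
        fs = []
        for j in range(p):
            groups = [corrected[b * per:(b + 1) * per, j] for b in range(n_b)]
            fs.append(stats.f_oneway(*groups).statistic)
        crit = stats.f.ppf(0.99, n_b - 1, n_b * per - n_b)
        assert np.mean(np.array(fs) < crit) > 0.9

    def test_singleton_batch_needs_shrinkage(self):
        vals = 10 ** np.random.default_rng(3).normal(1, 0.1, size=(5, 2))
        mat = _mat(vals, block="protein")
        batches = pd.Series(["B1"] * 4 + ["B2"], index=mat.values.index)
        with pytest.raises(ValidationError):
            batch_correct(mat, batches, shrinkage=False)


class TestAutoscale:
    def test_log_decades(self):
        mat = _mat([[10.0], [100.0], [1000.0]])
        out = transform_autoscale(mat)
        np.testing.assert_allclose(out.values["A0"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_columns_standardized(self, small_cohort):
        mat = impute_lod(small_cohort.matrices["metabolite"])
        out = transform_autoscale(mat)
        v = out.values.to_numpy()
        assert np.abs(v.mean(axis=0)).max() < 1e-8
        assert np.abs(v.std(axis=0, ddof=1) - 1).max() < 1e-8

    def test_constant_column_dropped_with_warning(self):
        mat = _mat(np.column_stack([np.ones(4), np.arange(1.0, 5.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = transform_autoscale(mat)
        assert out.analyte_ids == ["A1"]

    def test_nonpositive_rejected(self):
        mat = _mat([[1.0], [0.0]])
        with pytest.raises(ValidationError, match="non-positive"):
            transform_autoscale(mat)

    def test_autoscale_idempotent(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        once = autoscale(df)
        twice = autoscale(once.values)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-8)


class TestFilterComposition:
    def test_cv_then_detection_equals_joint(self, small_cohort):
        """Applying the CV rule and detection rule in either order gives
        the same retained set as the joint rule."""
        mat = small_cohort.matrices["metabolite"]
        qc = small_cohort.qc_samples
        g = small_cohort.subjects["outcome"]
        _, joint = cv_detection_filter(mat, qc, g)
        only_cv, _ = cv_detection_filter(mat, qc, g, detect_min=0.0)
        both, _ = cv_detection_filter(only_cv, qc, g, cv_max=np.inf)
        assert set(both.analyte_ids) == set(joint.retained)
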