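"""Clinical slopes, covariate adjustment and mechanism-symptom PLS-SVD."""

import numpy as np
import pytest

import remcm
from remcm.axes import (MechanismSymptomPLS, _procrustes_align,
                        adjust_covariates, bootstrap_stability,
                        clinical_slopes, cross_covariance_svd,
                        permutation_test_axes, variance_per_parameter)
from remcm.data import ASSESSMENTS, ClinicalRecord
from remcm.exceptions import ParameterError


def record(scores, times):
    scores = np.asarray(scores, float)
    return ClinicalRecord("s", scores, times, np.array([60.0, 14.0, 1.0]),
                          assessment_names=[f"A{i}" for i in
                                            range(scores.shape[0])])


class TestClinicalSlopes:
    def test_line_examples(self):
        r = record([[0.0, 1.0], [5.0, 5.0], [0.0, 2.0]], [0.0, 1.0])
        np.testing.assert_allclose(clinical_slopes(r), [1.0, 0.0, 2.0])

    def test_three_collinear_points(self):
        r = record([[0.0, 2.0, 4.0]], [0.0, 1.0, 2.0])
        assert clinical_slopes(r)[0] == pytest.approx(2.0)

    def test_missing_visits_flagged_not_fatal(self):
        r = record([[1.0, np.nan, 2.0], [np.nan, np.nan, 3.0]],
                   [0.0, 1.0, 2.0])
        s = clinical_slopes(r)
        assert s[0] == pytest.approx(0.5)
        assert np.isnan(s[1])


class TestAdjustCovariates:
    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.normal(size=(40, 6))
        cov = rng.normal(size=(40, 3))
        Z, kept = adjust_covariates(X, cov)
        assert kept.all()
        C = np.column_stack([np.ones(40), cov])
        assert np.abs(C.T @ Z).max() < 1e-8
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_column_linear_in_age_dropped(self, rng):
        cov = rng.normal(size=(30, 3))
        X = np.column_stack([2.0 * cov[:, 0] + 1.0, rng.normal(size=30)])
        Z, kept = adjust_covariates(X, cov)
        assert not kept[0] and kept[1]
        assert np.all(Z[:, 0] == 0)

    def test_orthogonal_covariates_only_zscore(self, rng):
        cov = rng.normal(size=(200, 3))
        x = rng.normal(size=200)
        x = x - np.column_stack([np.ones(200), cov]) @ np.linalg.lstsq(
            np.column_stack([np.ones(200), cov]), x, rcond=None)[0]
        Z, _ = adjust_covariates(x[:, None], cov)
        np.testing.assert_allclose(Z[:, 0], x / x.std(), atol=1e-8)

    def test_rank_deficient_covariates(self, rng):
        cov = np.ones((10, 3))
        with pytest.raises(ParameterError, match="rank"):
            adjust_covariates(rng.normal(size=(10, 2)), cov)


class TestCrossCovarianceSVD:
    def test_rank_one_planted(self, rng):
        X = rng.normal(size=(50, 30))
        X = (X - X.mean(0)) / X.std(0)
        w = rng.normal(size=(30, 4))
        Y = X @ w[:, :1] @ np.ones((1, 4))  # rank-1 map
        Y = Y - Y.mean(0)
        axes = cross_covariance_svd(X, Y)
        assert axes.covariance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_spreads_covariance(self, rng):
        X = rng.standard_normal((100, 40))
        Y = rng.standard_normal((100, 8))
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        assert axes.covariance_explained.max() < 0.5
        assert axes.covariance_explained.sum() == pytest.approx(1.0)

    def test_toy_singular_values_match_dense_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 3))
        axes = cross_covariance_svd(X, Y)
        C = X.T @ Y / 5
        # eigenvalue oracle: s^2 are eigenvalues of C C'
        eig = np.sort(np.linalg.eigvalsh(C @ C.T))[::-1][:3]
        np.testing.assert_allclose(axes.singular_values ** 2,
                                   np.clip(eig, 0, None), atol=1e-10)

    def test_cross_projections_diagonalized(self, full_fits, zcohort):
        # the SVD guarantee: cov(X u_i, Y v_j) is diagonal with the
        # singular values on the diagonal
        axes = MechanismSymptomPLS(full_fits, zcohort).fit()
        n = axes.X.shape[0]
        cross = (axes.X @ axes.U).T @ (axes.Y @ axes.V) / (n - 1)
        np.testing.assert_allclose(cross, np.diag(axes.singular_values),
                                   atol=1e-6)

    def test_singular_values_nonincreasing_and_orthonormal(self, full_fits,
                                                           zcohort):
        axes = MechanismSymptomPLS(full_fits, zcohort).fit()
        assert np.all(np.diff(axes.singular_values) <= 1e-12)
        np.testing.assert_allclose(axes.U.T @ axes.U,
                                   np.eye(axes.n_components), atol=1e-8)
        np.testing.assert_allclose(axes.V.T @ axes.V,
                                   np.eye(axes.n_components), atol=1e-8)


class TestProcrustes:
    def test_self_alignment_is_identity(self, rng):
        X = rng.normal(size=(30, 20))
        Y = rng.normal(size=(30, 5))
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        U_a, V_a, s_a = _procrustes_align(axes.V, axes.U, axes.singular_values,
                                          axes.V)
        np.testing.assert_allclose(U_a, axes.U, atol=1e-8)
        np.testing.assert_allclose(V_a, axes.V, atol=1e-8)
        np.testing.assert_allclose(s_a, axes.singular_values, atol=1e-8)


class TestPermutationAndBootstrap:
    def test_add_one_floor(self, rng):
        X = rng.standard_normal((30, 15))
        w = rng.normal(size=(15, 3))
        Y = X @ w + 0.05 * rng.standard_normal((30, 3))
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        p = permutation_test_axes(axes, n_perm=100, seed=0)
        assert p.min() >= 1 / 101
        assert p[0] == pytest.approx(1 / 101)

    def test_n_perm_validation(self, rng):
        X = rng.standard_normal((10, 4))
        axes = cross_covariance_svd(X, X[:, :2])
        with pytest.raises(ParameterError):
            permutation_test_axes(axes, n_perm=50)

    def test_bootstrap_stable_on_strong_structure(self, rng):
        X = rng.standard_normal((60, 10))
        Y = np.column_stack([X[:, 0] * 2, X[:, 1],
                             0.05 * rng.standard_normal(60)])
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        bootstrap_stability(axes, n_boot=200, seed=3)
        # the dominant loading of the first axis is reliably stable
        j = np.argmax(np.abs(axes.U[:, 0]))
        assert axes.stable_mask_U[j, 0]
        assert np.abs(axes.bootstrap_ratios_U[j, 0]) > 3


class TestVariancePerParameter:
    def test_shares_sum_to_one(self, rng):
        X = rng.standard_normal((40, 25))
        Y = rng.standard_normal((40, 6))
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        out = variance_per_parameter(axes, 0, stable_only=False)
        assert out.share.sum() == pytest.approx(1.0, abs=1e-8)

    def test_single_stable_parameter_share_one(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 3))
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        axes.stable_mask_U = np.zeros_like(axes.U, dtype=bool)
        axes.stable_mask_U[2, 0] = True
        out = variance_per_parameter(axes, 0)
        assert out.share[2] == pytest.approx(1.0)
        assert out.share.drop(2).sum() == pytest.approx(0.0)

    def test_grouped_shares_match_oracle(self, rng):
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 4))
        axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
        import pandas as pd
        groups = pd.Series(["a", "a", "b", "b", "b", "c"],
                           index=axes.mech_labels)
        out = variance_per_parameter(axes, 0, grouping=groups,
                                     stable_only=False)
        gs = out.attrs["group_share"]
        for g in ("a", "b", "c"):
            members = [l for l in axes.mech_labels if groups[l] == g]
            expected = out.set_index("parameter").loc[members, "share"].sum() \
                * axes.covariance_explained[0]
            assert gs[g] == pytest.approx(expected)


class TestEndToEnd:
    def test_pipeline_axes_from_fixture(self, full_fits, zcohort):
        axes = MechanismSymptomPLS(full_fits, zcohort).fit(n_perm=100,
                                                           n_boot=100,
                                                           seed=5)
        assert axes.U.shape[0] == 678
        assert axes.V.shape[0] == 11
        assert axes.perm_p is not None and len(axes.perm_p) == 11
        assert axes.stable_mask_U.shape == axes.U.shape
        assert axes.summary()
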