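"""Design assembly, propagation, OLS fitting and nesting properties."""

import numpy as np
import pytest

import remcm
from remcm.design import (build_design_matrix, compute_propagation,
                          compute_rate_of_change, propagation_of_state)
from remcm.exceptions import ConsistencyError, UnderDeterminedError
from remcm.model import FactorDynamicsModel, fit_factor_model
from remcm.simulate import make_cohort


class TestRateOfChange:
    def test_examples(self, zcohort):
        ts = zcohort.subjects[0]
        rates, mids = compute_rate_of_change(ts, "GM")
        assert rates.shape == (ts.n_regions, ts.n_visits - 1)
        m = ts.factor_index("GM")
        dt = np.diff(ts.visit_times)
        np.testing.assert_allclose(
            rates, np.diff(ts.values[m], axis=1) / dt, atol=1e-12)
        np.testing.assert_allclose(
            mids, 0.5 * (ts.visit_times[1:] + ts.visit_times[:-1]))

    def test_step_and_constant(self):
        from test_data_model import toy_timeseries
        gm = np.array([[0.0, 1.0, 1.0]])  # one region, visits at 0,1,2 y
        ts = toy_timeseries(gm)
        rates, _ = compute_rate_of_change(ts, "GM")
        np.testing.assert_allclose(rates[0], [1.0, 0.0])


class TestPropagation:
    def test_uniform_state_is_zero(self):
        W = remcm.generate_connectome(8, seed=0).weights
        np.testing.assert_allclose(propagation_of_state(np.ones(8), W), 0,
                                   atol=1e-12)

    def test_two_region_hand_example(self):
        W = np.array([[0.0, 2.0], [2.0, 0.0]])
        p = propagation_of_state(np.array([0.0, 1.0]), W)
        np.testing.assert_allclose(p, [2.0, -2.0])

    def test_against_double_loop_oracle(self, rng):
        W = remcm.generate_connectome(5, density=0.9, seed=6).weights
        s = rng.normal(size=5)
        oracle = np.array([
            sum(W[i, j] * (s[j] - s[i]) for j in range(5) if j != i)
            for i in range(5)])
        np.testing.assert_allclose(propagation_of_state(s, W), oracle,
                                   atol=1e-12)

    def test_asymmetric_connectome_rejected(self, rng):
        with pytest.raises(ConsistencyError, match="symmetric"):
            propagation_of_state(rng.normal(size=3),
                                 np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0.]]))

    def test_unweighted_sum_telescopes(self, zcohort):
        for visit in range(zcohort.subjects[0].n_visits):
            p = compute_propagation(zcohort.subjects[0], "MD",
                                    zcohort.connectome, visit)
            assert abs(p.sum()) < 1e-10


class TestDesignMatrix:
    def test_column_counts(self, zcohort):
        ts = zcohort.subjects[0]
        full = build_design_matrix(ts, "GM", zcohort.receptors,
                                   zcohort.connectome)
        restricted = build_design_matrix(ts, "GM", zcohort.receptors,
                                         zcohort.connectome, [])
        single = build_design_matrix(ts, "GM", zcohort.receptors,
                                     zcohort.connectome, ["kainate"])
        assert full.n_columns == 113
        assert restricted.n_columns == 8
        assert single.n_columns == 15

    def test_columns_standardized(self, zcohort):
        d = build_design_matrix(zcohort.subjects[3], "FA", zcohort.receptors,
                                zcohort.connectome)
        nonint = [j for j, l in enumerate(d.labels) if l != "const"]
        kept = [j for j in nonint if d.kept[j]]
        assert np.all(np.abs(d.X[:, kept].mean(axis=0)) < 1e-10)
        assert np.all(np.abs(d.X[:, kept].std(axis=0) - 1) < 1e-10)

    def test_midpoint_state_convention(self, zcohort):
        from remcm.design import INTERCEPT_LABEL
        ts = zcohort.subjects[0]
        a = build_design_matrix(ts, "GM", zcohort.receptors,
                                zcohort.connectome)
        b = build_design_matrix(ts, "GM", zcohort.receptors,
                                zcohort.connectome,
                                predictor_states="midpoint")
        assert a.X.shape == b.X.shape
        assert not np.allclose(a.X, b.X)
        np.testing.assert_allclose(a.y, b.y)  # the target is unchanged

    def test_row_count(self, zcohort):
        ts = zcohort.subjects[0]
        d = build_design_matrix(ts, "MD", zcohort.receptors,
                                zcohort.connectome)
        assert d.X.shape[0] == ts.n_regions * (ts.n_visits - 1)


class TestFit:
    def test_exact_linear_target_recovered(self, zcohort, rng):
        d = build_design_matrix(zcohort.subjects[0], "GM", zcohort.receptors,
                                zcohort.connectome)
        beta = rng.normal(size=int(d.kept.sum()))
        d.y = d.X[:, d.kept] @ beta
        res = fit_factor_model(d)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res.params[d.kept], beta, atol=1e-8)

    def test_orthogonal_centered_target_r2_zero(self, zcohort, rng):
        d = build_design_matrix(zcohort.subjects[1], "FA", zcohort.receptors,
                                zcohort.connectome)
        y = rng.normal(size=d.X.shape[0])
        Xk = d.X[:, d.kept]
        beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        d.y = y - Xk @ beta  # orthogonal to all columns incl. intercept
        res = fit_factor_model(d)
        assert res.rsquared == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_oracle(self, zcohort):
        import statsmodels.api as sm
        d = build_design_matrix(zcohort.subjects[2], "DAT", zcohort.receptors,
                                zcohort.connectome)
        res = fit_factor_model(d)
        sm_res = sm.OLS(d.y, d.X[:, d.kept]).fit()
        np.testing.assert_allclose(res.params[d.kept], sm_res.params,
                                   atol=1e-8)
        assert res.ssr == pytest.approx(sm_res.ssr, rel=1e-8)

    def test_under_determined_raises(self):
        cohort, _ = make_cohort(n_subjects=1, n_regions=20,
                                visit_schedule=(0.0, 0.5, 1.0, 1.5), seed=5)
        z = remcm.zscore_imaging(cohort)
        with pytest.raises(UnderDeterminedError, match="restricted"):
            FactorDynamicsModel(z.subjects[0], "GM", z.receptors,
                                z.connectome).fit()

    def test_residuals_orthogonal_to_design(self, full_fits):
        res = full_fits[("sub-004", "MD")]
        Xk = res.design.X[:, res.design.kept]
        dots = Xk.T @ res.resid
        assert np.abs(dots).max() < 1e-6 * max(1.0, np.abs(res.design.y).max())


class TestCohortFits:
    def test_fit_count(self, full_fits):
        assert len(full_fits.fits) == 120
        assert not full_fits.failures

    def test_nested_r2_dominance(self, zcohort, full_fits, restricted_fits):
        single = remcm.fit_cohort(zcohort, ["M2"])
        r2f = full_fits.r2_table().to_numpy()
        r2s = single.r2_table().to_numpy()
        r2r = restricted_fits.r2_table().to_numpy()
        assert np.all(r2f >= r2s - 1e-10)
        assert np.all(r2s >= r2r - 1e-10)

    def test_noise_free_cohort_near_perfect_fit(self):
        cohort, _ = make_cohort(n_subjects=4, n_regions=40, noise_sd=0.0,
                                euler_dt=None, seed=21)
        res = remcm.fit_cohort(remcm.zscore_imaging(cohort))
        assert res.r2_table().median().median() > 0.99

    def test_destandardized_params_reproduce_fit(self, full_fits):
        # params_raw applied to raw predictor values equals the fitted values
        res = full_fits[("sub-000", "GM")]
        d = res.design
        raw = d.X * d.col_sds + d.col_means
        np.testing.assert_allclose(raw @ res.params_raw, res.fittedvalues,
                                   atol=1e-8)

    def test_tidy_export_shape(self, full_fits):
        tidy = full_fits.tidy()
        assert set(tidy.columns) == {"subject_id", "factor", "parameter",
                                     "coefficient"}
        assert len(tidy) == 20 * 6 * 113
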