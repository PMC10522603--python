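"""Generator determinism, structural invariants and dynamical consistency."""

import dataclasses
import time

import numpy as np
import pytest
from scipy import stats

import remcm
from remcm.design import INTERCEPT_LABEL, PROPAGATION_LABEL, design_labels
from remcm.exceptions import ParameterError
from remcm.simulate import (DEFAULT_VISITS, GroundTruth, _dynamics_operator,
                            generate_clinical_from_axes, generate_connectome,
                            generate_receptor_maps, make_ground_truth,
                            simulate_trajectories)


def zero_truth(n_subjects=2, **overrides):
    """Ground truth with all coefficients zero (frozen baseline dynamics)."""
    truth = make_ground_truth(n_subjects, seed=3)
    truth.population_alpha[:] = 0.0
    truth.subject_alpha[:] = 0.0
    truth.sparse_support[:] = False
    for k, v in overrides.items():
        setattr(truth, k, v)
    return truth


class TestReceptorMaps:
    def test_columns_standardized_and_deterministic(self):
        a = generate_receptor_maps(30, 15, smoothness=0.5, seed=9)
        b = generate_receptor_maps(30, 15, smoothness=0.5, seed=9)
        np.testing.assert_array_equal(a.densities, b.densities)
        assert np.allclose(a.densities.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(a.densities.std(axis=0), 1, atol=1e-10)

    def test_zero_smoothness_has_no_spatial_autocorrelation(self):
        rec = generate_receptor_maps(200, 15, smoothness=0.0, seed=2)
        lags = [stats.pearsonr(col[:-1], col[1:])[0]
                for col in rec.densities.T]
        # single-map bound plus an aggregate check (15 maps share the bound
        # only up to Monte-Carlo spread ~ 1/sqrt(200))
        assert abs(lags[0]) < 0.2
        assert np.median(np.abs(lags)) < 0.1

    def test_smoothness_raises_neighbor_correlation(self):
        rec = generate_receptor_maps(200, 15, smoothness=0.8, seed=2)
        lags = [stats.pearsonr(col[:-1], col[1:])[0]
                for col in rec.densities.T]
        assert np.median(lags) > 0.5

    def test_smoothness_out_of_range(self):
        with pytest.raises(ParameterError):
            generate_receptor_maps(20, smoothness=1.0)


class TestConnectome:
    def test_structure(self):
        con = generate_connectome(25, density=0.4, seed=1)
        W = con.weights
        np.testing.assert_array_equal(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert np.all(W >= 0)

    def test_full_density_is_complete(self):
        W = generate_connectome(10, density=1.0, seed=0).weights
        off = ~np.eye(10, dtype=bool)
        assert np.all(W[off] > 0)

    def test_density_within_binomial_band(self):
        # n=50 -> 1225 potential edges; 99% binomial band around 0.2
        W = generate_connectome(50, density=0.2, seed=4).weights
        iu = np.triu_indices(50, k=1)
        frac = (W[iu] > 0).mean()
        half = 2.576 * np.sqrt(0.2 * 0.8 / len(iu[0]))
        assert 0.2 - half <= frac <= 0.2 + half


class TestTrajectories:
    def test_zero_dynamics_constant(self):
        rec = generate_receptor_maps(10, 15, seed=0)
        con = generate_connectome(10, seed=0)
        subs = simulate_trajectories(zero_truth(), rec, con,
                                     noise_sd=0.0, seed=5)
        for s in subs:
            for v in range(1, s.n_visits):
                np.testing.assert_allclose(s.values[..., v],
                                           s.values[..., 0], atol=1e-12)

    def test_propagation_only_conserves_total(self):
        # with symmetric C, sum_i p_i = 0, so the regional total is invariant
        labels = design_labels(remcm.FACTORS, remcm.RECEPTORS)
        truth = zero_truth()
        truth.population_alpha[:, labels.index(PROPAGATION_LABEL)] = 0.4
        truth.subject_alpha[:] = truth.population_alpha[None]
        rec = generate_receptor_maps(15, 15, seed=1)
        con = generate_connectome(15, seed=1)
        subs = simulate_trajectories(truth, rec, con, noise_sd=0.0, seed=2,
                                     max_log_growth=None)
        for s in subs:
            totals = s.values.sum(axis=1)  # (factor, visit)
            np.testing.assert_allclose(totals - totals[:, :1],
                                       np.zeros_like(totals), atol=1e-8)

    def test_discrete_mode_matches_regression_rhs(self):
        # one Euler step per interval: forward difference == model RHS at t'
        rec = generate_receptor_maps(12, 15, seed=3)
        con = generate_connectome(12, seed=3)
        truth = make_ground_truth(2, seed=3)
        subs = simulate_trajectories(truth, rec, con, euler_dt=None,
                                     noise_sd=0.0, seed=4)
        for si, s in enumerate(subs):
            apply_lin, const = _dynamics_operator(
                truth.subject_alpha[si], rec.densities, con.weights,
                truth.param_labels, truth.factor_names, truth.receptor_names,
                None)
            for v in range(s.n_visits - 1):
                dt = s.visit_times[v + 1] - s.visit_times[v]
                fd = (s.values[..., v + 1] - s.values[..., v]) / dt
                rhs = apply_lin(s.values[..., v]) + const
                np.testing.assert_allclose(fd, rhs, atol=1e-9)

    def test_determinism(self):
        rec = generate_receptor_maps(10, 15, seed=0)
        con = generate_connectome(10, seed=0)
        truth1 = make_ground_truth(3, seed=8)
        truth2 = make_ground_truth(3, seed=8)
        a = simulate_trajectories(truth1, rec, con, seed=9)
        b = simulate_trajectories(truth2, rec, con, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_euler_dt_guard(self):
        rec = generate_receptor_maps(8, 15, seed=0)
        con = generate_connectome(8, seed=0)
        with pytest.raises(ParameterError, match="euler_dt"):
            simulate_trajectories(make_ground_truth(1, seed=0), rec, con,
                                  euler_dt=0.2)


class TestClinicalGenerator:
    def test_two_point_slope_recovery(self):
        truth = make_ground_truth(6, seed=2)
        records = generate_clinical_from_axes(truth, noise_sd=0.0, seed=2,
                                              exam_times=(0.0, 1.5))
        planted = truth.planted_slopes()
        for i, rec in enumerate(records):
            np.testing.assert_allclose(remcm.clinical_slopes(rec),
                                       planted[i], atol=1e-10)

    def test_rank_one_loadings_give_rank_one_cross_covariance(self):
        truth = make_ground_truth(40, n_axes=1, axis_strengths=(3.0,), seed=5)
        records = generate_clinical_from_axes(truth, noise_sd=0.0, seed=5)
        slopes = np.array([remcm.clinical_slopes(r) for r in records])
        params = truth.flat_subject_params()
        Z = (params - params.mean(0)) / params.std(0)
        Y = (slopes - slopes.mean(0))
        s = np.linalg.svd(Z.T @ Y, compute_uv=False)
        assert s[1] < 1e-8 * s[0]

    def test_zero_loadings_slopes_are_noise(self):
        truth = make_ground_truth(30, seed=6)
        truth.axis_strengths[:] = 0.0
        records = generate_clinical_from_axes(truth, noise_sd=1.0, seed=6)
        slopes = np.array([remcm.clinical_slopes(r) for r in records])
        # pure noise: no correlation structure with the parameters
        params = truth.flat_subject_params()
        Z = (params - params.mean(0)) / params.std(0)
        r = np.corrcoef(Z[:, 0], slopes[:, 0])[0, 1]
        assert abs(r) < 0.5


class TestCohortFixture:
    def test_default_fixture_fast_and_valid(self, cohort_and_truth):
        t0 = time.time()
        cohort, truth = remcm.make_cohort(seed=99)
        assert time.time() - t0 < 10
        assert cohort.receptors.is_normalized
        assert len(cohort.subjects) == 20
        assert truth.sparse_support.mean() <= 0.20
        # subject deviations centred on the population values
        dev = truth.subject_alpha - truth.population_alpha[None]
        se = dev.std() / np.sqrt(truth.n_subjects)
        assert np.abs(dev.mean(axis=0)).max() < 6 * se
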