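"""Reusable validation studies on synthetic ground truth.

Each function builds its own cohorts from a seed and returns the summary
quantities of one study: structural counts, nested-R^2 dominance,
generative parameter recovery, null calibration of the F- and
permuted-map tests, propagation conservation, latent-axis recovery,
variance-share normalization, the rank-sum oracle check, and
influence-map calibration/power.

Estimator-recovery and test-calibration studies run in the generator's
discrete-exact mode with process noise, where the regression model's
assumptions hold exactly; robustness studies use the continuous
integrator with per-visit observation noise.
"""

from __future__ import annotations

import itertools

import numpy as np

from .axes import (adjust_covariates, cross_covariance_svd,
                   permutation_test_axes)
from .data import Cohort, zscore_imaging
from .design import compute_propagation, design_labels
from .influence import influence_null_z, rank_auroc, wilcoxon_rank_sum
from .model import FactorDynamicsModel, fit_cohort
from .simulate import (generate_clinical_from_axes, generate_connectome,
                       generate_receptor_maps, make_cohort,
                       make_ground_truth, simulate_trajectories)
from .validation import nested_f_test, permutation_test_r2

FOUR_VISITS = (0.0, 0.5, 1.0, 1.5)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# structural counts and algebraic properties
# ---------------------------------------------------------------------------

def design_counts() -> dict[str, int]:
    """Column counts of the full/restricted designs and per-subject total."""
    from .data import FACTORS, RECEPTORS
    full = len(design_labels(FACTORS, RECEPTORS))
    restricted = len(design_labels(FACTORS, ()))
    return {"full": full, "restricted": restricted,
            "per_subject": len(FACTORS) * full}


def nested_dominance_study(seed: int = 0, receptor: str = "M2"):
    """Count R^2 ordering violations full >= single-receptor >= restricted."""
    cohort, _ = make_cohort(seed=seed)
    z = zscore_imaging(cohort)
    r2_full = fit_cohort(z).r2_table().to_numpy()
    r2_single = fit_cohort(z, [receptor]).r2_table().to_numpy()
    r2_restr = fit_cohort(z, []).r2_table().to_numpy()
    tol = 1e-10
    violations = int(np.sum(r2_full < r2_single - tol)
                     + np.sum(r2_single < r2_restr - tol))
    return {"violations": violations, "n_fits": r2_full.size,
            "min_gap_full_single": float((r2_full - r2_single).min()),
            "min_gap_single_restr": float((r2_single - r2_restr).min())}


def recovery_study(seed: int = 0, n_subjects: int = 5, n_regions: int = 95,
                   noise_sd: float = 1e-6):
    """Max |alpha_hat - alpha| over all full-model fits, discrete-exact mode.

    95 regions x 3 intervals give 285 rows for the 113-column design; with
    near-zero process noise the de-standardized OLS coefficients must
    reproduce the generating dynamics.
    """
    cohort, truth = make_cohort(
        n_subjects=n_subjects, n_regions=n_regions,
        visit_schedule=FOUR_VISITS, euler_dt=None, noise_model="process",
        noise_sd=noise_sd, seed=seed)
    # fit on the raw trajectories: the cohort-level modality z-scoring is a
    # linear rescaling that would change the coefficients away from the
    # generative units being recovered
    fits = fit_cohort(Cohort(cohort.subjects, cohort.receptors,
                             cohort.connectome))
    labels = truth.param_labels
    err = 0.0
    for si, sid in enumerate(cohort.subject_ids):
        for m, factor in enumerate(truth.factor_names):
            res = fits[(sid, factor)]
            err = max(err, float(np.abs(
                res.params_raw - truth.subject_alpha[si, m]).max()))
    return {"max_abs_error": err, "n_fits": len(fits.fits)}


def propagation_conservation_study(seed: int = 0, n_regions: int = 20):
    """Max |sum_i p_i| over factors and visits for propagation-only dynamics."""
    truth = make_ground_truth(3, seed=seed)
    truth.population_alpha[:] = 0.0
    labels = truth.param_labels
    truth.population_alpha[:, labels.index("prop")] = 0.4
    truth.subject_alpha[:] = truth.population_alpha[None]
    receptors = generate_receptor_maps(n_regions, seed=seed)
    connectome = generate_connectome(n_regions, seed=seed)
    subjects = simulate_trajectories(truth, receptors, connectome,
                                     noise_sd=0.0, seed=seed,
                                     max_log_growth=None)
    worst = 0.0
    n_checks = 0
    for ts in subjects:
        for factor in ts.factor_names:
            for v in range(ts.n_visits):
                p = compute_propagation(ts, factor, connectome, v)
                worst = max(worst, abs(float(p.sum())))
                n_checks += 1
    return {"max_abs_sum": worst, "n_checks": n_checks}


# ---------------------------------------------------------------------------
# null calibration of the receptor-term tests
# ---------------------------------------------------------------------------

def _null_subject_cohort(seed: int, n_regions: int = 40,
                         noise_sd: float = 0.1):
    """One-subject receptor-free cohort in the exact-model condition."""
    cohort, _ = make_cohort(
        n_subjects=1, n_regions=n_regions, receptor_terms=False,
        euler_dt=None, noise_model="process", noise_sd=noise_sd, seed=seed)
    return zscore_imaging(cohort)


def f_calibration_study(n_rep: int = 1000, seed: int = 0,
                        alpha: float = 0.05, noise_sd: float = 0.003):
    """Nested F-test rejection rate under the receptor-free generator.

    Run at small process noise, where the lagged-state design is
    effectively strictly exogenous and the exact F distribution applies;
    at larger noise the feedback of process noise into later predictors
    genuinely inflates the test (a property of pooled finite-difference
    regressions, not of this implementation).
    """
    rejections = 0
    for s in _child_seeds(seed, n_rep):
        z = _null_subject_cohort(s, noise_sd=noise_sd)
        ts = z.subjects[0]
        full = FactorDynamicsModel(ts, "GM", z.receptors, z.connectome).fit()
        restr = FactorDynamicsModel(ts, "GM", z.receptors, z.connectome,
                                    []).fit()
        _, p = nested_f_test(full, restr)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep}


def perm_calibration_study(n_rep: int = 400, n_perm: int = 200,
                           seed: int = 0, alpha: float = 0.05):
    """Permuted-map R^2 test rejection rate under the receptor-free generator."""
    rejections = 0
    for s in _child_seeds(seed, n_rep):
        z = _null_subject_cohort(s)
        p, _ = permutation_test_r2(z, z.subject_ids[0], "GM",
                                   n_perm=n_perm, seed=s + 1)
        rejections += p <= alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep,
            "n_perm": n_perm}


# ---------------------------------------------------------------------------
# latent-axis (PLS) recovery
# ---------------------------------------------------------------------------

def pls_recovery_replicate(seed: int, n_subjects: int = 80,
                           n_perm: int = 500, alpha: float = 0.05):
    """One planted-rank-2 replicate; returns per-component p and angles."""
    truth = make_ground_truth(n_subjects, seed=seed)
    clinical = generate_clinical_from_axes(truth, noise_sd=0.3, seed=seed + 1)
    params = truth.flat_subject_params()
    cov = np.array([c.covariates for c in clinical])
    slopes = np.array([[s for s in _slopes(c)] for c in clinical])
    X, _ = adjust_covariates(params, cov)
    Y, _ = adjust_covariates(slopes, cov)
    axes = cross_covariance_svd(X, Y)
    p = permutation_test_axes(axes, n_perm=n_perm, seed=seed + 2)
    # principal angles between recovered and planted rank-2 subspaces;
    # the planted loadings are mapped into the analysis (z-scored,
    # adjusted) coordinates via the mechanism covariance
    target = (X.T @ X / (X.shape[0] - 1)) @ truth.latent_loadings_mech
    Q_true = np.linalg.qr(target)[0]
    cosines = np.linalg.svd(axes.U[:, :2].T @ Q_true, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(cosines, -1, 1)))
    return {"p": p[:3], "max_angle_deg": float(angles.max()),
            "detected": bool(p[0] < alpha and p[1] < alpha and p[2] > 0.1)}


def _slopes(record):
    from .axes import clinical_slopes
    return clinical_slopes(record)


def pls_recovery_study(n_rep: int = 50, seed: int = 0, n_perm: int = 500):
    """Fraction of replicates detecting exactly the two planted axes."""
    detected = 0
    angle_ok = 0
    angles = []
    for s in _child_seeds(seed, n_rep):
        rep = pls_recovery_replicate(s, n_perm=n_perm)
        detected += rep["detected"]
        angle_ok += rep["max_angle_deg"] < 20.0
        angles.append(rep["max_angle_deg"])
    return {"detection_rate": detected / n_rep,
            "angle_rate": angle_ok / n_rep,
            "median_max_angle_deg": float(np.median(angles)),
            "n_rep": n_rep}


def variance_share_sum(seed: int = 0):
    """Sum of per-parameter variance shares along the leading axis."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((40, 30))
    Y = rng.standard_normal((40, 8))
    axes = cross_covariance_svd(X - X.mean(0), Y - Y.mean(0))
    from .axes import variance_per_parameter
    out = variance_per_parameter(axes, 0, stable_only=False)
    return {"share_sum": float(out.share.sum()), "n_params": len(out)}


# ---------------------------------------------------------------------------
# rank-sum oracle and influence maps
# ---------------------------------------------------------------------------

def wilcoxon_oracle_check(seed: int = 0, n_instances: int = 5):
    """Max |statistic - enumeration oracle| over all splits n1+n2 <= 10."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for n1, n2 in itertools.product(range(1, 10), repeat=2):
        if n1 + n2 > 10:
            continue
        for _ in range(n_instances):
            for draw in ("continuous", "tied"):
                if draw == "continuous":
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                else:
                    x = rng.integers(0, 3, size=n1).astype(float)
                    y = rng.integers(0, 3, size=n2).astype(float)
                oracle = _midrank_oracle(x, y)
                worst = max(worst, abs(wilcoxon_rank_sum(x, y) - oracle))
                n_checked += 1
    return {"max_abs_diff": worst, "n_instances": n_checked}


def _midrank_oracle(sample, other):
    combined = list(sample) + list(other)
    total = 0.0
    for x in sample:
        below = sum(1 for v in combined if v < x)
        ties = sum(1 for v in combined if v == x)
        total += below + (ties + 1) / 2
    return total


def influence_calibration_study(n_rep: int = 25, n_perm: int = 100,
                                seed: int = 0, n_subjects: int = 12,
                                n_regions: int = 25, alpha: float = 0.05):
    """Fraction of significant regions under the receptor-free generator."""
    significant = 0
    total = 0
    for s in _child_seeds(seed, n_rep):
        cohort, _ = make_cohort(n_subjects=n_subjects, n_regions=n_regions,
                                visit_schedule=FOUR_VISITS,
                                receptor_terms=False, seed=s)
        z = zscore_imaging(cohort)
        imap = influence_null_z(z, "M2", "MD", n_perm=n_perm, seed=s + 1,
                                alpha=alpha)
        significant += int(imap.table.significant.sum())
        total += len(imap.table)
    return {"significant_fraction": significant / total, "n_regions": total,
            "n_rep": n_rep}


def make_planted_influence_cohort(seed: int, n_subjects: int = 40,
                                  n_regions: int = 30, receptor: str = "M2",
                                  factor: str = "MD", n_top: int = 10,
                                  coef: float = 0.6):
    """Receptor-free cohort plus a strong receptor pathway in a region subset.

    The designated subset is the ``n_top`` regions with the largest
    |density| of the planted receptor — where its terms can actually move
    the dynamics.  Returns (cohort, subset mask).
    """
    seeds = _child_seeds(seed, 4)
    receptors = generate_receptor_maps(n_regions, seed=seeds[0])
    k = receptors.receptor_names.index(receptor)
    order = np.argsort(-np.abs(receptors.densities[:, k]))
    mask = np.zeros(n_regions, dtype=bool)
    mask[order[:n_top]] = True
    forced = {(factor, f"r[{receptor}]*S[GM]"): coef,
              (factor, f"r[{receptor}]*S[{factor}]"): coef,
              (factor, f"r[{receptor}]"): 0.8 * coef}
    truth = make_ground_truth(n_subjects, receptor_terms=False,
                              forced=forced, seed=seeds[2])
    truth.region_support = mask
    connectome = generate_connectome(n_regions, seed=seeds[1])
    subjects = simulate_trajectories(truth, receptors, connectome,
                                     euler_dt=None, noise_model="process",
                                     seed=seeds[3])
    return Cohort(subjects, receptors, connectome), mask


def influence_power_study(n_rep: int = 5, n_perm: int = 150, seed: int = 0):
    """Mean AUROC of influence z-scores against the planted region subset."""
    aurocs = []
    for s in _child_seeds(seed, n_rep):
        cohort, mask = make_planted_influence_cohort(s)
        z = zscore_imaging(cohort)
        imap = influence_null_z(z, "M2", "MD", n_perm=n_perm, seed=s + 1)
        aurocs.append(rank_auroc(imap.table.z.to_numpy(), mask))
    return {"mean_auroc": float(np.mean(aurocs)),
            "aurocs": [float(a) for a in aurocs], "n_rep": n_rep}
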