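"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: six
co-evolving biological factors obeying the locally linear receptor-enriched
dynamics, z-scored receptor maps with tunable spatial smoothness, a
symmetric nonnegative connectome, and clinical decline rates carrying a
planted low-rank dependence on the per-subject model coefficients.

Two simulation modes are provided:

* continuous (``euler_dt`` a small number): explicit Euler integration of
  the differential equation, recorded at the visit schedule.  The forward
  difference between visits then equals the time-averaged right-hand side,
  which differs from the regression model's instantaneous RHS by a term of
  order the inter-visit gap.
* discrete-exact (``euler_dt=None``): one Euler step per inter-visit
  interval.  The generative map coincides exactly with the regression
  model, which is the appropriate condition for estimator-recovery and
  test-calibration studies.

Noise placements (``noise_model``):

* ``"visit"`` (default): i.i.d. Gaussian observation noise added to each
  recorded visit.  Consecutive finite-difference rows then share an
  endpoint, giving MA(1) regression errors.
* ``"process"``: Gaussian noise injected into the dynamics between
  recordings (unmodeled biological variability).  Regression errors are
  then i.i.d. given the predictors, so classical OLS inference is exact.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .data import (ASSESSMENTS, FACTORS, RECEPTORS, ClinicalRecord, Cohort,
                   Connectome, ReceptorMatrix, SubjectTimeSeries)
from .design import PROPAGATION_LABEL, INTERCEPT_LABEL, design_labels
from .exceptions import ParameterError, StabilityError

logger = logging.getLogger(__name__)

DEFAULT_VISITS = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclasses.dataclass
class GroundTruth:
    """Generating coefficients and planted latent structure of a cohort.

    ``population_alpha``/``subject_alpha`` are on the raw (un-standardized)
    predictor scale, aligned with :func:`remcm.design.design_labels`.
    """

    population_alpha: np.ndarray          # (n_factors, n_params)
    subject_alpha: np.ndarray             # (n_subjects, n_factors, n_params)
    sparse_support: np.ndarray            # bool (n_factors, n_params)
    latent_loadings_mech: np.ndarray      # (n_factors*n_params, n_axes)
    latent_loadings_sym: np.ndarray       # (n_assessments, n_axes)
    axis_strengths: np.ndarray            # (n_axes,)
    noise_sd: float
    seed: int
    factor_names: Sequence[str] = FACTORS
    receptor_names: Sequence[str] = RECEPTORS
    #: optional region mask restricting receptor-mediated terms (planted
    #: regional receptor influence); None -> receptor terms act everywhere
    region_support: np.ndarray | None = None

    @property
    def param_labels(self) -> list[str]:
        return design_labels(self.factor_names, self.receptor_names)

    @property
    def n_subjects(self) -> int:
        return self.subject_alpha.shape[0]

    def flat_subject_params(self) -> np.ndarray:
        """(n_subjects, n_factors*n_params) view used for latent planting."""
        return self.subject_alpha.reshape(self.n_subjects, -1)

    def planted_slopes(self, params: np.ndarray | None = None) -> np.ndarray:
        """Noiseless clinical decline slopes implied by the latent axes.

        Per-subject latent scores (z-scored coefficients projected onto the
        mechanism loadings) are standardized per axis, scaled by
        ``axis_strengths`` and mapped through the symptom loadings.
        """
        if params is None:
            params = self.flat_subject_params()
        params = np.asarray(params, float)
        sd = params.std(axis=0)
        Z = np.where(sd > 0, (params - params.mean(axis=0))
                     / np.where(sd == 0, 1, sd), 0.0)
        T = Z @ self.latent_loadings_mech
        t_sd = T.std(axis=0)
        T = (T - T.mean(axis=0)) / np.where(t_sd == 0, 1, t_sd)
        return T @ np.diag(self.axis_strengths) @ self.latent_loadings_sym.T


def make_ground_truth(n_subjects: int,
                      factor_names: Sequence[str] = FACTORS,
                      receptor_names: Sequence[str] = RECEPTORS,
                      n_nonzero: int = 15,
                      effect_scale: float = 0.35,
                      self_decay: float = 0.3,
                      drift_sd: float = 0.1,
                      jitter_sd: float = 0.03,
                      n_modes: int = 5,
                      mode_sd: float = 0.1,
                      n_axes: int = 2,
                      axis_strengths: Sequence[float] = (4.0, 2.0),
                      noise_sd: float = 0.1,
                      receptor_terms: bool = True,
                      forced: Mapping[tuple[str, str], float] | None = None,
                      seed: int = 0) -> GroundTruth:
    """Draw sparse population dynamics plus structured per-subject variation.

    Each factor's own state always enters with a stabilizing negative
    coefficient (-``self_decay``) and the intercept carries a small drift;
    ``n_nonzero`` further mechanisms per factor are drawn at random with
    magnitudes in [0.5, 1] x ``effect_scale`` and random sign.

    Between-subject coefficient deviations are low-rank plus noise:
    ``n_modes`` shared variation modes (per-coefficient scale ``mode_sd``)
    with standard-normal subject scores, plus i.i.d. jitter ``jitter_sd``.
    This emulates the strong cross-coefficient correlation of fitted
    mechanism matrices; fully isotropic 678-dimensional variation would
    make any latent mechanism-symptom axis undetectable at cohort sizes.
    The first ``n_axes`` modes (normalized) are the planted mechanism
    loadings linking coefficients to clinical decline.

    With ``receptor_terms=False`` both the population support and all
    subject-level variation are confined to the neuroimaging-only columns
    (a true receptor-free generator).
    """
    rng = np.random.default_rng(seed)
    labels = design_labels(factor_names, receptor_names)
    n_fac, n_par = len(factor_names), len(labels)
    alpha = np.zeros((n_fac, n_par))
    support = np.zeros((n_fac, n_par), dtype=bool)
    i_const = labels.index(INTERCEPT_LABEL)
    i_prop = labels.index(PROPAGATION_LABEL)
    restricted_idx = [labels.index(f"S[{n}]") for n in factor_names] + [i_prop]

    for m, factor in enumerate(factor_names):
        i_self = labels.index(f"S[{factor}]")
        alpha[m, i_self] = -self_decay
        alpha[m, i_const] = drift_sd * rng.standard_normal()
        support[m, [i_self, i_const]] = True
        pool = (np.array(restricted_idx) if not receptor_terms
                else np.arange(n_par - 1))  # intercept excluded from pool
        pool = pool[pool != i_self]
        chosen = rng.choice(pool, size=min(n_nonzero, pool.size),
                            replace=False)
        mags = effect_scale * rng.uniform(0.5, 1.0, size=chosen.size)
        signs = rng.choice([-1.0, 1.0], size=chosen.size)
        alpha[m, chosen] = mags * signs
        support[m, chosen] = True

    if forced:
        for (factor, label), value in forced.items():
            m = list(factor_names).index(factor)
            j = labels.index(label)
            alpha[m, j] = value
            support[m, j] = value != 0

    # subject deviations confined to the admissible columns
    var_mask = np.zeros((n_fac, n_par), dtype=bool)
    if receptor_terms:
        var_mask[:] = True
    else:
        var_mask[:, restricted_idx] = True
        var_mask[:, i_const] = True
    flat_mask = var_mask.ravel().astype(float)

    modes = mode_sd * rng.standard_normal((n_modes, n_fac * n_par))
    modes *= flat_mask[None, :]
    scores = rng.standard_normal((n_subjects, n_modes))
    jitter = jitter_sd * rng.standard_normal((n_subjects, n_fac * n_par))
    jitter *= flat_mask[None, :]
    subject_alpha = (alpha.ravel()[None] + scores @ modes + jitter
                     ).reshape(n_subjects, n_fac, n_par)

    n_axes = int(n_axes)
    lm = modes[:n_axes].T.copy()
    norms = np.linalg.norm(lm, axis=0)
    lm = lm / np.where(norms == 0, 1.0, norms)
    ls = np.linalg.qr(rng.standard_normal((len(ASSESSMENTS), n_axes)))[0]
    return GroundTruth(
        population_alpha=alpha, subject_alpha=subject_alpha,
        sparse_support=support, latent_loadings_mech=lm,
        latent_loadings_sym=ls,
        axis_strengths=np.asarray(axis_strengths, float)[:n_axes],
        noise_sd=noise_sd, seed=seed, factor_names=tuple(factor_names),
        receptor_names=tuple(receptor_names))


def generate_receptor_maps(n_regions: int, n_receptors: int = 15,
                           smoothness: float = 0.3, seed: int = 0,
                           receptor_names: Sequence[str] | None = None,
                           ) -> ReceptorMatrix:
    """Spatially correlated Gaussian receptor maps, column-z-scored.

    Columns are draws from a multivariate normal on a ring lattice whose
    neighboring regions correlate at ``smoothness``; 0 gives i.i.d. maps.
    """
    if not 0 <= smoothness < 1:
        raise ParameterError("smoothness must be in [0, 1)")
    if n_regions < 4:
        raise ParameterError("need at least 4 regions")
    if receptor_names is None:
        receptor_names = (RECEPTORS if n_receptors == 15 else
                          tuple(f"REC{i:02d}" for i in range(n_receptors)))
    rng = np.random.default_rng(seed)
    idx = np.arange(n_regions)
    ring_dist = np.minimum(np.abs(idx[:, None] - idx[None, :]),
                           n_regions - np.abs(idx[:, None] - idx[None, :]))
    cov = smoothness ** ring_dist
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0, None))
    for _ in range(10):
        raw = root @ rng.standard_normal((n_regions, n_receptors))
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        corr = np.corrcoef(z.T)
        np.fill_diagonal(corr, 0)
        if np.max(np.abs(corr)) < 0.9:
            return ReceptorMatrix(z, receptor_names=receptor_names)
    raise StabilityError("could not draw receptor maps with inter-receptor "
                         "correlations below 0.9")


def generate_connectome(n_regions: int, density: float = 0.3,
                        seed: int = 0) -> Connectome:
    """Symmetric nonnegative random connectome with given edge density.

    Off-diagonal pairs are present independently with probability
    ``density``; weights are log-normal (tract-count-like heavy tail),
    rescaled so the largest nodal strength (row sum) is 1 — the overall
    connectome scale is arbitrary in tract-count units and a bounded graph
    Laplacian keeps the propagation term on the same footing as the local
    couplings.
    """
    if not 0 < density <= 1:
        raise ParameterError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    present = rng.random(iu[0].size) < density
    weights = rng.lognormal(mean=0.0, sigma=0.5, size=iu[0].size) * present
    W[iu] = weights
    W = W + W.T
    max_strength = W.sum(axis=1).max()
    if max_strength > 0:
        W = W / max_strength
    return Connectome(W)


def _dynamics_operator(alpha: np.ndarray, R: np.ndarray, W: np.ndarray,
                       labels: list[str], factor_names, receptor_names,
                       region_support: np.ndarray | None):
    """Return (apply, const) with apply(S) the linear part of dS/dt.

    ``S`` has shape (n_factors, n_regions).
    """
    n_fac = len(factor_names)
    n_rec = len(receptor_names)
    n_reg = R.shape[0]
    idx = {l: j for j, l in enumerate(labels)}
    A0 = np.array([[alpha[m, idx[f"S[{n}]"]] for n in factor_names]
                   for m in range(n_fac)])
    AI = np.array([[[alpha[m, idx[f"r[{k}]*S[{n}]"]] for k in receptor_names]
                    for n in factor_names] for m in range(n_fac)])
    AR = np.array([[alpha[m, idx[f"r[{k}]"]] for k in receptor_names]
                   for m in range(n_fac)])
    ap = np.array([alpha[m, idx[PROPAGATION_LABEL]] for m in range(n_fac)])
    const = np.repeat(
        np.array([alpha[m, idx[INTERCEPT_LABEL]] for m in range(n_fac)]
                 )[:, None], n_reg, axis=1)

    mask = (np.ones(n_reg) if region_support is None
            else region_support.astype(float))
    # per-region effective factor-coupling matrix G[m, n, i]
    G = A0[:, :, None] + np.einsum("mnk,ik->mni", AI, R * mask[:, None])
    rec_term = (AR @ R.T) * mask[None, :]
    degree = W.sum(axis=1)

    def apply_linear(S: np.ndarray) -> np.ndarray:
        local = np.einsum("mni,ni->mi", G, S)
        prop = S @ W.T - S * degree[None, :]
        return local + ap[:, None] * prop

    return apply_linear, rec_term + const


def _dense_operator(alpha, R, W, labels, factor_names, receptor_names,
                    region_support):
    """Dense (n_fac*n_reg)^2 matrix of the linear dynamics (for spectra)."""
    n_fac = len(factor_names)
    n_reg = R.shape[0]
    apply_lin, _ = _dynamics_operator(alpha, R, W, labels, factor_names,
                                      receptor_names, region_support)
    A = np.empty((n_fac * n_reg, n_fac * n_reg))
    basis = np.zeros((n_fac, n_reg))
    for j in range(n_fac * n_reg):
        basis.flat[j] = 1.0
        A[:, j] = apply_lin(basis).ravel()
        basis.flat[j] = 0.0
    return A


def _operator_norm(apply_linear, n_fac, n_reg, rng, n_iter=30):
    v = rng.standard_normal((n_fac, n_reg))
    v /= np.linalg.norm(v)
    norm = 0.0
    for _ in range(n_iter):
        w = apply_linear(v)
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        v = w / norm
    return norm


def simulate_trajectories(truth: GroundTruth, receptors: ReceptorMatrix,
                          connectome: Connectome,
                          visit_schedule: Sequence[float] = DEFAULT_VISITS,
                          euler_dt: float | None = 0.01,
                          noise_sd: float | None = None,
                          seed: int = 0,
                          noise_model: str = "visit",
                          max_log_growth: float | None = 1.0,
                          ) -> list[SubjectTimeSeries]:
    """Integrate the receptor-enriched dynamics for every subject.

    Baseline states are standard normal per region and factor (matching
    the z-scored imaging convention).  ``euler_dt=None`` selects the
    discrete-exact mode (one update per inter-visit interval).  If the
    per-step update would be unstable (step size x operator norm > 0.95),
    all dynamic coefficients of the ground truth are rescaled in place and
    a warning is logged.

    ``max_log_growth`` caps the dominant exponential growth of every
    subject's dynamics over the visit horizon: if the largest real
    eigenvalue exceeds the cap, extra self-decay is added to every
    factor's own-state coefficient (an exact diagonal shift of the
    operator, recorded in the ground truth in place).  This keeps
    simulated pathology on the O(1) scale of z-scored imaging; set it to
    None to disable.
    """
    if noise_model not in ("visit", "process"):
        raise ParameterError("noise_model must be 'visit' or 'process'")
    visit_schedule = np.asarray(visit_schedule, float)
    gaps = np.diff(visit_schedule)
    if np.any(gaps <= 0):
        raise ParameterError("visit_schedule must be strictly increasing")
    if euler_dt is not None and euler_dt > gaps.min() / 10:
        raise ParameterError("euler_dt must be <= min inter-visit gap / 10")
    if noise_sd is None:
        noise_sd = truth.noise_sd
    if not receptors.is_normalized:
        receptors = receptors.zscore()
    if truth.region_support is not None and \
            len(truth.region_support) != receptors.n_regions:
        raise ParameterError("region_support length does not match regions")

    rng = np.random.default_rng(seed)
    n_fac = len(truth.factor_names)
    n_reg = receptors.n_regions
    labels = truth.param_labels
    step = gaps.max() if euler_dt is None else euler_dt

    # horizon-growth guard: shift self-decay so the dominant eigenvalue of
    # every subject's operator keeps log-growth below max_log_growth
    if max_log_growth is not None:
        horizon = visit_schedule[-1] - visit_schedule[0]
        lam = -np.inf
        for alpha_s in truth.subject_alpha:
            A = _dense_operator(alpha_s, receptors.densities,
                                connectome.weights, labels,
                                truth.factor_names, truth.receptor_names,
                                truth.region_support)
            lam = max(lam, float(np.max(np.linalg.eigvals(A).real)))
        cap = max_log_growth / horizon
        if lam > cap:
            delta = lam - cap
            logger.warning("self-decay increased by %.3g for horizon "
                           "stability", delta)
            for m, factor in enumerate(truth.factor_names):
                j = labels.index(f"S[{factor}]")
                truth.population_alpha[m, j] -= delta
                truth.subject_alpha[:, m, j] -= delta

    # stability guard on the population dynamics
    apply_pop, _ = _dynamics_operator(
        truth.population_alpha, receptors.densities, connectome.weights,
        labels, truth.factor_names, truth.receptor_names,
        truth.region_support)
    norm = _operator_norm(apply_pop, n_fac, n_reg, np.random.default_rng(1))
    if step * norm > 0.95:
        scale = 0.95 / (step * norm)
        logger.warning("dynamics rescaled by %.3g for per-step stability",
                       scale)
        i_const = labels.index(INTERCEPT_LABEL)
        dyn = np.ones(len(labels)) * scale
        dyn[i_const] = 1.0
        truth.population_alpha *= dyn
        truth.subject_alpha *= dyn

    out = []
    for s in range(truth.n_subjects):
        apply_lin, const = _dynamics_operator(
            truth.subject_alpha[s], receptors.densities, connectome.weights,
            labels, truth.factor_names, truth.receptor_names,
            truth.region_support)
        S = rng.standard_normal((n_fac, n_reg))
        recorded = np.empty((n_fac, n_reg, len(visit_schedule)))
        recorded[:, :, 0] = S
        t = visit_schedule[0]
        for v, t_next in enumerate(visit_schedule[1:], start=1):
            if euler_dt is None:
                dt = t_next - t
                S = S + dt * (apply_lin(S) + const)
                if noise_model == "process" and noise_sd > 0:
                    S = S + noise_sd * rng.standard_normal(S.shape)
            else:
                while t < t_next - 1e-12:
                    dt = min(euler_dt, t_next - t)
                    S = S + dt * (apply_lin(S) + const)
                    if noise_model == "process" and noise_sd > 0:
                        S = S + noise_sd * np.sqrt(dt) * \
                            rng.standard_normal(S.shape)
                    t += dt
            t = t_next
            if np.max(np.abs(S)) > 1e8:
                raise StabilityError(
                    "simulated trajectories diverged; use smaller "
                    "coefficients or a shorter horizon")
            recorded[:, :, v] = S
        if noise_model == "visit" and noise_sd > 0:
            recorded = recorded + noise_sd * rng.standard_normal(
                recorded.shape)
        out.append(SubjectTimeSeries(
            f"sub-{s:03d}", recorded, visit_schedule,
            truth.factor_names, receptors.region_names))
    return out


def generate_clinical_from_axes(truth: GroundTruth,
                                params: np.ndarray | None = None,
                                noise_sd: float = 0.3,
                                seed: int = 0,
                                exam_times: Sequence[float] = (0.0, 1.0, 2.0),
                                ) -> list[ClinicalRecord]:
    """Clinical records whose decline slopes carry the planted latent axes.

    Per-subject slopes are :meth:`GroundTruth.planted_slopes` plus Gaussian
    noise; scores are exactly linear in time around a random baseline, so
    per-assessment OLS slopes recover the planted slopes when ``noise_sd``
    is the only stochastic term.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = truth.flat_subject_params()
    params = np.asarray(params, float)
    n_sub = params.shape[0]
    slopes = truth.planted_slopes(params)
    if noise_sd > 0:
        slopes = slopes + noise_sd * rng.standard_normal(slopes.shape)

    times = np.asarray(exam_times, float)
    records = []
    for s in range(n_sub):
        baseline = rng.standard_normal(len(ASSESSMENTS))
        scores = baseline[:, None] + slopes[s][:, None] * times[None, :]
        age = rng.normal(61.0, 9.0)
        edu = np.clip(rng.normal(15.0, 3.0), 6, 24)
        sex = float(rng.integers(0, 2))
        records.append(ClinicalRecord(
            f"sub-{s:03d}", scores, times,
            np.array([age, edu, sex])))
    return records


def make_cohort(n_subjects: int = 20, n_regions: int = 40,
                n_receptors: int = 15,
                visit_schedule: Sequence[float] = DEFAULT_VISITS,
                smoothness: float = 0.3, density: float = 0.3,
                noise_sd: float = 0.1, clinical_noise_sd: float = 0.3,
                euler_dt: float | None = 0.01, noise_model: str = "visit",
                receptor_terms: bool = True, seed: int = 0,
                truth: GroundTruth | None = None,
                ) -> tuple[Cohort, GroundTruth]:
    """One-call synthetic cohort: receptors, connectome, imaging, clinical."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    receptors = generate_receptor_maps(n_regions, n_receptors,
                                       smoothness, seed=int(seeds[0]))
    connectome = generate_connectome(n_regions, density, seed=int(seeds[1]))
    if truth is None:
        truth = make_ground_truth(
            n_subjects, receptor_names=receptors.receptor_names,
            noise_sd=noise_sd, receptor_terms=receptor_terms,
            seed=int(seeds[2]))
    subjects = simulate_trajectories(
        truth, receptors, connectome, visit_schedule, euler_dt=euler_dt,
        noise_sd=noise_sd, seed=int(seeds[3]), noise_model=noise_model)
    clinical = generate_clinical_from_axes(
        truth, noise_sd=clinical_noise_sd, seed=int(seeds[3]) + 1)
    return Cohort(subjects, receptors, connectome, clinical), truth
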