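"""Latent axes linking model mechanisms to clinical decline (PLS-SVD).

The mechanism matrix X (subjects x 678 coefficients) and symptom matrix Y
(subjects x 11 clinical decline slopes) are covariate-adjusted
(baseline age, education, sex), z-scored, and their cross-covariance
C = X'Y/(n-1) is decomposed by SVD, C = U S V'.  Component significance
uses permutations of the subject correspondence with orthogonal-Procrustes
alignment of the permuted axes and a max-singular-value (FWE) null;
loading stability uses subject-level bootstrap with the same alignment.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy import stats

from .data import ClinicalRecord, Cohort
from .exceptions import ConsistencyError, ParameterError
from .model import CohortResults

logger = logging.getLogger(__name__)

BOOTSTRAP_RATIO_CAP = 1e6


def clinical_slopes(record: ClinicalRecord) -> np.ndarray:
    """Per-assessment OLS slope (score units / year) over available visits.

    Assessments with fewer than two non-missing visits get NaN (flagged,
    not fatal).
    """
    t = record.exam_times
    out = np.full(record.scores.shape[0], np.nan)
    for a in range(record.scores.shape[0]):
        y = record.scores[a]
        ok = np.isfinite(y)
        if ok.sum() < 2:
            continue
        tt = t[ok]
        yy = y[ok]
        tc = tt - tt.mean()
        denom = (tc ** 2).sum()
        if denom == 0:
            continue
        out[a] = float((tc * yy).sum() / denom)
    return out


def symptom_slopes_table(clinical: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Subjects x assessments table of decline slopes."""
    rows = {c.subject_id: clinical_slopes(c) for c in clinical}
    names = clinical[0].assessment_names
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(names))


def covariate_table(clinical: Sequence[ClinicalRecord]) -> pd.DataFrame:
    rows = {c.subject_id: c.covariates for c in clinical}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["age", "education", "sex"])


def adjust_covariates(X_raw: np.ndarray, covariates: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Residualize each column on [1, age, education, sex], then z-score.

    Returns ``(Z, kept)``: columns whose residuals are (numerically)
    degenerate are zeroed and flagged False in ``kept`` — they carry no
    information beyond the covariates and are dropped from the SVD.
    """
    X_raw = np.asarray(X_raw, float)
    C = np.column_stack([np.ones(len(covariates)),
                         np.asarray(covariates, float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ParameterError("covariate matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(C, X_raw, rcond=None)
    resid = X_raw - C @ beta
    sd = resid.std(axis=0)
    scale_ref = np.abs(X_raw).std(axis=0) + np.abs(X_raw).mean(axis=0)
    kept = sd > 1e-10 * np.maximum(scale_ref, 1.0)
    if not kept.all():
        logger.warning("%d column(s) degenerate after covariate adjustment; "
                       "dropped from SVD", int((~kept).sum()))
    Z = np.zeros_like(resid)
    Z[:, kept] = resid[:, kept] / sd[kept]
    return Z, kept


@dataclasses.dataclass
class LatentAxes:
    """SVD of the mechanism-symptom cross-covariance plus inference extras."""

    U: np.ndarray                      # (n_mech, K) mechanism saliences
    V: np.ndarray                      # (n_sym, K) symptom saliences
    singular_values: np.ndarray        # (K,)
    covariance_explained: np.ndarray   # (K,), fractions summing to 1
    projection_r: np.ndarray           # (K,) corr(X u_k, Y v_k)
    mech_labels: list
    sym_labels: list
    X: np.ndarray
    Y: np.ndarray
    kept_mech: np.ndarray
    perm_p: np.ndarray | None = None
    stable_mask_U: np.ndarray | None = None
    stable_mask_V: np.ndarray | None = None
    bootstrap_ratios_U: np.ndarray | None = None
    bootstrap_ratios_V: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def summary(self) -> str:
        lines = ["Mechanism-symptom latent axes"]
        for k in range(self.n_components):
            p = "  p=%.4g" % self.perm_p[k] if self.perm_p is not None else ""
            lines.append(
                f"  axis {k + 1}: s={self.singular_values[k]:.4f}  "
                f"cov expl {self.covariance_explained[k]:6.1%}  "
                f"r={self.projection_r[k]:+.3f}{p}")
        return "\n".join(lines)


def _svd_axes(X: np.ndarray, Y: np.ndarray):
    n = X.shape[0]
    C = X.T @ Y / (n - 1)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    return U, s, Vt.T


def cross_covariance_svd(X: np.ndarray, Y: np.ndarray,
                         mech_labels=None, sym_labels=None,
                         kept_mech: np.ndarray | None = None,
                         explained: str = "squared") -> LatentAxes:
    """Decompose C = X'Y/(n-1) into latent axes.

    ``explained`` selects the covariance-explained convention:
    ``"squared"`` (s_k^2 / sum s^2, the dominant PLS convention, default)
    or ``"linear"`` (s_k / sum s).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ConsistencyError("X and Y must have aligned subject rows")
    if X.shape[0] < 3:
        raise ParameterError("need at least 3 subjects")
    U, s, V = _svd_axes(X, Y)
    if explained == "squared":
        frac = s ** 2 / (s ** 2).sum()
    elif explained == "linear":
        frac = s / s.sum()
    else:
        raise ParameterError("explained must be 'squared' or 'linear'")
    proj_r = np.empty(len(s))
    for k in range(len(s)):
        xs, ys = X @ U[:, k], Y @ V[:, k]
        proj_r[k] = (np.corrcoef(xs, ys)[0, 1]
                     if xs.std() > 0 and ys.std() > 0 else np.nan)
    if mech_labels is None:
        mech_labels = list(range(X.shape[1]))
    if sym_labels is None:
        sym_labels = list(range(Y.shape[1]))
    if kept_mech is None:
        kept_mech = np.ones(X.shape[1], dtype=bool)
    return LatentAxes(U=U, V=V, singular_values=s,
                      covariance_explained=frac, projection_r=proj_r,
                      mech_labels=list(mech_labels),
                      sym_labels=list(sym_labels), X=X, Y=Y,
                      kept_mech=kept_mech)


def _procrustes_align(V_ref, U_p, s_p, V_p):
    """Align a resampled decomposition to reference symptom loadings.

    The rotation is computed on the well-conditioned symptom side and
    applied to both sides; aligned singular values are the column norms of
    V_p diag(s_p) R (equal to the norms of diag(s_p) R since V_p has
    orthonormal columns).
    """
    R, _ = orthogonal_procrustes(V_p, V_ref)
    M = np.diag(s_p) @ R
    s_aligned = np.linalg.norm(M, axis=0)
    return U_p @ R, V_p @ R, s_aligned


def permutation_test_axes(axes: LatentAxes, n_perm: int = 1000,
                          seed: int = 0) -> np.ndarray:
    """FWE-corrected permutation p per component (stored on ``axes``).

    Rows of Y are shuffled, the SVD recomputed and Procrustes-aligned;
    each observed singular value is compared against the null distribution
    of the *largest* aligned null singular value (max-statistic FWE).
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = axes.X.shape[0]
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        Yp = axes.Y[rng.permutation(n)]
        U_p, s_p, V_p = _svd_axes(axes.X, Yp)
        _, _, s_aligned = _procrustes_align(axes.V, U_p, s_p, V_p)
        max_null[b] = s_aligned.max()
    p = (1 + (max_null[None, :] >= axes.singular_values[:, None]).sum(axis=1)
         ) / (n_perm + 1)
    axes.perm_p = p
    return p


def bootstrap_stability(axes: LatentAxes, n_boot: int = 1000,
                        level: float = 0.95, seed: int = 0):
    """Bootstrap loading stability: percentile CIs and bootstrap ratios.

    Subjects are resampled with replacement (resamples with <3 distinct
    subjects are redrawn); each replicate decomposition is aligned to the
    original axes.  A loading is stable when its CI excludes zero; the
    bootstrap ratio is the original loading over the replicate SD, capped
    at 1e6 for degenerate (zero-variance) loadings.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = axes.X.shape[0]
    K = axes.n_components
    boot_U = np.empty((n_boot, *axes.U.shape))
    boot_V = np.empty((n_boot, *axes.V.shape))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= 3:
                break
            logger.warning("bootstrap resample had <3 distinct subjects; redrawn")
        U_b, s_b, V_b = _svd_axes(axes.X[idx], axes.Y[idx])
        U_b, V_b = U_b[:, :K], V_b[:, :K]
        s_b = s_b[:K]
        boot_U[b], boot_V[b], _ = _procrustes_align(axes.V, U_b, s_b, V_b)
    lo_q, hi_q = (1 - level) / 2, 0.5 + level / 2

    def _stats(orig, boot):
        lo = np.quantile(boot, lo_q, axis=0)
        hi = np.quantile(boot, hi_q, axis=0)
        stable = (lo > 0) | (hi < 0)
        se = boot.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(se > 0, orig / np.where(se == 0, 1, se),
                             np.sign(orig) * BOOTSTRAP_RATIO_CAP)
        ratio = np.clip(ratio, -BOOTSTRAP_RATIO_CAP, BOOTSTRAP_RATIO_CAP)
        return stable, ratio

    axes.stable_mask_U, axes.bootstrap_ratios_U = _stats(axes.U, boot_U)
    axes.stable_mask_V, axes.bootstrap_ratios_V = _stats(axes.V, boot_V)
    return axes.stable_mask_U, axes.stable_mask_V


def variance_per_parameter(axes: LatentAxes, component: int,
                           grouping: pd.Series | None = None,
                           stable_only: bool = True) -> pd.DataFrame:
    """Per-parameter variance shares U^2 / sum U^2 along one axis.

    Restricted to bootstrap-stable parameters when masks are available.
    ``grouping``, if given, maps mechanism labels to groups; grouped
    shares are scaled by the component's covariance-explained fraction.
    """
    u = axes.U[:, component]
    mask = np.ones(len(u), dtype=bool)
    if stable_only and axes.stable_mask_U is not None:
        mask = axes.stable_mask_U[:, component]
    if not mask.any():
        return pd.DataFrame(columns=["parameter", "share", "group_share"])
    u2 = np.where(mask, u ** 2, 0.0)
    shares = u2 / u2.sum()
    out = pd.DataFrame({"parameter": axes.mech_labels, "share": shares})
    if grouping is not None:
        g = out["parameter"].map(grouping)
        gs = out.groupby(g)["share"].sum() * \
            axes.covariance_explained[component]
        out = out.assign(group=g)
        out.attrs["group_share"] = gs
    return out


class MechanismSymptomPLS:
    """Model object: builds X and Y from a cohort's fits and clinical data.

    ``fit()`` performs covariate adjustment, z-scoring and the
    cross-covariance SVD, returning a :class:`LatentAxes` results object.
    """

    def __init__(self, fits: CohortResults | pd.DataFrame,
                 cohort: Cohort | None = None,
                 explained: str = "squared"):
        if isinstance(fits, CohortResults):
            cohort = cohort or fits.cohort
            coefs = fits.coef_table()
        else:
            coefs = fits
        if cohort is None or not cohort.clinical:
            raise ParameterError("cohort with clinical records required")
        slopes = symptom_slopes_table(cohort.clinical)
        cov = covariate_table(cohort.clinical)
        order = [s for s in coefs.index if s in slopes.index]
        self.subject_ids = order
        self.coefs = coefs.loc[order]
        self.slopes = slopes.loc[order]
        self.covariates = cov.loc[order]
        self.explained = explained

    def fit(self, n_perm: int = 0, n_boot: int = 0, level: float = 0.95,
            seed: int = 0) -> LatentAxes:
        X_raw = self.coefs.to_numpy(float)
        Y_raw = self.slopes.to_numpy(float)
        if np.isnan(Y_raw).any():
            raise ConsistencyError(
                "missing clinical slopes; all 11 assessments need >=2 visits")
        cov = self.covariates.to_numpy(float)
        X, kept_x = adjust_covariates(X_raw, cov)
        Y, kept_y = adjust_covariates(Y_raw, cov)
        if not kept_y.all():
            raise ConsistencyError("degenerate symptom column after adjustment")
        axes = cross_covariance_svd(
            X, Y, mech_labels=list(self.coefs.columns),
            sym_labels=list(self.slopes.columns), kept_mech=kept_x,
            explained=self.explained)
        rng = np.random.default_rng(seed)
        if n_perm:
            permutation_test_axes(axes, n_perm,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        if n_boot:
            bootstrap_stability(axes, n_boot, level,
                                seed=int(rng.integers(0, 2**31 - 1)))
        return axes
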