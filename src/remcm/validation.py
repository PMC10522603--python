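"""Receptor-term validation: nested F-tests, permuted-map nulls, Fisher's method.

The contribution of receptor densities and receptor-pathology interactions
is quantified two ways: a nested F-test of the full (113-parameter) model
against the neuroimaging-only (8-parameter) model on the same rows, and a
one-sided permutation test comparing the full-model R^2 against models
refitted with receptor maps shuffled across regions independently per
receptor.  Subject-level permutation p-values are combined per factor with
Fisher's method.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import Cohort, ReceptorMatrix
from .exceptions import ParameterError
from .model import FactorDynamicsModel, FactorDynamicsResults, fit_factor_model
from .design import build_design_matrix


def nested_f_test(full: FactorDynamicsResults,
                  restricted: FactorDynamicsResults) -> tuple[float, float]:
    """F-test of nested OLS fits on identical rows.

    F = ((RSS_r - RSS_f)/(p_f - p_r)) / (RSS_f/(n - p_f)), with the p-value
    from the F(p_f - p_r, n - p_f) distribution.
    """
    n = full.nobs
    if restricted.nobs != n:
        raise ParameterError("fits must share the same rows")
    p_f, p_r = full.df_model, restricted.df_model
    if p_f <= p_r:
        raise ParameterError("'full' model must have more parameters")
    if n <= p_f:
        raise ParameterError("residual degrees of freedom are not positive")
    num = (restricted.ssr - full.ssr) / (p_f - p_r)
    den = full.ssr / (n - p_f)
    F = num / den if den > 0 else np.inf
    p = float(stats.f.sf(F, p_f - p_r, n - p_f))
    return float(F), p


def permute_receptor_matrix(receptors: ReceptorMatrix,
                            seed: int | np.random.Generator = 0,
                            ) -> ReceptorMatrix:
    """Shuffle each receptor's densities across regions independently."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    perm = np.empty_like(receptors.densities)
    for k in range(receptors.n_receptors):
        perm[:, k] = receptors.densities[rng.permutation(receptors.n_regions), k]
    return ReceptorMatrix(perm, receptors.receptor_names,
                          receptors.region_names)


def permutation_test_r2(cohort: Cohort, subject: str, factor: str,
                        n_perm: int = 1000, seed: int = 0,
                        ) -> tuple[float, np.ndarray]:
    """One-sided permuted-receptor-map test of the full-model R^2.

    Returns the add-one p-value (1 + #{null R^2 >= observed}) / (n_perm + 1)
    and the null R^2 vector.  Failed null fits are dropped (and shrink the
    effective n_perm); they are counted via the returned vector's length.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    ts = next(s for s in cohort.subjects if s.subject_id == subject)
    receptors = (cohort.receptors if cohort.receptors.is_normalized
                 else cohort.receptors.zscore())
    observed = FactorDynamicsModel(ts, factor, receptors,
                                   cohort.connectome).fit().rsquared
    rng = np.random.default_rng(seed)
    null_r2 = []
    for _ in range(n_perm):
        permuted = permute_receptor_matrix(receptors, rng)
        try:
            res = fit_factor_model(build_design_matrix(
                ts, factor, permuted, cohort.connectome))
        except Exception:
            continue
        null_r2.append(res.rsquared)
    null_r2 = np.asarray(null_r2)
    b = len(null_r2)
    p = (1 + int(np.sum(null_r2 >= observed))) / (b + 1)
    return float(p), null_r2


def fishers_method(p_values, floor: float | None = None,
                   ) -> tuple[float, int, float]:
    """Fisher's combination: chi^2 = -2 sum ln p with df = 2 len(p).

    Zero p-values are invalid (the add-one permutation rule cannot produce
    them); if ``floor`` is given they are clipped to it with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        if floor is not None and np.all(p <= 1) and np.all(p >= 0):
            warnings.warn("p-values of 0 clipped to the permutation floor")
            p = np.clip(p, floor, 1.0)
        else:
            raise ParameterError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclasses.dataclass
class ValidationReport:
    """Per-fit F/permutation results and per-factor summaries."""

    per_fit: pd.DataFrame      # subject_id, factor, F, f_p, r2_full, r2_restricted, perm_p
    per_factor: pd.DataFrame   # factor, frac_f_significant, frac_perm_significant, fisher_chi2, fisher_p
    n_perm: int
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [f"Model validation (n_perm={self.n_perm}, alpha={self.alpha})"]
        for row in self.per_factor.itertuples(index=False):
            lines.append(
                f"  {row.factor:<6s} F-sig {row.frac_f_significant:5.1%}  "
                f"perm-sig {row.frac_perm_significant:5.1%}  "
                f"Fisher chi2 {row.fisher_chi2:9.1f} (p={row.fisher_p:.3g})")
        return "\n".join(lines)


def validate_cohort(cohort: Cohort, n_perm: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> ValidationReport:
    """Run nested F-tests and permuted-map R^2 tests for every fit."""
    receptors = (cohort.receptors if cohort.receptors.is_normalized
                 else cohort.receptors.zscore())
    rng = np.random.default_rng(seed)
    rows = []
    factors = cohort.subjects[0].factor_names
    for ts in cohort.subjects:
        for factor in factors:
            full = FactorDynamicsModel(ts, factor, receptors,
                                       cohort.connectome).fit()
            restr = FactorDynamicsModel(ts, factor, receptors,
                                        cohort.connectome, []).fit()
            F, f_p = nested_f_test(full, restr)
            perm_p, _ = permutation_test_r2(
                cohort, ts.subject_id, factor, n_perm,
                seed=int(rng.integers(0, 2**31 - 1)))
            rows.append((ts.subject_id, factor, F, f_p, full.rsquared,
                         restr.rsquared, perm_p))
    per_fit = pd.DataFrame(rows, columns=[
        "subject_id", "factor", "F", "f_p", "r2_full", "r2_restricted",
        "perm_p"])
    frows = []
    for factor in factors:
        sub = per_fit[per_fit.factor == factor]
        chi2, df, fp = fishers_method(sub.perm_p)
        frows.append((factor, (sub.f_p < alpha).mean(),
                      (sub.perm_p < alpha).mean(), chi2, fp))
    per_factor = pd.DataFrame(frows, columns=[
        "factor", "frac_f_significant", "frac_perm_significant",
        "fisher_chi2", "fisher_p"])
    return ValidationReport(per_fit, per_factor, n_perm, alpha)
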