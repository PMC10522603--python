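"""Regional receptor-influence maps.

For one receptor k and factor m, every subject is fitted with the
single-receptor model (direct factor terms, receptor-k interactions and
density, propagation, intercept) and with the neuroimaging-only model.
Residuals are internally studentized, pooled per region across subjects
and intervals, and the Wilcoxon rank-sum statistic of the *restricted*
model's absolute residuals within the combined sample measures how much
the receptor terms improve the fit at that region.  The statistic is
referenced to a null distribution from region-shuffled receptor maps,
yielding per-region z-scores and one-sided empirical p-values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import Cohort, ReceptorMatrix
from .exceptions import ParameterError
from .model import FactorDynamicsModel, FactorDynamicsResults

_LEVERAGE_TOL = 1e-8


def studentize_residuals(fit: FactorDynamicsResults) -> np.ndarray:
    """Internally studentized residuals r_i / (sigma_hat sqrt(1 - h_i)).

    Rows with leverage >= 1 - 1e-8 fall back to plain z-scored residuals;
    a fit with zero residual variance returns zeros (degenerate).
    """
    e = fit.resid
    if fit.df_resid <= 0 or fit.ssr == 0:
        return np.zeros_like(e)
    h = fit.leverage()
    sigma = np.sqrt(fit.ssr / fit.df_resid)
    bad = h >= 1 - _LEVERAGE_TOL
    t = np.empty_like(e)
    t[~bad] = e[~bad] / (sigma * np.sqrt(1 - h[~bad]))
    if bad.any():
        sd = e.std()
        t[bad] = (e[bad] - e.mean()) / sd if sd > 0 else 0.0
    return t


def wilcoxon_rank_sum(sample: np.ndarray, other: np.ndarray) -> float:
    """Rank-sum of ``sample`` within the combined sample, with midranks.

    For identical distributions the expectation is n1 (n1 + n2 + 1) / 2;
    a larger value means ``sample`` tends to rank above ``other``.
    """
    n1 = len(sample)
    ranks = rankdata(np.concatenate([sample, other]))
    return float(ranks[:n1].sum())


def regional_wilcoxon(restricted_resids: np.ndarray,
                      single_resids: np.ndarray) -> np.ndarray:
    """Per-region rank-sum of |restricted| vs |single-receptor| residuals.

    Both inputs have shape (n_regions, n_samples); absolute values are
    compared, so any strictly monotone transform of the pooled magnitudes
    leaves the statistic unchanged.  High values mean the restricted
    model's residuals are larger, i.e. the receptor improves the fit.
    """
    restricted_resids = np.atleast_2d(restricted_resids)
    single_resids = np.atleast_2d(single_resids)
    if restricted_resids.shape[0] != single_resids.shape[0]:
        raise ParameterError("region dimensions differ")
    out = np.empty(restricted_resids.shape[0])
    for i in range(len(out)):
        out[i] = wilcoxon_rank_sum(np.abs(restricted_resids[i]),
                                   np.abs(single_resids[i]))
    return out


@dataclasses.dataclass
class InfluenceMap:
    """Per-region receptor-influence statistics for one receptor x factor."""

    receptor: str
    factor: str
    table: pd.DataFrame  # region, w, null_mean, null_sd, z, p, significant
    n_perm: int

    def summary(self) -> str:
        sig = int(self.table.significant.sum())
        return (f"Influence map {self.receptor} -> {self.factor}: "
                f"{sig}/{len(self.table)} regions significant "
                f"(n_perm={self.n_perm})")


def _pooled_studentized(cohort: Cohort, factor: str,
                        receptors: ReceptorMatrix,
                        receptor_subset) -> np.ndarray:
    """(n_regions, n_subjects * n_intervals) studentized residual pool."""
    blocks = []
    for ts in cohort.subjects:
        fit = FactorDynamicsModel(ts, factor, receptors, cohort.connectome,
                                  receptor_subset).fit()
        t = studentize_residuals(fit)
        blocks.append(t.reshape(fit.design.n_intervals,
                                fit.design.n_regions).T)
    return np.concatenate(blocks, axis=1)


def influence_null_z(cohort: Cohort, receptor: str, factor: str,
                     n_perm: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> InfluenceMap:
    """Receptor-influence map with a permuted-receptor-map null.

    The restricted model has no receptor terms, so its residuals are
    computed once and reused across permutations.  ``z`` compares the
    observed per-region statistic to the null mean/SD; the significance
    flag uses the one-sided add-one empirical p-value.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    receptors = (cohort.receptors if cohort.receptors.is_normalized
                 else cohort.receptors.zscore())
    k = receptors.receptor_names.index(receptor)
    restricted = _pooled_studentized(cohort, factor, receptors, [])
    single = _pooled_studentized(cohort, factor, receptors, [receptor])
    w_obs = regional_wilcoxon(restricted, single)

    rng = np.random.default_rng(seed)
    n_reg = receptors.n_regions
    null_w = np.empty((n_perm, n_reg))
    densities = receptors.densities.copy()
    for b in range(n_perm):
        perm = densities.copy()
        perm[:, k] = densities[rng.permutation(n_reg), k]
        perm_rec = ReceptorMatrix(perm, receptors.receptor_names,
                                  receptors.region_names)
        single_b = _pooled_studentized(cohort, factor, perm_rec, [receptor])
        null_w[b] = regional_wilcoxon(restricted, single_b)

    null_mean = null_w.mean(axis=0)
    null_sd = null_w.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (w_obs - null_mean) / null_sd, np.nan)
    p = (1 + (null_w >= w_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    table = pd.DataFrame({
        "region": list(receptors.region_names),
        "w": w_obs, "null_mean": null_mean, "null_sd": null_sd,
        "z": z, "p": p, "significant": p < alpha,
    })
    return InfluenceMap(receptor, factor, table, n_perm)


def rank_auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUROC of ``scores`` for the boolean ``positives`` (rank formula)."""
    scores = np.asarray(scores, float)
    positives = np.asarray(positives, bool)
    n1, n0 = positives.sum(), (~positives).sum()
    if n1 == 0 or n0 == 0:
        raise ParameterError("need both positive and negative regions")
    ranks = rankdata(scores)
    return float((ranks[positives].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
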