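"""Design-matrix assembly for the receptor-enriched dynamical model.

For a subject and target factor *m*, the regression explains the local rate
of change of *m* at every region and inter-visit interval by

* 6 direct factor terms          S_n(t')
* 90 receptor-interaction terms  r_k * S_n(t')
* 15 direct receptor terms       r_k
* 1 connectome-propagation term  p_m(t') = sum_j C_ij (S_mj - S_mi)
* 1 intercept

for 113 columns in the full model.  Predictor states are evaluated at the
interval's start visit t' (forward-difference convention) and every
non-intercept column is standardized over the rows of that model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .data import Connectome, ReceptorMatrix, SubjectTimeSeries
from .exceptions import ConsistencyError, ParameterError

#: pairwise-correlation threshold above which a duplicate column is pruned
COLLINEARITY_TOL = 0.9999

INTERCEPT_LABEL = "const"
PROPAGATION_LABEL = "prop"


def compute_rate_of_change(ts: SubjectTimeSeries, factor: str):
    """Forward-difference rate (S(t) - S(t')) / (t - t') per region/interval.

    Returns ``(rates, midpoints)`` with ``rates`` of shape
    (n_regions, n_intervals).
    """
    m = ts.factor_index(factor)
    dt = np.diff(ts.visit_times)
    if np.any(dt == 0):
        raise ZeroDivisionError("duplicate visit times")
    rates = np.diff(ts.values[m], axis=1) / dt
    midpoints = 0.5 * (ts.visit_times[1:] + ts.visit_times[:-1])
    return rates, midpoints


def compute_propagation(ts: SubjectTimeSeries, factor: str,
                        connectome: Connectome, visit: int) -> np.ndarray:
    """Net connectome-weighted inflow p_i = sum_j C_ij (S_j - S_i) at a visit.

    With a symmetric connectome the unweighted sum over regions telescopes
    to zero exactly.
    """
    if connectome.region_names != ts.region_names:
        raise ConsistencyError("connectome regions do not match time series")
    s = ts.values[ts.factor_index(factor), :, visit]
    return propagation_of_state(s, connectome.weights)


def propagation_of_state(state: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Propagation of a region-state vector (or (n_regions, k) stack)."""
    if not np.allclose(weights, weights.T, atol=1e-12):
        raise ConsistencyError("propagation requires a symmetric connectome")
    degree = weights.sum(axis=1)
    if state.ndim == 1:
        return weights @ state - degree * state
    return weights @ state - degree[:, None] * state


def design_labels(factor_names: Sequence[str],
                  receptor_names: Sequence[str]) -> list[str]:
    """Ordered predictor labels for a given factor/receptor set."""
    labels = [f"S[{n}]" for n in factor_names]
    for n in factor_names:
        labels += [f"r[{k}]*S[{n}]" for k in receptor_names]
    labels += [f"r[{k}]" for k in receptor_names]
    labels += [PROPAGATION_LABEL, INTERCEPT_LABEL]
    return labels


@dataclasses.dataclass
class DesignMatrix:
    """Standardized predictors and the rate-of-change target for one model.

    Rows are ordered interval-major: all regions of interval 0, then all
    regions of interval 1, ...  ``X`` holds the standardized columns;
    ``kept`` flags columns surviving degeneracy/collinearity pruning.
    """

    X: np.ndarray
    y: np.ndarray
    labels: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray
    kept: np.ndarray
    n_regions: int
    n_intervals: int
    subject_id: str
    factor: str

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def intercept_index(self) -> int:
        return self.labels.index(INTERCEPT_LABEL)


def build_design_matrix(ts: SubjectTimeSeries, factor: str,
                        receptors: ReceptorMatrix, connectome: Connectome,
                        receptor_subset: Sequence[str] | None = None,
                        predictor_states: str = "start",
                        ) -> DesignMatrix:
    """Assemble the (standardized) design for one subject x factor model.

    ``receptor_subset=None`` uses all receptors (full, 113-column model);
    an empty subset gives the 8-column neuroimaging-only model; a single
    receptor gives the 15-column single-receptor model.

    ``predictor_states`` selects where states entering the predictors are
    evaluated: at the interval's start visit t' (default,
    forward-difference convention) or as the ``"midpoint"`` average of the
    two endpoint visits.
    """
    if predictor_states not in ("start", "midpoint"):
        raise ParameterError("predictor_states must be 'start' or 'midpoint'")
    if receptor_subset is None:
        rec_names = list(receptors.receptor_names)
    else:
        unknown = set(receptor_subset) - set(receptors.receptor_names)
        if unknown:
            raise ParameterError(f"unknown receptor(s) {sorted(unknown)}")
        rec_names = [k for k in receptors.receptor_names if k in set(receptor_subset)]
    if not receptors.is_normalized:
        receptors = receptors.zscore()
    rec_idx = [receptors.receptor_names.index(k) for k in rec_names]
    R = receptors.densities[:, rec_idx]  # (n_regions, n_rec)

    m = ts.factor_index(factor)
    n_reg, n_vis = ts.n_regions, ts.n_visits
    n_int = n_vis - 1
    dt = np.diff(ts.visit_times)

    if predictor_states == "start":
        states = ts.values[:, :, :-1]                  # (fac, reg, interval)
    else:
        states = 0.5 * (ts.values[:, :, :-1] + ts.values[:, :, 1:])
    y = (np.diff(ts.values[m], axis=1) / dt).T.ravel()  # interval-major

    prop = propagation_of_state(states[m], connectome.weights)

    n_fac = ts.n_factors
    n_rec = len(rec_names)
    cols = []
    # direct factor terms
    for n in range(n_fac):
        cols.append(states[n].T.ravel())
    # receptor x factor interactions
    for n in range(n_fac):
        for k in range(n_rec):
            cols.append((R[:, k][:, None] * states[n]).T.ravel())
    # direct receptor terms (repeat across intervals)
    for k in range(n_rec):
        cols.append(np.tile(R[:, k], n_int))
    cols.append(prop.T.ravel())
    cols.append(np.ones(n_reg * n_int))
    X = np.column_stack(cols)
    labels = design_labels(ts.factor_names, rec_names)

    # standardize non-intercept columns (population SD)
    p = X.shape[1]
    col_means = np.zeros(p)
    col_sds = np.ones(p)
    kept = np.ones(p, dtype=bool)
    nonint = np.arange(p - 1)
    mu = X[:, nonint].mean(axis=0)
    sd = X[:, nonint].std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    X[:, nonint] = (X[:, nonint] - mu) / sd_safe
    col_means[nonint] = mu
    col_sds[nonint] = sd_safe
    kept[nonint] = ~degenerate

    # prune near-duplicate columns (|corr| > COLLINEARITY_TOL), keep first
    live = [j for j in nonint if kept[j]]
    if live:
        Z = X[:, live]
        corr = np.abs((Z.T @ Z) / Z.shape[0])
        over = np.argwhere(np.triu(corr, k=1) > COLLINEARITY_TOL)
        for a, b in over:  # rare; ordered so earlier columns win
            if kept[live[a]] and kept[live[b]]:
                kept[live[b]] = False

    return DesignMatrix(X=X, y=y, labels=labels, col_means=col_means,
                        col_sds=col_sds, kept=kept, n_regions=n_reg,
                        n_intervals=n_int, subject_id=ts.subject_id,
                        factor=factor)
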