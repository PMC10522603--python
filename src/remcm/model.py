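"""Per-subject dynamical-model fitting (statsmodels-style Model/Results).

`FactorDynamicsModel` wraps the design for one subject and target factor;
its `fit()` solves the ordinary-least-squares problem and returns a
`FactorDynamicsResults`.  `CohortModel` fits every subject x factor model
of a cohort and aggregates coefficient and goodness-of-fit tables.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .data import Cohort, Connectome, ReceptorMatrix, SubjectTimeSeries
from .design import DesignMatrix, build_design_matrix
from .exceptions import UnderDeterminedError


class FactorDynamicsModel:
    """OLS model of one factor's regional rate of change for one subject.

    Parameters
    ----------
    ts : SubjectTimeSeries
        Z-scored imaging trajectories of the subject.
    factor : str
        Target biological factor (must be present in ``ts``).
    receptors, connectome :
        Receptor atlas and symmetric connectome shared across subjects.
    receptor_subset : sequence of str, optional
        ``None`` -> full model (all receptors); ``[]`` -> neuroimaging-only
        restricted model; a single receptor -> single-receptor model.
    """

    def __init__(self, ts: SubjectTimeSeries, factor: str,
                 receptors: ReceptorMatrix, connectome: Connectome,
                 receptor_subset: Sequence[str] | None = None):
        self.design = build_design_matrix(ts, factor, receptors, connectome,
                                          receptor_subset)

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "FactorDynamicsModel":
        obj = cls.__new__(cls)
        obj.design = design
        return obj

    def fit(self) -> "FactorDynamicsResults":
        return fit_factor_model(self.design)


@dataclasses.dataclass
class FactorDynamicsResults:
    """OLS estimates for one subject x factor model.

    ``params`` are on the standardized-predictor scale (the paper's
    "relative effect size" convention); ``params_raw`` undo the column
    standardization so coefficients are comparable to generative dynamics.
    Pruned (degenerate/collinear) columns carry zero in both.
    """

    design: DesignMatrix
    params: np.ndarray
    params_raw: np.ndarray
    resid: np.ndarray
    fittedvalues: np.ndarray
    rsquared: float
    ssr: float
    nobs: int
    df_model: int

    @property
    def subject_id(self) -> str:
        return self.design.subject_id

    @property
    def factor(self) -> str:
        return self.design.factor

    @property
    def df_resid(self) -> int:
        return self.nobs - self.df_model

    @property
    def pruned_labels(self) -> list[str]:
        return [l for l, k in zip(self.design.labels, self.design.kept) if not k]

    def leverage(self) -> np.ndarray:
        """Hat-matrix diagonal of the kept standardized design."""
        Xk = self.design.X[:, self.design.kept]
        Q, _ = np.linalg.qr(Xk)
        return np.einsum("ij,ij->i", Q, Q)

    def resid_by_region(self) -> np.ndarray:
        """Residuals reshaped to (n_regions, n_intervals)."""
        return self.resid.reshape(self.design.n_intervals,
                                  self.design.n_regions).T

    def summary(self) -> str:
        d = self.design
        lines = [
            f"Factor dynamics OLS  subject={self.subject_id}  factor={self.factor}",
            f"  rows: {self.nobs}  columns: {d.n_columns} "
            f"(fitted {self.df_model}, pruned {d.n_columns - self.df_model})",
            f"  R^2: {self.rsquared:.4f}   RSS: {self.ssr:.4g}",
        ]
        order = np.argsort(-np.abs(self.params))[:10]
        lines.append("  largest standardized coefficients:")
        for j in order:
            lines.append(f"    {d.labels[j]:<22s} {self.params[j]:+.4f}")
        return "\n".join(lines)


def fit_factor_model(design: DesignMatrix) -> FactorDynamicsResults:
    """Solve the OLS problem of a design and score it.

    R^2 follows the convention of comparing against the subject-wise mean
    rate pooled over all regions and intervals; it is stored unclipped and
    can be negative for pathological fits.
    """
    Xk = design.X[:, design.kept]
    n, p = Xk.shape
    if n <= p:
        raise UnderDeterminedError(
            f"{n} rows <= {p} columns for subject {design.subject_id}, "
            f"factor {design.factor}; use a restricted receptor subset or "
            "more visits/regions")
    beta_k = scipy.linalg.lstsq(Xk, design.y, lapack_driver="gelsy")[0]
    fitted = Xk @ beta_k
    resid = design.y - fitted
    ssr = float(resid @ resid)
    ybar = design.y.mean()
    tss = float(((design.y - ybar) ** 2).sum())
    rsquared = 1.0 - ssr / tss if tss > 0 else float("nan")

    params = np.zeros(design.n_columns)
    params[design.kept] = beta_k
    # undo per-column standardization: beta_raw = beta/sd, intercept absorbs means
    params_raw = params / design.col_sds
    i0 = design.intercept_index
    params_raw[i0] = params[i0] - float(
        np.sum(np.delete(params * design.col_means / design.col_sds, i0)))
    return FactorDynamicsResults(
        design=design, params=params, params_raw=params_raw, resid=resid,
        fittedvalues=fitted, rsquared=rsquared, ssr=ssr, nobs=n, df_model=p)


class CohortModel:
    """Fits one `FactorDynamicsModel` per subject per factor."""

    def __init__(self, cohort: Cohort,
                 receptor_subset: Sequence[str] | None = None):
        self.cohort = cohort
        self.receptor_subset = receptor_subset
        # z-score receptors once; the same normalized atlas enters every model
        self.receptors = (cohort.receptors if cohort.receptors.is_normalized
                          else cohort.receptors.zscore())

    def fit(self) -> "CohortResults":
        fits: dict[tuple[str, str], FactorDynamicsResults] = {}
        failures: dict[tuple[str, str], str] = {}
        for ts in self.cohort.subjects:
            for factor in ts.factor_names:
                key = (ts.subject_id, factor)
                try:
                    fits[key] = FactorDynamicsModel(
                        ts, factor, self.receptors, self.cohort.connectome,
                        self.receptor_subset).fit()
                except Exception as exc:  # collected, not fatal
                    failures[key] = f"{type(exc).__name__}: {exc}"
        return CohortResults(self.cohort, fits, failures, self.receptor_subset)


@dataclasses.dataclass
class CohortResults:
    """All per-subject, per-factor fits of a cohort plus tidy exports."""

    cohort: Cohort
    fits: dict[tuple[str, str], FactorDynamicsResults]
    failures: dict[tuple[str, str], str]
    receptor_subset: Sequence[str] | None = None

    def __getitem__(self, key) -> FactorDynamicsResults:
        return self.fits[key]

    @property
    def factor_names(self) -> tuple[str, ...]:
        return self.cohort.subjects[0].factor_names

    def r2_table(self) -> pd.DataFrame:
        """Subjects x factors table of R^2 (NaN for failed fits)."""
        subs = self.cohort.subject_ids
        data = {f: [self.fits[(s, f)].rsquared if (s, f) in self.fits
                    else np.nan for s in subs]
                for f in self.factor_names}
        return pd.DataFrame(data, index=subs)

    def coef_table(self, scale: str = "standardized") -> pd.DataFrame:
        """Subjects x (factor, parameter) coefficient table.

        ``scale`` is ``"standardized"`` (default, the paper's effect-size
        convention) or ``"raw"`` (de-standardized, generative units).
        """
        attr = {"standardized": "params", "raw": "params_raw"}[scale]
        subs = self.cohort.subject_ids
        blocks = []
        for f in self.factor_names:
            labels = None
            rows = []
            for s in subs:
                res = self.fits.get((s, f))
                if res is None:
                    rows.append(None)
                else:
                    labels = res.design.labels
                    rows.append(getattr(res, attr))
            rows = [np.full(len(labels), np.nan) if r is None else r
                    for r in rows]
            cols = pd.MultiIndex.from_product([[f], labels],
                                              names=["factor", "parameter"])
            blocks.append(pd.DataFrame(np.vstack(rows), index=subs,
                                       columns=cols))
        return pd.concat(blocks, axis=1)

    def tidy(self, scale: str = "standardized") -> pd.DataFrame:
        """Long-format coefficients: subject_id, factor, parameter, coefficient."""
        wide = self.coef_table(scale)
        out = wide.stack(level=["factor", "parameter"], future_stack=True)
        out.index.names = ["subject_id", "factor", "parameter"]
        return out.rename("coefficient").reset_index()

    def summary(self) -> str:
        r2 = self.r2_table()
        lines = [
            f"Cohort fit: {len(self.fits)} models "
            f"({len(self.cohort.subjects)} subjects x "
            f"{len(self.factor_names)} factors), "
            f"{len(self.failures)} failed",
            "  per-factor R^2 (median [IQR]):",
        ]
        for f in self.factor_names:
            q = r2[f].quantile([0.25, 0.5, 0.75])
            lines.append(f"    {f:<6s} {q[0.5]:.3f} [{q[0.25]:.3f}, {q[0.75]:.3f}]")
        for key, msg in self.failures.items():
            lines.append(f"  skipped {key}: {msg}")
        return "\n".join(lines)


def fit_cohort(cohort: Cohort,
               receptor_subset: Sequence[str] | None = None) -> CohortResults:
    """Convenience wrapper: ``CohortModel(cohort, receptor_subset).fit()``."""
    return CohortModel(cohort, receptor_subset).fit()
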