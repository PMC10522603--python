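"""Domain types, file I/O and normalization conventions.

The analysis treats the brain as a set of labelled regions carrying six
imaging-derived biological factors (gray-matter density, fALFF, DAT-SPECT
uptake, FA, MD and the t1/t2 ratio), a 15-receptor density atlas and a
symmetric anatomical connectome.  Everything downstream consumes the
validated containers defined here.

Conventions
-----------
* All z-scoring uses the population (divide-by-n) standard deviation.
* Region identity is by exact string label; files must agree label-for-label.
* Time is measured in years since baseline.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, DegenerateInputError, FormatError

#: Canonical biological-factor labels (imaging modalities).
FACTORS = ("GM", "fALFF", "DAT", "FA", "MD", "t1t2")

#: Canonical neurotransmitter-receptor labels of the autoradiography atlas.
RECEPTORS = (
    "AMPA", "NMDA", "kainate", "GABAA", "GABAB", "Bz",
    "M1", "M2", "M3", "alpha4beta2", "alpha1", "alpha2",
    "5HT1A", "5HT2", "D1",
)

#: Clinical assessments whose longitudinal slopes enter the symptom matrix.
ASSESSMENTS = (
    "BJLOT", "GDS", "HVLT", "LNS", "NP1", "NP2", "NP3",
    "MoCA", "SF", "STAIAD", "SDM",
)

COVARIATE_NAMES = ("age", "education", "sex")


@dataclasses.dataclass
class SubjectTimeSeries:
    """Regional values of each biological factor over a subject's visits.

    ``values`` has shape (n_factors, n_regions, n_visits); ``visit_times``
    are years since baseline and must be strictly increasing.
    """

    subject_id: str
    values: np.ndarray
    visit_times: np.ndarray
    factor_names: Sequence[str] = FACTORS
    region_names: Sequence[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.visit_times = np.asarray(self.visit_times, dtype=float)
        self.factor_names = tuple(self.factor_names)
        if self.values.ndim != 3:
            raise ConsistencyError("values must be (factor, region, visit)")
        n_fac, n_reg, n_vis = self.values.shape
        if self.region_names is None:
            self.region_names = tuple(f"R{i:03d}" for i in range(n_reg))
        self.region_names = tuple(self.region_names)
        if len(self.factor_names) != n_fac:
            raise ConsistencyError("factor_names does not match values")
        if len(self.region_names) != n_reg:
            raise ConsistencyError("region_names does not match values")
        if len(self.visit_times) != n_vis:
            raise ConsistencyError("visit_times does not match values")
        if n_vis < 3:
            raise ConsistencyError(
                f"subject {self.subject_id}: need >=3 visits, got {n_vis}")
        if n_fac < 2:
            raise ConsistencyError("need >=2 biological factors")
        if not np.all(np.diff(self.visit_times) > 0):
            raise ConsistencyError(
                f"subject {self.subject_id}: visit_times not strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ConsistencyError(
                f"subject {self.subject_id}: non-finite imaging values "
                "(missing imaging is rejected, not imputed)")

    @property
    def n_factors(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_visits(self) -> int:
        return self.values.shape[2]

    def factor_index(self, factor: str) -> int:
        try:
            return self.factor_names.index(factor)
        except ValueError:
            raise ConsistencyError(f"unknown factor {factor!r}") from None


@dataclasses.dataclass
class ReceptorMatrix:
    """Region x receptor density matrix r_{k,i}.

    ``zscore`` normalizes each receptor column by its mean and population SD
    across regions, the convention under which interaction terms are formed.
    """

    densities: np.ndarray
    receptor_names: Sequence[str] = RECEPTORS
    region_names: Sequence[str] | None = None

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        self.receptor_names = tuple(self.receptor_names)
        if self.densities.ndim != 2:
            raise ConsistencyError("densities must be (region, receptor)")
        n_reg, n_rec = self.densities.shape
        if self.region_names is None:
            self.region_names = tuple(f"R{i:03d}" for i in range(n_reg))
        self.region_names = tuple(self.region_names)
        if len(self.receptor_names) != n_rec:
            raise ConsistencyError("receptor_names does not match densities")
        if len(self.region_names) != n_reg:
            raise ConsistencyError("region_names does not match densities")
        if not np.all(np.isfinite(self.densities)):
            raise ConsistencyError("receptor densities contain missing values")

    @property
    def n_regions(self) -> int:
        return self.densities.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.densities.shape[1]

    def zscore(self) -> "ReceptorMatrix":
        sd = np.std(self.densities, axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            names = [self.receptor_names[i] for i in bad]
            raise DegenerateInputError(
                f"constant receptor column(s): {', '.join(names)}")
        z = (self.densities - self.densities.mean(axis=0)) / sd
        return ReceptorMatrix(z, self.receptor_names, self.region_names)

    @property
    def is_normalized(self) -> bool:
        return bool(
            np.all(np.abs(self.densities.mean(axis=0)) < 1e-8)
            and np.all(np.abs(self.densities.std(axis=0) - 1) < 1e-8)
        )


@dataclasses.dataclass
class Connectome:
    """Symmetric nonnegative region adjacency C (tract-count-like units)."""

    weights: np.ndarray
    region_names: Sequence[str] | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ConsistencyError("connectome must be square")
        n = self.weights.shape[0]
        if self.region_names is None:
            self.region_names = tuple(f"R{i:03d}" for i in range(n))
        self.region_names = tuple(self.region_names)
        if len(self.region_names) != n:
            raise ConsistencyError("region_names does not match weights")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ConsistencyError("connectome must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ConsistencyError("connectome diagonal must be zero")
        if np.any(self.weights < 0):
            raise ConsistencyError("connectome weights must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass
class ClinicalRecord:
    """Longitudinal clinical assessments and baseline covariates.

    ``scores`` has shape (n_assessments, n_visits); NaN marks a missing
    score at a visit (slopes then use the available visits).
    ``covariates`` is (age, education, sex).
    """

    subject_id: str
    scores: np.ndarray
    exam_times: np.ndarray
    covariates: np.ndarray
    assessment_names: Sequence[str] = ASSESSMENTS

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.exam_times = np.asarray(self.exam_times, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.assessment_names = tuple(self.assessment_names)
        if self.scores.ndim != 2:
            raise ConsistencyError("scores must be (assessment, visit)")
        if self.scores.shape[0] != len(self.assessment_names):
            raise ConsistencyError("assessment_names does not match scores")
        if self.scores.shape[1] != len(self.exam_times):
            raise ConsistencyError("exam_times does not match scores")
        if not np.all(np.diff(self.exam_times) > 0):
            raise ConsistencyError(
                f"subject {self.subject_id}: exam_times not increasing")
        if self.covariates.shape != (3,):
            raise ConsistencyError("covariates must be (age, education, sex)")


@dataclasses.dataclass
class Cohort:
    """A matched collection of imaging, clinical, receptor and connectome data."""

    subjects: list[SubjectTimeSeries]
    receptors: ReceptorMatrix
    connectome: Connectome
    clinical: list[ClinicalRecord] = dataclasses.field(default_factory=list)
    #: per-modality (mean, sd) applied by zscore_imaging; None when raw.
    normalization: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate subject_ids in imaging data")
        regions = self.receptors.region_names
        if self.connectome.region_names != regions:
            raise ConsistencyError(
                "region labels differ between receptors and connectome: "
                f"{_label_diff(regions, self.connectome.region_names)}")
        for s in self.subjects:
            if s.region_names != regions:
                raise ConsistencyError(
                    f"region labels of subject {s.subject_id} differ from "
                    f"receptor file: {_label_diff(regions, s.region_names)}")
        if self.clinical:
            cids = [c.subject_id for c in self.clinical]
            if len(set(cids)) != len(cids):
                raise ConsistencyError("duplicate subject_ids in clinical data")
            if set(cids) != set(ids):
                raise ConsistencyError(
                    "imaging/clinical subject_ids do not match: "
                    f"{sorted(set(cids) ^ set(ids))}")

    @property
    def n_regions(self) -> int:
        return self.receptors.n_regions

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def clinical_for(self, subject_id: str) -> ClinicalRecord:
        for c in self.clinical:
            if c.subject_id == subject_id:
                return c
        raise KeyError(subject_id)


def _label_diff(a, b):
    sa, sb = set(a), set(b)
    off = sorted(sa ^ sb)
    return off if off else "same labels, different order"


# ---------------------------------------------------------------------------
# normalization operations
# ---------------------------------------------------------------------------

def zscore_receptors(receptors: ReceptorMatrix) -> ReceptorMatrix:
    """Normalize each receptor column by its mean/SD across regions."""
    return receptors.zscore()


def zscore_imaging(cohort: Cohort, per_subject: bool = False) -> Cohort:
    """Standardize each imaging modality to pooled mean 0, SD 1.

    By default the mean/SD pool over all regions, visits and subjects of a
    modality, preserving between-subject severity differences.  With
    ``per_subject=True`` each subject is standardized separately.
    """
    factors = cohort.subjects[0].factor_names
    norm: dict[str, tuple[float, float]] = {}
    new_values = [s.values.copy() for s in cohort.subjects]
    for f_idx, factor in enumerate(factors):
        if per_subject:
            for vals, subj in zip(new_values, cohort.subjects):
                block = subj.values[f_idx]
                sd = block.std()
                if sd == 0:
                    raise DegenerateInputError(
                        f"modality {factor!r} constant for {subj.subject_id}")
                vals[f_idx] = (block - block.mean()) / sd
            norm[factor] = (float("nan"), float("nan"))
        else:
            pooled = np.concatenate(
                [s.values[f_idx].ravel() for s in cohort.subjects])
            sd = pooled.std()
            if sd == 0:
                raise DegenerateInputError(
                    f"modality {factor!r} has zero pooled variance")
            mean = pooled.mean()
            for vals in new_values:
                vals[f_idx] = (vals[f_idx] - mean) / sd
            norm[factor] = (float(mean), float(sd))
    subjects = [
        SubjectTimeSeries(s.subject_id, v, s.visit_times,
                          s.factor_names, s.region_names)
        for s, v in zip(cohort.subjects, new_values)
    ]
    return Cohort(subjects, cohort.receptors, cohort.connectome,
                  cohort.clinical, normalization=norm)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_IMAGING_COLS = ["subject_id", "factor", "region", "visit_time", "value"]
_CLINICAL_COLS = ["subject_id", "assessment", "exam_time", "score"]
_COVARIATE_COLS = ["subject_id", "age", "education", "sex"]


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_receptors(path) -> ReceptorMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "region":
        raise FormatError(f"{path}: first column must be 'region'")
    return ReceptorMatrix(
        df.iloc[:, 1:].to_numpy(float),
        receptor_names=tuple(df.columns[1:]),
        region_names=tuple(df["region"].astype(str)),
    )


def read_connectome(path) -> Connectome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise ConsistencyError(f"{path}: row and column labels disagree")
    return Connectome(df.to_numpy(float), region_names=labels)


def read_imaging(path, region_names) -> list[SubjectTimeSeries]:
    df = pd.read_csv(path)
    _require_columns(df, _IMAGING_COLS, path)
    out = []
    for sid, sdf in df.groupby("subject_id", sort=True):
        times = np.array(sorted(sdf["visit_time"].unique()), dtype=float)
        factors = tuple(f for f in FACTORS if f in set(sdf["factor"]))
        extra = set(sdf["factor"]) - set(FACTORS)
        if extra:
            raise FormatError(f"{path}: unknown factor label(s) {sorted(extra)}")
        regions = set(sdf["region"].astype(str))
        if regions != set(region_names):
            raise ConsistencyError(
                f"{path}: region labels for subject {sid} do not match the "
                f"receptor file: {sorted(regions ^ set(region_names))}")
        cube = np.full((len(factors), len(region_names), len(times)), np.nan)
        r_idx = {r: i for i, r in enumerate(region_names)}
        f_idx = {f: i for i, f in enumerate(factors)}
        t_idx = {t: i for i, t in enumerate(times)}
        for row in sdf.itertuples(index=False):
            cube[f_idx[row.factor], r_idx[str(row.region)],
                 t_idx[row.visit_time]] = row.value
        out.append(SubjectTimeSeries(str(sid), cube, times, factors,
                                     region_names))
    return out


def read_clinical(path, covariates_path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _CLINICAL_COLS, path)
    cov = pd.read_csv(covariates_path)
    _require_columns(cov, _COVARIATE_COLS, covariates_path)
    cov = cov.set_index(cov["subject_id"].astype(str))
    out = []
    for sid, sdf in df.groupby("subject_id", sort=True):
        sid = str(sid)
        times = np.array(sorted(sdf["exam_time"].unique()), dtype=float)
        names = tuple(a for a in ASSESSMENTS if a in set(sdf["assessment"]))
        scores = np.full((len(names), len(times)), np.nan)
        a_idx = {a: i for i, a in enumerate(names)}
        t_idx = {t: i for i, t in enumerate(times)}
        for row in sdf.itertuples(index=False):
            scores[a_idx[row.assessment], t_idx[row.exam_time]] = row.score
        if sid not in cov.index:
            raise ConsistencyError(f"{covariates_path}: no covariates for {sid}")
        c = cov.loc[sid]
        out.append(ClinicalRecord(
            sid, scores, times,
            np.array([c["age"], c["education"], c["sex"]], dtype=float),
            assessment_names=names))
    return out


def read_cohort(imaging_path, receptor_path, connectome_path,
                clinical_path=None, covariates_path=None,
                time_unit: str = "years") -> Cohort:
    """Load and cross-validate the four cohort files.

    Raw values are preserved; apply :func:`zscore_imaging` /
    :func:`zscore_receptors` explicitly for the normalized views.
    ``time_unit="months"`` declares that the files carry visit/exam times
    in months; they are converted to years on load (years is the unit
    everywhere downstream).
    """
    if time_unit not in ("years", "months"):
        raise FormatError("time_unit must be 'years' or 'months'")
    scale = 1.0 / 12.0 if time_unit == "months" else 1.0
    receptors = read_receptors(receptor_path)
    connectome = read_connectome(connectome_path)
    subjects = read_imaging(imaging_path, receptors.region_names)
    clinical = []
    if clinical_path is not None:
        if covariates_path is None:
            covariates_path = Path(str(clinical_path)).with_name("covariates.csv")
        clinical = read_clinical(clinical_path, covariates_path)
    if scale != 1.0:
        subjects = [SubjectTimeSeries(s.subject_id, s.values,
                                      s.visit_times * scale, s.factor_names,
                                      s.region_names) for s in subjects]
        clinical = [ClinicalRecord(c.subject_id, c.scores,
                                   c.exam_times * scale, c.covariates,
                                   c.assessment_names) for c in clinical]
    return Cohort(subjects, receptors, connectome, clinical)


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write the cohort to the standard file dialects; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "imaging": directory / "imaging.csv",
        "receptors": directory / "receptors.tsv",
        "connectome": directory / "connectome.tsv",
        "clinical": directory / "clinical.csv",
        "covariates": directory / "covariates.csv",
    }
    rows = []
    for s in cohort.subjects:
        for fi, factor in enumerate(s.factor_names):
            for ri, region in enumerate(s.region_names):
                for ti, t in enumerate(s.visit_times):
                    rows.append((s.subject_id, factor, region, t,
                                 s.values[fi, ri, ti]))
    pd.DataFrame(rows, columns=_IMAGING_COLS).to_csv(
        paths["imaging"], index=False)

    rec = pd.DataFrame(cohort.receptors.densities,
                       columns=list(cohort.receptors.receptor_names))
    rec.insert(0, "region", list(cohort.receptors.region_names))
    rec.to_csv(paths["receptors"], sep="\t", index=False)

    con = pd.DataFrame(cohort.connectome.weights,
                       index=list(cohort.connectome.region_names),
                       columns=list(cohort.connectome.region_names))
    con.to_csv(paths["connectome"], sep="\t")

    crows, covrows = [], []
    for c in cohort.clinical:
        for ai, a in enumerate(c.assessment_names):
            for ti, t in enumerate(c.exam_times):
                if np.isfinite(c.scores[ai, ti]):
                    crows.append((c.subject_id, a, t, c.scores[ai, ti]))
        covrows.append((c.subject_id, *c.covariates))
    pd.DataFrame(crows, columns=_CLINICAL_COLS).to_csv(
        paths["clinical"], index=False)
    pd.DataFrame(covrows, columns=_COVARIATE_COLS).to_csv(
        paths["covariates"], index=False)
    return paths
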