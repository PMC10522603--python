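"""Population-level stability of fitted mechanisms.

A mechanism (one coefficient of one factor's model) is called *stable*
when the confidence interval for its across-subject mean excludes zero.
Stable mechanisms are then summarized as relative effect sizes (mean
coefficient magnitude, normalized within each factor) and grouped by
receptor family and mechanism class.

No multiple-testing correction is applied across the 678 parameters at
this stage; the stability criterion is the CI itself.
"""

from __future__ import annotations

import importlib.resources
import re

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .design import INTERCEPT_LABEL, PROPAGATION_LABEL
from .exceptions import ConsistencyError, ParameterError
from .model import CohortResults


def _coef_frame(fits) -> pd.DataFrame:
    if isinstance(fits, CohortResults):
        return fits.coef_table()
    return fits


def stable_mechanisms(fits, level: float = 0.99, method: str = "t",
                      n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Across-subject CI per (factor, parameter); stable = CI excludes 0.

    Parameters
    ----------
    fits : CohortResults or DataFrame
        Subjects x (factor, parameter) coefficient table.
    level : float
        Confidence level of the interval (default 0.99).
    method : {"t", "bootstrap"}
        t-interval for the mean (default) or percentile bootstrap.

    Returns a table indexed by (factor, parameter) with columns
    ``mean, mean_abs, ci_lower, ci_upper, stable, share`` where ``share``
    is the mean-|coefficient| fraction among the stable parameters of the
    same factor (NaN for non-stable rows).
    """
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    coefs = _coef_frame(fits)
    n = coefs.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    values = coefs.to_numpy(float)
    mean = np.nanmean(values, axis=0)
    mean_abs = np.nanmean(np.abs(values), axis=0)
    if method == "t":
        sd = np.nanstd(values, axis=0, ddof=1)
        tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
        half = tcrit * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = values[idx].mean(axis=1)
        lo = np.quantile(boot_means, (1 - level) / 2, axis=0)
        hi = np.quantile(boot_means, 0.5 + level / 2, axis=0)
    else:
        raise ParameterError("method must be 't' or 'bootstrap'")
    stable = (lo > 0) | (hi < 0)

    table = pd.DataFrame({
        "mean": mean, "mean_abs": mean_abs,
        "ci_lower": lo, "ci_upper": hi, "stable": stable,
    }, index=coefs.columns)
    table.index.names = ["factor", "parameter"]
    share = np.full(len(table), np.nan)
    for factor in table.index.get_level_values("factor").unique():
        sel = (table.index.get_level_values("factor") == factor) & stable
        total = table.loc[sel, "mean_abs"].sum()
        if total > 0:
            share[sel] = table.loc[sel, "mean_abs"] / total
    table["share"] = share
    return table


def receptor_families() -> dict[str, str]:
    """Receptor -> family map shipped with the package."""
    text = importlib.resources.files("remcm.resources").joinpath(
        "receptor_families.yaml").read_text()
    fam = yaml.safe_load(text)
    return {rec: family for family, recs in fam.items() for rec in recs}


_INTERACTION = re.compile(r"^r\[(.+)\]\*S\[(.+)\]$")
_DIRECT_REC = re.compile(r"^r\[(.+)\]$")
_DIRECT_FAC = re.compile(r"^S\[(.+)\]$")


def default_parameter_grouping(labels) -> pd.DataFrame:
    """Classify parameter labels by receptor, family and mechanism class."""
    fam = receptor_families()
    rows = []
    for label in labels:
        if m := _INTERACTION.match(label):
            rec = m.group(1)
            rows.append((label, rec, fam.get(rec, "other"),
                         "receptor-interaction"))
        elif m := _DIRECT_REC.match(label):
            rec = m.group(1)
            rows.append((label, rec, fam.get(rec, "other"),
                         "direct-receptor"))
        elif _DIRECT_FAC.match(label):
            rows.append((label, None, "non-receptor", "direct-factor"))
        elif label == PROPAGATION_LABEL:
            rows.append((label, None, "non-receptor", "propagation"))
        elif label == INTERCEPT_LABEL:
            rows.append((label, None, "non-receptor", "intercept"))
        else:
            raise ConsistencyError(f"unmapped parameter label {label!r}")
    return pd.DataFrame(rows, columns=["parameter", "receptor", "family",
                                       "mechanism_class"]
                        ).set_index("parameter")


def effect_size_summary(stability: pd.DataFrame,
                        grouping: pd.DataFrame | None = None,
                        by: str = "family") -> pd.DataFrame:
    """Grouped stable effect shares per (factor, group).

    For each factor, sums the mean-|coefficient| of its *stable*
    parameters within each group and normalizes the sums within the
    factor.  Factors with no stable parameter get a single row with share
    0 and ``empty=True``.
    """
    labels = stability.index.get_level_values("parameter").unique()
    if grouping is None:
        grouping = default_parameter_grouping(labels)
    missing = set(labels) - set(grouping.index)
    if missing:
        raise ConsistencyError(f"unmapped parameter label(s): {sorted(missing)[:5]}")
    rows = []
    for factor in stability.index.get_level_values("factor").unique():
        sub = stability.xs(factor, level="factor")
        stable = sub[sub["stable"]]
        if stable.empty:
            rows.append((factor, None, 0.0, True))
            continue
        groups = grouping.loc[stable.index, by]
        sums = stable["mean_abs"].groupby(groups).sum()
        total = sums.sum()
        for g, v in sums.items():
            rows.append((factor, g, v / total, False))
    return pd.DataFrame(rows, columns=["factor", by, "share", "empty"])
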