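"""Minimal diagnostic plots for fitted results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .axes import LatentAxes
from .model import CohortResults


def plot_r2_distributions(results: CohortResults, ax=None):
    """Histogram of per-subject R^2 for each biological factor."""
    r2 = results.r2_table()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for factor in r2.columns:
        ax.hist(r2[factor].dropna(), bins=15, alpha=0.5, label=factor)
    ax.set_xlabel(r"$R^2$")
    ax.set_ylabel("subjects")
    ax.legend(fontsize=8)
    return ax


def plot_symptom_loadings(axes_result: LatentAxes, component: int = 0,
                          ax=None):
    """Bar plot of symptom saliences (with bootstrap ratios if available)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    v = axes_result.V[:, component]
    ax.bar(range(len(v)), v)
    ax.set_xticks(range(len(v)))
    ax.set_xticklabels(axes_result.sym_labels, rotation=60, fontsize=7)
    ax.set_ylabel(f"axis {component + 1} salience")
    if axes_result.stable_mask_V is not None:
        for i, stable in enumerate(axes_result.stable_mask_V[:, component]):
            if not stable:
                ax.patches[i].set_alpha(0.3)
    return ax
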