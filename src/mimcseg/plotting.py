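"""Thin plotting helpers for the tidy result tables.

Everything here renders what the analysis modules computed — heatmaps of
validation metrics or neighbourhood log2 fold changes, and domain-composition
bar charts.  Figures are returned so callers can save or restyle them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["metric_heatmap", "enrichment_heatmap", "composition_bars", "domain_overlay"]

#: display colours for the tissue-domain codes
DOMAIN_COLOURS = {
    "none": (0, 0, 0),
    "normal": (0.85, 0.1, 0.1),
    "tumour": (0.55, 0.1, 0.6),
    "structural": (0.1, 0.8, 0.8),
    "interface": (0.1, 0.7, 0.2),
}


def metric_heatmap(metrics: pd.DataFrame, metric: str = "enrichment", ax=None):
    """Strategy x marker heatmap of one validation metric."""
    sub = metrics[metrics["metric"] == metric]
    mat = sub.pivot_table(index="strategy", columns="marker", values="value")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.8 * mat.shape[1], 1 + 0.5 * mat.shape[0]))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.set_title(metric)
    plt.colorbar(im, ax=ax)
    return ax


def enrichment_heatmap(result: pd.DataFrame, value: str = "log2fc", ax=None):
    """Type-pair heatmap of neighbourhood enrichment (one stratum)."""
    mat = result.pivot_table(index="type_a", columns="type_b", values=value)
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * mat.shape[1], 1 + 0.6 * mat.shape[0]))
    lim = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.set_title(f"neighbourhood {value}")
    plt.colorbar(im, ax=ax)
    return ax


def composition_bars(summary: pd.DataFrame, outer: str, inner: str, ax=None):
    """Stacked proportion bars with SEM whiskers from domain_composition()."""
    mat = summary.pivot_table(index=outer, columns=inner, values="mean").fillna(0.0)
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.9 * mat.shape[0], 4))
    bottom = np.zeros(mat.shape[0])
    for col in mat.columns:
        ax.bar(mat.index, mat[col], bottom=bottom, label=str(col))
        bottom += mat[col].to_numpy()
    ax.set_ylabel("proportion")
    ax.legend(fontsize=7)
    return ax


def domain_overlay(domain_mask: np.ndarray, ax=None):
    """False-colour rendering of a domain mask."""
    from .segmentation import DOMAIN_NAMES

    rgb = np.zeros((*domain_mask.shape, 3))
    for code, name in enumerate(DOMAIN_NAMES):
        rgb[domain_mask == code] = DOMAIN_COLOURS[name]
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(rgb)
    ax.set_axis_off()
    return ax
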