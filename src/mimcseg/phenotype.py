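"""Normalisation, scaling, graph clustering, and rule-based annotation.

Mirrors the standard IMC phenotyping path: per-ROI normalisation to an
ambient reference channel (Xe134), 99th-percentile scaling over the
concatenated multi-ROI dataset, Phenograph-style clustering (k-nearest-
neighbour graph on the scaled marker space, Jaccard edge weights over
neighbour sets, Louvain modularity partition with a fixed seed), then
supervised gating splits of clusters and a manual cluster -> cell-type map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "GatingRule",
    "normalise_to_channel",
    "percentile_scale",
    "cluster_cells",
    "apply_gating",
    "annotate_types",
]


@dataclass(frozen=True)
class GatingRule:
    """Split one cluster into two children by thresholding one marker.

    ``comparator`` is ``">"`` (pass when value > threshold) or ``"<="``.
    """

    cluster_id: object
    marker: str
    threshold: float
    comparator: str = ">"
    pass_label: object = None
    fail_label: object = None

    def __post_init__(self):
        if self.comparator not in (">", "<="):
            raise ValueError("comparator must be '>' or '<='")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def _marker_columns(cell_table: pd.DataFrame, markers: Sequence[str] | None) -> list[str]:
    meta = {
        "cell_id", "centroid_x", "centroid_y", "area", "layer", "domain",
        "roi_id", "treatment", "cluster", "cell_type",
    }
    if markers is None:
        return [
            c for c in cell_table.columns
            if c not in meta and pd.api.types.is_numeric_dtype(cell_table[c])
        ]
    missing = [m for m in markers if m not in cell_table.columns]
    if missing:
        raise KeyError(f"markers not in cell table: {missing}")
    return list(markers)


def normalise_to_channel(
    cell_table: pd.DataFrame,
    channel: str = "Xe134",
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Divide every marker mean by the ROI-wide mean of a reference channel.

    Each ROI is normalised independently; a zero reference mean is an error.
    """
    if channel not in cell_table.columns:
        raise KeyError(f"reference channel {channel!r} not in cell table")
    out = cell_table.copy()
    cols = _marker_columns(cell_table, markers)
    roi = out["roi_id"] if "roi_id" in out.columns else pd.Series(["roi"] * len(out))
    for roi_id, idx in out.groupby(roi, sort=False).groups.items():
        ref = out.loc[idx, channel].mean()
        if ref == 0:
            raise ValueError(f"reference channel mean is zero in ROI {roi_id!r}")
        out.loc[idx, cols] = out.loc[idx, cols] / ref
    return out


def percentile_scale(
    cell_table: pd.DataFrame, p: float = 99.0, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scale each marker to its p-th percentile over the whole table, clip to [0, 1].

    Computed on the concatenated dataset (all ROIs together).  The percentile
    is the lower order statistic, which makes the transform exactly
    idempotent: after one pass that cell's value is 1.0 and stays there.
    """
    out = cell_table.copy()
    for col in _marker_columns(cell_table, markers):
        q = np.percentile(out[col].to_numpy(dtype=float), p, method="lower")
        if q > 0:
            out[col] = np.clip(out[col] / q, 0.0, 1.0)
        else:
            out[col] = np.clip(out[col].to_numpy(dtype=float), 0.0, 1.0)
    return out


def cluster_cells(
    cell_table: pd.DataFrame,
    markers: Sequence[str],
    k: int = 20,
    seed: int = 0,
    resolution: float = 1.0,
) -> np.ndarray:
    """Phenograph-style clustering of cells in marker space.

    Builds the exact k-nearest-neighbour graph (Euclidean) on the selected
    marker columns, weights each edge by the Jaccard overlap of the two
    cells' neighbour sets, and partitions with Louvain modularity
    maximisation at a fixed seed.  Rows are canonically ordered by
    ``cell_id`` internally, so the partition is invariant to row shuffling.
    Returns integer labels 1..C aligned with the input rows.

    ``resolution`` is the Louvain resolution: at the default 1.0 the
    resolution limit of modularity tiles large uniform populations into
    patches (as Phenograph does); small values (<~0.1) merge everything up
    to graph components, recovering coarse well-separated structure exactly.
    """
    cols = _marker_columns(cell_table, markers)
    n = len(cell_table)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cell count {n}")
    if "cell_id" in cell_table.columns:
        order = np.lexsort(
            (
                cell_table["cell_id"].to_numpy(),
                cell_table["roi_id"].to_numpy()
                if "roi_id" in cell_table.columns
                else np.zeros(n),
            )
        )
    else:
        order = np.arange(n)
    X = cell_table.iloc[order][cols].to_numpy(dtype=float)
    if np.ptp(X, axis=0).max(initial=0.0) == 0.0:
        # degenerate input: every cell identical in marker space
        return np.ones(n, dtype=int)

    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row[1:]) for row in idx]  # drop self

    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            j = int(j)
            if G.has_edge(i, j):
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union if union else 0.0
            if w > 0:
                G.add_edge(i, j, weight=w)
            else:
                G.add_edge(i, j, weight=1e-9)
    communities = nx.community.louvain_communities(
        G, weight="weight", seed=seed, resolution=resolution
    )
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels_sorted = np.zeros(n, dtype=int)
    for ci, members in enumerate(communities, start=1):
        labels_sorted[list(members)] = ci
    labels = np.zeros(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def apply_gating(cell_table: pd.DataFrame, rules: Sequence[GatingRule]) -> pd.DataFrame:
    """Apply supervised cluster-splitting rules in order.

    Each rule splits one cluster id into two child labels (defaults:
    ``"<id>+"`` / ``"<id>-"``); cells outside the rule's cluster are
    untouched.  An empty rule list is the identity.
    """
    out = cell_table.copy()
    if "cluster" not in out.columns:
        raise KeyError("cell table has no 'cluster' column; run clustering first")
    if rules:
        out["cluster"] = out["cluster"].astype(object)
    for rule in rules:
        in_cluster = out["cluster"] == rule.cluster_id
        if rule.marker not in out.columns:
            raise KeyError(f"gating marker {rule.marker!r} not in cell table")
        vals = out.loc[in_cluster, rule.marker].to_numpy(dtype=float)
        passed = vals > rule.threshold if rule.comparator == ">" else vals <= rule.threshold
        pass_label = rule.pass_label if rule.pass_label is not None else f"{rule.cluster_id}+"
        fail_label = rule.fail_label if rule.fail_label is not None else f"{rule.cluster_id}-"
        sub = out.loc[in_cluster, "cluster"].copy()
        sub[passed] = pass_label
        sub[~passed] = fail_label
        out.loc[in_cluster, "cluster"] = sub
    return out


def annotate_types(cell_table: pd.DataFrame, mapping: Mapping) -> pd.DataFrame:
    """Map every cluster to a cell type; an unmapped cluster is an error."""
    out = cell_table.copy()
    if "cluster" not in out.columns:
        raise KeyError("cell table has no 'cluster' column")
    clusters = pd.unique(out["cluster"])
    missing = [c for c in clusters if c not in mapping]
    if missing:
        raise KeyError(f"no cell type mapped for cluster(s) {missing}")
    out["cell_type"] = out["cluster"].map(mapping)
    return out
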