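"""Segmentation-quality metrics based on the brightest cells per marker.

Three complementary metrics compare segmentation strategies without ground
truth: signal *enrichment* (mean marker intensity in the top-k expressing
cells over the mean in the rest), a *signal/noise* matrix against "polluting"
markers that should not co-occur in the same cell but may sit adjacent in
tissue (a readout of spatial spillover), and the percentage of manually
annotated cells matched (within a pixel radius, one-to-one) by the top-k
cells for their marker.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet

__all__ = [
    "top_k_cells",
    "top_k_enrichment",
    "signal_noise_matrix",
    "match_annotations",
    "metrics_table",
    "INF_SENTINEL",
]

#: value used in CSV output in place of an infinite ratio
INF_SENTINEL = 1e6


def top_k_cells(cell_table: pd.DataFrame, marker: str, k: int = 500) -> pd.DataFrame:
    """The k highest-expressing cells for a marker.

    Ties at the k-th rank are resolved deterministically by ascending
    ``cell_id`` (among equal values, lower ids are included first); the
    enrichment ratio is invariant to which tied cells enter the top set.
    """
    if marker not in cell_table.columns:
        raise KeyError(f"marker {marker!r} not in cell table")
    if k >= len(cell_table):
        raise ValueError(f"k={k} must be smaller than the cell count {len(cell_table)}")
    ordered = cell_table.sort_values(
        [marker, "cell_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(k)


def top_k_enrichment(cell_table: pd.DataFrame, marker: str, k: int = 500) -> float:
    """Mean marker intensity in the top-k cells over the mean in the rest.

    A zero denominator returns ``inf``.
    """
    top = top_k_cells(cell_table, marker, k)
    rest = cell_table.loc[~cell_table.index.isin(top.index)]
    denom = rest[marker].mean()
    num = top[marker].mean()
    if denom == 0:
        return math.inf
    return float(num / denom)


def signal_noise_matrix(
    cell_table: pd.DataFrame,
    key_markers: Sequence[str],
    pollutant_map: Mapping[str, Sequence[str]],
    k: int = 500,
) -> pd.DataFrame:
    """Signal-to-noise ratios against markers of neighbouring cell types.

    Entry (key, pollutant) is the mean of the *key* marker over its own top-k
    cells divided by the mean of the *pollutant* marker over those same
    cells.  Rows are key markers; columns the union of pollutant markers.
    A pollutant mean of zero yields ``inf``; intensity rescaling of the whole
    table leaves every entry unchanged.
    """
    columns: list[str] = []
    for key in key_markers:
        for pol in pollutant_map.get(key, ()):
            if pol not in columns:
                columns.append(pol)
    out = pd.DataFrame(index=list(key_markers), columns=columns, dtype=float)
    for key in key_markers:
        top = top_k_cells(cell_table, key, k)
        key_mean = top[key].mean()
        for pol in pollutant_map.get(key, ()):
            pol_mean = top[pol].mean()
            out.loc[key, pol] = math.inf if pol_mean == 0 else key_mean / pol_mean
    return out


def match_annotations(
    cell_table: pd.DataFrame,
    marker: str,
    annotations: AnnotationSet | pd.DataFrame,
    k: int = 500,
    radius: float = 5.0,
) -> float:
    """Percent of annotated cells matched by top-k cell centroids.

    A match requires the centroid of a top-k cell within Euclidean distance
    ``radius`` of the annotation point; matching is one-to-one and greedy
    nearest-pair-first, so one bright cell cannot satisfy two annotations.
    The result is order-invariant in the annotations and at most 100.
    """
    if isinstance(annotations, AnnotationSet):
        ann = annotations.to_frame()
    else:
        ann = annotations
    if len(ann) == 0:
        raise ValueError("annotations must be non-empty")
    top = top_k_cells(cell_table, marker, k)
    cx = top["centroid_x"].to_numpy(dtype=float)
    cy = top["centroid_y"].to_numpy(dtype=float)
    ax = ann["x"].to_numpy(dtype=float)
    ay = ann["y"].to_numpy(dtype=float)

    d = np.hypot(ax[:, None] - cx[None, :], ay[:, None] - cy[None, :])
    cand = np.argwhere(d <= radius)
    if cand.size == 0:
        return 0.0
    dists = d[cand[:, 0], cand[:, 1]]
    # greedy nearest-pair-first; ties broken by (annotation, cell) index
    order = np.lexsort((cand[:, 1], cand[:, 0], dists))
    used_ann = np.zeros(len(ann), dtype=bool)
    used_cell = np.zeros(len(top), dtype=bool)
    matched = 0
    for i in order:
        a, c = cand[i]
        if used_ann[a] or used_cell[c]:
            continue
        used_ann[a] = True
        used_cell[c] = True
        matched += 1
    return 100.0 * matched / len(ann)


def metrics_table(
    tables_by_strategy: Mapping[str, pd.DataFrame],
    markers: Sequence[str],
    k: int = 500,
    pollutant_map: Mapping[str, Sequence[str]] | None = None,
    annotations: AnnotationSet | None = None,
    radius: float = 5.0,
) -> pd.DataFrame:
    """Tidy (strategy, marker, metric, value) table across strategies.

    Infinite ratios are capped at :data:`INF_SENTINEL` for CSV friendliness.
    Annotation rows are emitted only when annotations are provided.
    """
    rows = []
    for strategy, table in tables_by_strategy.items():
        for marker in markers:
            val = top_k_enrichment(table, marker, k)
            rows.append((strategy, marker, "enrichment", min(val, INF_SENTINEL)))
            if pollutant_map and marker in pollutant_map:
                sn = signal_noise_matrix(table, [marker], pollutant_map, k)
                for pol in pollutant_map[marker]:
                    rows.append(
                        (
                            strategy,
                            marker,
                            f"signal_noise_vs_{pol}",
                            min(float(sn.loc[marker, pol]), INF_SENTINEL),
                        )
                    )
            if annotations is not None:
                sub = annotations.subset(marker)
                if len(sub):
                    rows.append(
                        (
                            strategy,
                            marker,
                            "annotation_match_pct",
                            match_annotations(table, marker, sub, k, radius),
                        )
                    )
    return pd.DataFrame(rows, columns=["strategy", "marker", "metric", "value"])
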