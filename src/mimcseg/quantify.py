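"""Single-cell quantification: masks + images -> cell table + neighbour graph.

The cell table carries, per cell, the unweighted centroid (pixel units, x =
column, y = row, 0-based), pixel-count area, per-channel mean intensity over
the cell's member pixels, and categorical metadata (segmentation layer,
tissue domain, ROI, treatment).  The neighbour graph lists unordered pairs of
cells whose supports come within a fixed edge-to-edge Euclidean distance
(15 px by default); a centroid-distance variant is available.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .io_formats import ImageStack
from .segmentation import DOMAIN_NAMES

__all__ = [
    "measure_cells",
    "assign_domains",
    "object_relationships",
    "exclude_regions",
]

# tie priority for majority-domain assignment (highest wins)
_DOMAIN_PRIORITY = {"interface": 4, "tumour": 3, "normal": 2, "structural": 1, "none": 0}


def measure_cells(mask: np.ndarray, stack: ImageStack) -> pd.DataFrame:
    """Measure every labelled object: centroid, area, per-channel means.

    Returns a DataFrame with ``cell_id``, ``centroid_x``, ``centroid_y``,
    ``area`` and one column per channel marker, plus ``roi_id``.
    """
    mask = np.asarray(mask)
    if mask.shape != stack.shape:
        raise ValueError("mask and stack shapes differ")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        cols = ["cell_id", "centroid_x", "centroid_y", "area"] + stack.markers
        df = pd.DataFrame(columns=cols)
        df["roi_id"] = pd.Series(dtype=object)
        return df

    flat = mask.ravel()
    maxlab = int(labels.max())
    areas = np.bincount(flat, minlength=maxlab + 1).astype(np.float64)
    yy, xx = np.indices(mask.shape)
    sum_y = np.bincount(flat, weights=yy.ravel(), minlength=maxlab + 1)
    sum_x = np.bincount(flat, weights=xx.ravel(), minlength=maxlab + 1)

    data = {
        "cell_id": labels.astype(int),
        "centroid_x": sum_x[labels] / areas[labels],
        "centroid_y": sum_y[labels] / areas[labels],
        "area": areas[labels].astype(int),
    }
    for marker, plane in zip(stack.markers, stack.pixels):
        sums = np.bincount(flat, weights=plane.ravel(), minlength=maxlab + 1)
        data[marker] = sums[labels] / areas[labels]
    df = pd.DataFrame(data)
    df["roi_id"] = stack.roi_id
    return df


def assign_domains(
    cell_table: pd.DataFrame, mask: np.ndarray, domain_mask: np.ndarray
) -> pd.DataFrame:
    """Assign each cell the majority domain of its member pixels.

    Ties resolve by priority interface > tumour > normal > structural > none.
    """
    mask = np.asarray(mask)
    domain_mask = np.asarray(domain_mask)
    if mask.shape != domain_mask.shape:
        raise ValueError("mask and domain mask shapes differ")
    out = cell_table.copy()
    if len(out) == 0:
        out["domain"] = pd.Series(dtype=object)
        return out
    maxlab = int(mask.max())
    n_dom = len(DOMAIN_NAMES)
    # count domain pixels per label in one pass
    joint = mask.ravel().astype(np.int64) * n_dom + domain_mask.ravel().astype(np.int64)
    counts = np.bincount(joint, minlength=(maxlab + 1) * n_dom).reshape(maxlab + 1, n_dom)
    prio = np.array([_DOMAIN_PRIORITY[d] for d in DOMAIN_NAMES])
    # maximise (count, priority) lexicographically
    key = counts * (prio.max() + 1) + prio[None, :]
    best = key.argmax(axis=1)
    names = np.array(DOMAIN_NAMES, dtype=object)
    out["domain"] = names[best[out["cell_id"].to_numpy(dtype=int)]]
    return out


def _boundary_pixels(mask: np.ndarray, lab_slice, lab: int) -> np.ndarray:
    """Coordinates of the label's boundary pixels (support minus erosion)."""
    sub = mask[lab_slice] == lab
    inner = ndi.binary_erosion(sub, structure=np.ones((3, 3), dtype=bool), border_value=0)
    edge = sub & ~inner
    coords = np.argwhere(edge)
    coords[:, 0] += lab_slice[0].start
    coords[:, 1] += lab_slice[1].start
    return coords


def object_relationships(
    mask: np.ndarray,
    max_dist: float = 15.0,
    metric: str = "edge",
    cell_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """List unordered pairs of cells within ``max_dist`` of each other.

    ``metric="edge"`` (default) uses the exact minimum edge-to-edge Euclidean
    distance between the two supports — sufficient to evaluate on boundary
    pixels, since the closest points of two disjoint supports are boundary
    pixels.  ``metric="centroid"`` uses centroid distance (requires
    ``cell_table``).  Returns columns ``cell_id_a`` < ``cell_id_b``.
    """
    if metric == "centroid":
        if cell_table is None:
            raise ValueError("centroid metric requires a cell table")
        ids = cell_table["cell_id"].to_numpy(dtype=int)
        pts = cell_table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
        tree = cKDTree(pts)
        pairs = sorted(
            tuple(sorted((int(ids[i]), int(ids[j]))))
            for i, j in tree.query_pairs(max_dist)
        )
        return pd.DataFrame(pairs or None, columns=["cell_id_a", "cell_id_b"])

    mask = np.asarray(mask)
    objects = ndi.find_objects(mask)
    labels = [i + 1 for i, sl in enumerate(objects) if sl is not None]
    coords = {
        lab: _boundary_pixels(mask, objects[lab - 1], lab) for lab in labels
    }
    trees = {lab: cKDTree(c) for lab, c in coords.items()}

    # candidate pairs: bounding boxes within max_dist
    boxes = {}
    for lab in labels:
        sl = objects[lab - 1]
        boxes[lab] = (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop)
    pairs = []
    for i, a in enumerate(labels):
        ay0, ay1, ax0, ax1 = boxes[a]
        for b in labels[i + 1:]:
            by0, by1, bx0, bx1 = boxes[b]
            gap_y = max(by0 - ay1, ay0 - by1, 0)
            gap_x = max(bx0 - ax1, ax0 - bx1, 0)
            if gap_y * gap_y + gap_x * gap_x > max_dist * max_dist:
                continue
            d, _ = trees[a].query(coords[b], k=1, distance_upper_bound=max_dist + 1e-9)
            if np.min(d) <= max_dist:
                pairs.append((a, b))
    return pd.DataFrame(pairs or None, columns=["cell_id_a", "cell_id_b"]).astype(
        {"cell_id_a": int, "cell_id_b": int}
    ) if pairs else pd.DataFrame(columns=["cell_id_a", "cell_id_b"], dtype=int)


def exclude_regions(
    cell_table: pd.DataFrame, rectangles: Sequence[tuple[float, float, float, float]]
) -> pd.DataFrame:
    """Remove cells whose centroid falls inside any rectangle.

    Rectangles are ``(x0, y0, x1, y1)`` with closed intervals: a centroid
    exactly on an edge is excluded.  Used to drop image areas with acquisition
    artefacts (e.g. a sudden drop in counts).
    """
    if not rectangles:
        return cell_table.copy()
    x = cell_table["centroid_x"].to_numpy(dtype=float)
    y = cell_table["centroid_y"].to_numpy(dtype=float)
    drop = np.zeros(len(cell_table), dtype=bool)
    for x0, y0, x1, y1 in rectangles:
        if x1 < x0 or y1 < y0:
            raise ValueError("rectangle must have x0 <= x1 and y0 <= y1")
        drop |= (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    return cell_table.loc[~drop].reset_index(drop=True)
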