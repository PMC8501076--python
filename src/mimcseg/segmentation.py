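"""Nucleus detection, whole-cell segmentation strategies, and tissue domains.

Four whole-cell strategies are provided, matching the comparison this package
was built around:

* fixed pixel expansion of detected nuclei (1 px or 3 px),
* seeded propagation onto a membrane probability map, where each in-region
  pixel is assigned to the nucleus of minimal intensity-aware geodesic cost,
* the sequential cell-type-prioritised strategy: an ordered stack of
  segmentation layers, each with its own probability class and nucleus
  detection settings, consuming nuclei so that later layers never re-segment
  an already-claimed cell; a probability-only layer captures spindle-shaped
  cells (fibroblast-like) that lack a detectable nucleus, and a terminal
  one-pixel-expansion layer mops up all remaining nuclei.

Tissue domains (normal / tumour / structural, with interface defined as the
overlap of normal and tumour) are segmented by thresholding smoothed domain
probability maps.

The geodesic propagation step cost between 4-connected pixels ``p`` and ``q``
is ``sqrt(lambda + (g(p) - g(q))^2)`` on the guidance image ``g``: ``lambda``
trades pure Euclidean path length against intensity-aware distance.  All
tie-breaks resolve to the lowest label id, making every segmenter
deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "NucleusParams",
    "LayerSpec",
    "DOMAIN_NAMES",
    "DOMAIN_CODES",
    "detect_nuclei",
    "expand_labels",
    "propagate_labels",
    "sequential_segment",
    "segment_domains",
    "count_disconnected_labels",
]

# Tissue-domain categorical codes; every pixel gets exactly one.
DOMAIN_NAMES = ["none", "normal", "tumour", "structural", "interface"]
DOMAIN_CODES = {name: i for i, name in enumerate(DOMAIN_NAMES)}

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class NucleusParams:
    """Settings for nucleus detection.

    ``declump`` selects how touching nuclei are split: ``"intensity"``
    watersheds on smoothed-intensity peaks, ``"shape"`` on the distance
    transform, ``"none"`` keeps connected components whole.  ``threshold``
    is ``"otsu"``, ``"quantile"`` or ``"manual"`` (the latter two read
    ``threshold_value``).
    """

    min_diameter: float = 4.0
    max_diameter: float = 30.0
    declump: str = "intensity"
    threshold: str = "otsu"
    threshold_value: float | None = None
    smoothing_sigma: float = 1.0

    def __post_init__(self):
        if not (0 < self.min_diameter <= self.max_diameter):
            raise ValueError("need 0 < min_diameter <= max_diameter")
        if self.declump not in ("none", "intensity", "shape"):
            raise ValueError(f"unknown declump mode {self.declump!r}")
        if self.threshold not in ("otsu", "quantile", "manual"):
            raise ValueError(f"unknown threshold method {self.threshold!r}")


@dataclass
class LayerSpec:
    """One layer of the sequential segmentation stack."""

    name: str
    probability_class: str = ""
    nucleus_params: NucleusParams | None = None
    mode: str = "propagate"  # propagate | probability_only | expand1
    propagation_lambda: float = 0.05
    map_threshold: float = 0.5
    min_area: float = 25.0  # size filter for probability_only layers
    # a seed nucleus must sit in its layer's class region: mean class
    # probability over the nucleus support must reach this value
    seed_class_threshold: float = 0.5

    def __post_init__(self):
        if self.mode not in ("propagate", "probability_only", "expand1"):
            raise ValueError(f"unknown layer mode {self.mode!r}")
        if self.mode == "propagate" and self.nucleus_params is None:
            self.nucleus_params = NucleusParams()


def _threshold(image: np.ndarray, params: NucleusParams) -> float:
    if params.threshold == "manual":
        if params.threshold_value is None:
            raise ValueError("manual threshold requires threshold_value")
        return float(params.threshold_value)
    if params.threshold == "quantile":
        q = 0.9 if params.threshold_value is None else float(params.threshold_value)
        return float(np.quantile(image, q))
    if image.max() == image.min():
        return float(image.max())  # nothing above threshold
    return float(threshold_otsu(image))


def detect_nuclei(dna_image: np.ndarray, params: NucleusParams | None = None) -> np.ndarray:
    """Detect and label nuclei in a (preprocessed) DNA image.

    Objects whose equivalent diameter ``sqrt(4*area/pi)`` falls outside
    ``[min_diameter, max_diameter]`` are removed; labels are renumbered 1..N.
    An empty image yields an empty mask.
    """
    params = params or NucleusParams()
    dna_image = np.asarray(dna_image, dtype=np.float64)
    if dna_image.size == 0:
        return np.zeros_like(dna_image, dtype=np.int32)
    smoothed = (
        ndi.gaussian_filter(dna_image, params.smoothing_sigma)
        if params.smoothing_sigma > 0
        else dna_image
    )
    thr = _threshold(smoothed, params)
    binary = smoothed > thr
    if not binary.any():
        return np.zeros(dna_image.shape, dtype=np.int32)

    if params.declump == "none":
        labels, _ = ndi.label(binary, structure=_EIGHT)
    else:
        if params.declump == "intensity":
            surface = smoothed
        else:  # shape: peaks of the (lightly smoothed) distance transform
            surface = ndi.gaussian_filter(ndi.distance_transform_edt(binary), 1.0)
        min_dist = max(1, int(round(params.min_diameter / 2)))
        peaks = peak_local_max(
            surface, min_distance=min_dist, labels=binary, exclude_border=False
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.max() == 0:
            labels, _ = ndi.label(binary, structure=_EIGHT)
        else:
            labels = watershed(-surface, markers=markers, mask=binary)

    return _filter_by_diameter(labels, params.min_diameter, params.max_diameter)


def _filter_by_diameter(labels: np.ndarray, dmin: float, dmax: float) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    diam = np.sqrt(4.0 * areas / np.pi)
    keep = (diam >= dmin) & (diam <= dmax)
    keep[0] = False
    mapping = np.zeros(len(areas), dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]


def expand_labels(nuclei: np.ndarray, n_px: float) -> np.ndarray:
    """Expand every label into surrounding background by up to ``n_px``.

    A background pixel within Euclidean distance ``n_px`` of any labelled
    pixel adopts the label of its *nearest* labelled pixel; exact ties in
    squared integer distance resolve to the lowest label id.  Labelled pixels
    are unchanged; ``n_px = 0`` is the identity.
    """
    nuclei = np.asarray(nuclei)
    out = nuclei.astype(np.int32).copy()
    if n_px <= 0 or nuclei.max() == 0:
        return out
    background = nuclei == 0
    dist, (iy, ix) = ndi.distance_transform_edt(background, return_indices=True)
    yy, xx = np.indices(nuclei.shape)
    d2 = (yy - iy) ** 2 + (xx - ix) ** 2  # exact integer squared distance
    target = background & (d2 <= n_px * n_px)
    if not target.any():
        return out

    seed_coords = np.argwhere(nuclei > 0)
    seed_labels = nuclei[tuple(seed_coords.T)].astype(np.int64)
    tree = cKDTree(seed_coords)
    pts = np.argwhere(target)
    want_d2 = d2[target]

    k = 4
    best = np.full(len(pts), np.iinfo(np.int64).max, dtype=np.int64)
    unresolved = np.arange(len(pts))
    while unresolved.size:
        k = min(k, len(seed_coords))
        _, idx = tree.query(pts[unresolved], k=k)
        idx = np.asarray(idx).reshape(len(unresolved), -1)
        diff = seed_coords[idx] - pts[unresolved][:, None, :]
        q2 = (diff**2).sum(axis=2)
        lab = seed_labels[idx]
        at_min = q2 == want_d2[unresolved][:, None]
        cand = np.where(at_min, lab, np.iinfo(np.int64).max).min(axis=1)
        best[unresolved] = np.minimum(best[unresolved], cand)
        # a pixel is resolved once the k-th neighbour is strictly farther
        still = (q2[:, -1] == want_d2[unresolved]) & (k < len(seed_coords))
        unresolved = unresolved[still]
        k *= 2

    out[target] = best.astype(np.int32)
    return out


def propagate_labels(
    nuclei: np.ndarray,
    guidance: np.ndarray,
    lam: float = 0.05,
    map_threshold: float = 0.5,
) -> np.ndarray:
    """Seeded geodesic propagation of nucleus labels onto a guidance map.

    The region of interest is every pixel whose guidance value is at least
    ``map_threshold``, plus all nucleus pixels.  Each in-region pixel is
    assigned to the seed nucleus reachable at minimal geodesic cost over the
    4-connected pixel graph with step cost ``sqrt(lam + (g(p) - g(q))^2)``;
    equal-cost ties resolve to the lowest label id.  Out-of-region pixels
    stay 0.  No nuclei yields an empty mask.
    """
    nuclei = np.asarray(nuclei)
    guidance = np.asarray(guidance, dtype=np.float64)
    if nuclei.shape != guidance.shape:
        raise ValueError("nuclei and guidance shapes differ")
    out = np.zeros(nuclei.shape, dtype=np.int32)
    if nuclei.max() == 0:
        return out
    h, w = nuclei.shape
    region = (guidance >= map_threshold) | (nuclei > 0)

    flat_g = guidance.ravel()
    flat_region = region.ravel()
    flat_seed = nuclei.ravel()
    n = h * w
    INF = np.inf
    best_cost = np.full(n, INF)
    best_label = np.zeros(n, dtype=np.int64)
    done = np.zeros(n, dtype=bool)

    heap: list[tuple[float, int, int]] = []
    seeds = np.flatnonzero(flat_seed > 0)
    for p in seeds:
        lab = int(flat_seed[p])
        best_cost[p] = 0.0
        best_label[p] = lab
        heap.append((0.0, lab, int(p)))
    heapq.heapify(heap)

    sqrt = np.sqrt
    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        cost, lab, p = pop(heap)
        if done[p] or (cost, lab) > (best_cost[p], best_label[p]):
            continue
        done[p] = True
        gp = flat_g[p]
        # 4-connected neighbours with border checks on the flat index
        x = p % w
        if x + 1 < w:
            _relax(p + 1, cost, lab, gp, lam, flat_region, done, best_cost, best_label, flat_g, heap, push, sqrt)
        if x > 0:
            _relax(p - 1, cost, lab, gp, lam, flat_region, done, best_cost, best_label, flat_g, heap, push, sqrt)
        if p + w < n:
            _relax(p + w, cost, lab, gp, lam, flat_region, done, best_cost, best_label, flat_g, heap, push, sqrt)
        if p >= w:
            _relax(p - w, cost, lab, gp, lam, flat_region, done, best_cost, best_label, flat_g, heap, push, sqrt)

    assigned = done & (best_label > 0)
    out.ravel()[assigned] = best_label[assigned]
    return out


def _relax(q, cost, lab, gp, lam, region, done, best_cost, best_label, flat_g, heap, push, sqrt):
    if done[q] or not region[q]:
        return
    dg = gp - flat_g[q]
    c = cost + sqrt(lam + dg * dg)
    if (c, lab) < (best_cost[q], best_label[q] if best_label[q] else np.inf):
        best_cost[q] = c
        best_label[q] = lab
        push(heap, (c, lab, int(q)))


def _restrict_to_pool(candidates: np.ndarray, pool_support: np.ndarray) -> np.ndarray:
    """Keep candidate nuclei whose area overlaps the remaining pool by >50%."""
    if candidates.max() == 0:
        return candidates
    areas = np.bincount(candidates.ravel())
    overlap = np.bincount(candidates.ravel(), weights=pool_support.ravel().astype(float))
    keep = np.zeros(len(areas), dtype=bool)
    keep[1:] = overlap[1:] > 0.5 * areas[1:]
    mapping = np.zeros(len(areas), dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[candidates]


def _filter_seeds_by_class(seeds: np.ndarray, class_map: np.ndarray, threshold: float) -> np.ndarray:
    """Keep seed nuclei whose mean layer-class probability over their support
    reaches ``threshold`` — a nucleus of some other cell type sits in a
    near-zero region of this layer's map and must not seed a cell here."""
    if seeds.max() == 0 or threshold <= 0:
        return seeds
    areas = np.bincount(seeds.ravel())
    probsum = np.bincount(seeds.ravel(), weights=np.asarray(class_map, dtype=float).ravel())
    keep = np.zeros(len(areas), dtype=bool)
    keep[1:] = probsum[1:] >= threshold * areas[1:]
    mapping = np.zeros(len(areas), dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[seeds]


def _compact(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to 1..N preserving order."""
    vals = np.unique(labels)
    vals = vals[vals > 0]
    mapping = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    mapping[vals] = np.arange(1, len(vals) + 1)
    return mapping[labels]


def sequential_segment(
    probmaps: Mapping[str, np.ndarray],
    dna_image: np.ndarray,
    layers: Sequence[LayerSpec],
    pool_params: NucleusParams | None = None,
):
    """Cell-type-prioritised sequential segmentation.

    Parameters
    ----------
    probmaps
        Mapping from probability-class name to its 2-D probability map; each
        ``LayerSpec.probability_class`` must resolve here (except for the
        terminal ``expand1`` layer).
    dna_image
        Preprocessed nuclear image (summed iridium channels, equalised).
    layers
        Ordered by priority.  Earlier layers consume nuclei: after each layer,
        every pool nucleus whose area overlaps a newly created cell by more
        than 50% is removed from the pool, so later layers cannot reuse it.
    pool_params
        Settings for the one-off permissive detection of the global nucleus
        pool (default: wide diameter range, shape declumping).

    Returns
    -------
    total_mask : int ndarray
        Union of all layer masks with globally unique labels.
    layer_table : DataFrame with columns ``cell_id``, ``layer``.
    layer_masks : dict of per-layer masks (original per-layer labelling
        shifted to the global ids).
    """
    dna_image = np.asarray(dna_image, dtype=np.float64)
    pool_params = pool_params or NucleusParams(
        min_diameter=1.5, max_diameter=40.0, declump="shape", smoothing_sigma=0.5
    )
    pool = detect_nuclei(dna_image, pool_params)

    total = np.zeros(dna_image.shape, dtype=np.int32)
    layer_masks: dict[str, np.ndarray] = {}
    records: list[tuple[int, str]] = []
    next_id = 1
    claimed = np.zeros(dna_image.shape, dtype=bool)

    n_expand1 = sum(1 for sp in layers if sp.mode == "expand1")
    if n_expand1 > 1:
        raise ValueError("at most one expand1 (terminal) layer is allowed")

    for spec in layers:
        pool_support = pool > 0
        if spec.mode == "probability_only":
            pm = _get_map(probmaps, spec.probability_class)
            binary = pm >= spec.map_threshold
            cells, _ = ndi.label(binary, structure=_EIGHT)
            if spec.nucleus_params is not None:
                cells = _filter_by_diameter(
                    cells, spec.nucleus_params.min_diameter, spec.nucleus_params.max_diameter
                )
            else:
                cells = _filter_by_area(cells, spec.min_area)
        elif spec.mode == "expand1":
            cells = expand_labels(_compact(pool), 1)
        else:  # propagate
            pm = _get_map(probmaps, spec.probability_class)
            # layer nuclei = remaining pool nuclei passing the layer's size
            # window, and sitting inside this layer's class region
            np_ = spec.nucleus_params or NucleusParams()
            seeds = _filter_by_diameter(_compact(pool), np_.min_diameter, np_.max_diameter)
            seeds = _filter_seeds_by_class(seeds, pm, spec.seed_class_threshold)
            cells = propagate_labels(seeds, pm, spec.propagation_lambda, spec.map_threshold)

        cells = cells.copy()
        cells[claimed] = 0
        cells = _compact(cells)
        n_new = int(cells.max())
        if n_new:
            shifted = np.where(cells > 0, cells + (next_id - 1), 0).astype(np.int32)
            layer_masks[spec.name] = shifted
            total[shifted > 0] = shifted[shifted > 0]
            claimed |= shifted > 0
            records.extend((next_id + i, spec.name) for i in range(n_new))
            next_id += n_new
            # consume pool nuclei covered >50% by the new layer's cells
            pool = _consume_pool(pool, shifted > 0)
        else:
            layer_masks[spec.name] = np.zeros_like(total)

    layer_table = pd.DataFrame(records, columns=["cell_id", "layer"])
    return total, layer_table, layer_masks


def _get_map(probmaps: Mapping[str, np.ndarray], name: str) -> np.ndarray:
    if name not in probmaps:
        raise KeyError(f"probability class {name!r} not in {sorted(probmaps)}")
    return np.asarray(probmaps[name], dtype=np.float64)


def _filter_by_area(labels: np.ndarray, min_area: float) -> np.ndarray:
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    mapping = np.zeros(len(areas), dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]


def _consume_pool(pool: np.ndarray, new_cells: np.ndarray) -> np.ndarray:
    if pool.max() == 0:
        return pool
    areas = np.bincount(pool.ravel())
    overlap = np.bincount(pool.ravel(), weights=new_cells.ravel().astype(float))
    consumed = np.zeros(len(areas), dtype=bool)
    consumed[1:] = overlap[1:] > 0.5 * areas[1:]
    out = pool.copy()
    out[consumed[pool]] = 0
    return out


def segment_domains(
    domain_probmaps,
    min_region_area: int = 625,
    sigma: float = 2.0,
) -> np.ndarray:
    """Segment tissue domains from domain-class probability maps.

    Each of the classes ``normal``, ``tumour`` and ``structural`` is smoothed
    (Gaussian, default sigma 2 px), thresholded at 0.5, and cleaned of regions
    smaller than ``min_region_area``.  Interface — the hallmark of the
    tumour margin — is assigned *first*, wherever smoothed normal and tumour
    probabilities are both at least 0.5; remaining contested pixels go to the
    class of largest smoothed probability, and pixels below every threshold
    are ``none``.  Returns a uint8 image of :data:`DOMAIN_CODES`.
    """
    classes = ("normal", "tumour", "structural")
    if hasattr(domain_probmaps, "get") and hasattr(domain_probmaps, "class_names"):
        maps = {c: domain_probmaps.get(c) for c in classes}
    else:
        maps = {c: np.asarray(domain_probmaps[c], dtype=np.float64) for c in classes}

    smoothed = {}
    bins = {}
    for c in classes:
        sm = ndi.gaussian_filter(maps[c], sigma) if sigma > 0 else maps[c]
        b = sm >= 0.5
        if min_region_area > 1 and b.any():
            comp, _ = ndi.label(b, structure=_EIGHT)
            areas = np.bincount(comp.ravel())
            small = areas < min_region_area
            small[0] = False
            b &= ~small[comp]
        smoothed[c] = sm
        bins[c] = b

    shape = next(iter(smoothed.values())).shape
    out = np.zeros(shape, dtype=np.uint8)
    interface = bins["normal"] & bins["tumour"]
    out[interface] = DOMAIN_CODES["interface"]

    stack_bin = np.stack([bins[c] for c in classes])
    stack_sm = np.stack([smoothed[c] for c in classes])
    any_bin = stack_bin.any(axis=0) & ~interface
    # contested pixels resolve to the largest smoothed probability
    masked = np.where(stack_bin, stack_sm, -1.0)
    winner = masked.argmax(axis=0)
    codes = np.array([DOMAIN_CODES[c] for c in classes], dtype=np.uint8)
    out[any_bin] = codes[winner[any_bin]]
    return out


def count_disconnected_labels(mask: np.ndarray) -> int:
    """QC: number of labels whose support is not 8-connected."""
    mask = np.asarray(mask)
    n_bad = 0
    for lab in np.unique(mask):
        if lab == 0:
            continue
        _, n = ndi.label(mask == lab, structure=_EIGHT)
        if n > 1:
            n_bad += 1
    return n_bad
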