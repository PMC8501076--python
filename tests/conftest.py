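"""Shared fixtures: small synthetic tissues and independent oracles."""

from __future__ import annotations

import heapq

import numpy as np
import pandas as pd
import pytest

from mimcseg import pipeline, preprocess, synthetic
from mimcseg.synthetic import CellTypeSpec, TissueConfig


def small_tissue_config(seed: int = 0, **overrides) -> TissueConfig:
    """A 160-px ROI with ~90 cells — cheap enough for per-test generation."""
    kwargs = dict(
        size=160,
        tumour_radius=52.0,
        tumour_waviness=8.0,
        n_vessels=1,
        vessel_width=6.0,
        interface_width=5.0,
        cell_types=(
            CellTypeSpec("lymphocyte", 10, 7.0, 5.0, 0.5,
                         {"CD3": 20.0}, ("normal", "interface")),
            CellTypeSpec("macrophage", 8, 12.0, 7.0, 0.8,
                         {"F480": 20.0}, ("tumour", "interface")),
            CellTypeSpec("fibroblast", 4, 0.0, 0.0, 0.0,
                         {"aSMA": 20.0}, ("tumour", "structural"), spindle=True),
            CellTypeSpec("normal", 20, 12.0, 8.0, 0.8,
                         {"PECAM": 18.0, "EPCAM": 4.0}, ("normal",)),
            CellTypeSpec("tumour", 18, 14.0, 10.0, 1.0,
                         {"CD44": 18.0}, ("tumour",)),
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return TissueConfig(**kwargs)


@pytest.fixture(scope="session")
def small_gt():
    return synthetic.generate_tissue(small_tissue_config(seed=7))


@pytest.fixture(scope="session")
def small_pipeline(small_gt):
    """Preprocessed stack + probability maps for the small tissue."""
    stack = preprocess.preprocess_stack(small_gt.stack)
    cell_maps, dom_maps = pipeline.probability_maps_from_truth(stack, small_gt, seed=11)
    return stack, cell_maps, dom_maps


@pytest.fixture(scope="session")
def default_gt():
    """The default study-condition tissue: 512 px, ~600 cells."""
    return synthetic.generate_tissue(TissueConfig(seed=3))


@pytest.fixture(scope="session")
def default_run(default_gt):
    """Full default-condition run: probability maps plus the sequential and
    3-px-expansion segmentations with their cell tables."""
    gt = default_gt
    stack = preprocess.preprocess_stack(gt.stack)
    cell_maps, dom_maps = pipeline.probability_maps_from_truth(stack, gt, seed=23)
    out = {"stack": stack, "cell_maps": cell_maps, "dom_maps": dom_maps, "gt": gt}
    for strategy in ("sequential", "expand3"):
        res = pipeline.segment_roi(stack, strategy, cell_maps, dom_maps)
        table, rel = pipeline.quantify_roi(stack, res, treatment="vehicle")
        out[strategy] = {"result": res, "table": table, "relationships": rel}
    return out


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dijkstra_oracle(nuclei: np.ndarray, guidance: np.ndarray, lam: float,
                    map_threshold: float) -> np.ndarray:
    """Reference geodesic propagation via scipy's sparse Dijkstra.

    Builds the explicit 4-connected pixel graph of the region, runs Dijkstra
    from every seed pixel, reduces to per-label minimal cost, and assigns
    each pixel the label of minimal (cost, label).  Independent of the
    implementation under test.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as sp_dijkstra

    nuclei = np.asarray(nuclei)
    guidance = np.asarray(guidance, dtype=float)
    h, w = nuclei.shape
    region = (guidance >= map_threshold) | (nuclei > 0)
    idx = -np.ones((h, w), dtype=int)
    nodes = np.argwhere(region)
    idx[tuple(nodes.T)] = np.arange(len(nodes))
    rows, cols, costs = [], [], []
    for (dy, dx) in ((0, 1), (1, 0)):
        for (y, x) in nodes:
            ny, nx_ = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx_ < w and region[ny, nx_]:
                c = np.sqrt(lam + (guidance[y, x] - guidance[ny, nx_]) ** 2)
                rows += [idx[y, x], idx[ny, nx_]]
                cols += [idx[ny, nx_], idx[y, x]]
                costs += [c, c]
    n = len(nodes)
    out = np.zeros((h, w), dtype=np.int32)
    seeds = np.argwhere(nuclei > 0)
    if len(seeds) == 0:
        return out
    g = coo_matrix((costs, (rows, cols)), shape=(n, n)).tocsr()
    seed_nodes = idx[tuple(seeds.T)]
    dist = sp_dijkstra(g, indices=seed_nodes)
    seed_labels = nuclei[tuple(seeds.T)]
    labels_sorted = np.unique(seed_labels)
    per_label = np.full((len(labels_sorted), n), np.inf)
    for li, lab in enumerate(labels_sorted):
        per_label[li] = dist[seed_labels == lab].min(axis=0)
    best = per_label.min(axis=0)
    # lowest label among those achieving the minimum
    winner = np.argmax(per_label == best[None, :], axis=0)
    reach = np.isfinite(best)
    out_flat = np.zeros(n, dtype=np.int32)
    out_flat[reach] = labels_sorted[winner[reach]]
    out[tuple(nodes.T)] = out_flat
    return out


def geodesic_bfs_oracle(nuclei: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Nearest-seed partition in the 4-connected geodesic metric: expansion
    of every label to unbounded radius within the region, ties to the lowest
    label.  Implemented as a lexicographic multi-source BFS."""
    nuclei = np.asarray(nuclei)
    h, w = nuclei.shape
    INF = np.inf
    dist = np.full((h, w), INF)
    lab = np.zeros((h, w), dtype=np.int64)
    heap = []
    for (y, x) in np.argwhere(nuclei > 0):
        dist[y, x] = 0
        lab[y, x] = nuclei[y, x]
        heap.append((0, int(nuclei[y, x]), int(y), int(x)))
    heapq.heapify(heap)
    while heap:
        d, l, y, x = heapq.heappop(heap)
        if (d, l) > (dist[y, x], lab[y, x]):
            continue
        for ny, nx_ in ((y + 1, x), (y - 1, x), (y, x + 1), (y, x - 1)):
            if 0 <= ny < h and 0 <= nx_ < w and region[ny, nx_]:
                nd = d + 1
                if (nd, l) < (dist[ny, nx_], lab[ny, nx_] if lab[ny, nx_] else INF):
                    dist[ny, nx_] = nd
                    lab[ny, nx_] = l
                    heapq.heappush(heap, (nd, l, ny, nx_))
    return lab.astype(np.int32)


def brute_force_relationships(mask: np.ndarray, max_dist: float) -> set:
    """O(n^2) oracle: exact minimum support-to-support distance per pair."""
    from scipy.spatial.distance import cdist

    labels = np.unique(mask)
    labels = labels[labels > 0]
    coords = {lab: np.argwhere(mask == lab) for lab in labels}
    pairs = set()
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if cdist(coords[a], coords[b]).min() <= max_dist:
                pairs.add((int(a), int(b)))
    return pairs


def match_centroids(truth: pd.DataFrame, detected: pd.DataFrame, radius: float = 5.0):
    """Greedy one-to-one truth-to-detected matching; returns index pairs."""
    tx = truth["centroid_x"].to_numpy(float)
    ty = truth["centroid_y"].to_numpy(float)
    dx = detected["centroid_x"].to_numpy(float)
    dy = detected["centroid_y"].to_numpy(float)
    d = np.hypot(tx[:, None] - dx[None, :], ty[:, None] - dy[None, :])
    cand = np.argwhere(d <= radius)
    pairs = []
    if cand.size:
        order = np.lexsort((cand[:, 1], cand[:, 0], d[cand[:, 0], cand[:, 1]]))
        ut = np.zeros(len(truth), bool)
        ud = np.zeros(len(detected), bool)
        for i in order:
            a, b = cand[i]
            if ut[a] or ud[b]:
                continue
            ut[a] = True
            ud[b] = True
            pairs.append((int(a), int(b)))
    return pairs
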