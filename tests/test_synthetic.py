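"""Ground-truth generator: determinism, construction guarantees, and the
attraction/repulsion calibration of the spatial statistics."""

import numpy as np
import pandas as pd
import pytest

from mimcseg import synthetic
from mimcseg.quantify import measure_cells
from mimcseg.spatial import neighbourhood_permutation
from mimcseg.synthetic import (
    CellTypeSpec,
    TissueConfig,
    generate_annotations,
    generate_tissue,
    scribbles_from_truth,
)

from conftest import small_tissue_config


class TestGenerateTissue:
    def test_same_seed_reproducible(self):
        g1 = generate_tissue(small_tissue_config(seed=4))
        g2 = generate_tissue(small_tissue_config(seed=4))
        np.testing.assert_array_equal(g1.stack.pixels, g2.stack.pixels)
        np.testing.assert_array_equal(g1.cells, g2.cells)
        pd.testing.assert_frame_equal(g1.cell_table, g2.cell_table)

    def test_zero_densities_empty_masks_pure_noise(self):
        cfg = small_tissue_config(
            seed=1,
            cell_types=tuple(
                CellTypeSpec(s.name, 0, s.cell_diameter, s.nucleus_diameter_mean,
                             s.nucleus_diameter_sd, s.signature, s.domains, s.spindle)
                for s in small_tissue_config().cell_types
            ),
        )
        gt = generate_tissue(cfg)
        assert gt.cells.max() == 0 and gt.nuclei.max() == 0
        assert len(gt.cell_table) == 0
        # ambient reference channel still carries counts
        assert gt.stack.get("Xe134").mean() > 0

    def test_no_noise_no_spillover_means_equal_signature(self):
        cfg = small_tissue_config(
            seed=2, spillover=0.0, poisson_noise=False, hot_pixel_rate=0.0
        )
        gt = generate_tissue(cfg)
        table = measure_cells(gt.cells, gt.stack)
        merged = table.merge(gt.cell_table[["cell_id", "cell_type"]], on="cell_id")
        for spec in cfg.cell_types:
            sub = merged[merged["cell_type"] == spec.name]
            if not len(sub):
                continue
            for marker, value in spec.signature.items():
                np.testing.assert_allclose(sub[marker], value, rtol=1e-12)

    def test_cell_table_consistent_with_masks(self, small_gt):
        gt = small_gt
        assert set(gt.cell_table["cell_id"]) == set(np.unique(gt.cells[gt.cells > 0]))
        areas = np.bincount(gt.cells.ravel())
        for _, row in gt.cell_table.iterrows():
            assert areas[int(row["cell_id"])] == row["area"]

    def test_every_non_spindle_cell_has_nucleus_pixels(self, small_gt):
        gt = small_gt
        nuc_labels = set(np.unique(gt.nuclei[gt.nuclei > 0]))
        for _, row in gt.cell_table.iterrows():
            if row["cell_type"] == "fibroblast":
                assert int(row["cell_id"]) not in nuc_labels
            else:
                assert int(row["cell_id"]) in nuc_labels

    def test_hot_pixels_planted(self):
        cfg = small_tissue_config(seed=3, poisson_noise=False, hot_pixel_rate=5e-3)
        gt = generate_tissue(cfg)
        clean = generate_tissue(small_tissue_config(seed=3, poisson_noise=False,
                                                    hot_pixel_rate=0.0))
        assert (gt.stack.pixels - clean.stack.pixels).max() >= cfg.hot_pixel_amplitude

    def test_overcrowding_raises(self):
        crowded = small_tissue_config(
            seed=5, size=64,
            cell_types=(CellTypeSpec("tumour", 400, 14.0, 10.0, 1.0,
                                     {"CD44": 18.0}, ("tumour",)),),
        )
        with pytest.raises(ValueError, match="hard-core"):
            generate_tissue(crowded)


class TestGenerateAnnotations:
    def test_zero_jitter_hits_exact_centroids(self, small_gt):
        ann = generate_annotations(small_gt, 3, jitter_sd=0.0, seed=0)
        pts = set(zip(small_gt.cell_table["centroid_x"], small_gt.cell_table["centroid_y"]))
        for x, y in zip(ann.x, ann.y):
            assert (x, y) in pts

    def test_requesting_too_many_rejected(self, small_gt):
        with pytest.raises(ValueError, match="only"):
            generate_annotations(small_gt, 10_000, seed=0)

    def test_reproducible_given_seed(self, small_gt):
        a1 = generate_annotations(small_gt, 4, jitter_sd=1.0, seed=9)
        a2 = generate_annotations(small_gt, 4, jitter_sd=1.0, seed=9)
        np.testing.assert_array_equal(a1.x, a2.x)


def test_scribbles_cover_requested_classes(small_gt):
    roster = ["background", "lymphocyte", "tumour"]
    scr = scribbles_from_truth(small_gt, roster, n_per_class=50, seed=0)
    assert set(np.unique(scr)) == {0, 1, 2, 3}
    # scribbled pixels carry the right truth
    lut = np.zeros(int(small_gt.cells.max()) + 1, dtype=object)
    lut[:] = "background"
    for _, r in small_gt.cell_table.iterrows():
        lut[int(r["cell_id"])] = r["cell_type"]
    for k, name in enumerate(roster, start=1):
        truth_at = lut[small_gt.cells[scr == k]]
        assert (truth_at == name).all()


def _interaction_pattern(rng, attract: bool, n=120, box=300.0, radius=12.0):
    """Point pattern with planted attraction (B placed near A) or repulsion
    (B rejected near A); neighbour graph by centroid distance <= 15 px."""
    ax = rng.uniform(0, box, n)
    ay = rng.uniform(0, box, n)
    bx, by = [], []
    while len(bx) < n:
        if attract:
            i = rng.integers(n)
            r = rng.uniform(2.0, radius)
            th = rng.uniform(0, 2 * np.pi)
            x, y = ax[i] + r * np.cos(th), ay[i] + r * np.sin(th)
        else:
            x, y = rng.uniform(0, box), rng.uniform(0, box)
            if np.hypot(ax - x, ay - y).min() < radius:
                continue
        bx.append(x)
        by.append(y)
    cells = pd.DataFrame({
        "cell_id": np.arange(1, 2 * n + 1),
        "cell_type": ["A"] * n + ["B"] * n,
        "centroid_x": np.concatenate([ax, bx]),
        "centroid_y": np.concatenate([ay, by]),
        "roi_id": "r1",
    })
    from scipy.spatial import cKDTree

    pts = cells[["centroid_x", "centroid_y"]].to_numpy()
    pairs = sorted(cKDTree(pts).query_pairs(15.0))
    rel = pd.DataFrame(
        [(i + 1, j + 1) for i, j in pairs], columns=["cell_id_a", "cell_id_b"]
    )
    return cells, rel


@pytest.mark.parametrize("attract", [True, False])
def test_planted_interaction_sign_recovered(attract):
    """log2fc sign matches the planted attraction/repulsion in >=95% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        cells, rel = _interaction_pattern(rng, attract)
        out = neighbourhood_permutation(cells, rel, n_perm=500, seed=seed)
        row = out[(out.type_a == "A") & (out.type_b == "B")].iloc[0]
        if (row["log2fc"] > 0) == attract:
            hits += 1
    assert hits >= 0.95 * n_seeds
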