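"""Segmentation core: nucleus detection, expansion, geodesic propagation
(against an independent Dijkstra oracle), sequential layering, domains."""

import numpy as np
import pytest

from mimcseg.segmentation import (
    DOMAIN_CODES,
    LayerSpec,
    NucleusParams,
    detect_nuclei,
    expand_labels,
    propagate_labels,
    segment_domains,
    sequential_segment,
)

from conftest import dijkstra_oracle, geodesic_bfs_oracle


def _disk(image, cy, cx, r, value=1.0):
    yy, xx = np.indices(image.shape)
    image[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = value
    return image


class TestDetectNuclei:
    def test_two_separated_disks_found(self):
        img = np.zeros((40, 40))
        _disk(img, 10, 10, 4)
        _disk(img, 28, 28, 4)
        labels = detect_nuclei(img, NucleusParams(5, 15, declump="none", smoothing_sigma=0))
        assert labels.max() == 2

    def test_too_small_disk_filtered(self):
        img = np.zeros((20, 20))
        _disk(img, 10, 10, 1.5)
        labels = detect_nuclei(img, NucleusParams(5, 15, declump="none", smoothing_sigma=0))
        assert labels.max() == 0

    def test_declumping_splits_dumbbell(self):
        # two touching disks with two intensity peaks
        img = np.zeros((30, 50))
        yy, xx = np.indices(img.shape)
        for cx, peak in ((18, 10.0), (30, 10.0)):
            img += peak * np.exp(-(((yy - 15) ** 2 + (xx - cx) ** 2) / (2 * 4.0**2)))
        none = detect_nuclei(img, NucleusParams(6, 25, declump="none",
                                                smoothing_sigma=0, threshold="manual",
                                                threshold_value=2.0))
        split = detect_nuclei(img, NucleusParams(6, 25, declump="intensity",
                                                 smoothing_sigma=0, threshold="manual",
                                                 threshold_value=2.0))
        assert none.max() == 1
        assert split.max() == 2

    def test_empty_image_gives_empty_mask(self):
        assert detect_nuclei(np.zeros((10, 10))).max() == 0

    def test_count_invariant_under_rescaling_with_quantile_threshold(self):
        rng = np.random.default_rng(4)
        img = np.zeros((60, 60))
        for _ in range(5):
            _disk(img, rng.integers(8, 52), rng.integers(8, 52), 4, value=rng.uniform(5, 10))
        params = NucleusParams(4, 20, declump="none", threshold="quantile",
                               threshold_value=0.9, smoothing_sigma=0)
        n1 = detect_nuclei(img, params).max()
        n2 = detect_nuclei(img * 37.5, params).max()
        assert n1 == n2 > 0


class TestExpandLabels:
    def test_zero_radius_is_identity(self):
        m = np.zeros((5, 5), int)
        m[2, 2] = 1
        np.testing.assert_array_equal(expand_labels(m, 0), m)

    def test_one_pixel_expansion_is_a_cross(self):
        # diagonals are at sqrt(2) > 1, so excluded
        m = np.zeros((5, 5), int)
        m[2, 2] = 1
        out = expand_labels(m, 1)
        expected = np.zeros((5, 5), int)
        expected[2, 1:4] = 1
        expected[1:4, 2] = 1
        np.testing.assert_array_equal(out, expected)

    def test_tie_at_midpoint_goes_to_lower_label(self):
        m = np.zeros((5, 7), int)
        m[2, 2] = 2
        m[2, 4] = 1
        out = expand_labels(m, 3)
        assert out[2, 3] == 1  # equidistant -> lowest label id
        # radius 3 covers the whole grid: the labels partition it
        assert set(np.unique(out)) == {1, 2}

    def test_matches_brute_force_nearest_seed(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = np.zeros((12, 12), int)
            n_seeds = rng.integers(2, 5)
            pts = rng.choice(144, size=n_seeds, replace=False)
            for i, p in enumerate(pts, start=1):
                m[p // 12, p % 12] = i
            n_px = float(rng.choice([1, 2, 3, 100]))
            out = expand_labels(m, n_px)
            yy, xx = np.indices(m.shape)
            seeds = np.argwhere(m > 0)
            labels = m[tuple(seeds.T)]
            for y in range(12):
                for x in range(12):
                    if m[y, x] > 0:
                        assert out[y, x] == m[y, x]
                        continue
                    d2 = (seeds[:, 0] - y) ** 2 + (seeds[:, 1] - x) ** 2
                    if d2.min() > n_px * n_px:
                        assert out[y, x] == 0
                    else:
                        best = labels[d2 == d2.min()].min()
                        assert out[y, x] == best

    def test_support_monotone_in_radius(self):
        rng = np.random.default_rng(12)
        m = np.zeros((20, 20), int)
        m[4, 4] = 1
        m[15, 11] = 2
        prev = expand_labels(m, 1)
        for r in (2, 3, 5):
            cur = expand_labels(m, r)
            assert ((prev > 0) <= (cur > 0)).all()
            prev = cur


class TestPropagateLabels:
    def test_matches_dijkstra_oracle_on_random_instances(self):
        rng = np.random.default_rng(100)
        for trial in range(30):
            h, w = rng.integers(6, 17, 2)
            guidance = rng.random((h, w))
            nuclei = np.zeros((h, w), int)
            n_seeds = rng.integers(1, 4)
            pts = rng.choice(h * w, size=n_seeds, replace=False)
            for i, p in enumerate(pts, start=1):
                nuclei[p // w, p % w] = i
            lam = float(rng.choice([0.01, 0.05, 1.0]))
            thr = float(rng.choice([0.0, 0.3, 0.5]))
            got = propagate_labels(nuclei, guidance, lam, thr)
            want = dijkstra_oracle(nuclei, guidance, lam, thr)
            np.testing.assert_array_equal(got, want, err_msg=f"trial {trial}")

    def test_constant_guidance_reduces_to_geodesic_voronoi(self):
        rng = np.random.default_rng(101)
        for trial in range(10):
            h, w = rng.integers(6, 15, 2)
            guidance = np.full((h, w), 0.7)
            nuclei = np.zeros((h, w), int)
            pts = rng.choice(h * w, size=rng.integers(2, 4), replace=False)
            for i, p in enumerate(pts, start=1):
                nuclei[p // w, p % w] = i
            got = propagate_labels(nuclei, guidance, lam=0.05, map_threshold=0.5)
            region = np.ones((h, w), bool)
            want = geodesic_bfs_oracle(nuclei, region)
            np.testing.assert_array_equal(got, want, err_msg=f"trial {trial}")

    def test_threshold_one_keeps_only_nuclei(self):
        nuclei = np.zeros((6, 6), int)
        nuclei[2, 2] = 1
        guidance = np.full((6, 6), 0.9)
        out = propagate_labels(nuclei, guidance, 0.05, map_threshold=1.0)
        np.testing.assert_array_equal(out, nuclei)

    def test_bright_ridge_separates_sides(self):
        # a bright column between two seeds: each side sticks to its seed
        guidance = np.zeros((9, 9))
        guidance[:, 4] = 1.0
        nuclei = np.zeros((9, 9), int)
        nuclei[4, 1] = 1
        nuclei[4, 7] = 2
        out = propagate_labels(nuclei, guidance, lam=0.01, map_threshold=0.0)
        assert (out[:, :4] == 1).all()
        assert (out[:, 5:] == 2).all()

    def test_no_nuclei_empty_mask(self):
        out = propagate_labels(np.zeros((4, 4), int), np.ones((4, 4)), 0.05, 0.5)
        assert out.max() == 0


class TestSequentialSegment:
    def _fixture(self):
        """Small nucleus in a lymphocyte-class region, large nucleus in a
        tumour-class region, a seedless fibroblast ribbon region."""
        dna = np.zeros((48, 48))
        _disk(dna, 10, 10, 2.5, 1.0)   # small lymphocyte nucleus
        _disk(dna, 32, 32, 6, 1.0)     # large tumour nucleus
        lymph = np.zeros((48, 48))
        _disk(lymph, 10, 10, 5, 1.0)
        tum = np.zeros((48, 48))
        _disk(tum, 32, 32, 9, 1.0)
        fib = np.zeros((48, 48))
        fib[44:46, 5:40] = 1.0         # elongated seedless region
        probmaps = {"lymphocytes": lymph, "tumour": tum, "fibroblasts": fib}
        layers = [
            LayerSpec("lymphocytes", "lymphocytes",
                      NucleusParams(2, 8, declump="none", threshold="manual",
                                    threshold_value=0.5, smoothing_sigma=0)),
            LayerSpec("fibroblasts", "fibroblasts", None,
                      mode="probability_only", min_area=20),
            LayerSpec("tumour", "tumour",
                      NucleusParams(8, 20, declump="none", threshold="manual",
                                    threshold_value=0.5, smoothing_sigma=0)),
            LayerSpec("remaining", "", None, mode="expand1"),
        ]
        pool_params = NucleusParams(2, 40, declump="none", threshold="manual",
                                    threshold_value=0.5, smoothing_sigma=0)
        return probmaps, dna, layers, pool_params

    def test_layer_assignment_and_nucleus_consumption(self):
        probmaps, dna, layers, pool_params = self._fixture()
        total, table, masks = sequential_segment(probmaps, dna, layers, pool_params)
        by_layer = table.groupby("layer").size().to_dict()
        assert by_layer.get("lymphocytes") == 1
        assert by_layer.get("tumour") == 1
        assert by_layer.get("fibroblasts") == 1
        # the small nucleus was consumed at the first layer: nothing remains
        assert by_layer.get("remaining") is None

    def test_seedless_spindle_object_from_probability_layer(self):
        probmaps, dna, layers, pool_params = self._fixture()
        total, table, masks = sequential_segment(probmaps, dna, layers, pool_params)
        fib_ids = table.loc[table["layer"] == "fibroblasts", "cell_id"]
        assert len(fib_ids) == 1
        assert (masks["fibroblasts"] == fib_ids.iloc[0]).sum() >= 20

    def test_empty_maps_fall_through_to_expand1(self):
        probmaps, dna, layers, pool_params = self._fixture()
        empty = {k: np.zeros_like(v) for k, v in probmaps.items()}
        total, table, masks = sequential_segment(empty, dna, layers, pool_params)
        assert set(table["layer"]) == {"remaining"}
        assert len(table) == 2  # both pool nuclei emerge via 1-px expansion

    def test_layer_masks_disjoint_union_is_total(self):
        probmaps, dna, layers, pool_params = self._fixture()
        total, table, masks = sequential_segment(probmaps, dna, layers, pool_params)
        supports = [m > 0 for m in masks.values()]
        overlap = np.zeros_like(total, dtype=int)
        for s in supports:
            overlap += s
        assert overlap.max() <= 1
        union = np.zeros_like(total)
        for m in masks.values():
            union[m > 0] = m[m > 0]
        np.testing.assert_array_equal(union, total)
        assert set(table["cell_id"]) == set(np.unique(total[total > 0]))

    def test_two_expand1_layers_rejected(self):
        probmaps, dna, layers, pool_params = self._fixture()
        layers = layers + [LayerSpec("again", "", None, mode="expand1")]
        with pytest.raises(ValueError, match="expand1"):
            sequential_segment(probmaps, dna, layers, pool_params)


class TestSegmentDomains:
    def _maps(self, normal, tumour, structural=None):
        z = np.zeros_like(normal)
        return {"normal": normal, "tumour": tumour,
                "structural": structural if structural is not None else z}

    def test_disjoint_maps_have_no_interface(self):
        n = np.zeros((40, 40)); n[:, :15] = 1.0
        t = np.zeros((40, 40)); t[:, 25:] = 1.0
        out = segment_domains(self._maps(n, t), min_region_area=10, sigma=0)
        assert (out == DOMAIN_CODES["interface"]).sum() == 0
        assert (out[:, :15] == DOMAIN_CODES["normal"]).all()
        assert (out[:, 25:] == DOMAIN_CODES["tumour"]).all()

    def test_overlap_band_becomes_interface(self):
        n = np.zeros((40, 40)); n[:, :25] = 1.0
        t = np.zeros((40, 40)); t[:, 15:] = 1.0
        out = segment_domains(self._maps(n, t), min_region_area=10, sigma=0)
        assert (out[:, 15:25] == DOMAIN_CODES["interface"]).all()

    def test_all_zero_maps_give_none_everywhere(self):
        z = np.zeros((20, 20))
        out = segment_domains(self._maps(z, z), min_region_area=10, sigma=0)
        assert (out == DOMAIN_CODES["none"]).all()

    def test_small_speckle_removed(self):
        n = np.zeros((40, 40)); n[5:8, 5:8] = 1.0  # 9 px blob
        t = np.zeros((40, 40))
        out = segment_domains(self._maps(n, t), min_region_area=25, sigma=0)
        assert (out == DOMAIN_CODES["none"]).all()

    def test_every_pixel_exactly_one_category(self):
        rng = np.random.default_rng(13)
        n = rng.random((30, 30))
        t = rng.random((30, 30))
        s = rng.random((30, 30))
        out = segment_domains(self._maps(n, t, s), min_region_area=1, sigma=1.0)
        assert out.min() >= 0 and out.max() <= 4
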