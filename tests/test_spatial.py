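"""Spatial statistics: permutation test, nearest-type distances, profiles."""

import numpy as np
import pandas as pd
import pytest

from mimcseg.spatial import (
    binned_neighbour_profile,
    domain_composition,
    nearest_type_distance,
    neighbourhood_permutation,
)


def _cells(types, x=None, y=None, roi="r1", domain=None):
    n = len(types)
    df = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "cell_type": types,
        "centroid_x": x if x is not None else np.zeros(n),
        "centroid_y": y if y is not None else np.zeros(n),
        "roi_id": roi,
    })
    if domain is not None:
        df["domain"] = domain
    return df


def _ring_graph(n):
    return pd.DataFrame({
        "cell_id_a": np.arange(1, n + 1),
        "cell_id_b": np.roll(np.arange(1, n + 1), -1),
    }).apply(lambda r: sorted(r), axis=1, result_type="expand").rename(
        columns={0: "cell_id_a", 1: "cell_id_b"})


class TestNeighbourhoodPermutation:
    def test_planted_colocation_minimum_p_and_positive_log2fc(self):
        # A and B cells only ever adjacent to each other, C cells isolated
        types = ["A"] * 10 + ["B"] * 10 + ["C"] * 20
        rel = pd.DataFrame({
            "cell_id_a": np.arange(1, 11),
            "cell_id_b": np.arange(11, 21),
        })
        out = neighbourhood_permutation(_cells(types), rel, n_perm=200, seed=0)
        row = out[(out.type_a == "A") & (out.type_b == "B")].iloc[0]
        assert row["p_enriched"] == pytest.approx(1 / 201)
        assert row["log2fc"] > 0

    def test_zero_cell_type_rows_emitted_with_p_one(self):
        types = ["A"] * 5 + ["B"] * 5
        rel = pd.DataFrame({"cell_id_a": [1], "cell_id_b": [6]})
        out = neighbourhood_permutation(
            _cells(types), rel, n_perm=50, seed=0, type_names=["A", "B", "ghost"]
        )
        ghost = out[out.type_a == "ghost"]
        assert (ghost["baseline"] == 0).all()
        assert (ghost["p_enriched"] == 1.0).all()

    def test_p_enriched_plus_p_depleted_overlap_identity(self):
        rng = np.random.default_rng(5)
        types = rng.choice(["A", "B"], 30)
        rel = _ring_graph(30)
        out = neighbourhood_permutation(_cells(types), rel, n_perm=99, seed=1)
        assert (out["p_enriched"] + out["p_depleted"] >= 1 + 1 / 100 - 1e-12).all()

    def test_edge_count_identity(self):
        # sum over pairs of baseline(A,B) * n_A equals the directed edge count
        rng = np.random.default_rng(6)
        types = rng.choice(["A", "B", "C"], 40)
        rel = _ring_graph(40)
        cells = _cells(types)
        out = neighbourhood_permutation(cells, rel, n_perm=10, seed=2)
        counts = cells["cell_type"].value_counts()
        total = sum(
            row["baseline"] * counts.get(row["type_a"], 0)
            for _, row in out.iterrows()
        )
        assert total == pytest.approx(2 * len(rel))

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        types = rng.choice(["A", "B"], 25)
        rel = _ring_graph(25)
        o1 = neighbourhood_permutation(_cells(types), rel, n_perm=100, seed=3)
        o2 = neighbourhood_permutation(_cells(types), rel, n_perm=100, seed=3)
        pd.testing.assert_frame_equal(o1, o2)

    def test_unknown_relationship_id_rejected(self):
        rel = pd.DataFrame({"cell_id_a": [1], "cell_id_b": [99]})
        with pytest.raises(ValueError, match="absent"):
            neighbourhood_permutation(_cells(["A", "B"]), rel, n_perm=10, seed=0)

    def test_domain_stratification_permutes_within_stratum(self):
        types = ["A", "B"] * 10
        domains = ["tumour"] * 10 + ["normal"] * 10
        rel = pd.DataFrame({"cell_id_a": [1, 11], "cell_id_b": [2, 12]})
        out = neighbourhood_permutation(
            _cells(types, domain=domains), rel, n_perm=20, seed=0,
            stratify_by_domain=True,
        )
        assert set(out["stratum"]) == {"normal", "tumour"}


class TestNearestTypeDistance:
    def test_three_four_five(self):
        cells = _cells(["A", "B"], x=[0.0, 3.0], y=[0.0, 4.0])
        d = nearest_type_distance(cells, "B")
        assert d[0] == pytest.approx(5.0)

    def test_target_excludes_itself(self):
        cells = _cells(["B", "B"], x=[0.0, 7.0], y=[0.0, 0.0])
        d = nearest_type_distance(cells, "B")
        assert d[0] == pytest.approx(7.0)
        assert d[1] == pytest.approx(7.0)

    def test_no_target_in_roi_gives_nan(self):
        cells = _cells(["A", "A"], x=[0.0, 1.0], y=[0.0, 0.0])
        assert np.isnan(nearest_type_distance(cells, "B")).all()

    def test_matches_brute_force_on_1000_points(self):
        rng = np.random.default_rng(8)
        n = 1000
        cells = _cells(
            rng.choice(["A", "B", "C"], n),
            x=rng.uniform(0, 500, n), y=rng.uniform(0, 500, n),
        )
        got = nearest_type_distance(cells, "B")
        x = cells["centroid_x"].to_numpy()
        y = cells["centroid_y"].to_numpy()
        is_b = (cells["cell_type"] == "B").to_numpy()
        d = np.hypot(x[:, None] - x[None, is_b], y[:, None] - y[None, is_b])
        for i in range(n):
            di = d[i].copy()
            if is_b[i]:
                di[di == 0.0] = np.inf  # exclude self
            assert got[i] == pytest.approx(di.min())

    def test_computed_per_roi(self):
        cells = pd.concat([
            _cells(["A", "B"], x=[0.0, 3.0], y=[0.0, 4.0], roi="r1"),
            _cells(["A"], x=[0.0], y=[0.0], roi="r2"),
        ], ignore_index=True)
        d = nearest_type_distance(cells, "B")
        assert d[0] == pytest.approx(5.0)
        assert np.isnan(d[2])  # r2 has no B cells


class TestBinnedNeighbourProfile:
    def test_distance_25_falls_in_20_40_bin(self):
        cells = _cells(["ref", "other"], x=[0.0, 25.0], y=[0.0, 0.0])
        prof = binned_neighbour_profile(cells, "ref")
        row = prof[prof["cell_type"] == "other"].iloc[0]
        assert row["20-40"] == 1.0
        assert row["0-20"] == 0.0

    def test_columns_sum_to_one_or_zero(self):
        rng = np.random.default_rng(9)
        n = 60
        cells = _cells(
            rng.choice(["ref", "a", "b"], n),
            x=rng.uniform(0, 150, n), y=rng.uniform(0, 150, n),
        )
        prof = binned_neighbour_profile(cells, "ref")
        sums = prof[["0-20", "20-40", "40-60", "60-80", "80-100"]].sum(axis=0)
        for s in sums:
            assert s == pytest.approx(1.0) or s == 0.0

    def test_cells_beyond_last_edge_dropped(self):
        cells = _cells(["ref", "far"], x=[0.0, 500.0], y=[0.0, 0.0])
        prof = binned_neighbour_profile(cells, "ref")
        far = prof[prof["cell_type"] == "far"]
        assert far[["0-20", "20-40", "40-60", "60-80", "80-100"]].to_numpy().sum() == 0

    def test_bad_bin_edges_rejected(self):
        cells = _cells(["ref", "a"], x=[0.0, 5.0], y=[0.0, 0.0])
        with pytest.raises(ValueError):
            binned_neighbour_profile(cells, "ref", bin_edges=[10, 5])


class TestDomainComposition:
    def test_single_type_single_domain_proportion_one(self):
        cells = _cells(["A"] * 4, domain=["tumour"] * 4)
        cells["treatment"] = "vehicle"
        by_type, by_domain = domain_composition(cells)
        assert by_type["mean"].iloc[0] == 1.0
        assert by_domain["mean"].iloc[0] == 1.0

    def test_proportions_sum_to_one_per_grouping(self):
        rng = np.random.default_rng(10)
        cells = _cells(
            rng.choice(["A", "B"], 40),
            domain=rng.choice(["tumour", "normal"], 40),
        )
        cells["treatment"] = "vehicle"
        by_type, by_domain = domain_composition(cells)
        for _, grp in by_domain.groupby(["treatment", "domain"]):
            assert grp["mean"].sum() == pytest.approx(1.0)

    def test_sem_zero_for_identical_rois(self):
        one = _cells(["A", "B"], domain=["tumour", "tumour"], roi="r1")
        two = one.copy()
        two["roi_id"] = "r2"
        cells = pd.concat([one, two], ignore_index=True)
        cells["treatment"] = "vehicle"
        by_type, _ = domain_composition(cells)
        assert (by_type["sem"] == 0.0).all()
        assert (by_type["n_roi"] == 2).all()
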