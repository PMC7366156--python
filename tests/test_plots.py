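"""Nested plot geometry, splitting, tallies, h-tree selection, key habitats."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from conftest import StubLandscape, make_trees
from nfisim import StandAttributes
from nfisim.plots import (
    ChiConfig,
    angle_count_limit,
    circular_segment_area,
    classify_chi_habitats,
    layout_plot,
    measure_plot,
    select_h_trees,
    split_plot,
)


class TestLayout:
    def test_nested_radii_match_area_closed_forms(self):
        g = layout_plot((0.0, 0.0))
        assert round(g.tree_plot_radius, 2) == 8.92  # 250 m^2
        assert round(g.regen_subplot_radius, 2) == 2.26  # 16 m^2
        assert round(math.pi * g.smalltree_subplot_radius**2, 1) == 5.3  # 1.3 m radius
        assert g.stand_plot_radius == pytest.approx(math.sqrt(1000 / math.pi))
        assert g.habitat_plot_radius == pytest.approx(math.sqrt(2000 / math.pi))

    def test_subplot_offsets_and_transects(self):
        g = layout_plot((100.0, 200.0))
        rc = g.regen_subplot_centers()
        assert rc["N"] == (100.0, 212.0) and rc["C"] == (100.0, 200.0)
        sc = g.smalltree_subplot_centers()
        assert sc["W"] == (95.0, 200.0)
        t = g.transects()
        assert t["EW"].length == pytest.approx(18.0)
        assert t["NS"].length == pytest.approx(18.0)


class TestSplit:
    A = StandAttributes(maturity_class=5)
    B = StandAttributes(maturity_class=2)

    def chord_for_segment_area(self, target):
        from scipy.optimize import brentq

        r = layout_plot((0, 0)).tree_plot_radius
        return brentq(lambda d: circular_segment_area(r, d) - target, 0.0, r - 1e-9)

    def test_segment_below_minimum_does_not_split(self):
        d = self.chord_for_segment_area(30.0)
        parts = split_plot(layout_plot((0, 0)), d, 0.0, self.A, self.B)
        assert len(parts) == 1
        assert parts[0].area_m2 == pytest.approx(250.0)

    def test_diameter_chord_gives_two_equal_halves(self):
        parts = split_plot(layout_plot((0, 0)), 0.0, 90.0, self.A, self.B)
        assert len(parts) == 2
        assert parts[0].area_m2 == pytest.approx(125.0)
        assert parts[1].area_m2 == pytest.approx(125.0)

    def test_identical_attributes_never_split(self):
        parts = split_plot(layout_plot((0, 0)), 0.0, 0.0, self.A, self.A)
        assert len(parts) == 1

    def test_part_areas_sum_to_plot_area(self):
        for d in (0.5, 2.0, 4.0, 6.0):
            parts = split_plot(layout_plot((0, 0)), d, 45.0, self.A, self.B)
            assert sum(p.area_m2 for p in parts) == pytest.approx(250.0, abs=0.01)

    @pytest.mark.parametrize("chord_d", [1.0, 3.0, 5.5])
    def test_segment_area_matches_monte_carlo_integration(self, chord_d):
        """Closed-form circular-segment area vs uniform point counting."""
        r = layout_plot((0, 0)).tree_plot_radius
        rng = np.random.default_rng(int(chord_d * 10))
        n = 15_000_000
        hits = 0
        for _ in range(3):
            u = rng.random(n // 3)
            theta = rng.uniform(0, 2 * math.pi, n // 3)
            x = r * np.sqrt(u) * np.cos(theta)
            hits += int((x > chord_d).sum())
        mc_area = 250.0 * hits / n
        assert circular_segment_area(r, chord_d) == pytest.approx(mc_area, abs=0.1)


class TestMeasure:
    def test_boundary_tree_inclusion(self):
        trees = make_trees([
            (8.91, 0.0, "spruce", 5.0, 8.0),   # inside, dbh at threshold
            (8.93, 0.0, "spruce", 30.0, 20.0),  # just outside the radius
            (2.0, 2.0, "pine", 4.99, 5.0),      # below dbh threshold
        ])
        obs = measure_plot(StubLandscape(trees), layout_plot((0.0, 0.0)))
        assert list(obs.trees["tree_id"]) == [0]

    def test_tally_matches_brute_force_filter(self, forest_landscape):
        center = (200.0, 200.0)
        obs = measure_plot(forest_landscape, layout_plot(center))
        t = forest_landscape.trees
        d = np.hypot(t["x"] - center[0], t["y"] - center[1])
        expected = set(t.loc[(d <= layout_plot(center).tree_plot_radius)
                             & (t["dbh_cm"] >= 5.0), "tree_id"])
        assert set(obs.trees["tree_id"]) == expected

    def test_small_trees_and_regen_counted_on_subplots(self):
        trees = make_trees([
            (5.0, 0.5, "birch", 1.0, 1.5),    # in E small-tree subplot, class 1
            (5.0, -0.5, "birch", 3.0, 2.5),   # in E small-tree subplot, class 2
            (0.0, 12.0, "spruce", 0.5, 0.6),  # in N regen subplot, > 30 cm tall
            (0.0, 12.0, "spruce", 0.2, 0.2),  # too short for regen
        ])
        obs = measure_plot(StubLandscape(trees), layout_plot((0.0, 0.0)))
        east = obs.smalltrees.set_index("subplot")
        assert east.loc["E", "n_class1"] == 1 and east.loc["E", "n_class2"] == 1
        regen = obs.regen.set_index("subplot")
        assert regen.loc["N", "n_trees"] == 1  # only the stem taller than 30 cm

    def test_deadwood_transect_intersections(self):
        pieces = pd.DataFrame([
            # crosses the E-W transect perpendicular at x=3, diameters 20->10
            {"x": 3.0, "y": 0.0, "species_group": "spruce", "decay_class": 2,
             "length_m": 6.0, "azimuth_deg": 0.0, "d_root_cm": 20.0,
             "d_cross_cm": 15.0, "d_top_cm": 10.0},
            # parallel to and far from both transects: no intersection
            {"x": 4.0, "y": 5.0, "species_group": "pine", "decay_class": 1,
             "length_m": 4.0, "azimuth_deg": 90.0, "d_root_cm": 12.0,
             "d_cross_cm": 10.0, "d_top_cm": 8.0},
        ])
        obs = measure_plot(StubLandscape(deadwood=pieces), layout_plot((0.0, 0.0)))
        assert len(obs.deadwood) == 1
        row = obs.deadwood.iloc[0]
        assert row["transect_id"] == "EW"
        # intersection at the piece midpoint: linear taper gives 15 cm
        assert row["diameter_cm"] == pytest.approx(15.0)


class TestHTreeSelection:
    def test_ten_or_fewer_trees_all_measured(self):
        sel = select_h_trees(np.full(8, 20.0), np.linspace(1, 8, 8))
        assert sel.n_selected == 8
        assert sel.baf_m2ha is None
        assert np.all(sel.weights == 1.0)

    def test_relascope_limit_hand_evaluation(self):
        # dbh 20 cm at BAF 4: limit = 0.20 m * 50 / 2 = 5.0 m
        assert angle_count_limit(20.0, 4.0) == pytest.approx(5.0)
        dbh = np.full(12, 20.0)
        dist = np.array([4.9, 5.1] + [6.0] * 10)
        sel = select_h_trees(dbh, dist, baf_ladder=(4.0,))
        assert sel.baf_m2ha == 4.0
        assert bool(sel.selected[0]) is True
        assert bool(sel.selected[1]) is False

    def test_smallest_adequate_baf_chosen_from_previous_visit(self):
        rng = np.random.default_rng(3)
        dbh = rng.uniform(6, 35, 30)
        dist = rng.uniform(0.5, 8.9, 30)
        sel = select_h_trees(dbh, dist, prev_dbh_cm=dbh, prev_distance_m=dist)
        # the chosen BAF admits <= 10 by the previous-visit count and every
        # smaller ladder value admits more than 10
        from nfisim.plots import BAF_LADDER

        for baf in BAF_LADDER:
            count = int((dist <= angle_count_limit(dbh, baf)).sum())
            if baf < sel.baf_m2ha:
                assert count > 10
            elif baf == sel.baf_m2ha:
                assert count <= 10

    def test_selection_probability_proportional_to_basal_area(self):
        """Empirical selection frequency under uniform tree placement
        matches pi_i = min(1, (limit/R)^2), which is proportional to dbh^2."""
        rng = np.random.default_rng(12)
        dbh = np.array([8.0, 16.0, 32.0] * 5)
        R = layout_plot((0, 0)).tree_plot_radius
        hits = np.zeros(dbh.size)
        reps = 3000
        for _ in range(reps):
            r = R * np.sqrt(rng.random(dbh.size))
            sel = select_h_trees(dbh, r, baf_ladder=(9.0,))
            hits += sel.selected
        freq = hits / reps
        limit = angle_count_limit(dbh, 9.0)
        expected = np.minimum(1.0, (limit / R) ** 2)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert np.all(np.abs(freq - expected) < 4 * se + 1e-9)
        # dbh 16 vs 8: fourfold basal area, fourfold selection probability
        assert expected[1] / expected[0] == pytest.approx(4.0)


def habitat_frame(rows):
    """Habitat-plot tree table from (x, y, species, dbh, age, status,
    standing) tuples."""
    from nfisim import species_group

    recs = []
    for i, (x, y, sp, dbh, age, status, standing) in enumerate(rows):
        recs.append({
            "tree_id": i, "species": sp, "species_group": species_group(sp),
            "dbh_cm": dbh, "height_m": 15.0, "age": age, "status": status,
            "standing": standing, "distance_m": np.hypot(x, y),
            "azimuth_deg": 0.0, "x_rel": x, "y_rel": y,
        })
    return pd.DataFrame(recs)


def obs_with(trees):
    from nfisim.plots import PlotObservation, PlotPart, layout_plot

    return PlotObservation(
        plot_id=0, geometry=layout_plot((0, 0)),
        parts=[PlotPart(1, 250.0, StandAttributes())],
        trees=trees.head(0), habitat_trees=trees,
        smalltrees=pd.DataFrame(), regen=pd.DataFrame(),
        deadwood=pd.DataFrame(), berry=pd.DataFrame(), droppings=0,
        vegetation_type="heather",
    )


class TestChiHabitats:
    def test_nine_chained_standing_dead_trees_qualify(self):
        # 9 trees on 0.2 ha = 45/ha >= 40/ha, all within a 15 m chain
        rows = [(i * 10.0 - 40.0, 0.0, "spruce", 15.0, 80.0, "dead", True)
                for i in range(9)]
        records, _ = classify_chi_habitats(obs_with(habitat_frame(rows)))
        assert any(r.habitat_type == "standing_deadwood" for r in records)

    def test_density_met_but_chain_broken_does_not_qualify(self):
        rows = [(i * 16.0 - 64.0, 0.0, "spruce", 15.0, 80.0, "dead", True)
                for i in range(9)]  # 16 m gaps break the 15 m chaining
        records, _ = classify_chi_habitats(obs_with(habitat_frame(rows)))
        assert not any(r.habitat_type == "standing_deadwood" for r in records)

    def test_empty_plot_has_no_habitats(self):
        records, _ = classify_chi_habitats(obs_with(habitat_frame([])))
        assert records == []

    def test_missing_lichen_flags_reported_as_not_assessed(self):
        rows = [(0.0, 0.0, "spruce", 15.0, 80.0, "live", True)]
        _, not_assessed = classify_chi_habitats(obs_with(habitat_frame(rows)))
        assert "nutrient_rich_bark" in not_assessed
        assert "pendant_lichens" in not_assessed

    def test_chaining_is_permutation_invariant(self):
        rng = np.random.default_rng(8)
        rows = [(float(x), float(y), "pine", 15.0, 90.0, "dead", True)
                for x, y in rng.uniform(-25, 25, (12, 2))]
        base, _ = classify_chi_habitats(obs_with(habitat_frame(rows)))
        perm = [rows[i] for i in rng.permutation(len(rows))]
        shuf, _ = classify_chi_habitats(obs_with(habitat_frame(perm)))
        assert {r.habitat_type for r in base} == {r.habitat_type for r in shuf}

    @pytest.mark.parametrize("trial", range(10))
    def test_standing_deadwood_matches_brute_force_rule(self, trial):
        """Union-find chaining vs scipy connected components + direct
        density arithmetic."""
        rng = np.random.default_rng(900 + trial)
        n = rng.integers(0, 20)
        pts = rng.uniform(-25, 25, (n, 2))
        dbh = rng.uniform(5, 40, n)
        rows = [(pts[i, 0], pts[i, 1], "spruce", dbh[i], 80.0, "dead", True)
                for i in range(n)]
        records, _ = classify_chi_habitats(obs_with(habitat_frame(rows)))
        got = any(r.habitat_type == "standing_deadwood" for r in records)

        qualifying = pts[dbh >= 10.0]
        expect = False
        if len(qualifying):
            m = len(qualifying)
            adj = np.zeros((m, m))
            for i in range(m):
                for j in range(m):
                    if i != j and np.hypot(*(qualifying[i] - qualifying[j])) <= 15.0:
                        adj[i, j] = 1
            _, labels = connected_components(csr_matrix(adj), directed=False)
            biggest = max(np.bincount(labels)) if m else 0
            expect = biggest / 0.2 >= 40.0
        assert got == expect


class TestPartAssignment:
    def test_trees_assigned_to_the_part_containing_them(self):
        from nfisim.plots import PlotPart, split_plot

        a = StandAttributes(maturity_class=5)
        b = StandAttributes(maturity_class=2)
        parts = split_plot(layout_plot((0, 0)), 2.0, 90.0, a, b)  # chord x=2
        trees = make_trees([
            (-3.0, 0.0, "spruce", 10.0, 10.0),  # centre side
            (5.0, 0.0, "spruce", 10.0, 10.0),   # far side
        ])
        obs = measure_plot(StubLandscape(trees), layout_plot((0.0, 0.0)), parts)
        by_id = obs.trees.set_index("tree_id")["part_id"]
        assert by_id[0] == 1 and by_id[1] == 2
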