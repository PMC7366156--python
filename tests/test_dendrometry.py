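"""Height/volume chain, correction factors, increment, stand classifiers."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfisim.dendrometry import (
    AllometrySet,
    CorrectionContext,
    MaturityThresholds,
    SeasonCalendar,
    annual_volume_increment,
    growing_seasons,
    impute_annual_dbh_difference,
    maturity_class,
    plot_correction_factors,
    predict_biomass,
    predict_tree_volume,
    removal_volume,
    site_index_class,
    species_group,
    stand_age,
    volume_function_key,
)

ALLO = AllometrySet()


class TestSpeciesRouting:
    def test_sitka_gets_its_own_volume_function(self):
        assert volume_function_key("sitka_spruce") == "sitka"

    def test_other_firs_use_the_spruce_function(self):
        assert volume_function_key("silver_fir") == "spruce"

    def test_other_conifers_use_the_pine_function(self):
        assert volume_function_key("larch") == "pine"

    def test_broadleaves_use_the_deciduous_function(self):
        assert volume_function_key("rowan") == "deciduous"
        assert species_group("sitka_spruce") == "spruce"  # tally group


class TestHeightApproximation:
    def test_matches_closed_form_hand_evaluation(self):
        # h = 1.3 + (d / (a + b d))^3 with the documented spruce stand-in
        d = 20.0
        expected = 1.3 + (d / (2.3 + 0.32 * d)) ** 3
        assert float(ALLO.height("spruce", d)) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_dbh(self):
        d = np.linspace(5, 80, 200)
        h = ALLO.height("pine", d)
        assert np.all(np.diff(h) >= 0)

    def test_asymptote(self):
        b = 0.32
        assert float(ALLO.height("spruce", 1e6)) == pytest.approx(1.3 + b**-3, rel=1e-3)

    def test_missing_species_group_raises_with_name(self):
        allo = AllometrySet({"spruce": AllometrySet().coefficients["spruce"]})
        with pytest.raises(KeyError, match="pine"):
            allo.height("scots_pine", 20.0)


class TestCorrectionFactors:
    def test_identity_when_measured_equals_approximated(self):
        d = np.array([8.0, 15.0, 30.0])
        h_approx = np.array([float(ALLO.height("spruce", x)) for x in d])
        for w in (np.ones(3), np.array([5.0, 1.0, 0.2])):
            ctx = plot_correction_factors(
                1, ["spruce"] * 3, d, h_approx, w, ALLO, species_codes=["spruce"] * 3
            )
            assert ctx["spruce"].factor == pytest.approx(1.0, abs=1e-12)

    def test_weighted_ratio_hand_arithmetic(self):
        """Volumes (measured/approx) of (1.2/1.0) and (0.9/1.0) with weights
        (2, 1) give (2*1.2 + 0.9) / (2*1.0 + 1.0) = 1.1."""
        d = np.array([20.0, 20.0])
        h_approx = float(ALLO.height("spruce", 20.0))
        v_approx = float(ALLO.volume("spruce", 20.0, h_approx))
        # choose measured heights so v_meas/v_approx = 1.2 and 0.9 exactly
        h12 = ALLO.height_from_volume("spruce", 20.0, 1.2 * v_approx)
        h09 = ALLO.height_from_volume("spruce", 20.0, 0.9 * v_approx)
        ctx = plot_correction_factors(
            1, ["spruce"] * 2, d, [h12, h09], [2.0, 1.0], ALLO,
            species_codes=["spruce"] * 2,
        )
        assert ctx["spruce"].factor == pytest.approx(1.1, abs=1e-9)

    def test_small_trees_have_larger_influence(self):
        """Inverse selection-probability weighting: the same volume
        perturbation moves the factor more when it sits on the small tree
        (whose angle-count selection probability is lower)."""
        d = np.array([8.0, 40.0])
        h = np.array([float(ALLO.height("spruce", x)) for x in d])
        v = np.array([float(ALLO.volume("spruce", di, hi)) for di, hi in zip(d, h)])
        w = 1.0 / np.minimum(1.0, (d * 0.5 / 2.0 / 8.92) ** 2)  # 1/pi_i at BAF 4
        delta = 0.005  # m^3, added to one tree's measured-height volume

        def factor(v_meas):
            h_meas = [ALLO.height_from_volume("spruce", di, vi)
                      for di, vi in zip(d, v_meas)]
            return plot_correction_factors(
                1, ["spruce"] * 2, d, h_meas, w, ALLO, species_codes=["spruce"] * 2
            )["spruce"].factor

        bump_small = factor([v[0] + delta, v[1]])
        bump_large = factor([v[0], v[1] + delta])
        assert abs(bump_small - 1.0) > abs(bump_large - 1.0)

    def test_fallback_context_validates(self):
        with pytest.raises(ValueError):
            CorrectionContext(1, "spruce", 0.0, "fallback")


class TestVolumePrediction:
    def test_unit_correction_round_trips_the_approximated_height(self):
        v, h = predict_tree_volume("pine", 22.0, ALLO, correction=1.0)
        assert h == pytest.approx(float(ALLO.height("pine", 22.0)), abs=1e-6)

    def test_backsolved_height_matches_bisection_oracle(self):
        corr = 1.1
        v, h = predict_tree_volume("spruce", 20.0, ALLO, correction=corr)
        h_approx = float(ALLO.height("spruce", 20.0))
        target = corr * float(ALLO.volume("spruce", 20.0, h_approx))
        lo, hi = 0.5, 60.0
        for _ in range(60):  # plain bisection, independent of brentq
            mid = (lo + hi) / 2
            if float(ALLO.volume("spruce", 20.0, mid)) < target:
                lo = mid
            else:
                hi = mid
        assert h == pytest.approx((lo + hi) / 2, abs=1e-6)
        assert v == pytest.approx(target, abs=1e-12)

    def test_measured_height_used_directly(self):
        v, h = predict_tree_volume("birch", 18.0, ALLO, measured_height_m=14.0,
                                   correction=1.3)
        assert h == 14.0
        assert v == pytest.approx(float(ALLO.volume("birch", 18.0, 14.0)))

    def test_breakage_reduces_volume_by_cone_top_fraction(self):
        v_full, _ = predict_tree_volume("spruce", 30.0, ALLO)
        v_broken, _ = predict_tree_volume("spruce", 30.0, ALLO,
                                          relative_break_height=0.5)
        assert v_broken == pytest.approx(v_full * (1 - 0.125))
        v_off, _ = predict_tree_volume("spruce", 30.0, ALLO,
                                       relative_break_height=0.5,
                                       apply_breakage=False)
        assert v_off == pytest.approx(v_full)

    def test_dbh_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            predict_tree_volume("spruce", 4.0, ALLO)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        species=st.sampled_from(["spruce", "scots_pine", "birch", "sitka_spruce"]),
        dbh=st.floats(5.0, 60.0),
        h=st.floats(2.0, 40.0),
    )
    def test_height_backsolve_round_trip_to_one_millimetre(self, species, dbh, h):
        v = float(ALLO.volume(species, dbh, h))
        assert ALLO.height_from_volume(species, dbh, v) == pytest.approx(h, abs=1e-3)


class TestBiomass:
    def test_matches_closed_form_hand_evaluation(self):
        d = 25.0
        expected = math.exp(-2.0 + 11.0 * d / (d + 12.0))
        ag, bg = predict_biomass("spruce", d, ALLO)
        assert float(ag) == pytest.approx(expected, rel=1e-12)
        assert float(bg) < float(ag)

    def test_monotone_in_dbh_and_deciduous_routing(self):
        d = np.linspace(5, 80, 100)
        ag, _ = predict_biomass("rowan", d, ALLO)
        assert np.all(np.diff(ag) > 0)
        ag_birch, _ = predict_biomass("birch", 20.0, ALLO)
        ag_rowan, _ = predict_biomass("rowan", 20.0, ALLO)
        assert float(ag_birch) == float(ag_rowan)  # same deciduous function set


class TestGrowingSeasons:
    CAL = SeasonCalendar(season_start=152, season_length=100)

    def test_same_midseason_day_five_years_apart_is_five(self):
        a = dt.date(2015, 7, 1)
        b = dt.date(2020, 7, 1)
        assert growing_seasons(a, b, self.CAL) == pytest.approx(5.00)

    def test_season_start_to_season_end_is_six(self):
        a = dt.date(2015, 6, 1)  # day 152, s = 0
        b = dt.date(2020, 9, 30)  # well past day 252, s = 100
        assert growing_seasons(a, b, self.CAL) == pytest.approx(6.00)

    def test_season_end_to_season_start_is_four(self):
        a = dt.date(2015, 9, 30)
        b = dt.date(2020, 6, 1)
        assert growing_seasons(a, b, self.CAL) == pytest.approx(4.00)

    def test_bounds_over_arbitrary_five_year_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            doy_a = int(rng.integers(1, 365))
            doy_b = int(rng.integers(1, 365))
            a = dt.date(2013, 1, 1) + dt.timedelta(days=doy_a - 1)
            b = dt.date(2018, 1, 1) + dt.timedelta(days=doy_b - 1)
            s = growing_seasons(a, b, self.CAL)
            assert 4.0 <= s <= 6.0

    def test_rejects_reversed_dates(self):
        with pytest.raises(ValueError):
            growing_seasons(dt.date(2020, 1, 1), dt.date(2019, 1, 1))


class TestIncrementAndRemoval:
    def test_no_diameter_change_gives_zero_increment(self):
        v, _ = predict_tree_volume("spruce", 20.0, ALLO)
        inc = annual_volume_increment("spruce", 20.0, 20.0, v, 5.0, ALLO)
        assert inc == pytest.approx(0.0, abs=1e-12)

    def test_two_step_chain_hand_evaluation(self):
        """dbh 20 -> 21.5 cm over 5.00 seasons: dbh one year back is 21.2;
        the increment is v(21.5) - v(21.2) on the h-dbh curve."""
        v_curr = float(ALLO.volume("spruce", 21.5, ALLO.height("spruce", 21.5)))
        inc = annual_volume_increment("spruce", 20.0, 21.5, v_curr, 5.0, ALLO)
        dbh_m1 = 21.5 - 1.5 / 5.0
        assert dbh_m1 == pytest.approx(21.2)
        v_m1 = float(ALLO.volume("spruce", dbh_m1, ALLO.height("spruce", dbh_m1)))
        assert inc == pytest.approx(v_curr - v_m1, abs=1e-12)

    def test_previous_correction_factor_enters_the_baseline(self):
        v_curr = float(ALLO.volume("spruce", 21.5, ALLO.height("spruce", 21.5)))
        inc_1 = annual_volume_increment("spruce", 20.0, 21.5, v_curr, 5.0, ALLO, 1.0)
        inc_09 = annual_volume_increment("spruce", 20.0, 21.5, v_curr, 5.0, ALLO, 0.9)
        assert inc_09 > inc_1

    def test_population_increment_tracks_simulated_growth(self):
        """Summed matched-tree increments on a no-mortality, no-harvest
        stand approximate the true simulated annual volume growth."""
        from nfisim import LandscapeConfig, simulate_landscape, simulate_remeasurement

        cfg = LandscapeConfig(
            extent=(0, 0, 250, 250), cell_size=50, seed=11,
            alpine_threshold_m=2000, forest_fraction={1: 1.0, 2: 0.1},
            height_lognorm_sd=0.0, mortality_prob=0.0, harvest_prob_5yr=0.0,
            ingrowth_per_ha_yr=0.0, standing_dead_fraction=0.0,
        )
        prev = simulate_landscape(cfg)
        curr = simulate_remeasurement(prev, 5)
        t0 = prev.live_trees().set_index("tree_id")
        t1 = curr.live_trees().set_index("tree_id")
        common = t0.index.intersection(t1.index)
        inc = 0.0
        for tid in common:
            sp = t1.loc[tid, "species"]
            d1 = float(t1.loc[tid, "dbh_cm"])
            v1 = float(ALLO.volume(sp, d1, t1.loc[tid, "height_m"]))
            inc += annual_volume_increment(sp, float(t0.loc[tid, "dbh_cm"]),
                                           d1, v1, 5.0, ALLO)
        true_annual = (curr.total_volume_m3() - prev.total_volume_m3()) / 5.0
        assert inc == pytest.approx(true_annual, rel=0.10)

    def test_removal_volume_rule(self):
        assert removal_volume(1.00, 0.02) == pytest.approx(1.05)
        assert removal_volume(0.75, 0.0) == pytest.approx(0.75)

    def test_imputation_cell_widening_order(self):
        df = pd.DataFrame({
            "species": ["spruce", "spruce", "pine"],
            "dbh_cm": [12.0, 27.0, 12.0],
            "annual_dbh_diff": [0.30, 0.50, 0.20],
            "maturity_class": [3, 5, 3],
            "si_class": [14, 14, 14],
        })
        # exact cell hit
        assert impute_annual_dbh_difference(df, "spruce", 12.0, 3, 14) == 0.30
        # si mismatch -> drop si
        assert impute_annual_dbh_difference(df, "spruce", 12.0, 3, 20) == 0.30
        # diameter class mismatch -> species mean
        assert impute_annual_dbh_difference(df, "spruce", 45.0, 3, 14) == pytest.approx(0.40)
        with pytest.raises(ValueError):
            impute_annual_dbh_difference(df, "birch", 12.0, 3, 14)


class TestSiteIndex:
    @pytest.mark.parametrize("height,expected", [
        (12.5, 14),  # lower bin edge inclusive
        (15.5, 17),  # upper edge belongs to the next class
        (14.0, 14),  # bin centre
        (1.0, 6),    # clamped low
        (40.0, 26),  # clamped high
    ])
    def test_three_metre_bins(self, height, expected):
        assert site_index_class(height) == expected

    def test_rejects_nonpositive_height(self):
        with pytest.raises(ValueError):
            site_index_class(0.0)


class TestStandAge:
    def test_equal_basal_areas_average_the_ages(self):
        assert stand_age([40.0, 60.0], [20.0, 20.0]) == pytest.approx(50.0)

    def test_two_layered_stand_uses_overstory_only(self):
        age = stand_age([80.0, 20.0], [30.0, 10.0], ["overstory", "understory"])
        assert age == pytest.approx(80.0)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(14)
        ages = rng.uniform(10, 150, 40)
        dbh = rng.uniform(5, 50, 40)
        g = np.pi / 4 * dbh**2
        assert stand_age(ages, dbh) == pytest.approx(float((g * ages).sum() / g.sum()))

    def test_no_aged_trees_raises(self):
        with pytest.raises(ValueError):
            stand_age([], [])


class TestMaturityClass:
    def test_age_zero_is_regeneration(self):
        assert maturity_class(0.0, 14)[0] == 1

    def test_mature_entry_ages_at_the_site_index_extremes(self):
        t = MaturityThresholds()
        assert t.entry_age(5, 6) == 120
        assert t.entry_age(5, 26) == 40

    def test_class_non_decreasing_in_site_index_for_fixed_age(self):
        for age in (10, 30, 50, 90, 130):
            classes = [maturity_class(age, si)[0] for si in range(6, 27)]
            assert classes == sorted(classes)

    def test_entry_ages_within_printed_ranges(self):
        t = MaturityThresholds()
        for cls, (lo, hi) in t.RANGES.items():
            entries = [t.entry_age(cls, si) for si in range(6, 27)]
            assert min(entries) >= lo and max(entries) <= hi

    def test_bad_threshold_table_rejected_at_startup(self):
        with pytest.raises(ValueError):
            MaturityThresholds({3: (15, 84), 4: (25, 119), 5: (40, 30)})

    def test_stocking_flag(self):
        assert maturity_class(20, 14, crop_trees_per_ha=50.0)[1] == "poorly"
        assert maturity_class(20, 14, crop_trees_per_ha=500.0)[1] == "sufficiently"
        assert maturity_class(100, 14, basal_area_m2ha=1.0)[1] == "poorly"
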