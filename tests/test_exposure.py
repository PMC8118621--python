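"""Variable ranking, the geometric-mean IE, and habitat scenarios."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point

from coastvuln.exposure import (
    DEFAULT_SCHEMES,
    SCENARIOS,
    HabitatLayer,
    classify_ie,
    compute_ie,
    habitat_rank,
    rank_fixed_bins,
    rank_quantile,
    run_scenarios,
    shoreline_change_rank,
)


def coral(poly, reach=2000.0):
    return HabitatLayer("coral_reef", 1, reach, [poly])


def mangrove(poly, reach=1000.0):
    return HabitatLayer("mangrove", 1, reach, [poly])


def seagrass(poly, reach=500.0):
    return HabitatLayer("seagrass", 4, reach, [poly])


class TestFixedBins:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, 5), (15.0, 1), (4.0, 3), (2.0, 4), (12.0, 1), (-0.5, 5), (30.0, 1)],
    )
    def test_relief(self, value, expected):
        assert rank_fixed_bins(value, DEFAULT_SCHEMES["relief"]) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(100.0, 5), (0.5, 1), (0.75, 2), (18.75, 4), (48.0, 5), (300.0, 5)],
    )
    def test_wave(self, value, expected):
        assert rank_fixed_bins(value, DEFAULT_SCHEMES["wave"]) == expected

    def test_non_finite_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            rank_fixed_bins(np.nan, DEFAULT_SCHEMES["relief"])

    def test_monotone_step_function(self):
        v = np.linspace(-5, 60, 500)
        relief = rank_fixed_bins(v, DEFAULT_SCHEMES["relief"])
        wave = rank_fixed_bins(v, DEFAULT_SCHEMES["wave"])
        assert (np.diff(relief) <= 0).all()  # larger relief -> less exposed
        assert (np.diff(wave) >= 0).all()


def quantile_rank_oracle(values):
    """Brute-force sort-and-cut quintile oracle (manual R-7 percentiles)."""
    v = np.asarray(values, dtype=float)
    s = np.sort(v)
    n = len(s)
    breaks = []
    for p in (0.2, 0.4, 0.6, 0.8):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        breaks.append(s[lo] + (h - lo) * (s[hi] - s[lo]))
    ranks = []
    for x in v:
        ranks.append(sum(b < x for b in breaks) + 1)  # tie -> lower class
    return np.array(ranks)


class TestQuantileRank:
    def test_one_to_hundred(self):
        v = np.arange(1, 101, dtype=float)
        r = rank_quantile(v)
        assert r[v == 10][0] == 1
        assert r[v == 50][0] == 3
        assert r[v == 95][0] == 5

    def test_constant_vector(self):
        assert (rank_quantile(np.full(20, 3.3)) == 1).all()

    def test_two_value_tie_case(self):
        v = np.array([1.0] * 50 + [2.0] * 50)
        np.testing.assert_array_equal(rank_quantile(v), quantile_rank_oracle(v))

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 5"):
            rank_quantile([1, 2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 200)
        # coarse integers force ties at breakpoints
        v = rng.integers(0, 10, n).astype(float)
        np.testing.assert_array_equal(rank_quantile(v), quantile_rank_oracle(v))

    def test_class_populations_balanced_when_distinct(self):
        rng = np.random.default_rng(3)
        v = rng.permutation(200).astype(float)
        counts = np.bincount(rank_quantile(v), minlength=6)[1:]
        assert all(abs(c - 40) <= 1 for c in counts)


class TestShorelineChangeRank:
    @pytest.mark.parametrize(
        "rate,expected",
        [(3.0, 1), (2.0, 2), (1.5, 2), (1.0, 3), (0.0, 3), (-1.0, 3),
         (-1.5, 4), (-2.0, 4), (-2.5, 5)],
    )
    def test_bins(self, rate, expected):
        assert shoreline_change_rank(rate) == expected

    def test_missing_defaults_to_neutral(self):
        assert shoreline_change_rank(np.nan) == 3

    def test_missing_rank_configurable(self):
        assert shoreline_change_rank(np.nan, missing_rank=5) == 5


class TestHabitatRank:
    def test_coral_within_reach(self):
        layers = [coral(Point(500, 0).buffer(10))]
        assert habitat_rank([[0.0, 0.0]], layers, "S1_all")[0] == 1

    def test_seagrass_only(self):
        layers = [seagrass(Point(300, 0).buffer(10))]
        assert habitat_rank([[0.0, 0.0]], layers, "S1_all")[0] == 4

    def test_scenario_removes_only_habitat(self):
        layers = [coral(Point(500, 0).buffer(10))]
        assert habitat_rank([[0.0, 0.0]], layers, "S2_no_corals")[0] == 5

    def test_most_protective_wins(self):
        layers = [seagrass(Point(300, 0).buffer(10)), mangrove(Point(800, 0).buffer(10))]
        assert habitat_rank([[0.0, 0.0]], layers, "S1_all")[0] == 1

    def test_out_of_reach(self):
        layers = [coral(Point(5000, 0).buffer(10))]
        assert habitat_rank([[0.0, 0.0]], layers, "S1_all")[0] == 5

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            habitat_rank([[0, 0]], [], "S6")


class TestComputeIE:
    @pytest.mark.parametrize(
        "ranks,expected",
        [((1,) * 6, 1.0), ((5,) * 6, 5.0), ((1, 2, 3, 4, 5, 5), 600.0 ** (1 / 6))],
    )
    def test_examples(self, ranks, expected):
        assert compute_ie(ranks) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 1, 1, 1, 1), (1, 1, 1, 1, 1, 6), (1, 1, 1, 1, 1, 2.5)])
    def test_invalid_ranks(self, bad):
        with pytest.raises(ValueError):
            compute_ie(bad)

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(*[st.integers(1, 5)] * 6))
    def test_log_mean_bounds_permutation(self, ranks):
        ie = compute_ie(ranks)
        assert ie == pytest.approx(np.exp(np.mean(np.log(ranks))), abs=1e-12)
        assert min(ranks) - 1e-9 <= ie <= max(ranks) + 1e-9
        for perm in itertools.islice(itertools.permutations(ranks), 5):
            assert compute_ie(perm) == pytest.approx(ie, abs=1e-12)


class TestClassifyIE:
    @pytest.mark.parametrize(
        "ie,cls,lmh", [(1.2, 1, "L"), (3.5, 4, "H"), (3.49, 3, "M"), (2.5, 3, "M"), (4.9, 5, "H")]
    )
    def test_round_rule(self, ie, cls, lmh):
        assert classify_ie(ie) == (cls, lmh)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_ie(0.5)

    def test_quantile_rule_matches_rank_quantile(self):
        rng = np.random.default_rng(0)
        ie = rng.uniform(1, 5, 100)
        cls, _ = classify_ie(ie, rule="quantile")
        np.testing.assert_array_equal(cls, rank_quantile(ie))


def tiny_points(n=6):
    """Minimal attribute table: enough points for quantile ranking."""
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "point_id": range(n),
            "x": np.arange(n) * 1000.0,
            "y": 0.0,
            "spacing_km": 1.0,
            "relief_m": rng.uniform(0.5, 20, n),
            "wave_power": rng.uniform(1, 100, n),
            "wind_exposure": rng.uniform(1, 50, n),
            "shelf_distance_m": rng.uniform(100, 20000, n),
            "shoreline_change_rate": [0.0, np.nan, 1.5, -2.5, np.nan, 3.0],
        }
    )


class TestRunScenarios:
    def test_coral_only_point_scenario_ordering(self):
        pts = tiny_points()
        layers = [coral(Point(0, 500).buffer(10))]  # protects point 0 only
        exp = run_scenarios(pts, layers)
        by = exp[exp["point_id"] == 0].set_index("scenario")
        assert by.loc["S1_all", "r_habitats"] == 1
        assert by.loc["S2_no_corals", "r_habitats"] == 5
        assert by.loc["S5_no_habitats", "r_habitats"] == 5
        assert by.loc["S2_no_corals", "ie"] == by.loc["S5_no_habitats", "ie"]
        assert by.loc["S1_all", "ie"] == by.loc["S3_no_mangrove", "ie"]
        assert by.loc["S1_all", "ie"] == by.loc["S4_no_seagrasses", "ie"]
        assert by.loc["S2_no_corals", "ie"] > by.loc["S1_all", "ie"]

    def test_unprotected_point_identical_across_scenarios(self):
        pts = tiny_points()
        exp = run_scenarios(pts, [])
        ie = exp[exp["point_id"] == 3].set_index("scenario")["ie"]
        assert ie.nunique() == 1

    def test_s5_forces_rank_five(self, region, region_exposure):
        s5 = region_exposure[region_exposure["scenario"] == "S5_no_habitats"]
        assert (s5["r_habitats"] == 5).all()

    def test_scenario_monotonicity(self, region_exposure):
        wide = region_exposure.pivot(index="point_id", columns="scenario", values="ie")
        for scen in SCENARIOS:
            assert (wide["S1_all"] <= wide[scen] + 1e-12).all()
            assert (wide[scen] <= wide["S5_no_habitats"] + 1e-12).all()

    def test_non_habitat_ranks_shared(self, region_exposure):
        for col in ("r_relief", "r_waves", "r_wind", "r_surge", "r_shoreline_change"):
            wide = region_exposure.pivot(index="point_id", columns="scenario", values=col)
            assert (wide.nunique(axis=1) == 1).all()

    def test_unknown_scenario_errors(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenarios(tiny_points(), [], scenarios=["S9"])
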