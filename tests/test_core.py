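"""Surplus decomposition, yield aggregation, land conversion."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietfootprint as dfp
from dietfootprint.core import (
    apportion_pasture,
    combined_group_yield,
    decompose_surplus,
    import_dependency_ratio,
    land_spared,
    livestock_yield,
    world_average_yield,
)
from dietfootprint.records import (
    GroupSupply,
    GroupYield,
    RequirementRecord,
    SurplusDecomposition,
)


def gs(x, y, country="A", year=2010, group="grains"):
    return GroupSupply(country=country, year=year, food_group=group, x=x, y=y)


def req(z, country="A", year=2010, group="grains"):
    return RequirementRecord(country=country, year=year, food_group=group, required_mass=z)


def gy(value, scope="A", group="grains", basis="crop_area"):
    return GroupYield(scope=scope, year=2010, food_group=group, tonnes_per_ha=value, basis=basis)


class TestImportDependencyRatio:
    @pytest.mark.parametrize("x,y,expected", [(75, 25, 0.25), (0, 40, 1.0), (0, 0, 0.0)])
    def test_supply_share(self, x, y, expected):
        assert import_dependency_ratio(x, y) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            import_dependency_ratio(-1, 5)

    def test_literal_convention_clamped(self):
        # Y/X exceeds 1 for import-dominated supplies; clamp keeps r in [0,1]
        assert import_dependency_ratio(10, 25, convention="domestic_supply") == 1.0
        assert import_dependency_ratio(10, 25, clamp=False, convention="domestic_supply") == 2.5
        assert import_dependency_ratio(100, 25, convention="domestic_supply") == 0.25


class TestDecomposeSurplus:
    def test_surplus_split(self):
        dec = decompose_surplus(gs(75, 25), req(90))
        assert (dec.s, dec.r, dec.s_d, dec.s_i) == (10.0, 0.25, 7.5, 2.5)

    def test_exact_guideline_zero(self):
        dec = decompose_surplus(gs(75, 25), req(100))
        assert (dec.s, dec.s_d, dec.s_i) == (0.0, 0.0, 0.0)

    def test_deficit_split_by_same_ratio(self):
        dec = decompose_surplus(gs(75, 25), req(140))
        assert (dec.s, dec.s_d, dec.s_i) == (-40.0, -30.0, -10.0)
        assert dec.s_d + dec.s_i == dec.s

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            decompose_surplus(gs(75, 25), req(90, country="B"))

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(min_value=0, max_value=1e12),
        y=st.floats(min_value=0, max_value=1e12),
        z=st.floats(min_value=0, max_value=1e12),
    )
    def test_conservation_to_the_last_bit(self, x, y, z):
        dec = decompose_surplus(gs(x, y), req(z))
        assert 0.0 <= dec.r <= 1.0
        assert dec.s == x + y - z
        scale = max(abs(dec.s), 1.0)
        assert abs((dec.s_d + dec.s_i) - dec.s) <= 1e-12 * scale


class TestYields:
    def prod(self, rows):
        return pd.DataFrame(rows, columns=["country", "year", "commodity", "production", "area"])

    def cfg(self):
        cfg = dfp.default_config()
        cfg.group_map = {"W": "grains", "R": "grains"}
        cfg.validate()
        return cfg

    def test_area_weighted_aggregate(self):
        prod = self.prod([("A", 2010, "W", 300.0, 100.0), ("A", 2010, "R", 100.0, 100.0)])
        y = combined_group_yield(prod, "A", 2010, "grains", self.cfg())
        assert y.tonnes_per_ha == 2.0  # 400/200, equals naive mean only with equal areas

    def test_area_weighting_differs_from_naive_mean(self):
        prod = self.prod([("A", 2010, "W", 300.0, 50.0), ("A", 2010, "R", 100.0, 100.0)])
        y = combined_group_yield(prod, "A", 2010, "grains", self.cfg())
        assert math.isclose(y.tonnes_per_ha, 400.0 / 150.0)
        naive = (300.0 / 50.0 + 100.0 / 100.0) / 2
        assert y.tonnes_per_ha != naive

    def test_single_commodity(self):
        prod = self.prod([("A", 2010, "W", 300.0, 100.0)])
        assert combined_group_yield(prod, "A", 2010, "grains", self.cfg()).tonnes_per_ha == 3.0

    def test_all_zero_area_is_absent(self):
        prod = self.prod([("A", 2010, "W", 300.0, 0.0)])
        assert combined_group_yield(prod, "A", 2010, "grains", self.cfg()) is None

    def test_world_average(self):
        prod = self.prod([("A", 2010, "W", 300.0, 100.0), ("B", 2010, "W", 100.0, 100.0)])
        assert world_average_yield(prod, 2010, "grains", self.cfg()).tonnes_per_ha == 2.0

    def test_world_equals_single_country(self):
        prod = self.prod([("A", 2010, "W", 300.0, 100.0)])
        w = world_average_yield(prod, 2010, "grains", self.cfg())
        c = combined_group_yield(prod, "A", 2010, "grains", self.cfg())
        assert w.tonnes_per_ha == c.tonnes_per_ha

    @settings(derandomize=True, max_examples=30)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=1, max_value=1e6),
                st.floats(min_value=1, max_value=1e5),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_world_yield_between_country_extremes(self, data):
        prod = self.prod(
            [(f"C{i}", 2010, "W", p, a) for i, (p, a) in enumerate(data)]
        )
        cfg = self.cfg()
        w = world_average_yield(prod, 2010, "grains", cfg).tonnes_per_ha
        per_country = [p / a for p, a in data]
        assert min(per_country) <= w * (1 + 1e-12) and w <= max(per_country) * (1 + 1e-12)


class TestLivestockYield:
    def test_production_per_hectare(self):
        assert livestock_yield(500.0, 1000.0).tonnes_per_ha == 0.5

    def test_zero_production_absent(self):
        assert livestock_yield(0.0, 1000.0) is None

    def test_nonpositive_land_absent(self):
        assert livestock_yield(500.0, 0.0) is None

    def test_doubling_land_halves_yield(self):
        a = livestock_yield(500.0, 1000.0).tonnes_per_ha
        b = livestock_yield(500.0, 2000.0).tonnes_per_ha
        assert math.isclose(a, 2 * b)

    def test_pasture_apportioned_by_production_share(self):
        shares = apportion_pasture(1000.0, {"Beef": 300.0, "Milk": 100.0})
        assert shares == {"Beef": 750.0, "Milk": 250.0}
        assert sum(shares.values()) == 1000.0


def dec_from(x, y, z):
    return decompose_surplus(gs(x, y), req(z))


class TestLandSpared:
    def test_hand_example(self):
        # S_d=7.5 at 3 t/ha plus S_i=2.5 at 2.5 t/ha -> 2.5 + 1.0 = 3.5 ha spared
        res = land_spared(dec_from(75, 25, 90), gy(3.0), gy(2.5, scope="world"))
        assert (res.land_domestic, res.land_displaced, res.land_total) == (2.5, 1.0, 3.5)

    def test_zero_surplus_zero_land(self):
        res = land_spared(dec_from(75, 25, 100), gy(3.0), gy(2.5, scope="world"))
        assert (res.land_domestic, res.land_displaced, res.land_total) == (0.0, 0.0, 0.0)

    def test_deficit_is_negative_land(self):
        # a deficit means land is required: sign convention of the results
        res = land_spared(dec_from(75, 25, 140), gy(3.0), gy(2.5, scope="world"))
        assert res.land_domestic == -10.0
        assert res.land_total < 0

    def test_sign_matches_surplus_parts(self):
        dec = dec_from(10, 90, 140)
        res = land_spared(dec, gy(3.0), gy(2.5, scope="world"))
        assert math.copysign(1, res.land_domestic) == math.copysign(1, dec.s_d)
        assert math.copysign(1, res.land_displaced) == math.copysign(1, dec.s_i)

    def test_missing_domestic_yield_falls_back_to_world(self):
        res = land_spared(dec_from(75, 25, 90), None, gy(2.5, scope="world"))
        assert math.isclose(res.land_domestic, 7.5 / 2.5)

    def test_both_yields_absent_omits_cell(self):
        assert land_spared(dec_from(75, 25, 90), None, None) is None

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(min_value=0.1, max_value=100))
    def test_scaling_yields_inversely_scales_land(self, k):
        base = land_spared(dec_from(75, 25, 140), gy(3.0), gy(2.5, scope="world"))
        scaled = land_spared(dec_from(75, 25, 140), gy(3.0 * k), gy(2.5 * k, scope="world"))
        assert math.isclose(scaled.land_total, base.land_total / k, rel_tol=1e-12)

    def test_more_people_never_spares_more_land(self, config, population_1m):
        # holding supply and yields fixed, land_total is non-increasing in
        # population (more mouths -> larger Z -> smaller surplus)
        totals = []
        for persons in (10**5, 10**6, 10**7):
            pop = pd.DataFrame({"country": ["A"], "year": [2010], "persons": [persons]})
            z = dfp.annual_requirement("grains", 2000, "A", 2010, pop, config).required_mass
            res = land_spared(dec_from(7e4, 3e4, z), gy(3.0), gy(2.5, scope="world"))
            totals.append(res.land_total)
        assert totals == sorted(totals, reverse=True)


def test_pipeline_uses_pasture_proxy_for_livestock_groups(config):
    """With a pasture table, livestock groups convert at production/pasture."""
    cfg = dfp.default_config()
    cfg.group_map = {"Beef": "meat_beans", "Wheat": "grains"}
    cfg.validate()
    fbs = pd.DataFrame(
        [
            ("A", 2010, "Beef", "domestic_supply", 500.0),
            ("A", 2010, "Beef", "import_quantity", 0.0),
            ("A", 2010, "Wheat", "domestic_supply", 1000.0),
            ("A", 2010, "Wheat", "import_quantity", 0.0),
        ],
        columns=["country", "year", "commodity", "element", "value"],
    )
    production = pd.DataFrame(
        [("A", 2010, "Beef", 500.0, 0.0), ("A", 2010, "Wheat", 1000.0, 250.0)],
        columns=["country", "year", "commodity", "production", "area"],
    )
    population = pd.DataFrame({"country": ["A"], "year": [2010], "persons": [1000]})
    pasture = pd.DataFrame({"country": ["A"], "year": [2010], "pasture_ha": [2000.0]})
    out = dfp.compute_land_footprint(fbs, production, population, cfg, pasture=pasture)
    by_group = {r.food_group: r for r in out.land_results}
    meat = next(d for d in out.decompositions if d.food_group == "meat_beans")
    # livestock yield = 500 t / 2000 ha = 0.25 t/ha
    assert math.isclose(by_group["meat_beans"].land_domestic, meat.s_d / 0.25)
    grains = next(d for d in out.decompositions if d.food_group == "grains")
    assert math.isclose(by_group["grains"].land_domestic, grains.s_d / 4.0)
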