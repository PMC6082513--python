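"""Roll-up additivity, trade-discrepancy diagnostic, map export."""

import math

import pandas as pd
import pytest

import dietfootprint as dfp
from dietfootprint.aggregate import ALL_GROUPS, export_map_values, rollup, trade_discrepancy
from dietfootprint.records import LandResult

from conftest import run_world


def lr(country, group, dom, disp, year=2010):
    return LandResult(country=country, year=year, food_group=group, land_domestic=dom, land_displaced=disp)


CONTINENTS = {"A": "Oceania", "B": "Oceania", "C": "Asia"}


class TestRollup:
    def test_continent_sums_countries(self):
        results = [lr("A", "grains", 4.0, 1.0), lr("B", "grains", -6.0, -2.0)]
        series = rollup(results, "continent", CONTINENTS)
        oceania = next(s for s in series if s.scope_name == "Oceania" and s.food_group == "grains")
        assert oceania.total(2010) == -3.0
        assert oceania.domestic(2010) == -2.0

    def test_single_country_world_degenerate(self):
        results = [lr("A", "grains", 4.0, 1.0)]
        world = rollup(results, "world")
        country = rollup(results, "country")
        for group in ("grains", ALL_GROUPS):
            w = next(s for s in world if s.food_group == group)
            c = next(s for s in country if s.food_group == group)
            assert w.series == c.series

    def test_groups_sum_to_all_groups(self):
        results = [
            lr("A", "grains", 4.0, 1.0),
            lr("A", "fruit", -2.0, 0.5),
            lr("A", "milk", 1.0, -0.25),
        ]
        series = rollup(results, "country")
        allg = next(s for s in series if s.food_group == ALL_GROUPS)
        per_group = [s for s in series if s.food_group != ALL_GROUPS]
        assert math.isclose(allg.total(2010), sum(s.total(2010) for s in per_group))
        assert math.isclose(allg.domestic(2010), sum(s.domestic(2010) for s in per_group))

    def test_missing_continent_mapping_is_hard_error(self):
        with pytest.raises(ValueError, match="'D'"):
            rollup([lr("D", "grains", 1.0, 0.0)], "continent", CONTINENTS)

    def test_chain_exact_on_synthetic_world(self):
        params = dfp.SynthParams(seed=11)
        world = dfp.generate_world(
            dfp.SynthParams(seed=11, diet_skew=dfp.random_diet_skew(params))
        )
        results = run_world(world).land_results
        cmap = world.config.continent_map
        for year in world.years:
            country_sum = sum(
                s.total(year) for s in rollup(results, "country") if s.food_group == ALL_GROUPS
            )
            continent_sum = sum(
                s.total(year)
                for s in rollup(results, "continent", cmap)
                if s.food_group == ALL_GROUPS
            )
            world_all = next(
                s for s in rollup(results, "world") if s.food_group == ALL_GROUPS
            )
            assert math.isclose(country_sum, continent_sum, rel_tol=1e-12)
            assert math.isclose(continent_sum, world_all.total(year), rel_tol=1e-12)


class TestTradeDiscrepancy:
    def world_series(self, results):
        return next(s for s in rollup(results, "world") if s.food_group == ALL_GROUPS)

    def test_zero_on_balanced_at_guideline_world(self):
        world = dfp.generate_world(dfp.SynthParams(seed=4))
        series = self.world_series(world.expected)
        assert all(trade_discrepancy(series, y) == 0.0 for y in world.years)

    def test_positive_under_injected_imbalance(self):
        world = dfp.generate_world(
            dfp.SynthParams(seed=4, balanced_trade=False, discrepancy_injection=0.2)
        )
        series = self.world_series(run_world(world).land_results)
        assert all(trade_discrepancy(series, y) > 0 for y in world.years)

    def test_invariant_to_country_relabeling(self):
        results = [lr("A", "grains", 4.0, 1.0), lr("B", "grains", -1.0, 2.0)]
        relabeled = [lr("Zz" + r.country, r.food_group, r.land_domestic, r.land_displaced) for r in results]
        a = trade_discrepancy(self.world_series(results), 2010)
        b = trade_discrepancy(self.world_series(relabeled), 2010)
        assert a == b

    def test_requires_world_all_groups_series(self):
        series = rollup([lr("A", "grains", 1.0, 0.0)], "country")
        with pytest.raises(ValueError, match="world-scope"):
            trade_discrepancy(series[0], 2010)

    def test_missing_year_is_hard_error(self):
        series = self.world_series([lr("A", "grains", 1.0, 0.0)])
        with pytest.raises(ValueError, match="1999"):
            trade_discrepancy(series, 1999)


class TestMapExport:
    def test_values_in_millions_of_hectares(self, tmp_path):
        path = tmp_path / "map.csv"
        export_map_values([lr("A", "grains", 2_000_000.0, 500_000.0)], 2010, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["country", "land_total_MHa"]
        assert df["land_total_MHa"].iloc[0] == 2.5

    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "map.csv"
        export_map_values([], 2010, path)
        df = pd.read_csv(path)
        assert len(df) == 0 and "land_total_MHa" in df.columns

    def test_missing_year_is_hard_error(self, tmp_path):
        with pytest.raises(ValueError, match="2011"):
            export_map_values([lr("A", "grains", 1.0, 0.0)], 2011, tmp_path / "m.csv")

    def test_round_trip_preserves_values(self, tmp_path):
        path = tmp_path / "map.csv"
        export_map_values(
            [lr("A", "grains", 123_456.789, 0.0), lr("A", "fruit", -23_456.789, 1.0)],
            2010,
            path,
        )
        df = pd.read_csv(path)
        assert math.isclose(df["land_total_MHa"].iloc[0], (123_456.789 - 23_456.789 + 1.0) / 1e6)
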