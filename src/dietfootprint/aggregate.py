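"""Roll-ups to continent and world, time series, and map-value export.

Aggregation is plain addition of hectares, so the country -> continent ->
world chain is exact each year. The world-level gap between the
domestic-only series and the total (domestic + displaced) series is a data
quality diagnostic: displaced land is backed by somebody's exports, so at
the aggregated world level the two series should coincide when trade
reporting is consistent and surpluses balance; reporting inconsistencies
(e.g. over- or under-reported imports) open a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import land_results_frame
from .records import LandResult

ALL_GROUPS = "all_groups"
_LEVELS = ("country", "continent", "world")


@dataclass
class AggregateSeries:
    """Per-year (domestic, total) hectare sums for one scope and group."""

    scope: str  # "country" | "continent" | "world"
    scope_name: str
    food_group: str  # a food group or "all_groups"
    series: dict[int, tuple[float, float]] = field(default_factory=dict)

    def domestic(self, year: int) -> float:
        return self.series[year][0]

    def total(self, year: int) -> float:
        return self.series[year][1]

    @property
    def years(self) -> list[int]:
        return sorted(self.series)


def rollup(
    results: Iterable[LandResult],
    level: str,
    continent_map: Mapping[str, str] | None = None,
) -> list[AggregateSeries]:
    """Sum land results by scope and year, per group plus ``all_groups``.

    ``level`` is "country", "continent" or "world". At continent level
    every country must appear in ``continent_map`` (hard error naming the
    offender — silent drops would corrupt the roll-up).
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}, got {level!r}")
    df = land_results_frame(results)
    if level == "continent":
        if continent_map is None:
            raise ValueError("continent-level rollup needs a continent_map")
        unmapped = sorted(set(df["country"]) - set(continent_map))
        if unmapped:
            raise ValueError(f"country {unmapped[0]!r} missing from continent_map")
        df["scope_name"] = df["country"].map(dict(continent_map))
    elif level == "world":
        df["scope_name"] = "world"
    else:
        df["scope_name"] = df["country"]

    out: dict[tuple[str, str], AggregateSeries] = {}

    def _accumulate(frame: pd.DataFrame, group_label: str) -> None:
        sums = frame.groupby(["scope_name", "year"])[
            ["land_domestic_ha", "land_total_ha"]
        ].sum()
        for (name, year), row in sums.iterrows():
            series = out.setdefault(
                (name, group_label),
                AggregateSeries(scope=level, scope_name=name, food_group=group_label),
            )
            series.series[int(year)] = (
                float(row["land_domestic_ha"]),
                float(row["land_total_ha"]),
            )

    for group, chunk in df.groupby("food_group"):
        _accumulate(chunk, str(group))
    _accumulate(df, ALL_GROUPS)
    return [out[key] for key in sorted(out)]


def trade_discrepancy(series: AggregateSeries, year: int, eps: float = 1.0) -> float:
    """Relative gap between total and domestic-only world land in a year.

    ``|total - domestic| / max(|total|, eps)`` for the world-scope
    ``all_groups`` series. Zero on a world whose trade reporting is
    internally consistent and whose surpluses vanish; strictly positive
    when import misreporting is injected. ``eps`` is a one-hectare floor on
    the denominator: totals below it mean a zero-land world, where the gap
    is reported relative to a hectare rather than to rounding noise.
    """
    if series.scope != "world" or series.food_group != ALL_GROUPS:
        raise ValueError(
            "trade_discrepancy expects the world-scope all_groups series, got "
            f"scope={series.scope!r}, food_group={series.food_group!r}"
        )
    if year not in series.series:
        raise ValueError(f"year {year} absent from series (have {series.years})")
    domestic, total = series.series[year]
    return abs(total - domestic) / max(abs(total), eps)


def export_map_values(
    results: Iterable[LandResult], year: int, path: str | Path
) -> None:
    """Write per-country total land for one year, in millions of hectares.

    The CSV (``country, land_total_MHa``) joins onto any country-boundary
    dataset for choropleth rendering; rendering itself is out of scope.
    """
    df = land_results_frame(results)
    have_years = set(df["year"])
    if not df.empty and year not in have_years:
        raise ValueError(f"year {year} absent from results (have {sorted(have_years)})")
    sub = df[df["year"] == year]
    values = (
        sub.groupby("country")["land_total_ha"].sum().divide(1e6).rename("land_total_MHa")
    )
    values.reset_index().to_csv(path, index=False)


def series_frame(series_list: Iterable[AggregateSeries]) -> pd.DataFrame:
    """Tidy frame of aggregate series (scope, name, group, year, ha sums)."""
    rows = [
        (s.scope, s.scope_name, s.food_group, year, dom, tot)
        for s in series_list
        for year, (dom, tot) in sorted(s.series.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["scope", "scope_name", "food_group", "year", "land_domestic_ha", "land_total_ha"],
    )


def write_series(series_list: Iterable[AggregateSeries], path: str | Path) -> None:
    series_frame(series_list).to_csv(path, index=False)
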