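"""Surplus decomposition, yield aggregation and land conversion.

This is the accounting core. For each country, year and food group:

* supply is X (domestic) + Y (imported) primary-equivalent tonnes;
* the guideline requirement is Z tonnes;
* the surplus is ``S = X + Y - Z`` (negative S is a deficit);
* S splits by the import dependency ratio r into a domestic part
  ``S_d = S*(1-r)`` and a displaced part ``S_i = S*r`` — the land a
  country's diet occupies abroad through imports;
* land spared is ``S_d / y_dom + S_i / y_world`` where ``y_dom`` is the
  country's combined group yield (total production over total harvested
  area across the group's commodities) and ``y_world`` the world-average
  combined yield. Positive hectares = spared, negative = required.

Deficits split by the same r: guidelines may be met both by expanding
domestic production and by importing more, and proportional attribution is
the minimal assumption. All functions here are pure (no file access).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import Config
from .guidelines import GuidelineTable, annual_requirement, packaged_guidelines
from .mapping import group_supply
from .records import (
    GroupSupply,
    GroupYield,
    LandResult,
    RequirementRecord,
    SurplusDecomposition,
)

logger = logging.getLogger(__name__)


def import_dependency_ratio(
    x: float,
    y: float,
    clamp: bool = True,
    convention: str = "import_free",
) -> float:
    """Fraction of supply sourced abroad.

    Under the default convention (X excludes imports, so X + Y is the
    domestic supply) r = Y / (X + Y), which lies in [0, 1] by construction
    and equals imports over domestic supply. Under the literal
    "domestic_supply" convention r = Y / X; values outside [0, 1] are
    clamped (logged) when ``clamp`` is set. X + Y = 0 gives r = 0 by
    convention: there is nothing to attribute.
    """
    if x < 0 or y < 0:
        raise ValueError(f"supplies must be non-negative, got X={x}, Y={y}")
    if convention == "import_free":
        total = x + y
        r = y / total if total > 0 else 0.0
    elif convention == "domestic_supply":
        if x > 0:
            r = y / x
        else:
            r = 1.0 if y > 0 else 0.0
    else:
        raise ValueError(f"unknown ratio convention {convention!r}")
    if clamp and not 0.0 <= r <= 1.0:
        clamped = min(max(r, 0.0), 1.0)
        logger.warning("import dependency ratio %.4f clamped to %.1f", r, clamped)
        r = clamped
    return r


def decompose_surplus(
    gs: GroupSupply,
    req: RequirementRecord,
    clamp: bool = True,
    convention: str = "import_free",
) -> SurplusDecomposition:
    """Split the surplus S = X + Y - Z into domestic and displaced parts.

    ``S_i`` is computed as ``S - S_d`` so the split conserves S to the last
    bit. ``gs`` and ``req`` must agree on (country, year, food_group).
    """
    if (gs.country, gs.year, gs.food_group) != (req.country, req.year, req.food_group):
        raise ValueError(
            f"mismatched keys: supply {(gs.country, gs.year, gs.food_group)} vs "
            f"requirement {(req.country, req.year, req.food_group)}"
        )
    s = gs.x + gs.y - req.required_mass
    r = import_dependency_ratio(gs.x, gs.y, clamp=clamp, convention=convention)
    s_d = s * (1.0 - r)
    s_i = s - s_d
    return SurplusDecomposition(
        country=gs.country,
        year=gs.year,
        food_group=gs.food_group,
        x=gs.x,
        y=gs.y,
        z=req.required_mass,
        s=s,
        r=r,
        s_d=s_d,
        s_i=s_i,
    )


def _aggregate_yield(
    rows: pd.DataFrame, scope: str, year: int, food_group: str, basis: str = "crop_area"
) -> GroupYield | None:
    usable = rows[rows["area"] > 0]
    if usable.empty:
        return None
    area = float(usable["area"].sum())
    production = float(usable["production"].sum())
    if not production > 0:
        return None
    return GroupYield(
        scope=scope,
        year=year,
        food_group=food_group,
        tonnes_per_ha=production / area,
        basis=basis,
    )


def _member_rows(
    production: pd.DataFrame, year: int, food_group: str, config: Config
) -> pd.DataFrame:
    members = [c for c, g in config.group_map.items() if g == food_group]
    return production[
        (production["year"] == year) & production["commodity"].isin(members)
    ]


def combined_group_yield(
    production: pd.DataFrame,
    country: str,
    year: int,
    food_group: str,
    config: Config,
) -> GroupYield | None:
    """Country-level combined yield: total production over total area.

    The area-weighted aggregate, not the mean of per-commodity yields —
    it is exactly the quantity land conversion needs. ``None`` when no
    member commodity has positive area (absence, never zero).
    """
    rows = _member_rows(production, year, food_group, config)
    rows = rows[rows["country"] == country]
    return _aggregate_yield(rows, country, year, food_group)


def world_average_yield(
    production: pd.DataFrame, year: int, food_group: str, config: Config
) -> GroupYield | None:
    """World combined yield: sums over all countries."""
    rows = _member_rows(production, year, food_group, config)
    return _aggregate_yield(rows, "world", year, food_group)


def livestock_yield(
    production: float,
    land: float,
    scope: str = "",
    year: int = 0,
    food_group: str = "",
) -> GroupYield | None:
    """Livestock-product yield as production per hectare of land.

    ``None`` (with a warning) when the land denominator or production is
    not positive — an absent yield, never a zero.
    """
    if not land > 0:
        logger.warning(
            "livestock yield unavailable for (%s, %s, %s): land %s <= 0",
            scope, year, food_group, land,
        )
        return None
    if not production > 0:
        logger.warning(
            "livestock yield unavailable for (%s, %s, %s): no production",
            scope, year, food_group,
        )
        return None
    return GroupYield(
        scope=scope,
        year=year,
        food_group=food_group,
        tonnes_per_ha=production / land,
        basis="livestock_area",
    )


def apportion_pasture(
    pasture_ha: float, production_by_commodity: dict[str, float]
) -> dict[str, float]:
    """Split national pasture area over livestock commodities by production share."""
    if pasture_ha < 0:
        raise ValueError(f"pasture_ha must be non-negative, got {pasture_ha}")
    total = sum(production_by_commodity.values())
    if total <= 0:
        return {c: 0.0 for c in production_by_commodity}
    return {c: pasture_ha * p / total for c, p in production_by_commodity.items()}


def land_spared(
    dec: SurplusDecomposition,
    y_dom: GroupYield | None,
    y_world: GroupYield | None,
) -> LandResult | None:
    """Convert a surplus decomposition to hectares spared or required.

    The domestic part converts at the country's own yield, the displaced
    part at the world-average yield. A missing domestic yield falls back to
    the world yield (logged); if both are absent the result is ``None`` and
    the caller must omit the cell (never a silent zero).
    """
    if y_dom is None and y_world is None:
        logger.warning(
            "no yield available for (%s, %s, %s); cell omitted",
            dec.country, dec.year, dec.food_group,
        )
        return None
    if y_dom is None:
        logger.info(
            "domestic yield missing for (%s, %s, %s); using world-average yield",
            dec.country, dec.year, dec.food_group,
        )
        y_dom = y_world
    if y_world is None:
        y_world = y_dom
    assert y_dom is not None and y_world is not None
    return LandResult(
        country=dec.country,
        year=dec.year,
        food_group=dec.food_group,
        land_domestic=dec.s_d / y_dom.tonnes_per_ha,
        land_displaced=dec.s_i / y_world.tonnes_per_ha,
    )


def _crop_group_yields(
    production: pd.DataFrame, config: Config
) -> dict[tuple[str, int, str], GroupYield]:
    """Combined crop-area yields for every (country|world, year, group) at once.

    Same arithmetic as :func:`combined_group_yield` / :func:`world_average_yield`
    (total production over total usable area), computed with two groupbys so
    the pipeline does not rescan the production table per cell.
    """
    rows = production[production["commodity"].isin(config.group_map)].copy()
    rows = rows[rows["area"] > 0]
    out: dict[tuple[str, int, str], GroupYield] = {}
    if rows.empty:
        return out
    rows["food_group"] = rows["commodity"].map(config.group_map)
    national = rows.groupby(["country", "year", "food_group"])[["production", "area"]].sum()
    for (country, year, group), row in national.iterrows():
        if row["production"] > 0:
            out[(country, int(year), group)] = GroupYield(
                scope=country,
                year=int(year),
                food_group=group,
                tonnes_per_ha=float(row["production"] / row["area"]),
            )
    world = rows.groupby(["year", "food_group"])[["production", "area"]].sum()
    for (year, group), row in world.iterrows():
        if row["production"] > 0:
            out[("world", int(year), group)] = GroupYield(
                scope="world",
                year=int(year),
                food_group=group,
                tonnes_per_ha=float(row["production"] / row["area"]),
            )
    return out


@dataclass
class FootprintResult:
    """End-to-end pipeline output plus audit diagnostics."""

    land_results: list[LandResult]
    decompositions: list[SurplusDecomposition]
    omitted: list[tuple[str, int, str]] = field(default_factory=list)


def _livestock_group_yields(
    production: pd.DataFrame,
    pasture: pd.DataFrame,
    config: Config,
) -> dict[tuple[str, int, str], GroupYield]:
    """Pasture-proxy yields for livestock groups, per country/year and world.

    National pasture is apportioned to livestock commodities by production
    share; a group's land is the sum over its member commodities, which
    makes the group yield equal total livestock production over pasture.
    """
    out: dict[tuple[str, int, str], GroupYield] = {}
    livestock_groups = set(config.livestock_land.groups)
    commodities = {c for c, g in config.group_map.items() if g in livestock_groups}
    rows = production[production["commodity"].isin(commodities)].copy()
    if rows.empty:
        return out
    rows["food_group"] = rows["commodity"].map(config.group_map)

    pasture_idx = pasture.set_index(["country", "year"])["pasture_ha"]
    world_prod: dict[tuple[int, str], float] = {}
    world_land: dict[tuple[int, str], float] = {}
    for (country, year), chunk in rows.groupby(["country", "year"]):
        try:
            p_ha = float(pasture_idx.loc[(country, int(year))])
        except KeyError:
            continue
        shares = apportion_pasture(
            p_ha, dict(zip(chunk["commodity"], chunk["production"]))
        )
        chunk = chunk.assign(land=chunk["commodity"].map(shares))
        for group, grp in chunk.groupby("food_group"):
            prod = float(grp["production"].sum())
            land = float(grp["land"].sum())
            gy = livestock_yield(prod, land, scope=country, year=int(year), food_group=group)
            if gy is not None:
                out[(country, int(year), group)] = gy
            world_prod[(int(year), group)] = world_prod.get((int(year), group), 0.0) + prod
            world_land[(int(year), group)] = world_land.get((int(year), group), 0.0) + land
    for (year, group), prod in world_prod.items():
        gy = livestock_yield(prod, world_land[(year, group)], scope="world", year=year, food_group=group)
        if gy is not None:
            out[("world", year, group)] = gy
    return out


def compute_land_footprint(
    fbs: pd.DataFrame,
    production: pd.DataFrame,
    population: pd.DataFrame,
    config: Config,
    years: list[int] | None = None,
    pasture: pd.DataFrame | None = None,
    guideline_table: GuidelineTable | None = None,
) -> FootprintResult:
    """Run the full accounting chain for every country/year/group.

    Countries are those present in the food balance sheet; each must have a
    population entry for every processed year (hard error otherwise —
    silent drops would corrupt rollups). Groups are those named in
    ``config.group_map``; a group with a requirement but no supply records
    enters with X = Y = 0 (a pure deficit). Livestock groups use
    pasture-proxy yields when a pasture table is supplied and the policy
    asks for it; otherwise the crop-area route serves all groups.
    """
    table = guideline_table or packaged_guidelines()
    supplies = {
        (gs.country, gs.year, gs.food_group): gs for gs in group_supply(fbs, config)
    }
    all_years = sorted(set(fbs["year"])) if years is None else sorted(years)
    countries = sorted(set(fbs["country"]))
    groups = config.groups

    livestock: dict[tuple[str, int, str], GroupYield] = {}
    if pasture is not None and config.livestock_land.policy == "pasture_proxy":
        livestock = _livestock_group_yields(production, pasture, config)
    crop_yields = _crop_group_yields(production, config)

    world_yields: dict[tuple[int, str], GroupYield | None] = {}
    for year in all_years:
        for group in groups:
            gy = livestock.get(("world", year, group))
            world_yields[(year, group)] = gy or crop_yields.get(("world", year, group))

    results: list[LandResult] = []
    decomps: list[SurplusDecomposition] = []
    omitted: list[tuple[str, int, str]] = []
    for country in countries:
        for year in all_years:
            for group in groups:
                gs = supplies.get(
                    (country, year, group),
                    GroupSupply(country=country, year=year, food_group=group, x=0.0, y=0.0),
                )
                req = annual_requirement(
                    group, config.calorie_level, country, year, population, config, table
                )
                dec = decompose_surplus(
                    gs, req, clamp=config.ratio_clamp, convention=config.supply_convention
                )
                decomps.append(dec)
                y_dom = livestock.get((country, year, group)) or crop_yields.get(
                    (country, year, group)
                )
                res = land_spared(dec, y_dom, world_yields[(year, group)])
                if res is None:
                    omitted.append((country, year, group))
                else:
                    results.append(res)
    if omitted:
        logger.warning(
            "compute_land_footprint: omitted %d cell(s) with no usable yield", len(omitted)
        )
    return FootprintResult(land_results=results, decompositions=decomps, omitted=omitted)
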