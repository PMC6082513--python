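"""Generate internally consistent FAOSTAT-like worlds with known answers.

The generator builds a small world of placeholder countries and
commodities in which every quantity is constructed, not observed: each
country's primary-equivalent supply of each food group equals
``diet_skew x guideline requirement`` (so skew 1.0 means exactly at
guideline and zero surplus), a fixed fraction of each supply is booked as
imports matched by exports elsewhere (a ring: country i imports from
country i+1, which balances world trade exactly), and yields are uniform
draws that fix harvested areas. Because X, Y, Z and all yields are known
in closed form, the expected land results follow by direct substitution
into S = X + Y - Z, S_d = S(1-r), S_i = S r, land = S/yield — an
arithmetic path deliberately independent of the pipeline's code, usable
as an oracle for every stage.

Misreported trade can be injected: with ``balanced_trade=False`` the
import rows (and the domestic-supply identity built on them) are inflated
by ``discrepancy_injection`` while exports stay truthful, which opens a
world-level gap between domestic-only and total land series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import Config, default_config
from .guidelines import packaged_guidelines
from .io import write_land_results
from .records import DISCRETIONARY, LAND_GROUPS, LandResult

#: continent panels used for generated countries, round-robin
_PANELS = (
    "Asia",
    "Africa",
    "European Union",
    "Eastern Europe",
    "South America",
    "North America",
    "Oceania",
)


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic world; defaults are an at-guideline world."""

    n_countries: int = 5
    n_commodities: int = 8
    n_years: int = 3
    seed: int = 0
    diet_skew: Mapping[tuple[str, str], float] = field(default_factory=dict)
    trade_intensity: float = 0.25
    balanced_trade: bool = True
    yield_range: tuple[float, float] = (1.0, 10.0)
    population_range: tuple[int, int] = (100_000, 50_000_000)
    discrepancy_injection: float = 0.0
    calorie_level: int = 2000
    start_year: int = 2008

    def validate(self) -> None:
        if min(self.n_countries, self.n_commodities, self.n_years) < 1:
            raise ValueError("n_countries, n_commodities and n_years must be >= 1")
        if not 0.0 <= self.trade_intensity < 1.0:
            raise ValueError(
                f"trade_intensity must be in [0, 1), got {self.trade_intensity}"
            )
        lo, hi = self.yield_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid yield_range {self.yield_range}")
        plo, phi = self.population_range
        if not 0 < plo <= phi:
            raise ValueError(f"invalid population_range {self.population_range}")
        for key, mult in self.diet_skew.items():
            if mult < 0:
                raise ValueError(f"diet_skew{key} must be >= 0, got {mult}")
        if self.discrepancy_injection < 0:
            raise ValueError("discrepancy_injection must be >= 0")
        if self.balanced_trade and self.discrepancy_injection:
            raise ValueError(
                "discrepancy_injection applies only when balanced_trade is False"
            )


@dataclass
class SyntheticWorld:
    """A generated dataset plus its closed-form expected land results."""

    params: SynthParams
    fbs: pd.DataFrame
    production: pd.DataFrame
    population: pd.DataFrame
    config: Config
    expected: list[LandResult]
    #: closed-form ground truth: per-cell (X, Y, Z) and aggregate yields
    truth: dict = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(set(self.population["year"]))

    @property
    def countries(self) -> list[str]:
        return sorted(set(self.population["country"]))


def _country_names(n: int) -> list[str]:
    return [f"C{i:02d}" for i in range(n)]


def _commodity_names(n: int) -> list[str]:
    return [f"ITEM{j:02d}" for j in range(n)]


def generate_world(params: SynthParams) -> SyntheticWorld:
    """Build a deterministic synthetic world for the given parameters."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    countries = _country_names(params.n_countries)
    commodities = _commodity_names(params.n_commodities)
    years = [params.start_year + i for i in range(params.n_years)]
    group_of = {
        item: LAND_GROUPS[j % len(LAND_GROUPS)] for j, item in enumerate(commodities)
    }
    members: dict[str, list[str]] = {}
    for item, group in group_of.items():
        members.setdefault(group, []).append(item)

    # All random draws happen up front, independent of the skew map, so two
    # worlds differing only in diet_skew share populations, yields, factors.
    pops = rng.integers(
        params.population_range[0],
        params.population_range[1] + 1,
        size=(params.n_countries, params.n_years),
    )
    yields = rng.uniform(
        params.yield_range[0],
        params.yield_range[1],
        size=(params.n_countries, params.n_commodities, params.n_years),
    )
    factors = rng.choice([1.0, 1.0, 1.25, 1.5], size=params.n_commodities)

    base = default_config()
    config = Config(
        calorie_level=params.calorie_level,
        serving_mass=dict(base.serving_mass),
        energy_density=dict(base.energy_density),
        primary_factor={item: float(f) for item, f in zip(commodities, factors)},
        group_map=dict(group_of),
        continent_map={
            c: _PANELS[i % len(_PANELS)] for i, c in enumerate(countries)
        },
        livestock_land=base.livestock_land,
        ratio_clamp=True,
        supply_convention="import_free",
    )

    table = packaged_guidelines()
    t = params.trade_intensity
    inflate = 1.0 + (0.0 if params.balanced_trade else params.discrepancy_injection)

    def requirement(group: str, persons: int) -> float:
        daily = table.servings_for(group, params.calorie_level)
        if group == DISCRETIONARY:
            kg_day = daily / config.energy_density[DISCRETIONARY]
        else:
            kg_day = daily * config.serving_mass[group]
        return kg_day * 365.0 * persons / 1000.0

    # True per-commodity imports; the ring booking needs them all at once.
    target: dict[tuple[str, int, str], float] = {}  # (country, year, item) -> tonnes
    z_truth: dict[tuple[str, int, str], float] = {}
    for ci, country in enumerate(countries):
        for yi, year in enumerate(years):
            for group in LAND_GROUPS:
                z = requirement(group, int(pops[ci, yi]))
                z_truth[(country, year, group)] = z
                skew = params.diet_skew.get((country, group), 1.0)
                for item in members.get(group, []):
                    target[(country, year, item)] = skew * z / len(members[group])

    fbs_rows: list[tuple] = []
    prod_rows: list[tuple] = []
    xyz: dict[tuple[str, int, str], tuple[float, float, float]] = {}
    prod_truth: dict[tuple[str, int, str], tuple[float, float]] = {}
    for ci, country in enumerate(countries):
        exporter_of = countries[(ci - 1) % params.n_countries]  # we export to them
        for yi, year in enumerate(years):
            group_x: dict[str, float] = {g: 0.0 for g in LAND_GROUPS}
            group_y: dict[str, float] = {g: 0.0 for g in LAND_GROUPS}
            for ji, item in enumerate(commodities):
                supply = target.get((country, year, item), 0.0)
                imports = t * supply
                domestic = supply - imports
                exports = t * target.get((exporter_of, year, item), 0.0)
                reported_imports = inflate * imports
                reported_supply = domestic + reported_imports
                production = domestic + exports
                f = factors[ji]
                fbs_rows.extend(
                    [
                        (country, item, "Production", year, "tonnes", production / f),
                        (country, item, "Import Quantity", year, "tonnes", reported_imports / f),
                        (country, item, "Export Quantity", year, "tonnes", exports / f),
                        (country, item, "Domestic supply quantity", year, "tonnes", reported_supply / f),
                        (country, item, "Food supply quantity", year, "tonnes", reported_supply / f),
                    ]
                )
                area = production / yields[ci, ji, yi]
                prod_rows.append((country, year, item, production, area))
                group = group_of[item]
                # What a correct reading of the records should recover:
                group_x[group] += domestic
                group_y[group] += reported_imports
                pk, ak = prod_truth.get((country, year, group), (0.0, 0.0))
                if area > 0:
                    prod_truth[(country, year, group)] = (pk + production, ak + area)
            for group in LAND_GROUPS:
                xyz[(country, year, group)] = (
                    group_x[group],
                    group_y[group],
                    z_truth[(country, year, group)],
                )

    fbs = pd.DataFrame(
        fbs_rows, columns=["Area", "Item", "Element", "Year", "Unit", "Value"]
    )
    production_df = pd.DataFrame(
        prod_rows, columns=["country", "year", "commodity", "production", "area"]
    )
    population_df = pd.DataFrame(
        [
            (c, years[yi], int(pops[ci, yi]))
            for ci, c in enumerate(countries)
            for yi in range(params.n_years)
        ],
        columns=["country", "year", "persons"],
    )

    y_world: dict[tuple[int, str], tuple[float, float]] = {}
    for (country, year, group), (p, a) in prod_truth.items():
        pw, aw = y_world.get((year, group), (0.0, 0.0))
        y_world[(year, group)] = (pw + p, aw + a)

    truth = {
        "xyz": xyz,
        "y_dom": {
            key: p / a for key, (p, a) in prod_truth.items() if a > 0 and p > 0
        },
        "y_world": {
            key: p / a for key, (p, a) in y_world.items() if a > 0 and p > 0
        },
    }
    world = SyntheticWorld(
        params=params,
        fbs=fbs,
        production=production_df,
        population=population_df,
        config=config,
        expected=[],
        truth=truth,
    )
    world.expected = oracle_land(world)
    return world


def oracle_land(world: SyntheticWorld) -> list[LandResult]:
    """Expected land results by direct closed-form substitution.

    Recomputes S = X + Y - Z, r = Y/(X+Y), S_d = S(1-r), S_i = S r,
    land = S_part / yield from the generator's ground truth. Shares no
    code with the pipeline; this is the oracle the pipeline is tested
    against.
    """
    out: list[LandResult] = []
    xyz = world.truth["xyz"]
    y_dom = world.truth["y_dom"]
    y_world = world.truth["y_world"]
    for (country, year, group) in sorted(xyz):
        x, y, z = xyz[(country, year, group)]
        s = x + y - z
        r = y / (x + y) if x + y > 0 else 0.0
        s_d = s * (1.0 - r)
        s_i = s * r
        yd = y_dom.get((country, year, group))
        yw = y_world.get((year, group))
        if yd is None and yw is None:
            continue  # no usable yield anywhere; the pipeline omits too
        if yd is None:
            yd = yw
        if yw is None:
            yw = yd
        out.append(
            LandResult(
                country=country,
                year=year,
                food_group=group,
                land_domestic=s_d / yd,
                land_displaced=s_i / yw,
            )
        )
    return out


def random_diet_skew(
    params: SynthParams,
    low: float = 0.4,
    high: float = 2.0,
    seed: int | None = None,
) -> dict[tuple[str, str], float]:
    """Uniform per-(country, group) skew multipliers for randomized worlds."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return {
        (country, group): float(rng.uniform(low, high))
        for country in _country_names(params.n_countries)
        for group in LAND_GROUPS
    }


def world_with_net_deficit(
    deficit_ha: float, params: SynthParams, year: int | None = None
) -> SyntheticWorld:
    """A world whose expected world total land in ``year`` is -deficit_ha.

    Solves for the uniform diet skew s such that the closed-form world
    total equals -deficit_ha: land is linear in s with slope
    K = sum Z [(1-r)/y_dom + r/y_world], so s = 1 - deficit/K. Uniform
    scaling leaves every aggregate yield unchanged, so the construction is
    exact up to float arithmetic.
    """
    base = generate_world(replace(params, diet_skew={}))
    years = base.years
    year = years[-1] if year is None else year
    if year not in years:
        raise ValueError(f"year {year} not generated (have {years})")
    k = 0.0
    for (country, yr, group), (x, y, z) in base.truth["xyz"].items():
        if yr != year:
            continue
        r = y / (x + y) if x + y > 0 else 0.0
        yd = base.truth["y_dom"].get((country, yr, group))
        yw = base.truth["y_world"].get((yr, group))
        if yd is None and yw is None:
            continue
        yd = yd if yd is not None else yw
        yw = yw if yw is not None else yd
        k += z * ((1.0 - r) / yd + r / yw)
    if k <= 0:
        raise ValueError("world has no land-convertible requirement; cannot solve")
    s = 1.0 - deficit_ha / k
    if s < 0:
        raise ValueError(
            f"requested deficit {deficit_ha} ha exceeds the feasible range ({k} ha)"
        )
    skew = {
        (country, group): s
        for country in _country_names(params.n_countries)
        for group in LAND_GROUPS
    }
    return generate_world(replace(params, diet_skew=skew))


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write a world's inputs + expected results as the CSV dialects the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fbs": out / "fbs.csv",
        "production": out / "production.csv",
        "population": out / "population.csv",
        "config": out / "config.yaml",
        "expected": out / "expected_land.csv",
    }
    world.fbs.to_csv(paths["fbs"], index=False)
    world.production.to_csv(paths["production"], index=False)
    world.population.to_csv(paths["population"], index=False)
    import yaml

    cfg = world.config
    with paths["config"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "calorie_level": cfg.calorie_level,
                "serving_mass": cfg.serving_mass,
                "energy_density": cfg.energy_density,
                "primary_factor": cfg.primary_factor,
                "group_map": cfg.group_map,
                "continent_map": cfg.continent_map,
                "ratio_clamp": cfg.ratio_clamp,
                "supply_convention": cfg.supply_convention,
            },
            fh,
            sort_keys=True,
        )
    write_land_results(world.expected, paths["expected"])
    return paths
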