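"""The USDA 2010 guideline serving grid and annual mass requirements.

The guideline assigns, for each of twelve daily calorie levels (1000 to
3200 kcal in 200 kcal steps), daily servings of six food groups — fruit and
vegetables and milk in cups, grains and meat/beans in ounce-equivalents,
oils in teaspoons — plus a whole-grain sub-portion of the grains row and a
discretionary calorie allowance in kcal/day. The grid ships as packaged
data and is looked up exactly: there is no interpolation between levels.

A country's annual requirement for a group is::

    Z [tonnes] = servings/day x serving mass [kg] x 365 x population / 1000

and for the discretionary group the kcal allowance is converted to mass via
a configurable aggregate energy density (kcal/kg).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .config import Config
from .records import DISCRETIONARY, FOOD_GROUPS, WHOLE_GRAIN, RequirementRecord

#: groups whose servings must be non-decreasing in calorie level
_MONOTONE_GROUPS = ("fruit", "vegetables", "grains", "meat_beans", "oils")


class GuidelineTable:
    """Exact lookup of guideline servings per (food group, calorie level)."""

    def __init__(self, frame: pd.DataFrame):
        # frame: index = group, columns = int levels, values = servings/day
        self.levels: tuple[int, ...] = tuple(int(c) for c in frame.columns)
        self._units: dict[str, str] = dict(frame.attrs.get("units", {}))
        self._grid: dict[str, dict[int, float]] = {
            group: {int(level): float(v) for level, v in row.items()}
            for group, row in frame.iterrows()
        }
        self._validate()

    def _validate(self) -> None:
        expected = set(FOOD_GROUPS) | {WHOLE_GRAIN, DISCRETIONARY}
        missing = expected - set(self._grid)
        if missing:
            raise ValueError(f"guideline table missing group rows: {sorted(missing)}")
        for group in self._grid:
            absent = [lv for lv in self.levels if lv not in self._grid[group]]
            if absent:
                raise ValueError(f"guideline table row {group!r} missing levels {absent}")
        for group in _MONOTONE_GROUPS:
            values = [self._grid[group][lv] for lv in sorted(self.levels)]
            if any(b < a for a, b in zip(values, values[1:])):
                raise ValueError(f"servings for {group!r} must be non-decreasing in level")

    def unit(self, group: str) -> str:
        return self._units.get(group, "")

    def servings_for(self, group: str, level: int) -> float:
        """Exact table value: servings/day (kcal/day for discretionary)."""
        if group not in self._grid:
            raise ValueError(
                f"unknown food group {group!r}; expected one of {sorted(self._grid)}"
            )
        if level not in self._grid[group]:
            raise ValueError(
                f"calorie level {level} not in the guideline table; "
                f"valid levels: {sorted(self.levels)} (no interpolation)"
            )
        return self._grid[group][level]


@lru_cache(maxsize=1)
def packaged_guidelines() -> GuidelineTable:
    """The packaged guideline serving grid (read-only)."""
    with resources.files("dietfootprint.data").joinpath("guideline_servings.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        raw = pd.read_csv(fh)
    units = dict(zip(raw["group"], raw["unit"]))
    frame = raw.drop(columns=["unit"]).set_index("group")
    frame.columns = [int(c) for c in frame.columns]
    frame.attrs["units"] = units
    return GuidelineTable(frame)


def servings_for(group: str, level: int) -> float:
    """Module-level lookup into the packaged guideline grid."""
    return packaged_guidelines().servings_for(group, level)


def serving_mass(group: str, config: Config) -> float:
    """kg per serving unit for ``group``, from config (packaged defaults)."""
    try:
        return float(config.serving_mass[group])
    except KeyError:
        raise ValueError(
            f"no serving mass configured for food group {group!r}; "
            f"configured: {sorted(config.serving_mass)}"
        ) from None


def _persons(population: pd.DataFrame, country: str, year: int) -> int:
    match = population[(population["country"] == country) & (population["year"] == year)]
    if match.empty:
        raise ValueError(f"no population entry for ({country!r}, {year})")
    return int(match["persons"].iloc[0])


def annual_requirement(
    group: str,
    level: int,
    country: str,
    year: int,
    population: pd.DataFrame,
    config: Config,
    table: GuidelineTable | None = None,
) -> RequirementRecord:
    """Annual national mass requirement Z (tonnes) for one food group.

    For the named groups Z = servings x serving mass x 365 x persons; for
    the discretionary group the kcal/day allowance is divided by the
    configured energy density (kcal/kg). The whole-grain portion is a
    reporting sub-quantity of grains, not an additional requirement, and is
    rejected here.
    """
    if group == WHOLE_GRAIN:
        raise ValueError(
            "whole_grain_portion is a sub-portion of grains (reporting only); "
            "land accounting uses total grains"
        )
    table = table or packaged_guidelines()
    persons = _persons(population, country, year)
    daily = table.servings_for(group, level)
    if group == DISCRETIONARY:
        try:
            density = float(config.energy_density[group])
        except KeyError:
            raise ValueError(
                f"no energy density configured for {group!r} group"
            ) from None
        kg_per_day = daily / density
    else:
        kg_per_day = daily * serving_mass(group, config)
    tonnes = kg_per_day * 365.0 * persons / 1000.0
    return RequirementRecord(country=country, year=year, food_group=group, required_mass=tonnes)
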