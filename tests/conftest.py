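"""Shared fixtures: configs, tiny CSV builders, and world loading helpers."""

from __future__ import annotations

import io as _io

import pandas as pd
import pytest

import dietfootprint as dfp
from dietfootprint import io as dio


@pytest.fixture(scope="session")
def config() -> dfp.Config:
    return dfp.default_config()


@pytest.fixture()
def write_csv(tmp_path):
    """Write CSV text to a temp file and return its path."""

    def _write(text: str, name: str = "table.csv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write


def load_world_inputs(world: dfp.SyntheticWorld):
    """Push a generated world through the real readers (in memory)."""
    fbs = dio.read_fbs(_io.StringIO(world.fbs.to_csv(index=False)))
    prod = dio.read_production(_io.StringIO(world.production.to_csv(index=False)))
    pop = dio.read_population(_io.StringIO(world.population.to_csv(index=False)))
    return fbs, prod, pop


def run_world(world: dfp.SyntheticWorld) -> dfp.FootprintResult:
    """Full chain: readers -> grouping -> decomposition -> land."""
    fbs, prod, pop = load_world_inputs(world)
    return dfp.compute_land_footprint(fbs, prod, pop, world.config)


def land_by_key(results) -> dict[tuple[str, int, str], dfp.LandResult]:
    return {(r.country, r.year, r.food_group): r for r in results}


@pytest.fixture(scope="session")
def population_1m() -> pd.DataFrame:
    return pd.DataFrame(
        {"country": ["Atlantis"], "year": [2010], "persons": [1_000_000]}
    )
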