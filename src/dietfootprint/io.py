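"""Readers and writers for FAOSTAT-dialect CSV tables and result files.

FAOSTAT exports are long-format CSV whose column names drift between
vintages ("Area" vs "Country", "Item" vs "Commodity"); readers resolve
case-insensitive aliases, normalise units (tonnes, hectares), validate
uniqueness invariants, and return tidy pandas DataFrames with canonical
lower-case columns. All matching is exact after trimming and case-folding —
no fuzzy joins.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import read_config  # noqa: F401  (re-exported module surface)
from .records import FBS_ELEMENTS, LandResult

logger = logging.getLogger(__name__)

#: element spellings seen in FAOSTAT food balance sheets, case-folded
_ELEMENT_ALIASES = {
    "production": "production",
    "import quantity": "import_quantity",
    "import_quantity": "import_quantity",
    "imports": "import_quantity",
    "export quantity": "export_quantity",
    "export_quantity": "export_quantity",
    "exports": "export_quantity",
    "domestic supply": "domestic_supply",
    "domestic_supply": "domestic_supply",
    "domestic supply quantity": "domestic_supply",
    "food": "food_quantity",
    "food_quantity": "food_quantity",
    "food quantity": "food_quantity",
    "food supply quantity": "food_quantity",
}

_MASS_UNIT_FACTORS = {
    "tonnes": 1.0,
    "t": 1.0,
    "tonne": 1.0,
    "1000 tonnes": 1000.0,
    "1000 t": 1000.0,
    "kt": 1000.0,
    "kg": 0.001,
}

_AREA_UNIT_FACTORS = {
    "ha": 1.0,
    "hectares": 1.0,
    "1000 ha": 1000.0,
}


def _resolve_columns(
    df: pd.DataFrame,
    aliases: dict[str, Sequence[str]],
    required: Iterable[str],
) -> dict[str, str]:
    """Map canonical names to actual column names, case-insensitively."""
    lower = {str(c).strip().casefold(): c for c in df.columns}
    found: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lower:
                found[canonical] = lower[name]
                break
    missing = [c for c in required if c not in found]
    if missing:
        raise ValueError(
            f"missing required column(s) {missing}; "
            f"accepted aliases: {{{', '.join(f'{k}: {list(v)}' for k, v in aliases.items())}}}"
        )
    return found


def _numeric(series: pd.Series, column: str) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & ~series.isna() | series.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based plus header line
        raise ValueError(
            f"non-numeric value {series[bad.idxmax()]!r} in column {column!r} "
            f"at file row {row}"
        )
    return values


def _clean_text(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip()


def _check_unique(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise ValueError(f"duplicate {what} key {first}")


def read_fbs(path: str | Path) -> pd.DataFrame:
    """Read a food-balance-sheet table.

    Returns a DataFrame with columns ``country, year, commodity, element,
    value`` where ``value`` is in tonnes and ``element`` is one of
    ``production, import_quantity, export_quantity, domestic_supply,
    food_quantity``. Rows with unrecognised elements are skipped (count
    logged). Negative values are rejected for all elements except
    ``domestic_supply`` (stock drawdowns), which is kept with a warning and
    floored to zero downstream.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _resolve_columns(
        df,
        aliases={
            "country": ("country", "area"),
            "commodity": ("commodity", "item"),
            "element": ("element",),
            "year": ("year",),
            "unit": ("unit",),
            "value": ("value",),
        },
        required=("country", "commodity", "element", "year", "value"),
    )
    out = pd.DataFrame(
        {
            "country": _clean_text(df[cols["country"]]),
            "commodity": _clean_text(df[cols["commodity"]]),
            "element": _clean_text(df[cols["element"]]).str.casefold(),
            "year": _numeric(df[cols["year"]], "year").astype(int),
            "value": _numeric(df[cols["value"]], "value"),
        }
    )
    if "unit" in cols:
        unit = _clean_text(df[cols["unit"]]).str.casefold()
        unknown = ~unit.isin(_MASS_UNIT_FACTORS)
        if unknown.any():
            raise ValueError(
                f"unknown mass unit {unit[unknown.idxmax()]!r}; "
                f"accepted: {sorted(_MASS_UNIT_FACTORS)}"
            )
        out["value"] = out["value"] * unit.map(_MASS_UNIT_FACTORS)

    recognised = out["element"].isin(_ELEMENT_ALIASES)
    n_skipped = int((~recognised).sum())
    if n_skipped:
        logger.info("read_fbs: skipped %d row(s) with unrecognised elements", n_skipped)
    out = out[recognised].copy()
    out["element"] = out["element"].map(_ELEMENT_ALIASES)

    neg = (out["value"] < 0) & (out["element"] != "domestic_supply")
    if neg.any():
        bad = out[neg].iloc[0]
        raise ValueError(
            f"negative value {bad['value']} for element {bad['element']!r} "
            f"({bad['country']}, {bad['year']}, {bad['commodity']})"
        )
    n_neg_ds = int(((out["value"] < 0) & (out["element"] == "domestic_supply")).sum())
    if n_neg_ds:
        logger.warning(
            "read_fbs: %d negative domestic_supply value(s) retained; "
            "treated as 0 in domestic-supply accounting",
            n_neg_ds,
        )
    _check_unique(out, ["country", "year", "commodity", "element"], "food balance record")
    assert set(out["element"]) <= set(FBS_ELEMENTS)
    return out.reset_index(drop=True)


def read_production(path: str | Path) -> pd.DataFrame:
    """Read a production/area-harvested table (wide dialect).

    Returns columns ``country, year, commodity, production, area`` with
    production in tonnes and area in hectares. Rows with zero area are
    retained but are unusable for yields. To keep "Area" (FAOSTAT's country
    column) distinguishable from harvested area, a column literally named
    "area" is treated as hectares whenever a "country" column is present,
    and as the country otherwise (then hectares must come from
    "area_harvested").
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    lower = {str(c).strip().casefold() for c in df.columns}
    if "country" in lower:
        country_aliases: tuple[str, ...] = ("country",)
        area_aliases: tuple[str, ...] = ("area_harvested", "area_ha", "area")
    else:
        country_aliases = ("area",)
        area_aliases = ("area_harvested", "area_ha")
    cols = _resolve_columns(
        df,
        aliases={
            "country": country_aliases,
            "commodity": ("commodity", "item"),
            "year": ("year",),
            "production": ("production", "production_t", "production_tonnes"),
            "area": area_aliases,
            "area_unit": ("area_unit",),
        },
        required=("country", "commodity", "year", "production", "area"),
    )
    out = pd.DataFrame(
        {
            "country": _clean_text(df[cols["country"]]),
            "commodity": _clean_text(df[cols["commodity"]]),
            "year": _numeric(df[cols["year"]], "year").astype(int),
            "production": _numeric(df[cols["production"]], "production"),
            "area": _numeric(df[cols["area"]], "area"),
        }
    )
    if "area_unit" in cols:
        unit = _clean_text(df[cols["area_unit"]]).str.casefold()
        unknown = ~unit.isin(_AREA_UNIT_FACTORS)
        if unknown.any():
            raise ValueError(f"unknown area unit {unit[unknown.idxmax()]!r}")
        out["area"] = out["area"] * unit.map(_AREA_UNIT_FACTORS)
    if (out["production"] < 0).any() or (out["area"] < 0).any():
        raise ValueError("production and area must be non-negative")
    n_zero = int((out["area"] == 0).sum())
    if n_zero:
        logger.info(
            "read_production: %d record(s) with zero area retained "
            "(unusable for domestic yield)",
            n_zero,
        )
    _check_unique(out, ["country", "year", "commodity"], "production record")
    return out.reset_index(drop=True)


def read_population(path: str | Path) -> pd.DataFrame:
    """Read a population table; columns ``country, year, persons``."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _resolve_columns(
        df,
        aliases={
            "country": ("country", "area"),
            "year": ("year",),
            "persons": ("persons", "population", "value"),
        },
        required=("country", "year", "persons"),
    )
    out = pd.DataFrame(
        {
            "country": _clean_text(df[cols["country"]]),
            "year": _numeric(df[cols["year"]], "year").astype(int),
            "persons": _numeric(df[cols["persons"]], "persons"),
        }
    )
    if (out["persons"] <= 0).any():
        bad = out[out["persons"] <= 0].iloc[0]
        raise ValueError(
            f"population must be > 0; got {bad['persons']} for "
            f"({bad['country']}, {bad['year']})"
        )
    out["persons"] = out["persons"].astype("int64")
    _check_unique(out, ["country", "year"], "population")
    return out.reset_index(drop=True)


def read_pasture(path: str | Path) -> pd.DataFrame:
    """Read national permanent-meadow/pasture areas; ``country, year, pasture_ha``."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _resolve_columns(
        df,
        aliases={
            "country": ("country", "area"),
            "year": ("year",),
            "pasture_ha": ("pasture_ha", "pasture", "value"),
        },
        required=("country", "year", "pasture_ha"),
    )
    out = pd.DataFrame(
        {
            "country": _clean_text(df[cols["country"]]),
            "year": _numeric(df[cols["year"]], "year").astype(int),
            "pasture_ha": _numeric(df[cols["pasture_ha"]], "pasture_ha"),
        }
    )
    if (out["pasture_ha"] < 0).any():
        raise ValueError("pasture_ha must be non-negative")
    _check_unique(out, ["country", "year"], "pasture")
    return out.reset_index(drop=True)


_LAND_COLUMNS = [
    "country",
    "year",
    "food_group",
    "land_domestic_ha",
    "land_displaced_ha",
    "land_total_ha",
]


def land_results_frame(results: Iterable[LandResult]) -> pd.DataFrame:
    """Tidy DataFrame of land results, sorted (country, year, group)."""
    rows = [
        (
            res.country,
            res.year,
            res.food_group,
            res.land_domestic,
            res.land_displaced,
            res.land_total,
        )
        for res in results
    ]
    df = pd.DataFrame(rows, columns=_LAND_COLUMNS)
    return df.sort_values(["country", "year", "food_group"], kind="mergesort").reset_index(
        drop=True
    )


def write_land_results(results: Iterable[LandResult], path: str | Path) -> None:
    """Write land results as tidy CSV with a deterministic row order."""
    land_results_frame(results).to_csv(path, index=False)


def read_land_results(path: str | Path) -> list[LandResult]:
    """Round-trip reader for :func:`write_land_results` output."""
    df = pd.read_csv(path)
    missing = [c for c in _LAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing land-result column(s) {missing}")
    return [
        LandResult(
            country=str(row.country),
            year=int(row.year),
            food_group=str(row.food_group),
            land_domestic=float(row.land_domestic_ha),
            land_displaced=float(row.land_displaced_ha),
        )
        for row in df.itertuples()
    ]
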