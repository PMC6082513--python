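"""Primary-equivalent conversion and commodity -> food-group aggregation.

Processed commodities (wine, beer, butter, sugar ...) are converted to the
mass of their raw agricultural input with configurable multipliers, then
commodity-level food-balance records are aggregated into per-group domestic
(X) and imported (Y) quantities.

Under the default convention X is the import-free part of the domestic
supply: per commodity, X = max(0, domestic_supply - imports) and
Y = imports, both in primary-equivalent tonnes, so X + Y recovers the
domestic supply wherever the floor does not trigger. The alternative
"domestic_supply" convention keeps X as the full domestic supply (the
literal worked-example reading) for sensitivity analysis.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import Config
from .records import GroupSupply

logger = logging.getLogger(__name__)


def to_primary_equivalent(value: float, commodity: str, config: Config) -> float:
    """Convert a processed-commodity mass (tonnes) to its primary equivalent."""
    if value < 0:
        raise ValueError(f"quantity must be non-negative, got {value}")
    return value * config.primary_factor.get(commodity, 1.0)


def group_supply(fbs: pd.DataFrame, config: Config) -> list[GroupSupply]:
    """Aggregate food-balance records into per-group X and Y quantities.

    Commodities absent from ``config.group_map`` are skipped (count
    logged). Negative domestic-supply values (stock drawdowns) are floored
    to zero before the import subtraction. When a commodity has no
    domestic_supply element but does have production/imports/exports, the
    FAO identity (supply = production + imports - exports) is used instead
    and the derivation is logged.

    Returns one :class:`GroupSupply` per (country, year, group) with any
    mapped records, sorted.
    """
    mapped = fbs[fbs["commodity"].isin(config.group_map)]
    n_skipped = fbs["commodity"].nunique() - mapped["commodity"].nunique()
    if n_skipped:
        logger.info("group_supply: skipped %d unmapped commodity(ies)", n_skipped)
    if mapped.empty:
        return []

    wide = mapped.pivot_table(
        index=["country", "year", "commodity"],
        columns="element",
        values="value",
        aggfunc="first",
    )
    for element in ("domestic_supply", "import_quantity", "production", "export_quantity"):
        if element not in wide.columns:
            wide[element] = float("nan")

    ds = wide["domestic_supply"].copy()
    derivable = ds.isna() & wide["production"].notna()
    if derivable.any():
        logger.info(
            "group_supply: derived domestic_supply from the FAO identity for "
            "%d commodity cell(s)",
            int(derivable.sum()),
        )
        ds[derivable] = (
            wide["production"][derivable]
            + wide["import_quantity"].fillna(0.0)[derivable]
            - wide["export_quantity"].fillna(0.0)[derivable]
        )
    ds = ds.fillna(0.0).clip(lower=0.0)
    imports = wide["import_quantity"].fillna(0.0)

    factors = wide.index.get_level_values("commodity").map(
        lambda c: config.primary_factor.get(c, 1.0)
    )
    if config.supply_convention == "import_free":
        x = (ds - imports).clip(lower=0.0) * factors
    else:  # "domestic_supply": X is the full supply, imports included
        x = ds * factors
    y = imports * factors

    per_commodity = pd.DataFrame({"x": x, "y": y}, index=wide.index).reset_index()
    per_commodity["food_group"] = per_commodity["commodity"].map(config.group_map)
    grouped = (
        per_commodity.groupby(["country", "year", "food_group"])[["x", "y"]]
        .sum()
        .sort_index()
    )
    return [
        GroupSupply(
            country=country,
            year=int(year),
            food_group=group,
            x=float(row.x),
            y=float(row.y),
        )
        for (country, year, group), row in grouped.iterrows()
    ]
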