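"""Core record types shared across the pipeline.

Bulk tables (food balance sheets, production, population) travel as pandas
DataFrames with canonical lower-case columns; the per-cell results of the
accounting — supplies, requirements, surplus decompositions, yields and land
results — are small frozen dataclasses so that each stage has an explicit,
hashable atom.

Sign convention: positive land = hectares spared by switching to the
guideline diet, negative = additional hectares required (a land deficit).
"""

from __future__ import annotations

from dataclasses import dataclass

#: The six named food groups of the guideline table, in canonical order.
FOOD_GROUPS = ("fruit", "vegetables", "grains", "meat_beans", "milk", "oils")

#: Calorie budget outside the named groups, carried as a seventh group.
DISCRETIONARY = "discretionary"

#: Reporting-only sub-portion of the grains row.
WHOLE_GRAIN = "whole_grain_portion"

#: Groups that take part in land accounting.
LAND_GROUPS = FOOD_GROUPS + (DISCRETIONARY,)

#: Canonical food-balance-sheet elements.
FBS_ELEMENTS = (
    "production",
    "import_quantity",
    "export_quantity",
    "domestic_supply",
    "food_quantity",
)


@dataclass(frozen=True)
class GroupSupply:
    """Domestic (X) and imported (Y) primary-equivalent supply, in tonnes."""

    country: str
    year: int
    food_group: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(
                f"GroupSupply quantities must be non-negative, got X={self.x}, Y={self.y}"
            )


@dataclass(frozen=True)
class RequirementRecord:
    """Annual national mass requirement Z (tonnes) for one food group."""

    country: str
    year: int
    food_group: str
    required_mass: float

    def __post_init__(self) -> None:
        if self.required_mass < 0:
            raise ValueError(f"required_mass must be >= 0, got {self.required_mass}")


@dataclass(frozen=True)
class SurplusDecomposition:
    """Surplus S = X + Y - Z split into domestic and displaced parts.

    ``r`` is the import dependency ratio; ``s_d = S*(1-r)`` and
    ``s_i = S - s_d`` so that the split is conservative to the last bit.
    """

    country: str
    year: int
    food_group: str
    x: float
    y: float
    z: float
    s: float
    r: float
    s_d: float
    s_i: float


@dataclass(frozen=True)
class GroupYield:
    """Aggregate yield (tonnes/ha) for a food group within a scope.

    ``scope`` is a country name or ``"world"``. An unavailable yield is an
    explicit absence (``None`` at the call site), never a zero.
    """

    scope: str
    year: int
    food_group: str
    tonnes_per_ha: float
    basis: str = "crop_area"  # or "livestock_area"

    def __post_init__(self) -> None:
        if not self.tonnes_per_ha > 0:
            raise ValueError(f"yield must be > 0, got {self.tonnes_per_ha}")
        if self.basis not in ("crop_area", "livestock_area"):
            raise ValueError(f"unknown yield basis {self.basis!r}")


@dataclass(frozen=True)
class LandResult:
    """Hectares spared (positive) or required (negative) for one cell."""

    country: str
    year: int
    food_group: str
    land_domestic: float
    land_displaced: float

    @property
    def land_total(self) -> float:
        return self.land_domestic + self.land_displaced
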