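"""Pipeline configuration: serving masses, commodity maps, policies.

A :class:`Config` merges a user YAML file over the packaged defaults. The
guideline serving grid itself is *not* configurable (guideline integrity);
only the quantities the guidelines leave open — serving masses, the
discretionary energy density, primary-equivalent factors, the commodity and
continent maps, and the livestock land policy — can be overridden.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .records import LAND_GROUPS

_SUPPLY_CONVENTIONS = ("import_free", "domestic_supply")
_LIVESTOCK_POLICIES = ("pasture_proxy", "direct")


@dataclass(frozen=True)
class LivestockLandPolicy:
    """How the land denominator of livestock-product yields is obtained."""

    policy: str = "pasture_proxy"
    groups: tuple[str, ...] = ("meat_beans", "milk")

    def __post_init__(self) -> None:
        if self.policy not in _LIVESTOCK_POLICIES:
            raise ValueError(
                f"unknown livestock land policy {self.policy!r}; "
                f"expected one of {_LIVESTOCK_POLICIES}"
            )


@dataclass
class Config:
    calorie_level: int = 2000
    serving_mass: dict[str, float] = field(default_factory=dict)
    energy_density: dict[str, float] = field(default_factory=dict)
    primary_factor: dict[str, float] = field(default_factory=dict)
    group_map: dict[str, str] = field(default_factory=dict)
    continent_map: dict[str, str] = field(default_factory=dict)
    livestock_land: LivestockLandPolicy = field(default_factory=LivestockLandPolicy)
    ratio_clamp: bool = True
    supply_convention: str = "import_free"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.supply_convention not in _SUPPLY_CONVENTIONS:
            raise ValueError(
                f"unknown supply_convention {self.supply_convention!r}; "
                f"expected one of {_SUPPLY_CONVENTIONS}"
            )
        for group, mass in self.serving_mass.items():
            if not mass > 0:
                raise ValueError(f"serving_mass[{group!r}] must be > 0, got {mass}")
        for group, dens in self.energy_density.items():
            if not dens > 0:
                raise ValueError(f"energy_density[{group!r}] must be > 0, got {dens}")
        for commodity, factor in self.primary_factor.items():
            if not factor > 0:
                raise ValueError(
                    f"primary_factor[{commodity!r}] must be > 0, got {factor}"
                )
        for commodity, group in self.group_map.items():
            if group not in LAND_GROUPS:
                raise ValueError(
                    f"group_map[{commodity!r}] = {group!r} is not a known food group "
                    f"{LAND_GROUPS}"
                )
        # Every mapped commodity has a primary factor; default is the identity.
        for commodity in self.group_map:
            self.primary_factor.setdefault(commodity, 1.0)

    @property
    def groups(self) -> tuple[str, ...]:
        """Food groups that participate in the accounting (canonical order)."""
        present = set(self.group_map.values())
        return tuple(g for g in LAND_GROUPS if g in present)


def _packaged_defaults() -> dict[str, Any]:
    text = (
        resources.files("dietfootprint.data")
        .joinpath("default_config.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def _merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = {**out[key], **value}
        else:
            out[key] = copy.deepcopy(value) if isinstance(value, dict) else value
    return out


def config_from_mapping(raw: Mapping[str, Any]) -> Config:
    """Build a validated :class:`Config` from a plain mapping."""
    raw = dict(raw)
    ll = raw.pop("livestock_land", {}) or {}
    policy = LivestockLandPolicy(
        policy=ll.get("policy", "pasture_proxy"),
        groups=tuple(ll.get("groups", ("meat_beans", "milk"))),
    )
    known = {
        "calorie_level",
        "serving_mass",
        "energy_density",
        "primary_factor",
        "group_map",
        "continent_map",
        "ratio_clamp",
        "supply_convention",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(livestock_land=policy, **raw)


def default_config() -> Config:
    """The packaged default configuration."""
    return config_from_mapping(_packaged_defaults())


def read_config(path: str | Path | None = None) -> Config:
    """Read a user YAML config, merged over the packaged defaults.

    ``None`` or an empty file returns the defaults unchanged. Map-valued
    keys merge entry-wise (user entries override or extend); scalars replace.
    """
    merged = _packaged_defaults()
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {path} must contain a mapping at top level")
        merged = _merge(merged, user)
    return config_from_mapping(merged)
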