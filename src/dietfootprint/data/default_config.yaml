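# Packaged defaults for the land-footprint pipeline.
#
# Serving masses and the discretionary energy density are package choices
# (documented in docs/methods.md); user config files merge over everything
# here except the guideline serving grid, which is fixed packaged data.

calorie_level: 2000

# kg per serving unit (cups for fruit/vegetables/milk, oz-eq for grains and
# meat/beans, teaspoons for oils).
serving_mass:
  fruit: 0.24
  vegetables: 0.21
  grains: 0.028
  meat_beans: 0.028
  milk: 0.245
  oils: 0.0047

# kcal per kg, used only to turn the discretionary calorie allowance into a
# mass. The default treats discretionary calories as an aggregate of sugars,
# solid fats and alcohol at roughly 4000 kcal/kg.
energy_density:
  discretionary: 4000.0

# Processed -> primary-equivalent multipliers (dimensionless, tonnes primary
# per tonne processed). Commodities absent from this map default to 1.0.
primary_factor:
  Wine: 1.4
  Beer: 0.6
  Butter, Ghee: 6.6
  Sugar & Sweeteners: 1.1
  Coffee and products: 1.2

# FAOSTAT item -> food group. Items absent from this map are skipped (the
# skip count is logged). This default covers common FBS aggregates; extend
# it in a user config for a full run.
group_map:
  Wheat and products: grains
  Rice and products: grains
  Maize and products: grains
  Barley and products: grains
  Cereals, Other: grains
  Starchy Roots: vegetables
  Vegetables: vegetables
  Vegetables, Other: vegetables
  Fruits - Excluding Wine: fruit
  Fruits, Other: fruit
  Wine: fruit
  Pulses: meat_beans
  Bovine Meat: meat_beans
  Mutton & Goat Meat: meat_beans
  Pigmeat: meat_beans
  Poultry Meat: meat_beans
  Eggs: meat_beans
  Fish, Seafood: meat_beans
  Treenuts: meat_beans
  Milk - Excluding Butter: milk
  Butter, Ghee: milk
  Vegetable Oils: oils
  Oilcrops: oils
  Sugar & Sweeteners: discretionary
  Beer: discretionary
  Beverages, Alcoholic: discretionary
  Coffee and products: discretionary

# Country -> continent panel. The seven panels are a political grouping
# (European Union split from Eastern Europe); edit to taste.
continent_map:
  United States of America: North America
  Canada: North America
  Mexico: North America
  Brazil: South America
  Argentina: South America
  Chile: South America
  Peru: South America
  France: European Union
  Germany: European Union
  Italy: European Union
  Spain: European Union
  Poland: European Union
  Russian Federation: Eastern Europe
  Ukraine: Eastern Europe
  Belarus: Eastern Europe
  Serbia: Eastern Europe
  China: Asia
  India: Asia
  Japan: Asia
  Indonesia: Asia
  Saudi Arabia: Asia
  Nigeria: Africa
  Ethiopia: Africa
  Egypt: Africa
  South Africa: Africa
  Mozambique: Africa
  Australia: Oceania
  New Zealand: Oceania

# Land denominator for livestock-product yields. "pasture_proxy" apportions
# national permanent-meadow/pasture area to livestock commodities by
# production share (needs a pasture table); "direct" expects per-commodity
# land in the production table's area column.
livestock_land:
  policy: pasture_proxy
  groups: [meat_beans, milk]

ratio_clamp: true

# "import_free": X = domestic supply - imports (floored at 0 per commodity),
# r = Y/(X+Y). "domestic_supply": the literal convention with X the full
# domestic supply and r = Y/X (clamped); kept for sensitivity analysis.
supply_convention: import_free
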