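# dietfootprint

Accounting pipeline for the agricultural land footprint of guideline diets.
Given FAOSTAT-style food balance sheets, production/area tables and
populations, it computes — per country, year and food group — how many
hectares of agricultural land would be **spared** (positive) or **required**
(negative) if the country switched to a recommended diet, splitting each
change into a *domestic* part and a *displaced* part (land the country's
diet occupies abroad through imports), and rolls the results up to
continent and world time series.

The intended users are food-systems and land-use researchers who want a
tested, scriptable version of this accounting instead of one-off analysis
code, plus a synthetic-data module that makes every stage verifiable
without any FAOSTAT download.

## The model

For each country, year and food group (fruit, vegetables, grains,
meat/beans, milk, oils, plus the discretionary calorie allowance):

- **X** — domestic primary-equivalent supply (tonnes), computed per
  commodity as `max(0, domestic_supply − imports)` and summed over the
  group's commodities; processed commodities (wine, beer, butter, sugar …)
  are first converted to primary equivalents with configurable factors.
- **Y** — imported primary-equivalent supply (tonnes).
- **Z** — the guideline requirement:
  `Z = servings/day × serving mass × 365 × population`, with the
  discretionary kcal allowance converted to mass by an aggregate energy
  density. Serving counts come from a packaged 12-level guideline grid
  (1000–3200 kcal/day; default level 2000) looked up exactly, never
  interpolated.
- **Surplus** `S = X + Y − Z` (negative S is a deficit), split by the
  import dependency ratio `r = Y / (X + Y)` into a domestic part
  `S_d = S·(1−r)` and a displaced part `S_i = S·r`.
- **Land** `= S_d / y_dom + S_i / y_world`, where `y_dom` is the country's
  combined group yield (total production over total harvested area across
  the group's commodities) and `y_world` the world-average combined yield.
  Livestock groups can instead use production per hectare of pasture,
  apportioned by production share.

Aggregation is plain addition of hectares, so country → continent → world
roll-ups are exact. A world-level diagnostic reports the relative gap
between the domestic-only and the total (domestic + displaced) series — a
probe for inconsistent trade reporting in the underlying data.

## Worked example

```python
import dietfootprint as dfp

supply = dfp.GroupSupply(country="Atlantis", year=2010, food_group="grains", x=75.0, y=25.0)
need = dfp.RequirementRecord(country="Atlantis", year=2010, food_group="grains",
                             required_mass=90.0)
dec = dfp.decompose_surplus(supply, need)
print(f"surplus S      = {dec.s:.1f} t   (r = {dec.r:.2f})")
print(f"domestic part  = {dec.s_d:.1f} t, displaced part = {dec.s_i:.1f} t")

res = dfp.land_spared(
    dec,
    dfp.GroupYield(scope="Atlantis", year=2010, food_group="grains", tonnes_per_ha=3.0),
    dfp.GroupYield(scope="world", year=2010, food_group="grains", tonnes_per_ha=2.5),
)
print(f"land spared    = {res.land_domestic:.1f} + {res.land_displaced:.1f} "
      f"= {res.land_total:.1f} ha")
```

prints

```
surplus S      = 10.0 t   (r = 0.25)
domestic part  = 7.5 t, displaced part = 2.5 t
land spared    = 2.5 + 1.0 = 3.5 ha
```

The country holds 100 t of grain supply (25 % imported) against a 90 t
requirement; the 10 t surplus frees 2.5 ha at the domestic yield of
3 t/ha and 1.0 ha abroad at the world yield of 2.5 t/ha.

The same chain runs end to end from the command line on a generated
world — here one country over-consumes meat at twice the guideline:

```sh
dietfootprint synth --out-dir demo --seed 42 --skew C01 meat_beans 2.0
dietfootprint run --fbs demo/fbs.csv --production demo/production.csv \
    --population demo/population.csv --config demo/config.yaml --out-dir demo/out
```

logs `world 2010: domestic 475012.0 ha, total 592973.9 ha` and writes
`land_results.csv`, in which country C01's 2010 meat row shows
`+5.93e5` hectares spared (its doubled meat supply exceeds the guideline
requirement) while every other group sits at zero — the at-guideline
baseline. `series.csv` holds the roll-up time series and
`map_values.csv` per-country totals in millions of hectares, ready to
join onto country boundaries.

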