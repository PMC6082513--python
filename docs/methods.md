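# Methods

## The accounting model

The pipeline asks, for every country, year and food group: *if this
country ate exactly the guideline diet, how much agricultural land would
that free or claim, and where?* It is a static accounting model — no
behavioural, price or yield response — evaluated independently per year on
observed (or generated) supplies, populations and yields.

**Supplies.** Food balance sheets give, per commodity, production,
imports, exports and the resulting domestic supply. Processed commodities
are first rescaled to primary equivalents (wine → grapes, butter → milk …)
by configurable multipliers, so that land conversion later happens in the
units yields are measured in. Per commodity, the domestic quantity is
`max(0, domestic_supply − imports)` and the imported quantity is the
import figure itself; group totals X and Y sum these over the commodities
mapped to the group. With this convention `X + Y` equals the domestic
supply wherever the floor does not trigger, and the import dependency
ratio

```
r = Y / (X + Y)          (r = 0 when X + Y = 0)
```

is exactly "imports over domestic supply" and lies in [0, 1] with no
clamping. A literal alternative (X the full domestic supply, `r = Y/X`
clamped into [0, 1]) is kept behind `Config.supply_convention =
"domestic_supply"` for sensitivity analysis; it double-counts imports in
`S = X + Y − Z` and is not the default.

**Requirement.** The guideline grid assigns daily servings per food group
at twelve calorie levels (1000–3200 kcal/day). A single configurable level
(default 2000 kcal/day) applies to the whole population — the model does
not stratify by age or sex. The annual requirement is

```
Z [tonnes] = servings/day × serving mass [kg] × 365 × population / 1000 .
```

Look-ups are exact; interpolating between calorie levels would invent
guideline values and is refused. The whole-grain row is a sub-portion of
grains and is exposed for reporting only; land accounting uses total
grains.

**Surplus and its split.** `S = X + Y − Z`; `S_d = S·(1−r)`;
`S_i = S − S_d` (computing the displaced part as the remainder makes
`S_d + S_i = S` exact to the last bit, rather than merely close, at the
cost of `S_i` differing from `S·r` by at most one rounding). Deficits
(S < 0) split by the same r: a country may close its gap both by
expanding domestic production and by importing more, and proportional
attribution is the minimal assumption.

**Land.** `land = S_d / y_dom + S_i / y_world`, positive = spared,
negative = required. `y_dom` is the country's *combined group yield*,
total production over total harvested area across the group's commodities
— the area-weighted aggregate, not the mean of per-commodity yields,
because total tonnes per total hectare is precisely the rate at which the
group's mass converts to land. `y_world` uses the same sums over all
countries, so it always lies between the country extremes.

## Parameters and defaults

| parameter | unit | default | note |
|---|---|---|---|
| calorie level | kcal/day | 2000 | single level for everyone; configurable |
| serving mass, fruit | kg/cup | 0.24 | package choice (see below) |
| serving mass, vegetables | kg/cup | 0.21 | |
| serving mass, grains | kg/oz-eq | 0.028 | 1 oz ≈ 28 g |
| serving mass, meat/beans | kg/oz-eq | 0.028 | |
| serving mass, milk | kg/cup | 0.245 | |
| serving mass, oils | kg/tsp | 0.0047 | ~4.7 g of oil per teaspoon |
| discretionary energy density | kcal/kg | 4000 | aggregate of sugars/fats/alcohol |
| primary factors | – | 1.0 unless configured | wine 1.4, beer 0.6, butter 6.6 … |

The serving masses and the discretionary energy density are **this
package's documented choices**: guideline sources state servings in
household measures and the mass equivalents live in external FAO handbook
material, so any headline number is sensitive to them. They are plausible
round figures for the serving units involved, they are configurable, and
every structural guarantee tested here (conservation, additivity, oracle
agreement, signs) is independent of their values.

The discretionary group has no serving unit at all — the guideline gives
it as a kcal/day allowance — so its requirement is converted to mass
through the energy density; its land then follows the ordinary route.

**Livestock land.** Harvested area is undefined for animal products, so
livestock yields are production per hectare of land. The default
`pasture_proxy` policy apportions a country's permanent-meadow/pasture
area to livestock commodities by production share when a pasture table is
supplied; a consequence of proportional apportionment is that all
livestock groups in a country share one t/ha figure (total livestock
production over pasture). The `direct` policy instead takes per-commodity
land from the production table's area column. When no pasture table is
given, the crop-area route serves all groups — which is also how the
synthetic worlds are built.

## Degenerate inputs and numerical choices

- Negative domestic supply (FAO stock-drawdown artifacts) is retained on
  read with a warning and treated as 0 in X; per-commodity X is floored at
  0 (re-exporters can have imports above supply). Both events are logged.
- A missing yield is an explicit absence, never 0. A missing domestic
  yield falls back to the world yield (logged); if neither exists the cell
  is omitted with a warning — never silently zero — and the omission list
  is part of the pipeline result.
- Missing population for a processed country/year is a hard error, as is a
  country absent from the continent map during a continent roll-up:
  silent drops would corrupt every aggregate above them.
- `trade_discrepancy = |total − domestic| / max(|total|, 1 ha)`. The
  one-hectare floor keeps the diagnostic at zero on zero-land worlds,
  where the numerator is pure rounding noise.
- Readers accept FAOSTAT column aliases case-insensitively and normalise
  "1000 tonnes"/"1000 ha" rows; text keys are matched after trimming and
  case preservation, with no fuzzy matching (ambiguity is an error).

## The synthetic worlds and their oracle

The generator builds placeholder countries and commodities in which every
quantity is constructed: each country's supply of each group is
`diet_skew × Z` (skew 1.0 ⇒ exactly at guideline ⇒ zero surplus by
construction), a fixed trade intensity of each supply is booked as imports
matched by exports elsewhere on a ring (country *i* imports from *i*+1),
yields are uniform draws on a configured range (default 1–10 t/ha) that
fix harvested areas, and populations are uniform integer draws (default
10⁵–5×10⁷). All draws happen before skews are applied, so worlds differing
only in skew share populations, yields and primary factors — which is what
makes the deficit construction below exact. Expected land results come
from direct substitution into the model formulas using the generator's own
bookkeeping, a code path deliberately separate from the pipeline; the
pipeline is tested against it end to end, through the CSV readers.

Misreported trade is injected by inflating the import rows (and the
domestic-supply identity built on them) by a configurable fraction while
exports stay truthful. On at-guideline worlds this isolates the reporting
error: the world-level gap between the domestic-only and total series is
zero when balanced and grows strictly with the injected fraction. That
world-level identity — "total should equal domestic because world imports
equal world exports" — holds in this attribution-based accounting only
when surpluses vanish or trade is absent: for skewed worlds the displaced
parts `Σ S_i / y_world` do not cancel even under exactly balanced trade,
so the diagnostic is read as a *reporting-consistency* probe at the
at-guideline baseline, not as an invariant of arbitrary worlds.

A world with a prescribed net deficit D is built by solving for the
uniform skew s: world land is linear in s with slope
`K = Σ Z·[(1−r)/y_dom + r/y_world]`, and uniform scaling leaves every
aggregate yield and r unchanged, so `s = 1 − D/K` is exact up to float
arithmetic.

What the generator does **not** emulate: real FAOSTAT magnitudes, country
and commodity names, bilateral trade structure beyond the ring, stock
variations, missing data patterns, or reporting noise other than the
single import-inflation channel. Passing tests therefore demonstrate that
the accounting is implemented correctly and behaves lawfully, not that
any particular real-world headline number is right — real runs remain
sensitive to the serving-mass constants and to FAO data quality.

## Problem sizes

Tests and the acceptance script use worlds of 5 countries × 8 commodities
× 3 years; sweeps run 100 such worlds with randomized diet skews
(multipliers uniform on [0.4, 2.0]). These sizes exercise every code path
(all seven groups, trade, primary factors, fallbacks) while keeping the
full suite in seconds; the accounting itself is linear in
countries × commodities × years and runs comfortably at FAOSTAT scale.

## Known limitations

- One calorie level for the whole population; no demographic structure.
- No nutrient-level (protein/fat/micronutrient) accounting, no food
  waste, no greenhouse-gas or water coupling.
- Displaced land is converted at world-average yields; attributing it to
  actual exporter countries would require the bilateral trade matrix,
  which is out of scope.
- Static yields: no intensification, technology or projection scenarios.
- The plotting of series is left to the caller; the package exports tidy
  CSVs (including per-country map values in Mha) instead of figures.
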