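# Methods

## Scope and structure

`foodshift` projects global food demand by region and food group from
2020 to 2050, overlays consumer adoption of alternatives to animal-source
foods (ASF), converts demand to greenhouse-gas emissions with fixed
per-group factors, and evaluates cumulative emissions against a
food-sector carbon budget. Five modules implement the pipeline:
`synthetic` (calibrated regional baselines), `demand` (population and
diet-convergence paths, the GFD identity), `adoption` (Gompertz
replacement curves and the cultured split), `emissions` (factors,
substitution rules, annual/cumulative accounting, budget), `scenarios`
(families, sweeps, frontier, sensitivity), plus `reporting` and a thin
CLI.

## Demand model

Demand per region, year and group is `GFD_jt = 365·N_t·C_t·S_jt` in
kcal/yr. All time paths are linear between the 2020 and 2050 endpoints:
the endpoints are the only anchored quantities, and linearity is the
minimal interpolation that reproduces the expected ~24% total-demand
growth (population 7.8 → 9.71 billion at a constant 3220-kcal global
mean). Shares are renormalised to the simplex after interpolation — a
guard against floating-point drift only, since convex combinations of
simplex points stay on the simplex. Extrapolation outside the anchor
span is refused rather than guessed.

The business-as-usual (BAU) composition target is the 2020 OECD90+EU
diet (ASF 24.9% of calories, meat 11.6%): every region converges to it
by 2050, and OECD90+EU itself is constant. For intake, the benchmark
converges every region (OECD90+EU included) to 3220 kcal/person/day;
a variant flag holds OECD90+EU at its 3515-kcal baseline instead, and a
3515-kcal global target is the rich-diet sensitivity case. The "Other"
region receives no special treatment.

Driver decomposition (`decompose_drivers`) freezes one driver at a time
(population, composition, intake) and reports
`(BAU − counterfactual)/BAU`. The one-at-a-time convention is a
documented package choice — decompositions of this kind are not unique —
so the outputs are order-of-magnitude diagnostics, not calibrated
results; contributions are deliberately not forced to sum to the total.

## Synthetic fixture

Real FAO food-balance and UN population inputs are replaced by a
five-region generator (OECD90+EU, Asia, Latin America, Sub-Saharan
Africa, Other). Free parameters — the non-OECD archetype diets and the
within-plants calorie mix — are realism-motivated fixed values
(cereal-heavy Asia, root-heavy Sub-Saharan Africa, sugar-heavy Latin
America); seeded lognormal perturbations (σ = 0.05) add heterogeneity.
Calibration is exact, not approximate: populations are scaled
proportionally to the 7.8/9.71-billion totals, non-OECD share matrices
are adjusted by iterative proportional fitting until population-weighted
global shares hit the anchors to ~1e-13 with each region on the simplex,
and non-OECD intakes are scaled by a single linearly-solved factor to hit
the 3220-kcal mean. The OECD90+EU row is pinned because it doubles as
the convergence target (its ASF/meat shares back-solved from the 2050
targets, since full convergence makes the 2050 global composition equal
the OECD 2020 composition). Eggs carry the 2% of calories left by the
82/8/7/1 plants/meat/dairy/fish anchors.

Infeasible anchors (e.g. a global share below what the pinned row alone
contributes) raise a calibration error naming the violated anchor.
Everything is deterministic per seed; identical seeds give byte-identical
CSV fixtures.

What the fixture does *not* emulate: actual country-level diets, income
elasticities, within-region heterogeneity, non-linear population paths,
or year-to-year dietary noise. Passing tests therefore demonstrate the
pipeline's arithmetic and the scenario orderings under controlled
conditions, not the accuracy of any regional detail.

## Adoption model

Replacement follows a displaced Gompertz curve
`S0 + FA·exp(−b·exp(−α(t − t*)))` for `t ≥ t*`, held at `S0` before. The
displacement is `b = t* − 2020` rather than the calendar year `t*` inside
the double exponential: with a calendar-year displacement the inner term
`exp(−2025·x)` is numerically zero for decades and no adoption ever
occurs, so the package uses the offset-from-base-year reading, which
produces the expected S-curve dynamics (near-saturation by 2050 for fast
α). Consequences: at `t* = 2020` the displacement is zero and adoption
jumps immediately to `S0 + FA`; shares are capped at 1.

Speeds: α = 0.18 (meat & fish), 0.73 (dairy), 0.46 (eggs) — the lowest,
highest and mean of observed wind/solar adoption speeds. The plant-only
transition uses the slow 0.18 for every category; the healthy-diet
transition uses the fast 0.73. `S0 = 0.02` is the 2020 alternative
market share.

The cultured share of the alternative meat/fish market is linear:
rapid-shift (RS) from 0 in 2026 to 2/3 in 2050; mostly-plant-based (PB)
zero until 2033, then rising to 27% of alternatives by 2050. The PB
slope is calibrated to that 27% endpoint by default; a strict
quarter-of-RS-slope mode (`pb_mode="quarter_slope"`, ending near 11.8%)
is provided because the two published descriptions of the PB path are
mutually inconsistent and the package does not guess which was intended.
Egg and dairy alternatives are always plant-based (no cultured factor
exists for them).

## Emissions accounting

Default factors (kg CO₂e per 1000 kcal / per 100 g protein) are fixed
constants per group; the table is overridable via CSV or scaling (used
by the cultured ×2/×3 sensitivity). Protein density is implied by the
two bases, `0.1·ef_kcal/ef_protein` g/kcal, which makes kcal-basis and
protein-basis emissions identical for any group carrying both factors —
a deliberate consistency property. Sugar and oils & fats have no
per-protein factor and are treated as zero-protein: they contribute
nothing to protein-equivalent bookkeeping, and requesting their density
explicitly is an error.

Calorie-equivalent (CE) substitution moves replaced ASF calories 1:1
into the alternatives (or, for plant-only scenarios, into the region's
plant groups proportional to their current calorie shares — a uniform
mix is not assumed because the regional mix is known); total calories
are conserved exactly. Protein-equivalent (PE) substitution moves the
replaced *protein* and books the substitute at its own density, so total
protein is conserved exactly and total calories rise when the substitute
is less protein-dense; for plant-only PE the protein is spread over the
plant groups proportional to their current protein content.

Cumulative emissions sum the 31 annual values 2020–2050 inclusive. The
budget default is 390 GtCO₂e, one third of a 1170-Gt remaining global
budget allocated entirely to 2020–2050.

Out of scope by design: land-use-change sequestration credits,
gas-specific (CH₄ vs CO₂) accounting, food-waste reduction, and the
derivation of the factor table from item-level life-cycle data.

## Scenario families and numerical choices

BAU is implemented as the adoption pipeline at `FA = 0`: the constant 2%
alternative market share is carved out of ASF in *every* family, making
"alternatives at FA = 0 equals BAU" an exact identity rather than an
approximation (emission effect of the carve-out ≈ −0.3%/yr). The
EAT-Lancet family blends the BAU diet path toward a 2500-kcal,
ASF-light target with a Gompertz weight (fast α); its default target
composition is a Mediterranean-style placeholder — the authoritative
shares live in the external EAT-Lancet report — so results under it are
property-checked (emissions decline vs BAU) rather than value-anchored.

Sweeps use an FA step of 0.05 and a one-year start-year step over
2020–2035 (configurable); the demand stage is computed once per family
and only substitution/emissions run per cell, so the full five-family
grid evaluates in well under a minute. The budget frontier reports, per
start year, both the conservative first feasible FA grid point (used for
feasibility claims) and a linear interpolation between the bracketing
grid points; once a start year is infeasible at FA = 1, all later years
are too.

## Known limitations

* Cumulative levels are sensitive to the 2020 emission intensity implied
  by the anchors (≈ 18 Gt/yr here); alternative plant-mix assumptions
  shift the BAU cumulative by tens of Gt while leaving the *relative*
  scenario reductions (≈ 35% for 90% alternatives, ≈ 29% for plant-only)
  nearly unchanged. Conclusions should be read on the relative scale.
* Linear population/diet paths ignore the concavity of real demographic
  projections; the effect on 31-year cumulatives is small but not zero.
* Adoption speeds are transferred from energy-technology adoption, not
  fitted to food-market data.
* The fixture's regional detail beyond the calibrated global anchors and
  the pinned OECD90+EU row is synthetic.
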