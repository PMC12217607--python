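"""Business-as-usual projection: demand growth and cumulative emissions.

Evaluates GFD_jt = 365 * N_t * C_t * S_jt on the calibrated fixture with
all regions converging to the OECD90+EU composition by 2050, converts
demand to emissions with the default per-1000-kcal factors, and compares
the 31-year cumulative against the 390-Gt food-sector carbon budget."""

import foodshift as fs

fixture = fs.generate_fixture(seed=1)

kcal0, shares0 = fs.baseline_diet(fixture)
conv = fs.convergence_spec_from_fixture(fixture, kcal_target=3220.0)
pop = fs.population_path_from_fixture(fixture)
demand = fs.compute_demand(pop, fs.project_diet_path(kcal0, shares0, conv))

totals = demand.sum(axis=1).groupby(level="year").sum()
asf = demand[["eggs", "dairy", "meat", "fish"]].sum(axis=1).groupby(level="year").sum()
print(f"total demand growth 2020->2050: {totals[2050]/totals[2020]-1:+.0%}")
print(f"ASF calorie growth:             {asf[2050]/asf[2020]-1:+.0%}")

res = fs.run_scenario(fs.ScenarioSpec(family="BAU"), fixture)
gap = fs.budget_gap(res.cumulative)
print(f"annual emissions: {res.annual[2020]:.1f} Gt (2020) -> "
      f"{res.annual[2050]:.1f} Gt (2050)")
print(f"cumulative 2020-2050: {res.cumulative:.0f} GtCO2e "
      f"({gap:+.0f} Gt vs the 390-Gt food-sector budget)")
# Under business as usual the food system alone overshoots the whole
# food-sector carbon budget by roughly 300 Gt.
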