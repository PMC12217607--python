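"""Demand projection: population, diet convergence, and caloric demand.

Global food demand for group *j* in year *t* is

    GFD_jt = 365 * N_t * C_t * S_jt            [kcal / year]

per region, with N_t the population, C_t the per-capita daily caloric
intake and S_jt the calorie share of the group.  Populations are linearly
interpolated between anchor years; intake and shares move linearly from
each region's 2020 baseline to a common 2050 convergence target (the
business-as-usual "Western-diet convergence" assumption), with shares
renormalised to the simplex after interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .groups import BASE_GROUPS
from .synthetic import RegionFixture, oecd_target

__all__ = [
    "ConvergenceSpec",
    "DietPath",
    "interpolate_population",
    "population_path_from_fixture",
    "baseline_diet",
    "convergence_spec_from_fixture",
    "project_diet",
    "project_diet_path",
    "compute_demand",
    "demand_totals",
    "global_demand_by_group",
    "decompose_drivers",
    "YEARS",
]

#: Default projection horizon (inclusive of both endpoints: 31 years).
YEARS: tuple[int, ...] = tuple(range(2020, 2051))


@dataclass(frozen=True)
class ConvergenceSpec:
    """A 2050 convergence target for per-capita intake and composition.

    ``kcal_target`` is the per-person daily intake every region reaches at
    ``end_year`` (3220 kcal in the benchmark; 3515 in the rich-diet
    variant; 2500 in the EAT-Lancet healthy diet).  ``target_shares`` is
    the common 2050 calorie-share vector.  Regions listed in
    ``hold_baseline_kcal_regions`` keep their 2020 intake instead of
    converging (used for the variant where OECD90+EU stays at 3515 kcal
    while everyone else converges to 3220).
    """

    kcal_target: float
    target_shares: Mapping[str, float]
    start_year: int = 2020
    end_year: int = 2050
    hold_baseline_kcal_regions: tuple[str, ...] = ()

    def __post_init__(self):
        total = sum(self.target_shares.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"target shares sum to {total}, expected 1")
        if any(v < 0 for v in self.target_shares.values()):
            raise ValueError("target shares must be non-negative")
        if self.kcal_target <= 0:
            raise ValueError("kcal_target must be positive")


@dataclass(frozen=True)
class DietPath:
    """Projected per-capita intake and composition.

    ``kcal``: DataFrame, index years, columns regions.
    ``shares``: DataFrame, MultiIndex (year, region), columns food groups.
    """

    kcal: pd.DataFrame
    shares: pd.DataFrame


def interpolate_population(
    anchors: Mapping[str, Mapping[int, float]],
    years: Sequence[int] = YEARS,
) -> pd.DataFrame:
    """Linearly interpolate regional populations between anchor years.

    ``anchors`` maps region -> {year: persons} with at least two anchors
    per region.  Requests outside the anchor span raise ``ValueError``
    (no extrapolation).  Returns a DataFrame (index years, columns regions)
    exact at the anchors.
    """
    years = list(years)
    cols = {}
    for region, pts in anchors.items():
        if len(pts) < 2:
            raise ValueError(f"{region}: need at least two population anchors")
        xs = sorted(pts)
        ys = [pts[x] for x in xs]
        if any(v <= 0 for v in ys):
            raise ValueError(f"{region}: populations must be positive")
        if min(years) < xs[0] or max(years) > xs[-1]:
            raise ValueError(
                f"{region}: requested years extend outside the anchor span "
                f"[{xs[0]}, {xs[-1]}]; extrapolation is not supported"
            )
        cols[region] = np.interp(years, xs, ys)
    return pd.DataFrame(cols, index=pd.Index(years, name="year"))


def population_path_from_fixture(
    fixture: Iterable[RegionFixture], years: Sequence[int] = YEARS
) -> pd.DataFrame:
    anchors = {
        r.region_id: {2020: r.population_2020, 2050: r.population_2050}
        for r in fixture
    }
    return interpolate_population(anchors, years)


def baseline_diet(fixture: Iterable[RegionFixture]):
    """2020 baseline: (kcal Series by region, shares DataFrame region x group)."""
    fx = list(fixture)
    kcal = pd.Series(
        {r.region_id: r.kcal_2020 for r in fx}, name="kcal_per_person_day"
    )
    shares = pd.DataFrame(
        {r.region_id: [r.shares_2020[g] for g in BASE_GROUPS] for r in fx},
        index=list(BASE_GROUPS),
    ).T
    return kcal, shares


def convergence_spec_from_fixture(
    fixture: Iterable[RegionFixture],
    kcal_target: float = 3220.0,
    hold_oecd_kcal: bool = False,
) -> ConvergenceSpec:
    """Benchmark convergence spec: every region's composition converges to
    the OECD90+EU 2020 composition; intake converges to ``kcal_target``
    (or, with ``hold_oecd_kcal``, OECD90+EU keeps its richer baseline)."""
    target = oecd_target(fixture)
    return ConvergenceSpec(
        kcal_target=kcal_target,
        target_shares=dict(target.shares_2020),
        hold_baseline_kcal_regions=(target.region_id,) if hold_oecd_kcal else (),
    )


def _fraction(year: int, spec: ConvergenceSpec) -> float:
    if not spec.start_year <= year <= spec.end_year:
        raise ValueError(
            f"year {year} outside [{spec.start_year}, {spec.end_year}]"
        )
    return (year - spec.start_year) / (spec.end_year - spec.start_year)


def project_diet(
    baseline_kcal: pd.Series,
    baseline_shares: pd.DataFrame,
    spec: ConvergenceSpec,
    year: int,
):
    """Diet composition in one year: linear move from the 2020 baseline to
    the convergence target, exact at the endpoints.  Returns
    (kcal Series by region, shares DataFrame region x group)."""
    f = _fraction(year, spec)
    kcal = baseline_kcal * (1 - f) + spec.kcal_target * f
    for region in spec.hold_baseline_kcal_regions:
        if region in kcal.index:
            kcal[region] = baseline_kcal[region]
    target = pd.Series({g: spec.target_shares.get(g, 0.0) for g in BASE_GROUPS})
    shares = baseline_shares * (1 - f) + target * f
    # Convex combination of simplex points: renormalise only to absorb
    # floating-point drift, and assert non-negativity.
    if (shares.values < 0).any():
        raise ValueError("negative interpolated share")
    shares = shares.div(shares.sum(axis=1), axis=0)
    return kcal, shares


def project_diet_path(
    baseline_kcal: pd.Series,
    baseline_shares: pd.DataFrame,
    spec: ConvergenceSpec,
    years: Sequence[int] = YEARS,
) -> DietPath:
    kcal_rows, share_rows, idx = [], [], []
    for y in years:
        k, s = project_diet(baseline_kcal, baseline_shares, spec, y)
        kcal_rows.append(k)
        for region in s.index:
            idx.append((y, region))
            share_rows.append(s.loc[region])
    kcal = pd.DataFrame(kcal_rows, index=pd.Index(list(years), name="year"))
    shares = pd.DataFrame(
        share_rows,
        index=pd.MultiIndex.from_tuples(idx, names=["year", "region"]),
    )
    return DietPath(kcal=kcal, shares=shares)


def compute_demand(pop: pd.DataFrame, diet: DietPath) -> pd.DataFrame:
    """Evaluate GFD_jt = 365 * N_t * C_t * S_jt.

    Returns a DataFrame with MultiIndex (year, region) and one column per
    food group, in kcal/year.  Population and diet must cover identical
    region-years.
    """
    pop_years, pop_regions = set(pop.index), set(pop.columns)
    diet_years, diet_regions = set(diet.kcal.index), set(diet.kcal.columns)
    if pop_years != diet_years or pop_regions != diet_regions:
        raise ValueError("population and diet paths cover different region-years")

    idx = diet.shares.index
    n = pop.stack().reindex(idx)
    c = diet.kcal.stack().reindex(idx)
    demand = diet.shares.mul(365.0 * n * c, axis=0)
    demand.index.names = ["year", "region"]
    return demand


def demand_totals(demand: pd.DataFrame) -> pd.Series:
    """Total kcal/year per (year, region)."""
    return demand.sum(axis=1)


def global_demand_by_group(demand: pd.DataFrame) -> pd.DataFrame:
    """Global kcal/year by year x group (regions summed)."""
    return demand.groupby(level="year").sum()


def decompose_drivers(
    fixture: Iterable[RegionFixture],
    spec: ConvergenceSpec,
    emissions_fn: Callable[[pd.DataFrame], float],
    years: Sequence[int] = YEARS,
) -> dict[str, float]:
    """One-at-a-time decomposition of cumulative-emission growth drivers.

    Each driver (population, diet composition, per-capita intake) is in
    turn frozen at its 2020 value while the others follow their projected
    paths; its contribution is (BAU - counterfactual) / BAU, where both
    sides are evaluated by ``emissions_fn`` (a DemandTable -> cumulative
    GtCO2e map).  Contributions are reported independently and are not
    forced to sum to the total growth.
    """
    fx = list(fixture)
    kcal0, shares0 = baseline_diet(fx)
    pop = population_path_from_fixture(fx, years)
    path = project_diet_path(kcal0, shares0, spec, years)

    bau = emissions_fn(compute_demand(pop, path))

    # Frozen population: constant 2020 headcount.
    pop_frozen = pd.DataFrame(
        {r: np.full(len(list(years)), pop.loc[2020, r]) for r in pop.columns},
        index=pop.index,
    )
    # Frozen composition: 2020 shares, projected kcal.
    shares_frozen = DietPath(
        kcal=path.kcal,
        shares=pd.concat(
            {y: shares0 for y in years}, names=["year", "region"]
        ),
    )
    # Frozen intake: 2020 kcal, projected shares.
    kcal_frozen = DietPath(
        kcal=pd.DataFrame(
            {r: np.full(len(list(years)), kcal0[r]) for r in path.kcal.columns},
            index=path.kcal.index,
        ),
        shares=path.shares,
    )

    out = {}
    out["population"] = (bau - emissions_fn(compute_demand(pop_frozen, path))) / bau
    out["diet_change"] = (bau - emissions_fn(compute_demand(pop, shares_frozen))) / bau
    out["caloric_intake"] = (bau - emissions_fn(compute_demand(pop, kcal_frozen))) / bau
    return out
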