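"""End-to-end scenario runs, (start year x final share) sweeps, the
carbon-budget frontier, and one-at-a-time sensitivity analyses.

Scenario families
-----------------
BAU         Western-diet convergence, no adoption beyond the constant 2%
            alternative market share.
ALT_CE      ASF replaced by alternatives, calorie-matched.
ALT_PE      ASF replaced by alternatives, protein-matched.
PLANTS_CE   ASF replaced by the regional plant mix, calorie-matched
            (slow transition constant for every category).
PLANTS_PE   As PLANTS_CE but protein-matched.
EATLANCET   Diet composition and intake converge toward the EAT-Lancet
            healthy diet along a Gompertz path (fast constant), without
            extra substitution by alternatives.

Every family runs the same pipeline — population path, diet convergence,
demand (GFD = 365 N C S), adoption schedule, substitution, Table-style
emission factors — and reports annual and cumulative 2020-2050 GtCO2e.
BAU is the adoption pipeline evaluated at FA = 0, so "ALT_CE with FA = 0
equals BAU" holds as an identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import adoption, demand as dm, emissions as em
from .adoption import (
    ALPHA_HEALTHY_DIET,
    ALPHA_PLANT_ONLY,
    AdoptionParams,
    build_schedule,
    default_params,
    gompertz_share,
)
from .demand import YEARS, ConvergenceSpec
from .emissions import CarbonBudget, EmissionFactorTable, eat_lancet_spec
from .synthetic import RegionFixture

__all__ = [
    "FAMILIES",
    "ScenarioSpec",
    "EmissionsResult",
    "run_scenario",
    "sweep",
    "budget_frontier",
    "sensitivity",
]

FAMILIES: tuple[str, ...] = (
    "BAU",
    "ALT_CE",
    "ALT_PE",
    "PLANTS_CE",
    "PLANTS_PE",
    "EATLANCET",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to run one scenario."""

    family: str = "BAU"
    kcal_target: float = 3220.0
    composition: str = "PB"  # cultured split of alternatives: RS or PB
    fa: float = 0.9
    t_star: float = 2025.0
    s0: float = 0.02
    pb_mode: str = "endpoint27"
    hold_oecd_kcal: bool = False
    alpha: Mapping[str, float] | float | None = None
    ef: EmissionFactorTable | None = None
    healthy_shares: Mapping[str, float] | None = None
    years: tuple[int, ...] = YEARS

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError("fa must be in [0, 1]")
        if self.composition not in ("RS", "PB"):
            raise ValueError(f"unknown composition scenario {self.composition!r}")


@dataclass(frozen=True)
class EmissionsResult:
    scenario: str
    annual: pd.Series  # GtCO2e per year
    cumulative: float  # GtCO2e, 2020-2050 inclusive

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"scenario": self.scenario, "year": self.annual.index,
             "annual_gt": self.annual.values}
        )
        df["cumulative_gt"] = self.annual.cumsum().values
        return df


def _bau_demand(fixture: Sequence[RegionFixture], spec: ScenarioSpec) -> pd.DataFrame:
    kcal0, shares0 = dm.baseline_diet(fixture)
    conv = dm.convergence_spec_from_fixture(
        fixture, kcal_target=spec.kcal_target, hold_oecd_kcal=spec.hold_oecd_kcal
    )
    pop = dm.population_path_from_fixture(fixture, spec.years)
    path = dm.project_diet_path(kcal0, shares0, conv, spec.years)
    return dm.compute_demand(pop, path)


def _healthy_demand(fixture: Sequence[RegionFixture], spec: ScenarioSpec) -> pd.DataFrame:
    """EAT-Lancet family: blend the BAU diet path toward the healthy-diet
    target with a Gompertz weight (fast transition constant)."""
    kcal0, shares0 = dm.baseline_diet(fixture)
    conv = dm.convergence_spec_from_fixture(
        fixture, kcal_target=spec.kcal_target, hold_oecd_kcal=spec.hold_oecd_kcal
    )
    hd = eat_lancet_spec(spec.healthy_shares)
    pop = dm.population_path_from_fixture(fixture, spec.years)
    bau_path = dm.project_diet_path(kcal0, shares0, conv, spec.years)
    hd_path = dm.project_diet_path(kcal0, shares0, hd, spec.years)

    params = AdoptionParams(
        fa=spec.fa, t_star=spec.t_star, alpha=ALPHA_HEALTHY_DIET, s0=0.0
    )
    w = pd.Series(
        gompertz_share(np.asarray(list(spec.years), dtype=float), params),
        index=pd.Index(list(spec.years), name="year"),
    )
    kcal = bau_path.kcal.mul(1 - w, axis=0) + hd_path.kcal.mul(w, axis=0)
    w_rows = w.reindex(bau_path.shares.index.get_level_values("year")).to_numpy()
    shares = bau_path.shares.mul(1 - w_rows, axis=0) + hd_path.shares.mul(
        w_rows, axis=0
    )
    return dm.compute_demand(pop, dm.DietPath(kcal=kcal, shares=shares))


def _substituted_demand(
    base: pd.DataFrame, spec: ScenarioSpec, fa: float, t_star: float
) -> pd.DataFrame:
    family = spec.family
    ef = spec.ef or EmissionFactorTable.default()
    if family in ("PLANTS_CE", "PLANTS_PE"):
        alpha = spec.alpha if spec.alpha is not None else ALPHA_PLANT_ONLY
        target = "plants"
    else:
        alpha = spec.alpha
        target = "alternatives"
    params = default_params(fa=fa, t_star=t_star, alpha=alpha, s0=spec.s0)
    sched = build_schedule(
        params, scenario=spec.composition, years=spec.years, pb_mode=spec.pb_mode
    )
    if family in ("ALT_PE", "PLANTS_PE"):
        return em.substitute_PE(base, sched, target=target, ef=ef)
    return em.substitute_CE(base, sched, target=target, ef=ef)


def run_scenario(
    spec: ScenarioSpec, fixture: Sequence[RegionFixture]
) -> EmissionsResult:
    """Compose demand -> adoption -> substitution -> emissions."""
    ef = spec.ef or EmissionFactorTable.default()
    if spec.family == "EATLANCET":
        base = _healthy_demand(fixture, spec)
        # The constant 2% alternative market share is carved out here too,
        # so EATLANCET at FA=0 coincides with BAU.
        dem = _substituted_demand(base, replace(spec, family="ALT_CE"), 0.0, 2025.0)
    elif spec.family == "BAU":
        base = _bau_demand(fixture, spec)
        dem = _substituted_demand(base, replace(spec, family="ALT_CE"), 0.0, 2025.0)
    else:
        base = _bau_demand(fixture, spec)
        dem = _substituted_demand(base, spec, spec.fa, spec.t_star)
    annual = em.annual_emissions(dem, ef=ef, basis="kcal")
    return EmissionsResult(
        scenario=spec.family,
        annual=annual,
        cumulative=em.cumulative(annual, spec.years),
    )


def sweep(
    fixture: Sequence[RegionFixture],
    family: str,
    t_stars: Sequence[float] = tuple(range(2020, 2036)),
    fas: Sequence[float] | None = None,
    spec: ScenarioSpec | None = None,
) -> pd.DataFrame:
    """Grid of cumulative GtCO2e over adoption start year x final share.

    Returns a DataFrame indexed by t_star with one column per FA value.
    The demand stage is computed once per family; only the (cheap)
    substitution and emission stages run per cell.
    """
    if fas is None:
        fas = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    spec = replace(spec or ScenarioSpec(), family=family)
    ef = spec.ef or EmissionFactorTable.default()

    grid = pd.DataFrame(
        index=pd.Index(list(t_stars), name="t_star"),
        columns=pd.Index(list(fas), name="fa"),
        dtype=float,
    )
    if family == "EATLANCET":
        for t in t_stars:
            for fa in fas:
                res = run_scenario(replace(spec, fa=float(fa), t_star=float(t)), fixture)
                grid.loc[t, fa] = res.cumulative
        return grid

    base = _bau_demand(fixture, spec)
    for t in t_stars:
        for fa in fas:
            if family == "BAU":
                dem = _substituted_demand(
                    base, replace(spec, family="ALT_CE"), 0.0, 2025.0
                )
            else:
                dem = _substituted_demand(base, spec, float(fa), float(t))
            annual = em.annual_emissions(dem, ef=ef, basis="kcal")
            grid.loc[t, fa] = em.cumulative(annual, spec.years)
    return grid


def budget_frontier(
    grid: pd.DataFrame, budget: float | CarbonBudget = 390.0
) -> pd.DataFrame:
    """Minimal final replacement share meeting the budget, per start year.

    For each start year: ``fa_grid`` is the smallest FA grid point whose
    cumulative emissions stay within the budget (the conservative value to
    quote for feasibility); ``fa_interp`` linearly interpolates between
    the bracketing grid points; ``feasible`` is False when even the
    largest FA exceeds the budget (both FA columns are NaN there).
    """
    b = budget.food_budget if isinstance(budget, CarbonBudget) else float(budget)
    rows = []
    fas = np.asarray(grid.columns, dtype=float)
    for t, row in grid.iterrows():
        vals = row.to_numpy(dtype=float)
        ok = vals <= b
        if not ok.any():
            rows.append({"t_star": t, "fa_grid": np.nan, "fa_interp": np.nan,
                         "feasible": False})
            continue
        i = int(np.argmax(ok))  # first feasible FA (rows are non-increasing)
        fa_grid = fas[i]
        if i == 0:
            fa_interp = fas[0]
        else:
            x0, x1 = fas[i - 1], fas[i]
            y0, y1 = vals[i - 1], vals[i]
            fa_interp = x0 + (y0 - b) * (x1 - x0) / (y0 - y1) if y0 != y1 else x1
        rows.append({"t_star": t, "fa_grid": fa_grid, "fa_interp": fa_interp,
                     "feasible": True})
    return pd.DataFrame(rows).set_index("t_star")


#: Default one-at-a-time perturbation set for :func:`sensitivity`.
DEFAULT_PERTURBATIONS: tuple[str, ...] = (
    "base",
    "alpha_half",
    "alpha_double",
    "cultured_ef_x2",
    "cultured_ef_x3",
    "kcal_3515",
)


def sensitivity(
    fixture: Sequence[RegionFixture],
    spec: ScenarioSpec | None = None,
    perturbations: Iterable[str] = DEFAULT_PERTURBATIONS,
) -> pd.DataFrame:
    """Cumulative emissions under one-at-a-time parameter perturbations.

    Supported labels: ``base``; ``alpha_half`` / ``alpha_double`` (all
    categories, also per category as e.g. ``alpha_half:dairy``);
    ``cultured_ef_x2`` / ``cultured_ef_x3``; ``kcal_3515``.
    """
    spec = spec or ScenarioSpec(family="ALT_CE")
    ef = spec.ef or EmissionFactorTable.default()
    rows = []
    for label in perturbations:
        s = spec
        name, _, cat = label.partition(":")
        if name == "base":
            pass
        elif name in ("alpha_half", "alpha_double"):
            factor = 0.5 if name == "alpha_half" else 2.0
            amap = dict(adoption.ALPHA_DEFAULT)
            if spec.family in ("PLANTS_CE", "PLANTS_PE"):
                amap = {c: ALPHA_PLANT_ONLY for c in amap}
            if spec.alpha is not None:
                base_alpha = spec.alpha
                amap = (
                    dict(base_alpha)
                    if isinstance(base_alpha, Mapping)
                    else {c: float(base_alpha) for c in amap}
                )
            cats = [cat] if cat else list(amap)
            for c in cats:
                amap[c] = amap[c] * factor
            s = replace(spec, alpha=amap)
        elif name in ("cultured_ef_x2", "cultured_ef_x3"):
            factor = 2.0 if name.endswith("x2") else 3.0
            s = replace(spec, ef=ef.scaled(["cultured_meat_fish"], factor))
        elif name == "kcal_3515":
            s = replace(spec, kcal_target=3515.0)
        else:
            raise ValueError(f"unknown perturbation {label!r}")
        rows.append(
            {"perturbation": label,
             "cumulative_gt": run_scenario(s, fixture).cumulative}
        )
    return pd.DataFrame(rows).set_index("perturbation")
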