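"""Greenhouse-gas accounting for food demand.

Emission factors (kg CO2e per 1000 kcal and per 100 g protein) are fixed
per food group; the shipped defaults are mid-range literature values for
the ten base groups, the plant-based analogues and cultured meat/fish.
Because both factor bases describe the same food stream, the implied
protein density of a group is

    density = 0.1 * ef_kcal / ef_protein        [g protein per kcal]

and annual emissions computed on the kcal basis and on the protein basis
coincide for any group carrying both factors.  Sugar and oils & fats
carry no per-protein factor and are treated as zero-protein for
protein-equivalent bookkeeping.

Two substitution rules convert an adoption schedule into a new demand
table: caloric equivalence (CE) moves replaced ASF calories 1:1 into the
substitute groups (total kcal conserved exactly), protein equivalence
(PE) moves replaced ASF *protein* 1:1, so the substitute calories are
protein / density_substitute and total kcal generally rises (plant-based
substitutes are less protein-dense than the meat they replace).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adoption import AdoptionSchedule
from .demand import YEARS, ConvergenceSpec
from .groups import (
    ASF_GROUPS,
    CATEGORY_ALTERNATIVES,
    CATEGORY_SOURCES,
    PLANT_GROUPS,
)

__all__ = [
    "EmissionFactorTable",
    "CarbonBudget",
    "protein_density",
    "substitute_CE",
    "substitute_PE",
    "annual_emissions",
    "cumulative",
    "budget_gap",
    "eat_lancet_spec",
    "DEFAULT_EAT_LANCET_SHARES",
]

_DEFAULT_EF_KCAL = {
    "sugar": 0.7, "oils_fats": 0.5, "fruits_veg": 1.2, "starchy_roots": 1.0,
    "pulses": 0.4, "cereals": 0.8, "eggs": 3.2, "dairy": 5.4, "meat": 9.9,
    "fish": 9.5, "pb_eggs": 0.7, "pb_dairy": 0.7, "pb_meat_fish": 0.8,
    "cultured_meat_fish": 1.2,
}
_DEFAULT_EF_PROTEIN = {
    "fruits_veg": 5.4, "starchy_roots": 7.2, "pulses": 0.6, "cereals": 3.5,
    "eggs": 4.2, "dairy": 9.7, "meat": 13.6, "fish": 7.2, "pb_eggs": 1.6,
    "pb_dairy": 1.8, "pb_meat_fish": 1.6, "cultured_meat_fish": 2.5,
}


@dataclass(frozen=True)
class EmissionFactorTable:
    """Per-group emission factors.

    ``ef_kcal``: kg CO2e per 1000 kcal; ``ef_protein``: kg CO2e per 100 g
    protein (absent for sugar and oils & fats).
    """

    ef_kcal: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EF_KCAL))
    ef_protein: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EF_PROTEIN)
    )

    def __post_init__(self):
        for name, table in (("ef_kcal", self.ef_kcal), ("ef_protein", self.ef_protein)):
            for g, v in table.items():
                if v <= 0:
                    raise ValueError(f"{name}[{g!r}] must be positive, got {v}")

    @classmethod
    def default(cls) -> "EmissionFactorTable":
        return cls()

    def scaled(self, groups: Iterable[str], factor: float) -> "EmissionFactorTable":
        """A copy with both factor bases of ``groups`` multiplied by
        ``factor`` (used e.g. for the cultured-factor x2/x3 sensitivity)."""
        groups = set(groups)
        return EmissionFactorTable(
            ef_kcal={g: v * factor if g in groups else v
                     for g, v in self.ef_kcal.items()},
            ef_protein={g: v * factor if g in groups else v
                        for g, v in self.ef_protein.items()},
        )

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for g in self.ef_kcal:
            rows.append(
                {"group": g, "ef_per_1000kcal": self.ef_kcal[g],
                 "ef_per_100g_protein": self.ef_protein.get(g, "")}
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionFactorTable":
        df = pd.read_csv(path)
        ef_kcal = dict(zip(df["group"], df["ef_per_1000kcal"].astype(float)))
        ef_protein = {
            g: float(v)
            for g, v in zip(df["group"], df["ef_per_100g_protein"])
            if pd.notna(v) and str(v) != ""
        }
        return cls(ef_kcal=ef_kcal, ef_protein=ef_protein)


def protein_density(group: str, ef: EmissionFactorTable | None = None) -> float:
    """Protein density in g per kcal, implied by the two factor bases."""
    ef = ef or EmissionFactorTable.default()
    if group not in ef.ef_kcal:
        raise KeyError(f"no emission factor for group {group!r}")
    if group not in ef.ef_protein:
        raise KeyError(
            f"group {group!r} has no per-protein emission factor; "
            "its protein density is undefined"
        )
    return 0.1 * ef.ef_kcal[group] / ef.ef_protein[group]


def _density_map(ef: EmissionFactorTable, groups: Iterable[str]) -> dict[str, float]:
    """Protein densities with sugar/oils-style zero-protein groups mapped
    to 0 (they carry no per-protein factor)."""
    return {
        g: protein_density(g, ef) if g in ef.ef_protein else 0.0 for g in groups
    }


def _year_values(series: pd.Series, index: pd.MultiIndex) -> np.ndarray:
    return series.reindex(index.get_level_values("year")).to_numpy()


def _plant_weights(demand: pd.DataFrame, values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise weights over plant groups proportional to ``values``
    (kcal or protein of the pre-substitution demand)."""
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cannot redistribute to plants: zero plant demand")
    return values.div(totals, axis=0)


def substitute_CE(
    demand: pd.DataFrame,
    schedule: AdoptionSchedule,
    target: str = "alternatives",
    ef: EmissionFactorTable | None = None,
) -> pd.DataFrame:
    """Caloric-equivalent substitution: replaced ASF calories move 1:1 to
    the matching alternatives (plant-based/cultured split per schedule)
    or, with ``target="plants"``, into the region's existing plant groups
    proportional to their current calorie shares.  Total kcal per
    region-year is conserved exactly.
    """
    if target not in ("alternatives", "plants"):
        raise ValueError(f"unknown substitution target {target!r}")
    out = demand.copy()
    plant_w = _plant_weights(demand, demand[list(PLANT_GROUPS)]) \
        if target == "plants" else None
    cf = _year_values(schedule.cultured, demand.index)
    for cat, sources in CATEGORY_SOURCES.items():
        f = _year_values(schedule.replaced[cat], demand.index)
        moved = demand[list(sources)].mul(f, axis=0)
        out[list(sources)] = out[list(sources)] - moved
        moved_total = moved.sum(axis=1)
        if target == "plants":
            out[list(PLANT_GROUPS)] = out[list(PLANT_GROUPS)].add(
                plant_w.mul(moved_total, axis=0)
            )
        else:
            pb, cult = CATEGORY_ALTERNATIVES[cat]
            if cult is not None:
                out[cult] = out.get(cult, 0.0) + moved_total * cf
                out[pb] = out.get(pb, 0.0) + moved_total * (1.0 - cf)
            else:
                out[pb] = out.get(pb, 0.0) + moved_total
    return out


def substitute_PE(
    demand: pd.DataFrame,
    schedule: AdoptionSchedule,
    target: str = "alternatives",
    ef: EmissionFactorTable | None = None,
) -> pd.DataFrame:
    """Protein-equivalent substitution: the protein in replaced ASF
    calories is supplied by the substitute at the substitute's own protein
    density, conserving total protein per region-year exactly (total kcal
    may rise).  With ``target="plants"`` the protein is redistributed over
    the region's plant groups proportional to their current protein
    content (zero-protein groups receive nothing).
    """
    if target not in ("alternatives", "plants"):
        raise ValueError(f"unknown substitution target {target!r}")
    ef = ef or EmissionFactorTable.default()
    dens = _density_map(ef, demand.columns.union(
        [g for pair in CATEGORY_ALTERNATIVES.values() for g in pair if g]
    ))
    out = demand.copy()
    if target == "plants":
        plant_protein = demand[list(PLANT_GROUPS)].mul(
            pd.Series({g: dens[g] for g in PLANT_GROUPS})
        )
        plant_w = _plant_weights(demand, plant_protein)
    cf = _year_values(schedule.cultured, demand.index)
    for cat, sources in CATEGORY_SOURCES.items():
        f = _year_values(schedule.replaced[cat], demand.index)
        moved_kcal = demand[list(sources)].mul(f, axis=0)
        out[list(sources)] = out[list(sources)] - moved_kcal
        protein = moved_kcal.mul(
            pd.Series({g: dens[g] for g in sources})
        ).sum(axis=1)
        if target == "plants":
            protein_per_group = plant_w.mul(protein, axis=0)
            for g in PLANT_GROUPS:
                if dens[g] > 0:
                    out[g] = out[g] + protein_per_group[g] / dens[g]
                elif (protein_per_group[g] != 0).any():  # pragma: no cover
                    raise ValueError(f"protein routed to zero-protein group {g!r}")
        else:
            pb, cult = CATEGORY_ALTERNATIVES[cat]
            splits = [(pb, 1.0 - cf), (cult, cf)] if cult else [(pb, 1.0)]
            for alt, frac in splits:
                if dens.get(alt, 0.0) <= 0:
                    raise ValueError(
                        f"substitute group {alt!r} has no protein factor"
                    )
                out[alt] = out.get(alt, 0.0) + protein * frac / dens[alt]
    return out


def annual_emissions(
    demand: pd.DataFrame,
    ef: EmissionFactorTable | None = None,
    basis: str = "kcal",
) -> pd.Series:
    """Annual global emissions in GtCO2e per year.

    kcal basis: sum_j demand_j / 1000 * ef_kcal_j; protein basis:
    sum_j protein_j / 100 * ef_protein_j (identical for groups carrying
    both factors; zero-protein groups contribute nothing on the protein
    basis).  1 Gt = 1e12 kg.
    """
    ef = ef or EmissionFactorTable.default()
    missing = [g for g in demand.columns if g not in ef.ef_kcal]
    if missing:
        raise KeyError(f"no emission factor for groups {missing}")
    if basis == "kcal":
        factors = pd.Series({g: ef.ef_kcal[g] / 1000.0 for g in demand.columns})
    elif basis == "protein":
        dens = _density_map(ef, demand.columns)
        factors = pd.Series(
            {g: dens[g] * ef.ef_protein.get(g, 0.0) / 100.0 for g in demand.columns}
        )
    else:
        raise ValueError(f"unknown basis {basis!r}")
    kg = demand.mul(factors).sum(axis=1).groupby(level="year").sum()
    return kg / 1e12


def cumulative(annual: pd.Series, years: Sequence[int] = YEARS) -> float:
    """Cumulative GtCO2e over ``years`` (default 2020..2050 inclusive,
    31 annual terms).  Raises if any year is missing."""
    missing = [y for y in years if y not in annual.index]
    if missing:
        raise ValueError(f"annual series is missing years {missing}")
    return float(annual.loc[list(years)].sum())


@dataclass(frozen=True)
class CarbonBudget:
    """Remaining carbon budget and the food sector's slice of it."""

    total_remaining: float = 1170.0
    food_fraction: float = 1.0 / 3.0

    @property
    def food_budget(self) -> float:
        return self.total_remaining * self.food_fraction


def budget_gap(cumulative_gt: float, budget: CarbonBudget | None = None) -> float:
    """Cumulative emissions minus the food-sector budget (positive means
    the budget is exceeded)."""
    budget = budget or CarbonBudget()
    return cumulative_gt - budget.food_budget


#: Placeholder healthy-diet composition (Mediterranean-style: ASF capped
#: at 13% of calories).  The authoritative targets live in the external
#: EAT-Lancet report; results under this default are property-checked,
#: not value-anchored.
DEFAULT_EAT_LANCET_SHARES: dict[str, float] = {
    "sugar": 0.05, "oils_fats": 0.18, "fruits_veg": 0.18, "starchy_roots": 0.04,
    "pulses": 0.10, "cereals": 0.32, "eggs": 0.01, "dairy": 0.06,
    "meat": 0.03, "fish": 0.03,
}


def eat_lancet_spec(
    target_shares: Mapping[str, float] | None = None,
    kcal_target: float = 2500.0,
) -> ConvergenceSpec:
    """Convergence spec for the EAT-Lancet healthy diet (2500 kcal/person/
    day and an ASF-light composition)."""
    shares = dict(target_shares if target_shares is not None
                  else DEFAULT_EAT_LANCET_SHARES)
    if not shares:
        raise ValueError("healthy-diet target shares are required")
    total = sum(shares.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"healthy-diet shares sum to {total}, expected 1")
    return ConvergenceSpec(kcal_target=kcal_target, target_shares=shares)
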