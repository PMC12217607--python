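"""Synthetic regional population / baseline-diet fixtures.

Real inputs to this kind of analysis are FAO food-balance sheets and UN
population projections.  This module replaces them with a five-region
fixture whose *global* population-weighted aggregates are calibrated
exactly to configurable anchors — by default the 2020 world picture used
throughout the package: 3220 kcal/person/day, calorie shares of 82%
plants, 8% meat, 7% dairy, 1% fish (eggs take the 2% residual), and a
population of 7.8 billion growing to 9.71 billion by 2050.

Regional heterogeneity is drawn from seeded perturbations around fixed
archetypes and then rescaled to hit the global anchors exactly:

* regional populations are scaled proportionally to the 2020/2050 totals;
* regional diet-share matrices are adjusted by iterative proportional
  fitting (rows sum to one, population-weighted columns hit the anchors);
* regional caloric intakes are scaled by a single factor solved linearly.

The OECD90+EU region is pinned: its composition (ASF 24.9% of calories,
meat 11.6%) and intake (3515 kcal) double as the 2050 convergence target
of the business-as-usual diet projection, so it is excluded from the
rescaling and the other regions absorb the calibration.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .groups import ASF_GROUPS, BASE_GROUPS, PLANT_GROUPS

__all__ = [
    "RegionFixture",
    "CalibrationError",
    "FixtureValidationError",
    "REGIONS",
    "DEFAULT_GLOBAL_SHARES",
    "generate_fixture",
    "write_fixture",
    "read_fixture",
    "global_aggregates",
    "oecd_target",
]

REGIONS: tuple[str, ...] = (
    "OECD90+EU",
    "Asia",
    "LatinAmerica",
    "SubSaharanAfrica",
    "Other",
)

PINNED_REGION = "OECD90+EU"

#: Default global 2020 anchors (fractions of caloric intake).  The eggs
#: share is the residual left by the plants/meat/dairy/fish shares.
DEFAULT_GLOBAL_SHARES: dict[str, float] = {
    "plants": 0.82,
    "meat": 0.08,
    "dairy": 0.07,
    "fish": 0.01,
    "eggs": 0.02,
}

# Regional archetypes: population (persons, 2020 and 2050 pre-scaling),
# caloric intake, and calorie shares over the ten base groups.  OECD90+EU
# is the back-solved 2050 convergence target (ASF 24.9%, meat 11.6%,
# 3515 kcal); the other four are free, realism-motivated starting points
# that the calibration reshapes.
_ARCHETYPES: dict[str, dict] = {
    "OECD90+EU": dict(
        pop2020=1.35e9,
        pop2050=1.40e9,
        kcal=3515.0,
        shares={
            "sugar": 0.120, "oils_fats": 0.165, "fruits_veg": 0.098,
            "starchy_roots": 0.045, "pulses": 0.038, "cereals": 0.285,
            "eggs": 0.023, "dairy": 0.098, "meat": 0.116, "fish": 0.012,
        },
    ),
    "Asia": dict(
        pop2020=4.35e9,
        pop2050=4.90e9,
        kcal=3130.0,
        shares={
            "sugar": 0.055, "oils_fats": 0.085, "fruits_veg": 0.075,
            "starchy_roots": 0.045, "pulses": 0.045, "cereals": 0.545,
            "eggs": 0.025, "dairy": 0.040, "meat": 0.070, "fish": 0.015,
        },
    ),
    "LatinAmerica": dict(
        pop2020=0.65e9,
        pop2050=0.76e9,
        kcal=3260.0,
        shares={
            "sugar": 0.130, "oils_fats": 0.110, "fruits_veg": 0.075,
            "starchy_roots": 0.040, "pulses": 0.050, "cereals": 0.410,
            "eggs": 0.020, "dairy": 0.060, "meat": 0.095, "fish": 0.010,
        },
    ),
    "SubSaharanAfrica": dict(
        pop2020=1.10e9,
        pop2050=2.18e9,
        kcal=2450.0,
        shares={
            "sugar": 0.075, "oils_fats": 0.100, "fruits_veg": 0.060,
            "starchy_roots": 0.200, "pulses": 0.065, "cereals": 0.430,
            "eggs": 0.005, "dairy": 0.020, "meat": 0.035, "fish": 0.010,
        },
    ),
    "Other": dict(
        pop2020=0.35e9,
        pop2050=0.47e9,
        kcal=3050.0,
        shares={
            "sugar": 0.090, "oils_fats": 0.105, "fruits_veg": 0.080,
            "starchy_roots": 0.050, "pulses": 0.040, "cereals": 0.480,
            "eggs": 0.015, "dairy": 0.050, "meat": 0.075, "fish": 0.015,
        },
    ),
}


class CalibrationError(ValueError):
    """Raised when the requested global anchors cannot be met."""


class FixtureValidationError(ValueError):
    """Raised when a fixture (in memory or on disk) violates an invariant."""


@dataclass(frozen=True)
class RegionFixture:
    """One region's 2020 baseline and population endpoints."""

    region_id: str
    population_2020: float
    population_2050: float
    kcal_2020: float
    shares_2020: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.population_2020 <= 0 or self.population_2050 <= 0:
            raise FixtureValidationError(
                f"{self.region_id}: populations must be positive"
            )
        if self.kcal_2020 <= 0:
            raise FixtureValidationError(f"{self.region_id}: kcal must be positive")
        if set(self.shares_2020) != set(BASE_GROUPS):
            raise FixtureValidationError(
                f"{self.region_id}: shares must cover exactly the base groups"
            )
        if any(v < 0 for v in self.shares_2020.values()):
            raise FixtureValidationError(f"{self.region_id}: negative share")
        total = sum(self.shares_2020.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise FixtureValidationError(
                f"{self.region_id}: shares sum to {total!r}, expected 1"
            )


def _expand_anchor_shares(
    anchors: Mapping[str, float], plant_mix: Mapping[str, float]
) -> dict[str, float]:
    """Expand a {plants, meat, dairy, fish, eggs} anchor to the ten base
    groups, splitting the plants total by ``plant_mix`` (fractions within
    plants).  Ten-group anchors pass through unchanged."""
    if set(anchors) == set(BASE_GROUPS):
        return dict(anchors)
    if set(anchors) != {"plants", *ASF_GROUPS}:
        raise ValueError(
            "global_shares must map either the ten base groups or "
            "{plants, eggs, dairy, meat, fish}"
        )
    mix_total = sum(plant_mix[g] for g in PLANT_GROUPS)
    out = {g: anchors["plants"] * plant_mix[g] / mix_total for g in PLANT_GROUPS}
    out.update({g: anchors[g] for g in ASF_GROUPS})
    return out


def generate_fixture(
    seed: int,
    global_kcal: float = 3220.0,
    global_shares: Mapping[str, float] | None = None,
    population_2050_total: float = 9.71e9,
    population_2020_total: float = 7.8e9,
    regions: Sequence[str] | None = None,
    noise: float = 0.05,
) -> list[RegionFixture]:
    """Generate a calibrated regional fixture.

    Deterministic for a fixed ``seed``.  ``global_shares`` may be given at
    the five-group level (``plants`` plus the four ASF groups) or over all
    ten base groups; it must sum to one.  Raises :class:`CalibrationError`
    when an anchor is infeasible (e.g. a group share that the pinned
    OECD90+EU row already exceeds on its own).
    """
    if population_2050_total <= 0 or population_2020_total <= 0:
        raise ValueError("population totals must be positive")
    anchors_in = dict(global_shares or DEFAULT_GLOBAL_SHARES)
    if not math.isclose(sum(anchors_in.values()), 1.0, abs_tol=1e-9):
        raise ValueError("global_shares must sum to 1")
    region_ids = tuple(regions) if regions is not None else REGIONS
    unknown = set(region_ids) - set(_ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown regions: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = len(region_ids)
    groups = list(BASE_GROUPS)
    shares = np.array(
        [[_ARCHETYPES[r]["shares"][g] for g in groups] for r in region_ids]
    )
    kcal = np.array([_ARCHETYPES[r]["kcal"] for r in region_ids], dtype=float)
    pop20 = np.array([_ARCHETYPES[r]["pop2020"] for r in region_ids], dtype=float)
    pop50 = np.array([_ARCHETYPES[r]["pop2050"] for r in region_ids], dtype=float)

    pinned = np.array([r == PINNED_REGION for r in region_ids])
    free = ~pinned

    # Seeded heterogeneity on the free regions, renormalised row-wise.
    if noise > 0 and free.any():
        shares[free] *= rng.lognormal(0.0, noise, size=(free.sum(), len(groups)))
        shares[free] /= shares[free].sum(axis=1, keepdims=True)
        kcal[free] *= 1.0 + rng.uniform(-noise, noise, size=free.sum())

    # Populations: proportional scaling to the requested totals (exact).
    pop20 *= population_2020_total / pop20.sum()
    pop50 *= population_2050_total / pop50.sum()
    w = pop20 / pop20.sum()

    # Ten-group anchors; a five-group input splits plants by the current
    # population-weighted plant mix.
    plant_mix = {g: float(w @ shares[:, i]) for i, g in enumerate(groups)
                 if g in PLANT_GROUPS}
    anchors = _expand_anchor_shares(anchors_in, plant_mix)
    a = np.array([anchors[g] for g in groups])

    # Column targets for the free block after removing the pinned rows.
    w_free = w[free].sum()
    if w_free <= 0:
        raise CalibrationError("no free regions available for calibration")
    pinned_contrib = (w[pinned, None] * shares[pinned]).sum(axis=0)
    col_targets = (a - pinned_contrib) / w_free
    for g, t in zip(groups, col_targets):
        if t < 0:
            raise CalibrationError(
                f"anchor for {g!r} ({anchors[g]:.4f}) is below the pinned "
                "regions' contribution; calibration infeasible"
            )

    # IPF: weighted column sums -> targets, rows -> simplex.
    v = w[free] / w_free
    block = shares[free]
    for _ in range(10_000):
        col = v @ block
        if np.any(col <= 0):
            raise CalibrationError(
                "a requested share has no support in the regional draws"
            )
        block = block * (col_targets / col)
        block /= block.sum(axis=1, keepdims=True)
        if np.abs(v @ block - col_targets).max() < 1e-13:
            break
    else:  # pragma: no cover - IPF converges in a handful of sweeps here
        raise CalibrationError("share calibration did not converge")
    shares[free] = block

    # Caloric intake: one multiplicative factor on the free regions.
    pinned_kcal = float(w[pinned] @ kcal[pinned])
    free_kcal = float(w[free] @ kcal[free])
    lam = (global_kcal - pinned_kcal) / free_kcal
    if lam <= 0:
        raise CalibrationError(
            f"global kcal anchor {global_kcal} is below the pinned regions' "
            "contribution; calibration infeasible"
        )
    kcal[free] *= lam

    out = []
    for i, r in enumerate(region_ids):
        fx = RegionFixture(
            region_id=r,
            population_2020=float(pop20[i]),
            population_2050=float(pop50[i]),
            kcal_2020=float(kcal[i]),
            shares_2020={g: float(shares[i, j]) for j, g in enumerate(groups)},
        )
        fx.validate()
        out.append(fx)
    return out


def global_aggregates(fixture: Iterable[RegionFixture]):
    """Population-weighted 2020 global mean intake and calorie shares.

    Returns ``(kcal, shares_dict)``.
    """
    fx = list(fixture)
    w = np.array([r.population_2020 for r in fx])
    w = w / w.sum()
    kcal = float(sum(wi * r.kcal_2020 for wi, r in zip(w, fx)))
    shares = {
        g: float(sum(wi * r.shares_2020[g] for wi, r in zip(w, fx)))
        for g in BASE_GROUPS
    }
    return kcal, shares


def oecd_target(fixture: Iterable[RegionFixture]) -> RegionFixture:
    """The pinned OECD90+EU region, whose 2020 baseline doubles as the
    2050 convergence target of the business-as-usual projection."""
    for r in fixture:
        if r.region_id == PINNED_REGION:
            return r
    raise ValueError(f"fixture has no {PINNED_REGION} region")


_COLUMNS = ["region", "year", "population", "kcal_per_person_day", "group", "share"]


def write_fixture(fixture: Iterable[RegionFixture], path: str | Path) -> None:
    """Write a fixture as long-format CSV (schema: region, year,
    population, kcal_per_person_day, group, share).  2020 rows carry one
    food group each; 2050 rows carry only the population anchor."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(_COLUMNS)
        for r in fixture:
            for g in BASE_GROUPS:
                wr.writerow(
                    [r.region_id, 2020, f"{r.population_2020:.17g}",
                     f"{r.kcal_2020:.17g}", g, f"{r.shares_2020[g]:.17g}"]
                )
            wr.writerow([r.region_id, 2050, f"{r.population_2050:.17g}", "", "", ""])


def read_fixture(path: str | Path) -> list[RegionFixture]:
    """Read and validate a fixture CSV written by :func:`write_fixture`.

    Raises :class:`FixtureValidationError` (with the offending row or
    region) on schema or invariant violations.
    """
    path = Path(path)
    rows: list[dict] = []
    with path.open(newline="") as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or list(rd.fieldnames) != _COLUMNS:
            raise FixtureValidationError(
                f"bad header: expected {_COLUMNS}, got {rd.fieldnames}"
            )
        for i, row in enumerate(rd, start=2):
            rows.append((i, row))

    per_region: dict[str, dict] = {}
    for lineno, row in rows:
        region = row["region"]
        try:
            year = int(row["year"])
            pop = float(row["population"])
        except (TypeError, ValueError) as exc:
            raise FixtureValidationError(f"row {lineno}: {exc}") from exc
        if pop <= 0:
            raise FixtureValidationError(f"row {lineno}: non-positive population")
        rec = per_region.setdefault(region, {"shares": {}})
        if year == 2020:
            rec["population_2020"] = pop
            kcal = float(row["kcal_per_person_day"])
            if kcal <= 0:
                raise FixtureValidationError(f"row {lineno}: non-positive kcal")
            rec["kcal_2020"] = kcal
            share = float(row["share"])
            if share < 0:
                raise FixtureValidationError(f"row {lineno}: negative share")
            rec["shares"][row["group"]] = share
        elif year == 2050:
            rec["population_2050"] = pop
        else:
            raise FixtureValidationError(f"row {lineno}: unexpected year {year}")

    out = []
    for region, rec in per_region.items():
        missing = {"population_2020", "population_2050", "kcal_2020"} - set(rec)
        if missing:
            raise FixtureValidationError(f"{region}: missing {sorted(missing)}")
        fx = RegionFixture(
            region_id=region,
            population_2020=rec["population_2020"],
            population_2050=rec["population_2050"],
            kcal_2020=rec["kcal_2020"],
            shares_2020=rec["shares"],
        )
        fx.validate()
        out.append(fx)
    return out
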