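"""Gompertz adoption of alternatives to animal-source foods.

The fraction of an ASF category replaced by alternatives follows a
displaced Gompertz S-curve

    share(t) = S0 + FA * exp(-b * exp(-alpha * (t - t*)))      for t >= t*
    share(t) = S0                                              for t <  t*

with S0 the 2020 alternative market share (2% by default), FA the final
replacement (saturation) share, alpha the speed-of-adoption constant,
t* the adoption start year (the year alternatives reach taste/price/
attribute parity with the incumbent), and displacement b = t* minus a
base year (2020 by default).  The curve is flat at S0 before parity,
accelerates after it, and saturates at S0 + FA (capped at 1).

Benchmark speeds are borrowed from the wind/solar energy transition:
alpha = 0.18 (meat & fish alternatives, slowest), 0.73 (dairy, fastest),
0.46 (eggs, average).  A transition to plant-only diets uses the slow
constant 0.18 for every category; the EAT-Lancet healthy-diet transition
uses the fast constant 0.73.

Alternatives to meat/fish are split between plant-based and cultured
products by a composition scenario: "RS" (rapid shift to cultured:
cultured products enter in 2026 and grow linearly to two-thirds of the
alternative meat market by 2050) or "PB" (mostly plant-based: cultured
products enter after 2033).  Dairy and egg alternatives are always
plant-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .groups import ADOPTION_CATEGORIES

__all__ = [
    "AdoptionParams",
    "AdoptionSchedule",
    "ALPHA_DEFAULT",
    "ALPHA_PLANT_ONLY",
    "ALPHA_HEALTHY_DIET",
    "gompertz_share",
    "cultured_fraction",
    "build_schedule",
    "default_params",
]

#: Benchmark speed-of-adoption constants per ASF category (1/yr).
ALPHA_DEFAULT: dict[str, float] = {"meat_fish": 0.18, "dairy": 0.73, "eggs": 0.46}
#: Slow constant used for the transition to plant-only diets.
ALPHA_PLANT_ONLY: float = 0.18
#: Fast constant used for the EAT-Lancet healthy-diet transition.
ALPHA_HEALTHY_DIET: float = 0.73

RS_CULTURED_START = 2026
RS_CULTURED_END_SHARE = 2.0 / 3.0
PB_CULTURED_START = 2033
PB_CULTURED_END_SHARE = 0.27  # of all alternatives by 2050


@dataclass(frozen=True)
class AdoptionParams:
    """Gompertz parameters for one ASF category."""

    fa: float
    t_star: float
    alpha: float
    s0: float = 0.02
    displacement_base_year: float = 2020.0

    def __post_init__(self):
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError("final replacement share FA must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.s0 < 1.0:
            raise ValueError("initial share S0 must be in [0, 1)")
        if self.t_star < self.displacement_base_year:
            raise ValueError("adoption start year precedes the displacement base")


def gompertz_share(year, params: AdoptionParams):
    """Replaced fraction in ``year`` (scalar or array).

    Flat at S0 before the start year; displaced Gompertz afterwards, with
    displacement b = t_star - displacement_base_year and saturation at
    min(S0 + FA, 1).  Non-decreasing in year.
    """
    year = np.asarray(year, dtype=float)
    b = params.t_star - params.displacement_base_year
    curve = params.s0 + params.fa * np.exp(
        -b * np.exp(-params.alpha * (year - params.t_star))
    )
    out = np.where(year < params.t_star, params.s0, np.minimum(curve, 1.0))
    return out if out.ndim else float(out)


def cultured_fraction(year, scenario: str = "PB", pb_mode: str = "endpoint27"):
    """Cultured products' fraction of the alternative meat/fish market.

    RS: zero before 2026, then linear to two-thirds at 2050.
    PB: zero before 2033, then linear; by default the slope is set so the
    fraction reaches 27% of all alternatives in 2050 (``endpoint27``);
    ``pb_mode="quarter_slope"`` instead uses literally one quarter of the
    RS slope (which ends near 11.8% in 2050).
    """
    year = np.asarray(year, dtype=float)
    rs_slope = RS_CULTURED_END_SHARE / (2050 - RS_CULTURED_START)
    if scenario == "RS":
        frac = (year - RS_CULTURED_START) * rs_slope
    elif scenario == "PB":
        if pb_mode == "endpoint27":
            slope = PB_CULTURED_END_SHARE / (2050 - PB_CULTURED_START)
        elif pb_mode == "quarter_slope":
            slope = rs_slope / 4.0
        else:
            raise ValueError(f"unknown pb_mode {pb_mode!r}")
        frac = (year - PB_CULTURED_START) * slope
    else:
        raise ValueError(f"unknown composition scenario {scenario!r}")
    out = np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AdoptionSchedule:
    """Replaced fractions per ASF category and year, plus the cultured
    split of meat/fish alternatives.

    ``replaced``: DataFrame, index years, columns adoption categories.
    ``cultured``: Series, index years (fraction of meat/fish alternatives
    supplied by cultured products; dairy/egg alternatives are plant-based).
    """

    replaced: pd.DataFrame
    cultured: pd.Series


def default_params(
    fa: float,
    t_star: float,
    alpha: Mapping[str, float] | float | None = None,
    s0: float = 0.02,
) -> dict[str, AdoptionParams]:
    """Per-category parameter set; ``alpha`` may be one constant for all
    categories (e.g. the plant-only transition), a map, or None for the
    benchmark speeds."""
    if alpha is None:
        amap = dict(ALPHA_DEFAULT)
    elif isinstance(alpha, Mapping):
        amap = {c: alpha[c] for c in ADOPTION_CATEGORIES}
    else:
        amap = {c: float(alpha) for c in ADOPTION_CATEGORIES}
    return {
        c: AdoptionParams(fa=fa, t_star=t_star, alpha=amap[c], s0=s0)
        for c in ADOPTION_CATEGORIES
    }


def build_schedule(
    params: Mapping[str, AdoptionParams],
    scenario: str = "PB",
    years: Sequence[int] = tuple(range(2020, 2051)),
    pb_mode: str = "endpoint27",
) -> AdoptionSchedule:
    """Evaluate the Gompertz curves and cultured split on a year grid."""
    missing = set(ADOPTION_CATEGORIES) - set(params)
    if missing:
        raise ValueError(f"missing adoption parameters for {sorted(missing)}")
    years_idx = pd.Index(list(years), name="year")
    replaced = pd.DataFrame(
        {c: gompertz_share(np.asarray(years_idx), params[c]) for c in ADOPTION_CATEGORIES},
        index=years_idx,
    )
    cultured = pd.Series(
        cultured_fraction(np.asarray(years_idx), scenario, pb_mode),
        index=years_idx,
        name="cultured_fraction",
    )
    return AdoptionSchedule(replaced=replaced, cultured=cultured)
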