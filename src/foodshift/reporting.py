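"""CSV emitters and an optional heatmap for scenario results."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .adoption import AdoptionSchedule
from .scenarios import EmissionsResult


def write_demand_csv(demand: pd.DataFrame, path: str | Path) -> None:
    """Long format: region, year, group, kcal_per_year."""
    long = (
        demand.stack()
        .rename("kcal_per_year")
        .rename_axis(["year", "region", "group"])
        .reset_index()[["region", "year", "group", "kcal_per_year"]]
    )
    long.to_csv(path, index=False)


def read_demand_csv(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    return long.pivot_table(
        index=["year", "region"], columns="group", values="kcal_per_year"
    ).rename_axis(columns=None)


def write_schedule_csv(schedule: AdoptionSchedule, path: str | Path) -> None:
    """Long format: category, year, replaced_fraction, cultured_fraction.

    The cultured split applies to the meat/fish category only; it is
    repeated per row for convenience."""
    long = (
        schedule.replaced.stack()
        .rename("replaced_fraction")
        .rename_axis(["year", "category"])
        .reset_index()
    )
    long["cultured_fraction"] = long["year"].map(schedule.cultured)
    long[["category", "year", "replaced_fraction", "cultured_fraction"]].to_csv(
        path, index=False
    )


def write_results_csv(results: Iterable[EmissionsResult], path: str | Path) -> None:
    """Long format: scenario, year, annual_gt, cumulative_gt."""
    pd.concat([r.to_frame() for r in results], ignore_index=True).to_csv(
        path, index=False
    )


def write_grid_csv(grids: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Long format: family, start_year, final_share, cumulative_gt."""
    rows = []
    for family, grid in grids.items():
        long = (
            grid.stack()
            .rename("cumulative_gt")
            .rename_axis(["start_year", "final_share"])
            .reset_index()
        )
        long.insert(0, "family", family)
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def heatmap(
    grid: pd.DataFrame,
    path: str | Path,
    budget: float = 390.0,
    title: str | None = None,
) -> None:
    """Cumulative-emissions heatmap over start year x final share, with
    the colour scale centred on the food-sector budget."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    vals = grid.to_numpy(dtype=float)
    norm = TwoSlopeNorm(
        vcenter=budget,
        vmin=min(vals.min(), budget - 1),
        vmax=max(vals.max(), budget + 1),
    )
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.pcolormesh(
        grid.columns.astype(float), grid.index.astype(float), vals,
        norm=norm, cmap="RdBu_r", shading="nearest",
    )
    fig.colorbar(im, ax=ax, label="cumulative 2020-2050 GtCO2e")
    ax.set_xlabel("final replacement share (2050 target)")
    ax.set_ylabel("adoption start year")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
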