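"""Reach x benefit sensitivity surfaces for one predicted usage tier.

For a single predicted tier, reach and mean benefit are swept over a grid
(default 10%-90% in 10-point steps, 81 combinations); each cell runs a reduced
Monte Carlo simulation (default 1000 runs) with the tier's reach fixed at the
cell level — stochastic only through per-patient binomial uptake and benefit
draws — and reports summaries of the net (total) benefit and of the average
benefit per reached patient.  The long-format export is sufficient to rebuild
3-D scatter surfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import EconomicScenario, SimulationSummary, monte_carlo_benefit, summarize_draws
from .errors import EmptyInputError, InvalidSpecError
from ._seeds import derive_seed

__all__ = ["GridSpec", "run_grid", "cell_scenario", "export_plot_data", "plot_data_to_table", "write_plot_data", "render_grid"]

_DEFAULT_LEVELS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))

_SUMMARY_FIELDS = ("mean", "sd", "median", "iqr", "min", "max", "q25", "q75")


@dataclass
class GridSpec:
    """A reach x benefit sweep for one target predicted tier."""

    reach_levels: tuple = _DEFAULT_LEVELS
    benefit_levels: tuple = _DEFAULT_LEVELS
    runs_per_cell: int = 1000
    target_tier: int = 2
    benefit_sd: float = 0.05
    per_patient_denominator: str = "reached"  # or "eligible"
    seed: int = 0

    def validate(self) -> None:
        for name, levels in (("reach_levels", self.reach_levels), ("benefit_levels", self.benefit_levels)):
            lv = tuple(float(x) for x in levels)
            if not lv or any(not 0.0 < x <= 1.0 for x in lv):
                raise InvalidSpecError(f"{name} must lie within (0, 1]")
            if any(lv[i] >= lv[i + 1] for i in range(len(lv) - 1)):
                raise InvalidSpecError(f"{name} must be strictly increasing")
        if self.runs_per_cell < 1:
            raise InvalidSpecError("runs_per_cell must be >= 1")
        if self.target_tier not in (1, 2, 3):
            raise InvalidSpecError("target_tier must be in {1,2,3}")
        if self.per_patient_denominator not in ("reached", "eligible"):
            raise InvalidSpecError("per_patient_denominator must be 'reached' or 'eligible'")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["reach_levels"] = [float(x) for x in self.reach_levels]
        d["benefit_levels"] = [float(x) for x in self.benefit_levels]
        return d


def cell_scenario(grid: GridSpec, reach: float, benefit: float, i_reach: int, j_benefit: int) -> EconomicScenario:
    """The exact scenario a grid cell runs: the target tier's reach fixed at
    the cell level (reach SD zero, benefit stochastic).  The sweep isolates
    one tier — only target-tier patients are simulated — so the other tiers'
    reach values are inert; they are filled in below/at the cell level only to
    satisfy the scenario's non-decreasing-reach invariant.  Cell seeds derive
    from (grid seed, tier, reach idx, benefit idx) so cells are independent
    yet reproducible."""
    reach_means = {t: (0.0 if t < grid.target_tier else float(reach)) for t in (1, 2, 3)}
    return EconomicScenario(
        benefit_mean=float(benefit),
        benefit_sd=grid.benefit_sd,
        reach_means=reach_means,
        reach_sd=0.0,
        n_iterations=grid.runs_per_cell,
        seed=derive_seed(grid.seed, "grid", grid.target_tier, i_reach, j_benefit),
    )


def run_grid(eligible: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Run the sweep over all (reach, benefit) cells.

    ``eligible`` is the benefit base (predicted tier, cost); only rows
    predicted into the grid's target tier enter the simulation.
    Returns one row per cell with net-benefit and per-patient summaries.
    """
    grid.validate()
    cell = eligible.loc[eligible["predicted_tier"] == grid.target_tier].reset_index(drop=True)
    if len(cell) == 0:
        raise EmptyInputError(f"no eligible patients predicted into tier {grid.target_tier}")

    rows = []
    for i, reach in enumerate(grid.reach_levels):
        for j, benefit in enumerate(grid.benefit_levels):
            scenario = cell_scenario(grid, reach, benefit, i, j)
            draws, net_summary, reached = monte_carlo_benefit(cell, scenario, return_reached_counts=True)
            if grid.per_patient_denominator == "reached":
                with np.errstate(invalid="ignore", divide="ignore"):
                    per_patient = np.where(reached > 0, draws / np.maximum(reached, 1), np.nan)
                per_patient = per_patient[~np.isnan(per_patient)]
            else:
                per_patient = draws / len(cell)
            pp_summary = (
                summarize_draws(per_patient)
                if per_patient.size
                else SimulationSummary(*([float("nan")] * 8))
            )
            row = {"tier": grid.target_tier, "reach": float(reach), "benefit": float(benefit)}
            row.update({f"net_{k}": v for k, v in net_summary.to_dict().items()})
            row.update({f"per_patient_{k}": v for k, v in pp_summary.to_dict().items()})
            rows.append(row)
    return pd.DataFrame(rows)


def export_plot_data(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a grid table to long format (tier, reach, benefit, statistic, value)."""
    if len(table) == 0:
        raise EmptyInputError("empty grid table")
    long = table.melt(id_vars=["tier", "reach", "benefit"], var_name="statistic", value_name="value")
    return long.sort_values(["tier", "reach", "benefit", "statistic"]).reset_index(drop=True)


def plot_data_to_table(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`export_plot_data` (statistics back to columns)."""
    if len(long) == 0:
        raise EmptyInputError("empty plot data")
    wide = long.pivot_table(index=["tier", "reach", "benefit"], columns="statistic", values="value").reset_index()
    wide.columns.name = None
    return wide


def write_plot_data(table: pd.DataFrame, json_path=None, csv_path=None) -> pd.DataFrame:
    """Serialize the long-format plot data as JSON records and/or CSV."""
    long = export_plot_data(table)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(long.to_dict(orient="records"), indent=1))
    if csv_path is not None:
        long.to_csv(csv_path, index=False)
    return long


def render_grid(table: pd.DataFrame, path, statistic: str = "net_mean") -> None:
    """Optional static 3-D scatter of a grid statistic (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(table["reach"] * 100, table["benefit"] * 100, table[statistic], c=table[statistic], cmap="viridis")
    ax.set_xlabel("reach (%)")
    ax.set_ylabel("benefit (%)")
    ax.set_zlabel(statistic)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
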