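"""Oil-palm yield accounting around tree islands.

Per-palm fresh-fruit-bunch yields (kg palm⁻¹ yr⁻¹) are converted to
per-area yields through a stand-density expansion factor, and to a
per-island net yield change decomposed as

    ΔY_island = Y_spillover + Y_remain_change − Y_foregone

where Y_foregone = N_felled · Y_ref values the palms felled at island
establishment at the reference per-palm yield, Y_remain_change =
N_in · (Y_in − Y_ref) captures yield changes of the palms left standing
inside the island, and Y_spillover = N_adj · (Y_adj − Y_ref) captures
changes of the palms directly adjacent to the island (position 1; palms
further out are unaffected and ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PALM_DENSITY_PER_HA, PlotSpec

POSITIONS = ("inside", "adjacent1", "adjacent2", "adjacent3", "reference")


@dataclass(frozen=True)
class PalmYieldRecord:
    """One palm's annual fresh-fruit-bunch yield."""

    palm_id: str
    plot_id: str | None  # None for reference palms in the open plantation
    position: str  # one of POSITIONS
    annual_yield: float  # kg/palm/yr

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.annual_yield < 0:
            raise ValueError("annual yield must be non-negative")
        if self.position == "reference" and self.plot_id is not None:
            raise ValueError("reference palms carry no plot")


@dataclass(frozen=True)
class YieldChangeResult:
    """Per-island yield-change decomposition (kg island⁻¹ yr⁻¹)."""

    plot_id: str
    y_spillover: float
    y_remain_change: float
    y_foregone: float

    @property
    def delta_y_island(self) -> float:
        return self.y_spillover + self.y_remain_change - self.y_foregone


@dataclass(frozen=True)
class ExpansionFactor:
    """Palms per hectare converting per-palm to per-area quantities."""

    plot_id: str
    palms_per_ha: float

    def __post_init__(self) -> None:
        if self.palms_per_ha <= 0:
            raise ValueError("expansion factor must be positive")


def reference_yield(records: list[PalmYieldRecord]) -> float:
    """Median annual yield of the reference palms (kg/palm/yr)."""
    ref = [r.annual_yield for r in records if r.position == "reference"]
    if not ref:
        raise ValueError("no reference palms in the records")
    return float(np.median(ref))


def per_island_change(
    plot: PlotSpec, records: list[PalmYieldRecord], y_ref: float
) -> YieldChangeResult:
    """Yield-change decomposition for one plot.

    Y_in is the median over the plot's inside palms; Y_adj the mean over its
    adjacent-position-1 palms (positions 2-3 are ignored).  A plot whose
    design says palms remain inside but that has no inside records is a
    data-consistency error.
    """
    mine = [r for r in records if r.plot_id == plot.plot_id]
    inside = [r.annual_yield for r in mine if r.position == "inside"]
    adj1 = [r.annual_yield for r in mine if r.position == "adjacent1"]
    if plot.n_in > 0 and not inside:
        raise ValueError(
            f"plot {plot.plot_id}: {plot.n_in} palms inside but no inside records"
        )
    y_foregone = plot.n_felled * y_ref
    y_remain = plot.n_in * (float(np.median(inside)) - y_ref) if inside else 0.0
    y_spill = plot.n_adj * (float(np.mean(adj1)) - y_ref) if adj1 else 0.0
    return YieldChangeResult(
        plot_id=plot.plot_id,
        y_spillover=y_spill,
        y_remain_change=y_remain,
        y_foregone=y_foregone,
    )


def per_area_yield(y_palm: float, ef: ExpansionFactor) -> float:
    """Per-area yield (kg/ha/yr) from a per-palm yield."""
    return y_palm * ef.palms_per_ha


def expansion_factor(
    plot: PlotSpec,
    neighborhood_count: int | None = None,
    neighborhood_area: float | None = None,
) -> ExpansionFactor:
    """Stand-density expansion factor (palms/ha) for one plot.

    When a local neighbourhood census is given, the factor is
    10,000 × count / area (m²).  Plots unaffected by thinning default to the
    conventional planting density of 120 palms/ha.
    """
    if neighborhood_count is None and neighborhood_area is None:
        if plot.n_felled == 0:
            return ExpansionFactor(plot.plot_id, PALM_DENSITY_PER_HA)
        density = 10_000.0 * plot.n_in / plot.area
        return ExpansionFactor(plot.plot_id, density)
    if neighborhood_area is None or neighborhood_area <= 0:
        raise ValueError("neighborhood_area must be positive")
    if neighborhood_count is None or neighborhood_count < 0:
        raise ValueError("neighborhood_count must be non-negative")
    return ExpansionFactor(
        plot.plot_id, 10_000.0 * neighborhood_count / neighborhood_area
    )


def yield_change_table(
    plots: list[PlotSpec], records: list[PalmYieldRecord]
) -> pd.DataFrame:
    """Per-plot decomposition table, reference yield taken from the records."""
    y_ref = reference_yield(records)
    rows = []
    for plot in plots:
        res = per_island_change(plot, records, y_ref)
        rows.append(
            {
                "plot_id": res.plot_id,
                "y_spillover_kg": res.y_spillover,
                "y_remain_change_kg": res.y_remain_change,
                "y_foregone_kg": res.y_foregone,
                "delta_y_island_kg": res.delta_y_island,
            }
        )
    return pd.DataFrame(rows).set_index("plot_id")


def records_from_table(df: pd.DataFrame) -> list[PalmYieldRecord]:
    """Palm-yield records from a (palm_id, plot_id, position, annual_yield_kg) table."""
    out = []
    for row in df.itertuples(index=False):
        plot = None if pd.isna(row.plot_id) or row.plot_id == "" else str(row.plot_id)
        out.append(
            PalmYieldRecord(
                palm_id=str(row.palm_id),
                plot_id=plot,
                position=str(row.position),
                annual_yield=float(row.annual_yield_kg),
            )
        )
    return out


def records_to_table(records: list[PalmYieldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "palm_id": [r.palm_id for r in records],
            "plot_id": [r.plot_id if r.plot_id is not None else "" for r in records],
            "position": [r.position for r in records],
            "annual_yield_kg": [r.annual_yield for r in records],
        }
    )
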