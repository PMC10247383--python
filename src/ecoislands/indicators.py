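"""Formula-defined ecosystem-function indicators.

Covers allometric above-ground biomass of trees and oil palms, plot-level
basal-area increment (tree growth), microclimate buffering from 3-hourly
temperature series, annualized leaf-litter input from litter traps,
infiltration-device correction, molar soil C:N and decompaction, and
pollination rate.  Orientation to "higher = better" for panel assembly is
handled by :func:`orient_buffering` (negated amplitude) and the reciprocal
soil metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Wood density (g/cm³) of the six planted species.
WOOD_DENSITY: dict[str, float] = {
    "Peronema_canescens": 0.61,
    "Parkia_speciosa": 0.54,
    "Dyera_polyphylla": 0.36,
    "Archidendron_jiringa": 0.36,
    "Shorea_leprosula": 0.44,
    "Durio_zibethinus": 0.516,
}

#: Molar masses (g/mol) used for the molar C:N ratio.
MOLAR_MASS_C = 12.0107
MOLAR_MASS_N = 14.0067

#: Palm allometry AGB = _PALM_SLOPE * H - _PALM_INTERCEPT (kg, H in m).
_PALM_SLOPE = 71.797
_PALM_INTERCEPT = 7.0872

#: Minimum meristem height (m) yielding positive palm biomass.
MIN_PALM_HEIGHT = _PALM_INTERCEPT / _PALM_SLOPE


@dataclass(frozen=True)
class TreeMeasurement:
    species: str
    wood_density: float  # g/cm³
    dbh: float | None  # cm; None for trees below breast height
    basal_diameter: float | None  # cm
    height: float  # m


@dataclass(frozen=True)
class PalmMeasurement:
    height_meristem: float  # m


@dataclass(frozen=True)
class SoilSample:
    total_c: float  # mg/g
    total_n: float  # mg/g
    available_p: float  # mg/g
    bulk_density: float  # g/cm³


def agb_tree(t: TreeMeasurement) -> float | None:
    """Tree above-ground biomass (kg): 0.0673 · (ρ · DBH² · H)^0.976.

    Trees without a DBH (below breast height) return None and are excluded
    from plot sums.
    """
    if t.dbh is None:
        return None
    if min(t.wood_density, t.dbh, t.height) <= 0:
        raise ValueError("wood density, DBH and height must be positive")
    return 0.0673 * (t.wood_density * t.dbh**2 * t.height) ** 0.976


def agb_palm(p: PalmMeasurement) -> float:
    """Oil-palm above-ground biomass (kg): 71.797 · H − 7.0872."""
    value = _PALM_SLOPE * p.height_meristem - _PALM_INTERCEPT
    if value <= 0:
        raise ValueError(
            f"meristem height {p.height_meristem} m yields non-positive biomass "
            f"(minimum {MIN_PALM_HEIGHT:.4f} m)"
        )
    return value


def total_agb(
    plot,
    trees: list[TreeMeasurement],
    palms: list[PalmMeasurement],
    ef,
) -> float:
    """Total above-ground biomass of one plot (t/ha).

    Tree biomass is summed over the plot; palm biomass enters as the mean
    per-palm biomass of the measured remaining palms scaled by the local
    stand density (palms/ha) over the plot area.  Necromass, litter and
    understorey are excluded (negligible).
    """
    tree_kg = sum(m for m in (agb_tree(t) for t in trees) if m is not None)
    if palms:
        if plot.n_in == 0:
            raise ValueError(f"plot {plot.plot_id}: palm measurements but n_in = 0")
        mean_palm_kg = float(np.mean([agb_palm(p) for p in palms]))
        # palms/ha × kg/palm → kg/ha over the plot footprint
        palm_kg = mean_palm_kg * ef.palms_per_ha * (plot.area / 10_000.0)
    else:
        palm_kg = 0.0
    kg_per_m2 = (tree_kg + palm_kg) / plot.area
    return kg_per_m2 * 10.0  # kg/m² → t/ha


def ba_increment(
    basal_d_start: list[float],
    basal_d_end: list[float],
    area: float,
    shrink_tolerance: float = 0.5,
) -> float:
    """Plot-level basal-area increment (cm²/m²/yr) from matched basal diameters.

    Σ (π/4)(d_end² − d_start²) / A.  A tree shrinking by more than
    ``shrink_tolerance`` cm in diameter indicates a measurement mismatch.
    """
    if len(basal_d_start) != len(basal_d_end):
        raise ValueError("start and end diameters must be matched per tree")
    if area <= 0:
        raise ValueError("area must be positive")
    d0 = np.asarray(basal_d_start, dtype=float)
    d1 = np.asarray(basal_d_end, dtype=float)
    if ((d0 - d1) > shrink_tolerance).any():
        raise ValueError("tree diameter shrank beyond tolerance; check matching")
    return float(np.sum((math.pi / 4.0) * (d1**2 - d0**2)) / area)


def microclimate_amplitude(series: pd.Series) -> float:
    """Median daily temperature amplitude |T(15:00) − T(7:00)| in °C.

    ``series`` is a datetime-indexed temperature series at 3-h cadence;
    days missing either the 07:00 or the 15:00 reading are dropped.
    Lower amplitude means stronger microclimate buffering.
    """
    s = series.dropna()
    idx = pd.DatetimeIndex(s.index)
    frame = pd.DataFrame({"t": s.to_numpy(), "date": idx.date, "hour": idx.hour})
    morning = frame[frame.hour == 7].groupby("date")["t"].first()
    afternoon = frame[frame.hour == 15].groupby("date")["t"].first()
    both = pd.concat([morning, afternoon], axis=1, keys=["m", "a"]).dropna()
    if both.empty:
        raise ValueError("no day has both a 07:00 and a 15:00 reading")
    return float((both["a"] - both["m"]).abs().median())


def orient_buffering(amplitude: float) -> float:
    """Buffering indicator oriented so higher = more buffering (−amplitude)."""
    return -amplitude


def litter_annualize(
    trap_masses: pd.DataFrame,
    trap_area: float = 0.25,
    dates_per_year: int = 24,
    outlier_center: float | None = None,
    outlier_sd: float | None = None,
) -> float:
    """Annual leaf-litter input (g/m²/yr) for one plot.

    ``trap_masses`` is a date × trap table of dry masses (g per trap).  Per
    date the plot value is the median across traps; dates whose plot value
    falls outside ``outlier_center ± 3·outlier_sd`` (when given — normally
    the median and SD of the plot-date values of the whole campaign) are
    excluded; the mean retained per-date mass is scaled to a year
    (``dates_per_year`` semi-monthly collections) and divided by the trap
    area to express it per m².
    """
    if trap_masses.shape[0] < 1:
        raise ValueError("need at least one sampling date")
    per_date = trap_masses.median(axis=1, skipna=True).dropna()
    if outlier_center is not None and outlier_sd is not None:
        lo = outlier_center - 3.0 * outlier_sd
        hi = outlier_center + 3.0 * outlier_sd
        per_date = per_date[(per_date >= lo) & (per_date <= hi)]
    if per_date.empty:
        raise ValueError("all sampling dates excluded as outliers")
    mean_per_date = float(per_date.mean())
    return mean_per_date * dates_per_year / trap_area


def litter_panel_stats(per_date_values: pd.Series) -> tuple[float, float]:
    """(median, SD) of the campaign-wide plot-date litter values.

    These feed the 3-SD outlier rule of :func:`litter_annualize`.
    """
    vals = per_date_values.dropna()
    return float(vals.median()), float(vals.std(ddof=1))


def kfs_correct(k_double_ring: float) -> float:
    """Correct a manual double-ring K_fs (cm/h) to the dual-head scale.

    K_corr = 1.44 + 0.55 · K_double_ring (cross-device calibration).
    """
    if k_double_ring < 0:
        raise ValueError("hydraulic conductivity must be non-negative")
    return 1.44 + 0.55 * k_double_ring


def soil_indicators(s: SoilSample) -> tuple[float, float, float]:
    """(inv_cn, soil_p, decompaction) from one soil sample.

    inv_cn is the inverse of the molar C:N ratio (soil fertility,
    higher = better); decompaction is 1/bulk density; available P passes
    through unchanged.
    """
    if s.total_n <= 0:
        raise ValueError("total N must be positive for a C:N ratio")
    if s.bulk_density <= 0:
        raise ValueError("bulk density must be positive")
    molar_cn = (s.total_c / MOLAR_MASS_C) / (s.total_n / MOLAR_MASS_N)
    return 1.0 / molar_cn, s.available_p, 1.0 / s.bulk_density


def pollination_rate(fruits: int, flowers: int) -> float:
    """Fraction of observed flowers that set fruit; missing when no flowers."""
    if fruits < 0 or flowers < 0:
        raise ValueError("counts must be non-negative")
    if flowers == 0:
        return float("nan")
    if fruits > flowers:
        raise ValueError("more fruits than flowers is impossible under the protocol")
    return fruits / flowers
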