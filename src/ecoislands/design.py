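"""Random-partitions experimental design for a tree-island enrichment experiment.

The design crosses island area (25, 100, 400, 1600 m²) with planted tree
diversity (0-6 species from a six-species pool).  Within each area class the
species pool is partitioned into non-overlapping groups at each diversity
level, so that every species appears exactly once per diversity level per
area class: one 0-species plot, six 1-species plots, three 2-species plots,
two 3-species plots and one 6-species plot — 13 plots per area class, 52
islands in total, plus four conventionally managed 100 m² control plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six native tree species planted in the experiment.
SPECIES_POOL: tuple[str, ...] = (
    "Archidendron_jiringa",
    "Parkia_speciosa",
    "Durio_zibethinus",
    "Dyera_polyphylla",
    "Shorea_leprosula",
    "Peronema_canescens",
)

ISLAND_AREAS: tuple[float, ...] = (25.0, 100.0, 400.0, 1600.0)
CONTROL_AREA: float = 100.0
N_CONTROLS: int = 4

#: Conventional planting density of the surrounding plantation (palms per ha).
PALM_DENSITY_PER_HA: float = 120.0

#: Local-layout expansion applied to the nominal density when counting the
#: palms initially standing inside an island footprint: plot corners clip
#: palms of the triangular planting grid, so small plots hold slightly more
#: palms than area x density predicts.
_LAYOUT_EXPANSION: float = 1.3

#: Fraction of within-island palms felled at establishment.
FELLED_FRACTION: float = 0.40

#: Approximate palm-to-palm spacing (m) of a 120/ha triangular grid, used to
#: convert island perimeter into a count of directly adjacent palms.
_PALM_SPACING_M: float = 9.0


@dataclass(frozen=True)
class PlotSpec:
    """One experimental unit: a tree island or a control plot."""

    plot_id: str
    plot_type: str  # "island" | "control"
    area: float  # m²
    planted_diversity: int
    composition: tuple[str, ...] = field(default_factory=tuple)
    n_palms_initial: int = 0
    n_felled: int = 0
    n_adj: int = 0

    def __post_init__(self) -> None:
        if self.plot_type not in ("island", "control"):
            raise ValueError(f"unknown plot_type {self.plot_type!r}")
        if self.plot_type == "island" and self.area not in ISLAND_AREAS:
            raise ValueError(f"island area must be one of {ISLAND_AREAS}")
        if self.plot_type == "control":
            if self.n_felled != 0:
                raise ValueError("controls have no felled palms")
            if self.planted_diversity != 0 or self.composition:
                raise ValueError("controls are unplanted")
        if self.planted_diversity != len(self.composition):
            raise ValueError("planted_diversity must equal |composition|")
        if self.n_felled > self.n_palms_initial:
            raise ValueError("cannot fell more palms than initially present")
        if min(self.n_palms_initial, self.n_felled, self.n_adj) < 0:
            raise ValueError("palm counts must be non-negative")

    @property
    def edge_length(self) -> float:
        """Plot edge length in m (plots are square)."""
        return math.sqrt(self.area)

    @property
    def n_in(self) -> int:
        """Palms remaining inside the plot after felling."""
        return self.n_palms_initial - self.n_felled

    @property
    def is_island(self) -> bool:
        return self.plot_type == "island"


def _palm_counts(area: float, plot_type: str) -> tuple[int, int]:
    """(initial, felled) palm counts for one plot."""
    initial = max(1, round(area * PALM_DENSITY_PER_HA / 10_000.0 * _LAYOUT_EXPANSION))
    if plot_type == "control":
        return initial, 0
    felled = round(FELLED_FRACTION * initial)
    if area >= 100.0:
        felled = max(1, felled)
    return initial, felled


def build_design(
    n_replicates_per_area: int = 13,
    seed: int = 0,
    species_pool: tuple[str, ...] = SPECIES_POOL,
) -> list[PlotSpec]:
    """Build the factorial random-partitions design.

    Parameters
    ----------
    n_replicates_per_area
        Plots per area class.  The default 13 corresponds to the partition
        scheme of a six-species pool (1 + 6/1·? ... concretely
        1 zero-diversity plot + 6 + 3 + 2 + 1 partition plots).  Other values
        are accepted only when they match ``1 + sum(pool/k)`` over the
        divisors k < pool size of the pool, i.e. the partition arithmetic
        must stay consistent.
    seed
        Seeds the random assignment of species to partition groups.

    Returns
    -------
    list of PlotSpec — islands first (area-major order), then controls.
    """
    pool = tuple(species_pool)
    s = len(pool)
    divisors = [k for k in range(1, s) if s % k == 0]  # group sizes < pool
    n_partition_plots = sum(s // k for k in divisors) + 1  # + full-pool plot
    expected = 1 + n_partition_plots  # + zero-diversity plot
    if n_replicates_per_area != expected:
        raise ValueError(
            f"partition scheme for a {s}-species pool yields {expected} plots "
            f"per area class, got n_replicates_per_area={n_replicates_per_area}"
        )

    rng = np.random.default_rng(seed)
    plots: list[PlotSpec] = []
    i_plot = 0
    for area in ISLAND_AREAS:
        compositions: list[tuple[str, ...]] = [()]  # the zero-diversity plot
        for k in divisors + [s]:
            perm = list(rng.permutation(len(pool)))
            for g in range(s // k):
                idx = perm[g * k : (g + 1) * k]
                compositions.append(tuple(sorted(pool[i] for i in idx)))
        for comp in compositions:
            i_plot += 1
            initial, felled = _palm_counts(area, "island")
            edge = math.sqrt(area)
            n_adj = max(1, round(4.0 * edge / _PALM_SPACING_M))
            plots.append(
                PlotSpec(
                    plot_id=f"I{i_plot:02d}",
                    plot_type="island",
                    area=area,
                    planted_diversity=len(comp),
                    composition=comp,
                    n_palms_initial=initial,
                    n_felled=felled,
                    n_adj=n_adj,
                )
            )
    for c in range(N_CONTROLS):
        initial, felled = _palm_counts(CONTROL_AREA, "control")
        edge = math.sqrt(CONTROL_AREA)
        plots.append(
            PlotSpec(
                plot_id=f"C{c + 1:02d}",
                plot_type="control",
                area=CONTROL_AREA,
                planted_diversity=0,
                composition=(),
                n_palms_initial=initial,
                n_felled=felled,
                n_adj=max(1, round(4.0 * edge / _PALM_SPACING_M)),
            )
        )
    return plots


def design_table(plots: list[PlotSpec]) -> pd.DataFrame:
    """Design as a tidy table (one row per plot)."""
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "plot_type": [p.plot_type for p in plots],
            "area_m2": [p.area for p in plots],
            "edge_m": [p.edge_length for p in plots],
            "diversity": [p.planted_diversity for p in plots],
            "composition": ["+".join(p.composition) for p in plots],
            "n_palms_initial": [p.n_palms_initial for p in plots],
            "n_felled": [p.n_felled for p in plots],
            "n_in": [p.n_in for p in plots],
            "n_adj": [p.n_adj for p in plots],
        }
    )


def design_from_table(df: pd.DataFrame) -> list[PlotSpec]:
    """Inverse of :func:`design_table`."""
    plots = []
    for row in df.itertuples(index=False):
        raw = row.composition
        comp = () if pd.isna(raw) else tuple(s for s in str(raw).split("+") if s)
        plots.append(
            PlotSpec(
                plot_id=str(row.plot_id),
                plot_type=str(row.plot_type),
                area=float(row.area_m2),
                planted_diversity=int(row.diversity),
                composition=comp,
                n_palms_initial=int(row.n_palms_initial),
                n_felled=int(row.n_felled),
                n_adj=int(row.n_adj),
            )
        )
    return plots
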