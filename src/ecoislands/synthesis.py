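"""Seeded synthetic datasets with the causal structure the analysis assumes.

The generator encodes the hypothesized causal skeleton of the experiment:
planted tree diversity raises structural complexity (latent PC1), island
area raises tree dominance (latent PC2), and every restoration indicator
responds to the treatments directly and/or through those two latents.  It
emits all the data streams the pipeline consumes: the plot design,
plot × species abundance tables for ten taxa, a plot × indicator matrix,
per-palm yield records (with a spillover effect confined to the palm in
adjacent position 1), 3-hourly temperature series, litter-trap series and
the 12 vegetation-structure variables (noisy loadings of the two latents).

Latents are built with unit variance (β·z + √(1−β²)·ε), so the configured
path coefficients are standardized path coefficients and downstream path
models can be checked against them directly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import PlotSpec, build_design
from .indicators import pollination_rate
from .structure import STRUCTURE_VARIABLES
from .yields import PalmYieldRecord

TAXA: tuple[str, ...] = (
    "soil_bacteria",
    "soil_fungi",
    "soil_fauna",
    "herbs",
    "trees",
    "seeds",
    "pollen",
    "understorey_arthropods",
    "birds",
    "bats",
)

#: Species-pool size per taxon (order as TAXA).
_POOL_SIZES = (120, 80, 25, 40, 30, 30, 20, 60, 25, 8)

#: Functioning indicators stored directly in the indicator matrix.  The
#: remaining three of the 20-variable panel (oil palm yield, litter input,
#: microclimate buffering) are derived by the pipeline from raw streams.
DIRECT_FUNCTIONING: tuple[str, ...] = (
    "tree_growth",
    "agb",
    "native_seeds",
    "invasion_resistance",
    "pollinators",
    "pollination_rate",
    "soil_p",
    "inv_cn",
    "decompaction",
    "predators_vertebrates",
    "predators_arthropods",
    "predators_soilfauna",
    "herbivores_soilfauna",
    "decomposers",
    "litter_decomposition",
    "evapotranspiration",
    "infiltration",
)


@dataclass(frozen=True)
class IndicatorEffect:
    """Standardized effect sizes and natural-unit mapping for one indicator."""

    direct_island: float = 0.0
    direct_area: float = 0.0
    direct_div: float = 0.0
    via_pc1: float = 0.0
    via_pc2: float = 0.0
    noise_sd: float = 1.0
    base: float = 0.0
    scale: float = 1.0

    def standardized_response(
        self, island, z_edge, z_div, pc1, pc2, eps
    ) -> np.ndarray:
        return (
            self.direct_island * island
            + self.direct_area * z_edge
            + self.direct_div * z_div
            + self.via_pc1 * pc1
            + self.via_pc2 * pc2
            + self.noise_sd * eps
        )


def _default_effects() -> dict[str, IndicatorEffect]:
    """Default effect table: modest island benefits, varied mediation mix."""
    e = {}
    base_units = {
        "tree_growth": (0.15, 0.06),  # cm²/m²/yr
        "agb": (45.0, 18.0),  # t/ha
        "native_seeds": (12.0, 5.0),  # seeds/m²
        "invasion_resistance": (80.0, 8.0),  # 100 − invasive cover %
        "pollinators": (25.0, 8.0),  # individuals
        "pollination_rate": (0.25, 0.06),  # fraction
        "soil_p": (0.35, 0.08),  # mg/g
        "inv_cn": (0.085, 0.012),  # 1 / molar C:N
        "decompaction": (0.80, 0.08),  # cm³/g
        "predators_vertebrates": (300.0, 150.0),  # s activity
        "predators_arthropods": (35.0, 12.0),
        "predators_soilfauna": (3.0, 1.0),  # J/h
        "herbivores_soilfauna": (2.0, 0.7),
        "decomposers": (6.0, 2.0),
        "litter_decomposition": (45.0, 9.0),  # % mass loss
        "evapotranspiration": (380.0, 60.0),  # W/m²
        "infiltration": (8.0, 4.0),  # cm/h
    }
    mixes = [
        (0.35, 0.15),
        (0.15, 0.35),
        (0.30, -0.10),
        (-0.20, 0.30),
        (0.25, 0.25),
        (0.35, 0.0),
        (0.0, 0.35),
        (0.20, -0.25),
        (-0.15, 0.20),
    ]
    for i, (name, (base, scale)) in enumerate(base_units.items()):
        via1, via2 = mixes[i % len(mixes)]
        e[name] = IndicatorEffect(
            direct_island=1.0,
            direct_area=0.10 if i % 3 == 0 else 0.0,
            direct_div=0.10 if i % 3 == 1 else 0.0,
            via_pc1=via1,
            via_pc2=via2,
            noise_sd=1.0,
            base=base,
            scale=scale,
        )
    return e


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment.

    Path coefficients are standardized; yields are kg/palm/yr; the
    spillover effect shifts only the palm at adjacent position 1.
    """

    seed: int = 0
    beta_area_dominance: float = 0.6
    beta_div_complexity: float = 0.6
    effects: dict[str, IndicatorEffect] = field(default_factory=_default_effects)
    yield_ref_mean: float = 150.0
    yield_ref_sd: float = 20.0
    yield_inside_shift: float = -10.0
    spillover_effect: float = 15.0
    n_reference_palms: int = 34
    corr_treegrowth_litter: float = 0.9
    litter_base: float = 350.0  # g/m²/yr
    litter_scale: float = 120.0
    abundance_effect: float = 0.35  # log-intensity per unit treatment signal
    evenness_effect: float = 0.25
    amplitude_base: float = 9.0  # °C, open-plantation daily amplitude
    amplitude_island: float = 1.5
    amplitude_pc1: float = 0.8
    amplitude_noise_sd: float = 1.0
    structure_noise_sd: float = 0.3
    n_days_temperature: int = 180
    n_litter_dates: int = 24
    n_litter_traps: int = 4

    def __post_init__(self) -> None:
        if not (0 <= abs(self.corr_treegrowth_litter) < 1):
            raise ValueError("|corr_treegrowth_litter| must be < 1")
        for name in ("yield_ref_sd", "amplitude_noise_sd", "structure_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for b in (self.beta_area_dominance, self.beta_div_complexity):
            if not abs(b) <= 1:
                raise ValueError("standardized path coefficients must be in [-1, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    design: list[PlotSpec]
    abundances: dict[str, pd.DataFrame]  # taxon -> plot × species counts
    indicators: pd.DataFrame  # plot × direct indicators
    yields: list[PalmYieldRecord]
    temperature_series: pd.DataFrame  # plot_id, timestamp, temperature_c
    litter_series: pd.DataFrame  # plot_id, date_index, trap, mass_g
    structure_vars: pd.DataFrame  # plot × 12 structure variables
    latents: pd.DataFrame  # plot-level drivers and latent axes (ground truth)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic child RNG keyed by sub-generator name."""
    return np.random.default_rng([zlib.crc32(name.encode()) & 0x7FFFFFFF, seed])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _orthogonal_noise(
    rng: np.random.Generator, n: int, others: list[np.ndarray]
) -> np.ndarray:
    """Unit-sd noise with exactly zero in-sample correlation to ``others``.

    Simulating the latent disturbances conditionally orthogonal to the
    treatment drivers (and to each other) makes the generated data satisfy
    the encoded path model exactly at the experiment's modest sample size,
    so standardized paths and d-separation claims can be checked against
    the generating values without finite-sample rotation of the axes.
    """
    eps = rng.standard_normal(n)
    basis = np.column_stack([np.ones(n)] + [np.asarray(o) for o in others])
    eps = eps - basis @ np.linalg.lstsq(basis, eps, rcond=None)[0]
    return eps / eps.std(ddof=0)


def simulate_latent_table(
    design: list[PlotSpec], params: SimulationParams
) -> pd.DataFrame:
    """Plot-level treatment drivers and the two unit-variance latent axes.

    Controls enter with 10 m edge length and zero planted diversity.
    Latents: pc1 = β_div·z(log(div+1)) + √(1−β²)·ε (structural complexity),
    pc2 = β_area·z(log edge) + √(1−β²)·ε (tree dominance), with the two
    disturbances orthogonalized in sample (see :func:`_orthogonal_noise`).
    """
    rng = _stream(params.seed, "latents")
    island = np.array([1.0 if p.is_island else 0.0 for p in design])
    log_edge = np.log([p.edge_length for p in design])
    log_div1 = np.log1p([p.planted_diversity for p in design])
    z_edge = _zscore(log_edge)
    z_div = _zscore(log_div1)
    b1, b2 = params.beta_div_complexity, params.beta_area_dominance
    n = len(design)
    e1 = _orthogonal_noise(rng, n, [z_div, z_edge])
    e2 = _orthogonal_noise(rng, n, [z_div, z_edge, e1])
    pc1 = b1 * z_div + np.sqrt(1 - b1**2) * e1
    pc2 = b2 * z_edge + np.sqrt(1 - b2**2) * e2
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in design],
            "island": island,
            "log_edge": log_edge,
            "log_div1": log_div1,
            "z_log_edge": z_edge,
            "z_log_div1": z_div,
            "pc1_latent": pc1,
            "pc2_latent": pc2,
        }
    ).set_index("plot_id")


def _treatment_signal(lat: pd.DataFrame) -> np.ndarray:
    """Composite restoration signal used by abundance and stream generators."""
    return (
        0.6 * lat["island"].to_numpy()
        + 0.4 * lat["pc1_latent"].to_numpy()
        + 0.2 * lat["pc2_latent"].to_numpy()
    )


def _simulate_abundances(
    design: list[PlotSpec], lat: pd.DataFrame, params: SimulationParams
) -> dict[str, pd.DataFrame]:
    """Log-normal ranked species-abundance distributions, Poisson sampled.

    Per plot, expected totals rise with the treatment signal
    (``abundance_effect``) and relative abundances are flattened in richer
    plots via a tilt exponent (``evenness_effect``), so both richness and
    evenness respond to the treatments.
    """
    signal = _treatment_signal(lat)
    out: dict[str, pd.DataFrame] = {}
    for taxon, pool in zip(TAXA, _POOL_SIZES):
        rng = _stream(params.seed, f"abundance:{taxon}")
        sad = np.sort(np.exp(rng.normal(0.0, 1.2, size=pool)))[::-1]
        sad /= sad.sum()
        if taxon == "trees":
            # planted + regenerating individuals; sparse in unplanted controls
            log_n = 2.6 + 0.45 * lat["log_div1"].to_numpy() + 0.25 * lat[
                "z_log_edge"
            ].to_numpy()
        else:
            base_n = {
                "soil_bacteria": 6.5,
                "soil_fungi": 6.0,
                "soil_fauna": 4.5,
                "herbs": 5.0,
                "seeds": 4.8,
                "pollen": 4.2,
                "understorey_arthropods": 4.6,
                "birds": 3.2,
                "bats": 2.3,
            }[taxon]
            log_n = base_n + params.abundance_effect * signal
        counts = np.zeros((len(design), pool), dtype=int)
        for i in range(len(design)):
            theta = np.exp(-params.evenness_effect * signal[i])
            probs = sad**theta
            probs /= probs.sum()
            lam = np.exp(log_n[i]) * probs
            counts[i] = rng.poisson(lam)
        out[taxon] = pd.DataFrame(
            counts,
            index=lat.index,
            columns=[f"{taxon}_sp{j + 1:03d}" for j in range(pool)],
        )
    return out


def _simulate_indicators(
    design: list[PlotSpec], lat: pd.DataFrame, params: SimulationParams
) -> pd.DataFrame:
    rng = _stream(params.seed, "indicators")
    n = len(design)
    island = lat["island"].to_numpy()
    z_edge = lat["z_log_edge"].to_numpy()
    z_div = lat["z_log_div1"].to_numpy()
    pc1 = lat["pc1_latent"].to_numpy()
    pc2 = lat["pc2_latent"].to_numpy()

    # correlated residual pair: tree growth / litter input
    rho = params.corr_treegrowth_litter
    cov = np.array([[1.0, rho], [rho, 1.0]])
    pair = rng.multivariate_normal([0.0, 0.0], cov, size=n)

    cols: dict[str, np.ndarray] = {}
    for name, eff in params.effects.items():
        if name == "tree_growth":
            eps = pair[:, 0]
        else:
            eps = rng.standard_normal(n)
        std = eff.standardized_response(island, z_edge, z_div, pc1, pc2, eps)
        natural = eff.base + eff.scale * std
        if name == "pollination_rate":
            flowers = rng.poisson(40.0, size=n) + 1
            rate = np.clip(natural, 0.01, 0.95)
            fruits = rng.binomial(flowers, rate)
            natural = np.array(
                [pollination_rate(f, fl) for f, fl in zip(fruits, flowers)]
            )
        elif name in (
            "pollinators",
            "predators_arthropods",
            "native_seeds",
        ):
            natural = rng.poisson(np.clip(natural, 0.1, None)).astype(float)
        else:
            natural = np.clip(natural, 0.0, None)
            if name == "invasion_resistance" or name == "litter_decomposition":
                natural = np.clip(natural, 0.0, 100.0)
        cols[name] = natural

    # standardized litter-input target, correlated with tree growth via the
    # shared residual pair; the litter-trap stream is built from it
    tg = params.effects["tree_growth"]
    litter_std = tg.standardized_response(island, z_edge, z_div, pc1, pc2, pair[:, 1])
    cols["_litter_annual_target"] = np.clip(
        params.litter_base + params.litter_scale * litter_std, 30.0, None
    )
    frame = pd.DataFrame(cols, index=lat.index)
    order = [c for c in DIRECT_FUNCTIONING if c in frame.columns]
    extra = [c for c in frame.columns if c not in order]
    return frame[order + extra]


def _simulate_yields(
    design: list[PlotSpec], params: SimulationParams
) -> list[PalmYieldRecord]:
    rng = _stream(params.seed, "yields")
    mu, sd = params.yield_ref_mean, params.yield_ref_sd
    records: list[PalmYieldRecord] = []
    for i in range(params.n_reference_palms):
        records.append(
            PalmYieldRecord(
                palm_id=f"REF{i + 1:03d}",
                plot_id=None,
                position="reference",
                annual_yield=max(0.0, rng.normal(mu, sd)),
            )
        )
    for p in design:
        shift = params.yield_inside_shift if p.is_island else 0.0
        for j in range(p.n_in):
            records.append(
                PalmYieldRecord(
                    palm_id=f"{p.plot_id}_in{j + 1:02d}",
                    plot_id=p.plot_id,
                    position="inside",
                    annual_yield=max(0.0, rng.normal(mu + shift, sd)),
                )
            )
        if p.is_island:
            for pos in (1, 2, 3):
                shift = params.spillover_effect if pos == 1 else 0.0
                records.append(
                    PalmYieldRecord(
                        palm_id=f"{p.plot_id}_adj{pos}",
                        plot_id=p.plot_id,
                        position=f"adjacent{pos}",
                        annual_yield=max(0.0, rng.normal(mu + shift, sd)),
                    )
                )
    return records


def _simulate_temperature(
    lat: pd.DataFrame, params: SimulationParams
) -> pd.DataFrame:
    """3-hourly temperature series; amplitude shrinks with island/complexity."""
    rng = _stream(params.seed, "temperature")
    # near-3-hourly grid; 07:00 and 15:00 anchor the daily-amplitude metric
    hours = (0, 3, 7, 9, 12, 15, 18, 21)
    start = pd.Timestamp("2017-11-18")
    rows_plot, rows_ts, rows_t = [], [], []
    amp_plot = np.clip(
        params.amplitude_base
        - params.amplitude_island * lat["island"].to_numpy()
        - params.amplitude_pc1 * lat["pc1_latent"].to_numpy()
        + params.amplitude_noise_sd * rng.standard_normal(len(lat)),
        0.5,
        None,
    )
    for i, plot_id in enumerate(lat.index):
        day_amp = np.clip(
            amp_plot[i] + 0.4 * rng.standard_normal(params.n_days_temperature),
            0.2,
            None,
        )
        night = 23.0 + 0.8 * rng.standard_normal(params.n_days_temperature)
        for d in range(params.n_days_temperature):
            date = start + pd.Timedelta(days=d)
            # diurnal half-sine peaking at 15:00, trough at 07:00 and before
            for h in hours:
                phase = np.clip(np.sin(np.pi * (h - 7) / 16.0), 0.0, None) if h >= 7 else 0.0
                temp = night[d] + day_amp[d] * phase + 0.15 * rng.standard_normal()
                rows_plot.append(plot_id)
                rows_ts.append(date + pd.Timedelta(hours=int(h)))
                rows_t.append(temp)
    return pd.DataFrame(
        {"plot_id": rows_plot, "timestamp": rows_ts, "temperature_c": rows_t}
    )


def _simulate_litter(
    lat: pd.DataFrame, annual_target: pd.Series, params: SimulationParams
) -> pd.DataFrame:
    rng = _stream(params.seed, "litter")
    rows = []
    for plot_id in lat.index:
        per_date = (
            annual_target.loc[plot_id] * 0.25 / params.n_litter_dates
        )  # g per trap per date at the 0.25 m² trap
        for d in range(params.n_litter_dates):
            for trap in range(params.n_litter_traps):
                mass = max(0.0, rng.normal(per_date, 0.05 * per_date + 0.05))
                rows.append((plot_id, d, trap + 1, mass))
    return pd.DataFrame(rows, columns=["plot_id", "date_index", "trap", "mass_g"])


#: Loadings of the 12 structure variables on (pc1, pc2), natural-unit maps.
_STRUCTURE_MODEL: dict[str, tuple[float, float, float, float]] = {
    # name: (loading_pc1, loading_pc2, base, scale); the two loading columns
    # are kept near-orthogonal so the sample PCs recover the latents
    "ssci": (0.90, 0.00, 5.0, 1.5),
    "mean_frac": (0.85, 0.05, 1.6, 0.25),
    "enl": (0.80, 0.10, 3.0, 0.8),
    "understory_complexity": (0.85, -0.10, 1.4, 0.3),
    "canopy_gap_fraction": (-0.80, -0.05, 40.0, 15.0),
    "oil_palm_cover": (-0.10, -0.85, 60.0, 20.0),
    "tree_cover": (0.10, 0.90, 25.0, 18.0),
    "oil_palm_density": (0.00, -0.85, 110.0, 30.0),
    "tree_density": (0.10, 0.80, 400.0, 250.0),
    "understorey_cover": (0.70, -0.10, 45.0, 18.0),
    "litter_cover": (0.05, 0.50, 50.0, 15.0),
    "litter_depth": (0.50, 0.10, 2.5, 1.0),
}


def simulate_structure(
    lat: pd.DataFrame, params: SimulationParams
) -> pd.DataFrame:
    rng = _stream(params.seed, "structure")
    pc1 = lat["pc1_latent"].to_numpy()
    pc2 = lat["pc2_latent"].to_numpy()
    cols = {}
    for name in STRUCTURE_VARIABLES:
        l1, l2, base, scale = _STRUCTURE_MODEL[name]
        std = l1 * pc1 + l2 * pc2 + params.structure_noise_sd * rng.standard_normal(
            len(lat)
        )
        value = base + scale * std / np.hypot(l1, l2)
        if name.endswith(("cover", "fraction")) or name in (
            "oil_palm_cover",
            "tree_cover",
        ):
            value = np.clip(value, 0.0, 100.0)
        elif name in ("oil_palm_density", "tree_density", "litter_depth"):
            value = np.clip(value, 0.0, None)
        cols[name] = value
    return pd.DataFrame(cols, index=lat.index)


def simulate_dataset(
    design: list[PlotSpec] | None = None,
    params: SimulationParams | None = None,
) -> SyntheticDataset:
    """Generate one full synthetic dataset (deterministic in ``params.seed``)."""
    params = params or SimulationParams()
    if design is None:
        design = build_design(seed=params.seed)
    lat = simulate_latent_table(design, params)
    indicators = _simulate_indicators(design, lat, params)
    litter_target = indicators.pop("_litter_annual_target")
    return SyntheticDataset(
        design=design,
        abundances=_simulate_abundances(design, lat, params),
        indicators=indicators,
        yields=_simulate_yields(design, params),
        temperature_series=_simulate_temperature(lat, params),
        litter_series=_simulate_litter(lat, litter_target, params),
        structure_vars=simulate_structure(lat, params),
        latents=lat,
    )


def null_params(seed: int = 0, **overrides) -> SimulationParams:
    """Parameters with every treatment effect switched off (calibration runs)."""
    effects = {
        name: replace(
            eff, direct_island=0.0, direct_area=0.0, direct_div=0.0,
            via_pc1=0.0, via_pc2=0.0,
        )
        for name, eff in _default_effects().items()
    }
    return SimulationParams(
        seed=seed,
        beta_area_dominance=0.0,
        beta_div_complexity=0.0,
        effects=effects,
        yield_inside_shift=0.0,
        spillover_effect=0.0,
        abundance_effect=0.0,
        evenness_effect=0.0,
        amplitude_island=0.0,
        amplitude_pc1=0.0,
        **overrides,
    )
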