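"""Staged analysis pipeline: synth → indicators → diversity → multimetrics →
yield → inference.

Every stage reads and writes plain CSV in the run directory, so a run can
be resumed or a stage re-executed in isolation; a machine-readable
``summary.json`` collects the headline quantities (multidiversity /
multifunctionality medians for islands vs controls, the per-island yield
decomposition, SEM paths).  All randomness flows from the single seed in
the run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference as inf
from . import multimetrics as mm
from . import sem
from .design import build_design, design_from_table, design_table
from .diversity import abundance_long_to_wide, plotwise_diversity
from .indicators import litter_annualize, litter_panel_stats, microclimate_amplitude, orient_buffering
from .structure import structure_pca
from .synthesis import TAXA, SimulationParams, simulate_dataset
from .yields import records_from_table, records_to_table, yield_change_table

log = logging.getLogger("ecoislands")

STAGES = ("synth", "indicators", "diversity", "multimetrics", "yield", "infer")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    stages: tuple[str, ...] = STAGES
    thresholds: tuple[int, int] = (1, 99)  # inclusive percent range
    headline_threshold: int = 50
    rarefaction: dict[str, int] = field(default_factory=lambda: {"trees": 24})
    rarefaction_resamples: int = 200
    corr_cutoff: float = 0.7
    force_drop: tuple[str, ...] = ("tree_growth",)
    diversity_order_for_summary: int = 0
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        lo, hi = self.thresholds
        if not (1 <= lo <= hi <= 99):
            raise ValueError("thresholds must satisfy 1 <= lo <= hi <= 99")
        if not (lo <= self.headline_threshold <= hi):
            raise ValueError("headline threshold outside the grid")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["force_drop"] = list(d["force_drop"])
        d["thresholds"] = list(d["thresholds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def sim_params(self) -> SimulationParams:
        return SimulationParams(seed=self.seed, **self.simulation)


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _read(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} missing — run the producing stage first (resumable checkpoint)"
        )
    return pd.read_csv(path, **kw)


def stage_synth(cfg: RunConfig) -> None:
    out = _out(cfg)
    design = build_design(seed=cfg.seed)
    ds = simulate_dataset(design, cfg.sim_params())
    design_table(design).to_csv(out / "design.csv", index=False)
    for taxon in TAXA:
        wide = ds.abundances[taxon]
        long = wide.stack().rename("count").reset_index()
        long.columns = ["plot_id", "species", "count"]
        long = long[long["count"] > 0]
        long.to_csv(out / f"abundance_{taxon}.csv", index=False)
    ds.indicators.rename_axis("plot_id").to_csv(out / "indicators_direct.csv")
    records_to_table(ds.yields).to_csv(out / "yields_raw.csv", index=False)
    ds.temperature_series.to_csv(out / "temperature.csv", index=False)
    ds.litter_series.to_csv(out / "litter_traps.csv", index=False)
    ds.structure_vars.rename_axis("plot_id").to_csv(out / "structure.csv")
    ds.latents.to_csv(out / "latents_truth.csv")


def stage_indicators(cfg: RunConfig) -> None:
    """Derive the remaining functioning indicators and assemble the panel."""
    out = _out(cfg)
    direct = _read(out / "indicators_direct.csv", index_col="plot_id")
    design = design_from_table(_read(out / "design.csv"))
    plot_ids = [p.plot_id for p in design]

    # microclimate buffering (negated median daily amplitude)
    temp = _read(out / "temperature.csv", parse_dates=["timestamp"])
    buffering = {}
    for plot_id, grp in temp.groupby("plot_id"):
        series = pd.Series(
            grp["temperature_c"].to_numpy(), index=grp["timestamp"].to_numpy()
        )
        buffering[plot_id] = orient_buffering(microclimate_amplitude(series))

    # annualized litter input with the campaign-wide 3-SD outlier rule
    litter = _read(out / "litter_traps.csv")
    per_date = litter.pivot_table(
        index=["plot_id", "date_index"], columns="trap", values="mass_g"
    )
    center, sd = litter_panel_stats(per_date.median(axis=1))
    litter_input = {}
    for plot_id, grp in per_date.groupby(level="plot_id"):
        litter_input[plot_id] = litter_annualize(
            grp.droplevel(0), outlier_center=center, outlier_sd=sd
        )

    # per-island oil-palm yield change
    records = records_from_table(_read(out / "yields_raw.csv"))
    ychange = yield_change_table(design, records)
    ychange.to_csv(out / "yield_change.csv")

    panel = direct.copy()
    panel["microclimate_buffering"] = pd.Series(buffering).reindex(plot_ids).to_numpy()
    panel["litter_input"] = pd.Series(litter_input).reindex(plot_ids).to_numpy()
    panel["oil_palm_yield"] = ychange["delta_y_island_kg"].reindex(plot_ids).to_numpy()
    panel.rename_axis("plot_id").to_csv(out / "functioning_panel.csv")


def stage_diversity(cfg: RunConfig) -> None:
    out = _out(cfg)
    tables = {}
    for taxon in TAXA:
        long = _read(out / f"abundance_{taxon}.csv")
        tables[taxon] = abundance_long_to_wide(long)
    div = plotwise_diversity(
        tables,
        rarefy_spec=cfg.rarefaction,
        n_resamples=cfg.rarefaction_resamples,
        seed=cfg.seed,
    )
    div.rename_axis("plot_id").to_csv(out / "diversity.csv")


def stage_multimetrics(cfg: RunConfig) -> None:
    out = _out(cfg)
    func = _read(out / "functioning_panel.csv", index_col="plot_id")
    div = _read(out / "diversity.csv", index_col="plot_id")

    kept, dropped = mm.preselect_indicators(
        func, corr_cutoff=cfg.corr_cutoff, force_drop=list(cfg.force_drop)
    )
    pd.DataFrame(
        {"indicator": list(func.columns),
         "retained": [c in set(kept) for c in func.columns]}
    ).to_csv(out / "functioning_retained.csv", index=False)

    lo, hi = cfg.thresholds
    grid = range(lo, hi + 1)
    profiles = []
    scaled_func = mm.unit_scale(func[kept])
    counts = mm.multimetric_threshold(scaled_func, grid)
    counts.insert(0, "role", "functioning")
    profiles.append(counts)
    averages = {"functioning_avg": mm.multimetric_average(scaled_func)}
    for q in (0, 1, 2):
        cols = [c for c in div.columns if c.endswith(f"_q{q}")]
        scaled = mm.unit_scale(div[cols])
        c_q = mm.multimetric_threshold(scaled, grid)
        c_q.insert(0, "role", f"biodiversity_q{q}")
        profiles.append(c_q)
        averages[f"biodiversity_q{q}_avg"] = mm.multimetric_average(scaled)
    prof = pd.concat(profiles)
    prof.rename_axis("plot_id").to_csv(out / "multimetric_profiles.csv")
    pd.DataFrame(averages).rename_axis("plot_id").to_csv(out / "multimetric_averages.csv")


def stage_yield(cfg: RunConfig) -> None:
    out = _out(cfg)
    if not (out / "yield_change.csv").exists():
        design = design_from_table(_read(out / "design.csv"))
        records = records_from_table(_read(out / "yields_raw.csv"))
        yield_change_table(design, records).to_csv(out / "yield_change.csv")


def stage_infer(cfg: RunConfig) -> None:
    out = _out(cfg)
    design = design_from_table(_read(out / "design.csv"))
    func = _read(out / "functioning_panel.csv", index_col="plot_id")
    retained = _read(out / "functioning_retained.csv")
    kept = retained.loc[retained["retained"], "indicator"].tolist()
    div = _read(out / "diversity.csv", index_col="plot_id")
    structure = _read(out / "structure.csv", index_col="plot_id")
    records = records_from_table(_read(out / "yields_raw.csv"))

    results = []
    panels = {"functioning": func[kept]}
    for q in (0, 1, 2):
        cols = [c for c in div.columns if c.endswith(f"_q{q}")]
        panels[f"biodiversity_q{q}"] = div[cols]
    for name, panel in panels.items():
        long = inf.make_long_table(mm.unit_scale(panel), design)
        tests = inf.fit_treatment_lmm(long)
        tests.insert(0, "panel", name)
        results.append(tests)
    pd.concat(results).to_csv(out / "treatment_tests.csv", index=False)

    flags = pd.Series(
        {p.plot_id: p.is_island for p in design}, name="island"
    )
    kw = pd.concat(
        [
            inf.kruskal_wallis_panel(panel, flags).assign(panel=name)
            for name, panel in panels.items()
        ]
    )
    kw.to_csv(out / "kruskal_wallis.csv", index=False)

    inf.tukey_position_test(records).to_csv(out / "tukey_positions.csv", index=False)

    # SEM on islands, with ordination axes as mediators
    axes = structure_pca(structure)
    island_ids = [p.plot_id for p in design if p.is_island]
    base = pd.DataFrame(
        {
            "log_area": np.log([p.edge_length for p in design if p.is_island]),
            "log_div": np.log1p([p.planted_diversity for p in design if p.is_island]),
        },
        index=island_ids,
    )
    base["pc1"] = axes.scores.loc[island_ids, "pc1"]
    base["pc2"] = axes.scores.loc[island_ids, "pc2"]
    prof = _read(out / "multimetric_profiles.csv", index_col="plot_id")
    t = str(cfg.headline_threshold)
    sem_tables = []
    for role, label in (
        ("functioning", "multifunctionality"),
        (f"biodiversity_q{cfg.diversity_order_for_summary}", "multidiversity"),
    ):
        data = base.copy()
        data["outcome"] = prof.loc[prof["role"] == role, t].reindex(island_ids)
        fit = sem.fit_piecewise_sem(data)
        tab = fit.paths.copy()
        tab.insert(0, "outcome", label)
        tab["fisher_c"] = fit.fisher_c
        tab["df"] = fit.df
        tab["p_model"] = fit.p_value
        sem_tables.append(tab)
    pd.concat(sem_tables).to_csv(out / "sem_paths.csv", index=False)


def _summary(cfg: RunConfig) -> dict:
    """Headline numbers from whichever stage outputs exist."""
    out = _out(cfg)
    design = design_from_table(_read(out / "design.csv"))
    islands = [p.plot_id for p in design if p.is_island]
    controls = [p.plot_id for p in design if not p.is_island]
    q = cfg.diversity_order_for_summary
    summary: dict = {
        "n_plots": len(design),
        "n_islands": len(islands),
        "island_area_ha": round(sum(p.area for p in design if p.is_island) / 1e4, 4),
        "headline_threshold_pct": cfg.headline_threshold,
    }
    if (out / "diversity.csv").exists():
        div = _read(out / "diversity.csv", index_col="plot_id")
        summary["n_biodiversity_indicators"] = int(
            sum(c.endswith(f"_q{q}") for c in div.columns)
        )
    if (out / "functioning_retained.csv").exists():
        retained = _read(out / "functioning_retained.csv")
        summary["n_functioning_retained"] = int(retained["retained"].sum())
    if (out / "multimetric_profiles.csv").exists():
        prof = _read(out / "multimetric_profiles.csv", index_col="plot_id")
        t = str(cfg.headline_threshold)

        def med(role, ids):
            sub = prof[prof["role"] == role]
            return float(sub.loc[sub.index.intersection(ids), t].median())

        summary.update(
            {
                "multifunctionality_median_islands": med("functioning", islands),
                "multifunctionality_median_controls": med("functioning", controls),
                f"multidiversity_q{q}_median_islands": med(f"biodiversity_q{q}", islands),
                f"multidiversity_q{q}_median_controls": med(f"biodiversity_q{q}", controls),
            }
        )
    if (out / "yield_change.csv").exists():
        ychange = _read(out / "yield_change.csv", index_col="plot_id")
        summary["delta_y_island_median_kg"] = float(
            ychange.loc[ychange.index.intersection(islands), "delta_y_island_kg"].median()
        )
    if (out / "sem_paths.csv").exists():
        sem_paths = _read(out / "sem_paths.csv")
        summary["sem_paths"] = sem_paths.round(6).to_dict(orient="records")
    return summary


def run_pipeline(cfg: RunConfig, resume: bool = False) -> Path:
    """Run the configured stages in order; returns the run directory."""
    cfg.validate()
    out = _out(cfg)
    cfg.to_yaml(out / "config.yaml")
    markers = {
        "synth": "design.csv",
        "indicators": "functioning_panel.csv",
        "diversity": "diversity.csv",
        "multimetrics": "multimetric_profiles.csv",
        "yield": "yield_change.csv",
        "infer": "sem_paths.csv",
    }
    funcs = {
        "synth": stage_synth,
        "indicators": stage_indicators,
        "diversity": stage_diversity,
        "multimetrics": stage_multimetrics,
        "yield": stage_yield,
        "infer": stage_infer,
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if resume and (out / markers[stage]).exists():
            log.info("stage %s: outputs present, skipped (resume)", stage)
            continue
        t0 = time.perf_counter()
        funcs[stage](cfg)
        log.info("stage %s: %.2f s", stage, time.perf_counter() - t0)
    summary = _summary(cfg)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
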