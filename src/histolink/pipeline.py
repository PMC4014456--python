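"""End-to-end orchestration: simulate -> enrich -> de -> concord -> report.

One seeded run produces a result bundle directory containing the
synthetic fixtures, per-male enriched regions and gene calls, per-embryo
DE tables, the concordance grid and a machine-readable summary.  Every
number in the summary is recomputable from the bundle's intermediate
files, and identical configs give byte-identical bundles (log messages
carry no timestamps for that reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression, overlap, tiling
from .simulate import SimulationConfig, StudyData, simulate_study, write_fixtures

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("histolink")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds plus an embedded simulation config."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    window: int = 600
    step: int = 100
    min_probes: int = 4
    p_enrich: float = 0.01
    merge_gap: int = 300
    mode: str = "single_vs_each_control"
    null_method: str = "auto"
    n_permutations: int = 1000
    fdr: float = 0.1
    cv_threshold: float = 5.0
    alpha: float = 0.05
    phi_convention: str = "paper"
    write_outputs: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("p_enrich", "fdr", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v!r} outside (0, 1)")
        if self.cv_threshold < 0:
            raise ValueError("cv_threshold must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        return cls(sim=SimulationConfig.from_dict(sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: RunConfig
    study: StudyData
    histone_results: tiling.TilingDifferentialResults
    de_calls: pd.DataFrame
    de_lists: dict[str, set]
    grid: pd.DataFrame
    summary: dict
    outdir: Path | None


def _setup_logging(outdir: Path | None, level: str = "INFO") -> None:
    log.setLevel(level)
    log.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(sh)
    if outdir is not None:
        fh = logging.FileHandler(outdir / "run.log", mode="w")
        fh.setFormatter(fmt)
        log.addHandler(fh)


def build_de_lists(de_calls: pd.DataFrame,
                   pedigree: dict[str, list[str]]) -> dict[str, set]:
    """Family (level 2) and genotype (level 3) DE lists, each also split
    by direction; labels like 'prt1:family', 'genotype:up'."""
    lists: dict[str, set] = {}
    for direction, suffix in ((None, ""), ("up", ":up"), ("down", ":down")):
        fam = overlap.build_level_lists(de_calls, pedigree, level=2,
                                        direction=direction)
        for sire, genes in fam.items():
            lists[f"{sire}:family{suffix}"] = set(genes)
        gen = overlap.build_level_lists(de_calls, pedigree, level=3,
                                        direction=direction)
        lists[f"genotype{suffix}"] = set(gen["genotype"])
    return lists


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study and concordance analysis.

    When ``outdir`` is given (and ``config.write_outputs``), the bundle
    is written there; partial outputs are preserved if a stage fails.
    """
    outdir = Path(outdir) if outdir is not None else None
    writing = outdir is not None and config.write_outputs
    if writing:
        outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir if writing else None, level=config.log_level)
    log.info("stage simulate: seed=%d genes=%d", config.sim.seed,
             config.sim.n_genes)

    study = simulate_study(config.sim)
    if writing:
        write_fixtures(study, outdir / "fixtures")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    log.info("stage enrich: %d perturbed vs %d control males, mode=%s",
             len(study.perturbed_males), len(study.control_males),
             config.mode)
    raw = tiling.ProbeTrack(probes=study.probes, values=study.intensities)
    normed = tiling.normalize_probes(raw)
    ratio = tiling.input_subtract(normed)
    model = tiling.TilingDifferential(ratio, study.genome,
                                      study.perturbed_males,
                                      study.control_males)
    regions: dict[str, pd.DataFrame] = {}
    hres = model.fit(mode=config.mode, window=config.window,
                     step=config.step, min_probes=config.min_probes,
                     p_threshold=config.p_enrich, merge_gap=config.merge_gap,
                     null_method=config.null_method,
                     n_permutations=config.n_permutations,
                     seed=config.sim.seed, region_sink=regions)
    if writing:
        enr = outdir / "enrichment"
        enr.mkdir(exist_ok=True)
        hres.to_frame().to_csv(enr / "gene_calls.tsv", sep="\t", index=False)
        hres.summary().to_csv(enr / "per_male_counts.tsv", sep="\t",
                              index=False)
        regdir = enr / "regions"
        regdir.mkdir(exist_ok=True)
        for key in sorted(regions):
            tiling.write_regions_bed(regions[key], regdir / f"{key}.bed")

    log.info("stage de: %d experimental embryos vs %d control embryos",
             (study.sample_meta["group"] == "perturbed").sum(),
             (study.sample_meta["group"] == "control").sum())
    meta = study.sample_meta
    control_embryos = list(meta.loc[meta["group"] == "control", "embryo_id"])
    experimental = list(meta.loc[meta["group"] == "perturbed", "embryo_id"])
    de_model = expression.EmbryoDEModel(study.expression, control_embryos)
    de_calls = de_model.fit_all(experimental, fdr=config.fdr)
    if writing:
        ded = outdir / "de"
        ded.mkdir(exist_ok=True)
        de_calls[de_calls["de"]].to_csv(ded / "de_calls.tsv", sep="\t",
                                        index=False)
        de_model.control_cv().to_csv(ded / "control_cv.tsv", sep="\t",
                                     index=False)

    log.info("stage concord: building level lists and overlap grid")
    pedigree = {s: e for s, e in study.pedigree().items()
                if s in study.perturbed_males}
    de_lists = build_de_lists(de_calls, pedigree)
    histone_sets = {m: hres.gene_sets(m) for m in study.perturbed_males}
    universe = set(study.genome.gene_ids)
    grid = overlap.pairwise_concordance_grid(
        histone_sets, de_lists, universe, alpha=config.alpha,
        phi_convention=config.phi_convention)

    summary = _summarize(config, study, hres, de_calls, grid)
    if writing:
        con = outdir / "concordance"
        con.mkdir(exist_ok=True)
        grid.to_csv(con / "grid.tsv", sep="\t", index=False)
        with open(con / "grid.json", "w") as fh:
            json.dump(grid.to_dict(orient="records"), fh, indent=1,
                      sort_keys=True, default=str)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("done: %d/%d grid cells significant",
             int(grid["significant"].sum()), len(grid))
    return PipelineResult(config=config, study=study, histone_results=hres,
                          de_calls=de_calls, de_lists=de_lists, grid=grid,
                          summary=summary, outdir=outdir)


def _summarize(config: RunConfig, study: StudyData,
               hres: tiling.TilingDifferentialResults,
               de_calls: pd.DataFrame, grid: pd.DataFrame) -> dict:
    per_male = hres.summary().set_index("male_id").to_dict(orient="index")
    de_by_embryo = {}
    for embryo, calls in de_calls.groupby("embryo_id"):
        de_by_embryo[embryo] = expression.summarize_direction(
            calls[calls["de"]])
    sig_by_stratum = {}
    for stratum, cells in grid.groupby("stratum"):
        sig_by_stratum[stratum] = {
            "n_cells": int(len(cells)),
            "n_significant": int(cells["significant"].sum()),
        }
    sig_cells = grid[grid["significant"]]
    return {
        "seed": config.sim.seed,
        "n_genes": config.sim.n_genes,
        "universe_size": len(study.genome.gene_ids),
        "histone_calls_per_male": per_male,
        "de_per_embryo": de_by_embryo,
        "grid_cells": int(len(grid)),
        "grid_significant": int(grid["significant"].sum()),
        "grid_significant_by_stratum": sig_by_stratum,
        "significant_cells": [
            f"{r.sire}:{r.stratum} x {r.de_list}"
            for r in sig_cells.itertuples(index=False)],
    }
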