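"""Synthetic sperm-chromatin and single-embryo expression generator.

Emulates the statistical structure of a sire -> offspring epigenetic
concordance study: most gene promoters carry a low level of retained
nucleosomes in mature sperm (the genome-wide retention level is on the
order of 1% in mouse), a chromatin perturbation shifts histone occupancy
up at some loci (MAT+) and down at others (MAT-), and only a fraction of
the sperm in a perturbed male actually express the aberrant states
(variegation, as seen in per-sperm protamine-deficiency staining).  Each
2-cell embryo is the product of a single sperm, so an aberrant paternal
locus is carried by an embryo only when the fertilizing sperm is one of
the affected ones, and even then it perturbs zygotic expression only with
a per-locus linkage probability ``p_link``.

Occupancy-to-signal link: the MNase-fraction probe intensity is linear in
the log-odds of the mean occupancy over the sperm population at that
probe, plus Gaussian noise in log2 space; the genomic-input channel is
occupancy-independent.  Maternal-class transcripts are never affected by
the paternal chromatin state; depleted loci (MAT-) bias embryo expression
up (precocious activation), enriched loci (MAT+) bias it down.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "GenomeModel",
    "SpermSample",
    "EmbryoSample",
    "StudyData",
    "generate_genome",
    "build_probe_table",
    "simulate_sperm_sample",
    "simulate_embryo",
    "simulate_study",
    "write_fixtures",
    "read_fixtures",
]

# log2 offsets placing raw channel intensities in a plausible scanner range
_MNASE_OFFSET = 12.0
_INPUT_OFFSET = 12.0

# occupancy penalty (log-odds units) of gene-body probes relative to promoter
FEATURE_LOGIT_OFFSET = {"promoter": 0.0, "cds": -1.5}

STATES = ("normal", "mat_plus", "mat_minus")


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig carries out-of-range parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Fractions/probabilities must lie in [0, 1]; identical configs produce
    byte-identical fixture files.  Effect sizes are in log-odds
    (``occupancy_shift``) or log2 units (``de_effect``, noise SDs).
    """

    seed: int = 0
    # genome / array geometry
    n_genes: int = 2000
    n_chroms: int = 5
    probes_per_promoter: int = 20
    probes_per_cds: int = 8
    probe_spacing: int = 50
    probe_length: int = 25
    cds_length: int = 2000
    gene_spacing: int = 10_000
    # occupancy model
    global_retention: float = 0.01
    gc_occupancy_coupling: float = 0.8
    methylation_occupancy_coupling: float = 1.2
    occupancy_logit_sd: float = 0.5
    # study design
    n_control_males: int = 3
    n_perturbed_males: int = 3
    sperm_per_sample: int = 100_000
    embryos_per_male: int = 3
    # perturbation
    frac_unaffected_sperm: float = 0.30
    frac_mat_plus_genes: float = 0.10
    frac_mat_minus_genes: float = 0.14
    occupancy_shift: float = 3.0
    probe_noise_sd: float = 0.25
    # sperm -> embryo linkage
    p_link: float = 0.05
    de_effect: float = 1.5
    expr_noise_sd: float = 0.065
    frac_maternal_genes: float = 0.30
    frac_zga_genes: float = 0.25

    def __post_init__(self) -> None:
        fracs = {
            "frac_unaffected_sperm": self.frac_unaffected_sperm,
            "frac_mat_plus_genes": self.frac_mat_plus_genes,
            "frac_mat_minus_genes": self.frac_mat_minus_genes,
            "p_link": self.p_link,
            "frac_maternal_genes": self.frac_maternal_genes,
            "frac_zga_genes": self.frac_zga_genes,
            "global_retention": self.global_retention,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value!r} outside [0, 1]")
        if self.frac_mat_plus_genes + self.frac_mat_minus_genes > 1.0:
            raise ConfigurationError("MAT+ and MAT- gene fractions sum above 1")
        if self.frac_maternal_genes + self.frac_zga_genes > 1.0:
            raise ConfigurationError("maternal and ZGA gene fractions sum above 1")
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        for name in ("n_chroms", "probes_per_promoter", "probe_spacing",
                     "probe_length", "sperm_per_sample", "n_control_males",
                     "n_perturbed_males", "embryos_per_male"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("probe_noise_sd", "expr_noise_sd", "occupancy_logit_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def promoter_length(self) -> int:
        return self.probes_per_promoter * self.probe_spacing

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class GenomeModel:
    """Gene universe: one row per gene plus chromosome sizes.

    ``genes`` columns: gene_id, chrom, strand, tss, promoter_start,
    promoter_end, cds_start, cds_end, gc_class, cpg_class, methylation,
    baseline_occupancy, expr_class, expr_baseline.
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids are not unique")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def extents(self) -> pd.DataFrame:
        """Annotated extent per gene (promoter union gene body), half-open."""
        g = self.genes
        return pd.DataFrame({
            "gene_id": g["gene_id"],
            "chrom": g["chrom"],
            "start": np.minimum(g["promoter_start"], g["cds_start"]),
            "end": np.maximum(g["promoter_end"], g["cds_end"]),
        })


@dataclass
class SpermSample:
    male_id: str
    genotype: str  # "control" | "perturbed"
    true_state: pd.Series  # gene_id -> normal / mat_plus / mat_minus
    occupancy: pd.Series  # realized population-mean occupancy per gene
    probe_values: pd.DataFrame  # raw linear intensities, cols <id>.mnase/.input


@dataclass
class EmbryoSample:
    embryo_id: str
    sire_id: str
    sperm_affected: bool
    fertilizing_states: pd.Series  # gene_id -> state carried by this sperm
    expression: pd.Series  # log2 values per gene
    true_de: pd.Series  # gene_id -> none / up / down


@dataclass
class StudyData:
    """Complete simulated study: genome, probe tracks, embryos, truth."""

    config: SimulationConfig
    genome: GenomeModel
    probes: pd.DataFrame  # chrom,start,end,probe_id,gene_id,feature (sorted)
    intensities: pd.DataFrame  # probe_id-indexed raw linear intensities
    sperm_samples: list[SpermSample]
    embryos: list[EmbryoSample]
    expression: pd.DataFrame  # genes x embryos, log2
    sample_meta: pd.DataFrame  # embryo_id, sire_id, group

    @property
    def control_males(self) -> list[str]:
        return [s.male_id for s in self.sperm_samples if s.genotype == "control"]

    @property
    def perturbed_males(self) -> list[str]:
        return [s.male_id for s in self.sperm_samples if s.genotype == "perturbed"]

    def sperm_truth(self) -> pd.DataFrame:
        rows = []
        for s in self.sperm_samples:
            df = pd.DataFrame({"gene_id": s.true_state.index,
                               "state": s.true_state.values})
            df.insert(0, "male_id", s.male_id)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def embryo_truth(self) -> pd.DataFrame:
        rows = []
        for e in self.embryos:
            de = e.true_de[e.true_de != "none"]
            df = pd.DataFrame({"gene_id": de.index, "true_de": de.values})
            df.insert(0, "embryo_id", e.embryo_id)
            rows.append(df)
        out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["embryo_id", "gene_id", "true_de"])
        return out

    def true_gene_sets(self, male_id: str) -> dict[str, set[str]]:
        """Truth MAT+/- gene sets for one male (for recovery checks)."""
        sample = next(s for s in self.sperm_samples if s.male_id == male_id)
        st = sample.true_state
        return {
            "MAT+": set(st.index[st == "mat_plus"]),
            "MAT-": set(st.index[st == "mat_minus"]),
        }

    def pedigree(self) -> dict[str, list[str]]:
        ped: dict[str, list[str]] = {}
        for e in self.embryos:
            ped.setdefault(e.sire_id, []).append(e.embryo_id)
        return ped


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Substream generator: fixed spawn keys keep per-male / per-embryo
    draws reproducible and independent of generation order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log2(p / (1.0 - p))


def _expit2(x):
    # inverse of _logit (base-2 log-odds)
    return 1.0 / (1.0 + 2.0 ** (-np.asarray(x, dtype=float)))


def generate_genome(config: SimulationConfig) -> GenomeModel:
    """Lay out ``n_genes`` loci with promoter/CDS intervals and the
    occupancy covariates: occupancy rises with GC class, falls with
    promoter methylation, and averages the configured global retention.
    """
    rng = _rng(config.seed, 0)
    n = config.n_genes
    chroms = np.array([f"chr{(i % config.n_chroms) + 1}" for i in range(n)])
    rank_on_chrom = np.zeros(n, dtype=int)
    counts: dict[str, int] = {}
    for i, c in enumerate(chroms):
        rank_on_chrom[i] = counts.get(c, 0)
        counts[c] = rank_on_chrom[i] + 1

    prom_len = config.promoter_length
    start0 = 5_000
    promoter_start = start0 + rank_on_chrom * config.gene_spacing
    tss = promoter_start + prom_len
    cds_start = tss
    cds_end = cds_start + config.cds_length

    strand = np.where(rng.random(n) < 0.5, "+", "-")

    gc_score = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
    gc_class = np.array(["low", "mid", "high"])[gc_score]
    # CpG promoter class largely tracks GC with some scrambling
    cpg_score = np.clip(gc_score + rng.choice([-1, 0, 1], size=n,
                                              p=[0.1, 0.8, 0.1]), 0, 2)
    cpg_class = np.array(["LCP", "ICP", "HCP"])[cpg_score]
    methylation = rng.beta(2.0, 5.0, size=n)

    logit = (
        _logit(config.global_retention)
        + config.gc_occupancy_coupling * (gc_score - 1)
        - config.methylation_occupancy_coupling * (methylation - methylation.mean())
        + rng.normal(0.0, config.occupancy_logit_sd, size=n)
    )
    occ = _expit2(logit)
    # renormalize so the population mean matches the configured retention
    occ = np.clip(occ * (config.global_retention / occ.mean()), 1e-6, 0.5)

    expr_class = np.full(n, "other", dtype=object)
    u = rng.random(n)
    expr_class[u < config.frac_maternal_genes] = "maternal"
    expr_class[(u >= config.frac_maternal_genes)
               & (u < config.frac_maternal_genes + config.frac_zga_genes)] = "zga"
    expr_baseline = np.where(
        expr_class == "maternal", rng.normal(7.0, 0.8, n),
        np.where(expr_class == "zga", rng.normal(6.0, 0.8, n),
                 rng.normal(2.0, 0.3, n)))

    width = len(str(n - 1))
    genes = pd.DataFrame({
        "gene_id": [f"g{i:0{width}d}" for i in range(n)],
        "chrom": chroms,
        "strand": strand,
        "tss": tss,
        "promoter_start": promoter_start,
        "promoter_end": tss,
        "cds_start": cds_start,
        "cds_end": cds_end,
        "gc_class": gc_class,
        "cpg_class": cpg_class,
        "methylation": methylation,
        "baseline_occupancy": occ,
        "expr_class": expr_class,
        "expr_baseline": expr_baseline,
    })
    chrom_lengths = {c: int(genes.loc[genes["chrom"] == c, "cds_end"].max() + 5_000)
                     for c in sorted(set(chroms))}
    return GenomeModel(genes=genes, chrom_lengths=chrom_lengths)


def build_probe_table(genome: GenomeModel, config: SimulationConfig) -> pd.DataFrame:
    """Tiling probes over each promoter and the 5' end of each gene body.

    Coordinates are 0-based half-open; probes are sorted by (chrom, start).
    """
    recs = []
    for row in genome.genes.itertuples(index=False):
        for j in range(config.probes_per_promoter):
            s = row.promoter_start + j * config.probe_spacing
            recs.append((row.chrom, s, s + config.probe_length,
                         f"{row.gene_id}:p{j}", row.gene_id, "promoter"))
        for j in range(config.probes_per_cds):
            s = row.cds_start + j * config.probe_spacing
            recs.append((row.chrom, s, s + config.probe_length,
                         f"{row.gene_id}:c{j}", row.gene_id, "cds"))
    probes = pd.DataFrame(recs, columns=["chrom", "start", "end", "probe_id",
                                         "gene_id", "feature"])
    return probes.sort_values(["chrom", "start"], kind="mergesort",
                              ignore_index=True)


def _draw_states(config: SimulationConfig, gene_ids: pd.Index,
                 rng: np.random.Generator) -> pd.Series:
    u = rng.random(len(gene_ids))
    states = np.full(len(gene_ids), "normal", dtype=object)
    states[u < config.frac_mat_plus_genes] = "mat_plus"
    states[(u >= config.frac_mat_plus_genes)
           & (u < config.frac_mat_plus_genes + config.frac_mat_minus_genes)] = "mat_minus"
    return pd.Series(states, index=gene_ids)


def simulate_sperm_sample(genome: GenomeModel, config: SimulationConfig,
                          genotype: str, male_id: str | None = None,
                          stream: int = 0,
                          probes: pd.DataFrame | None = None) -> SpermSample:
    """One male's MNase-fraction + input probe track.

    Perturbed males draw per-gene MAT states once; the aberrant occupancy
    is expressed only in ``1 - frac_unaffected_sperm`` of the sperm, so
    the population-mean occupancy at an aberrant locus is the variegated
    mixture of shifted and baseline occupancy.
    """
    if genotype not in ("control", "perturbed"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if male_id is None:
        male_id = f"{genotype}{stream}"
    if probes is None:
        probes = build_probe_table(genome, config)
    rng = _rng(config.seed, 1, 0 if genotype == "control" else 1, stream)

    gene_ids = genome.gene_ids
    base_occ = pd.Series(genome.genes["baseline_occupancy"].to_numpy(),
                         index=gene_ids)
    if genotype == "perturbed":
        states = _draw_states(config, gene_ids, rng)
    else:
        states = pd.Series("normal", index=gene_ids)

    logit0 = _logit(base_occ.to_numpy())
    shift = np.where(states.to_numpy() == "mat_plus", config.occupancy_shift,
                     np.where(states.to_numpy() == "mat_minus",
                              -config.occupancy_shift, 0.0))
    occ_affected = _expit2(logit0 + shift)
    fu = config.frac_unaffected_sperm
    pop_occ = (1.0 - fu) * occ_affected + fu * base_occ.to_numpy()

    # finite sperm population: binomial sampling of per-locus retention
    S = config.sperm_per_sample
    occ_hat = rng.binomial(S, pop_occ) / S
    occ_hat = np.clip(occ_hat, 0.5 / S, 1.0 - 0.5 / S)
    occ_series = pd.Series(occ_hat, index=gene_ids)

    probe_occ = occ_series.reindex(probes["gene_id"]).to_numpy()
    feat_off = probes["feature"].map(FEATURE_LOGIT_OFFSET).to_numpy()
    probe_logit = _logit(probe_occ) + feat_off

    n_probes = len(probes)
    mnase_log2 = (_MNASE_OFFSET + probe_logit
                  + rng.normal(0.0, config.probe_noise_sd, n_probes))
    input_log2 = (_INPUT_OFFSET
                  + rng.normal(0.0, config.probe_noise_sd, n_probes))
    values = pd.DataFrame({
        f"{male_id}.mnase": np.power(2.0, mnase_log2),
        f"{male_id}.input": np.power(2.0, input_log2),
    }, index=pd.Index(probes["probe_id"], name="probe_id"))

    return SpermSample(male_id=male_id, genotype=genotype, true_state=states,
                       occupancy=occ_series, probe_values=values)


def simulate_embryo(sire: SpermSample, genome: GenomeModel,
                    config: SimulationConfig, embryo_id: str | None = None,
                    stream: int = 0) -> EmbryoSample:
    """One 2-cell embryo fertilized by a single sperm drawn from the sire.

    The sperm carries the sire's aberrant states with probability
    ``1 - frac_unaffected_sperm`` (affected sperm) and is otherwise
    normal.  Each carried aberrant, non-maternal locus becomes truly
    differentially expressed with probability ``p_link``: MAT- biases up,
    MAT+ biases down.  Maternal-class genes are never affected.
    """
    if embryo_id is None:
        embryo_id = f"{sire.male_id}.e{stream}"
    rng = _rng(config.seed, 2, zlib.crc32(sire.male_id.encode()) % (2 ** 31),
               stream)

    gene_ids = genome.gene_ids
    affected = bool(rng.random() < (1.0 - config.frac_unaffected_sperm)) \
        if sire.genotype == "perturbed" else False
    if affected:
        fert_states = sire.true_state.copy()
    else:
        fert_states = pd.Series("normal", index=gene_ids)

    expr_class = pd.Series(genome.genes["expr_class"].to_numpy(), index=gene_ids)
    aberrant = (fert_states != "normal") & (expr_class != "maternal")
    linked = aberrant & pd.Series(rng.random(len(gene_ids)) < config.p_link,
                                  index=gene_ids)
    true_de = pd.Series("none", index=gene_ids)
    true_de[linked & (fert_states == "mat_minus")] = "up"
    true_de[linked & (fert_states == "mat_plus")] = "down"

    effect = np.where(true_de.to_numpy() == "up", config.de_effect,
                      np.where(true_de.to_numpy() == "down",
                               -config.de_effect, 0.0))
    expression = pd.Series(
        genome.genes["expr_baseline"].to_numpy() + effect
        + rng.normal(0.0, config.expr_noise_sd, len(gene_ids)),
        index=gene_ids)

    return EmbryoSample(embryo_id=embryo_id, sire_id=sire.male_id,
                        sperm_affected=affected, fertilizing_states=fert_states,
                        expression=expression, true_de=true_de)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Full study: genome, per-male probe tracks, per-embryo transcriptomes."""
    genome = generate_genome(config)
    probes = build_probe_table(genome, config)

    samples: list[SpermSample] = []
    for i in range(config.n_control_males):
        samples.append(simulate_sperm_sample(
            genome, config, "control", male_id=f"ctl{i + 1}", stream=i,
            probes=probes))
    for i in range(config.n_perturbed_males):
        samples.append(simulate_sperm_sample(
            genome, config, "perturbed", male_id=f"prt{i + 1}", stream=i,
            probes=probes))

    intensities = pd.concat([s.probe_values for s in samples], axis=1)

    embryos: list[EmbryoSample] = []
    for s in samples:
        for k in range(config.embryos_per_male):
            embryos.append(simulate_embryo(s, genome, config,
                                           embryo_id=f"{s.male_id}.e{k + 1}",
                                           stream=k))
    expression = pd.DataFrame(
        {e.embryo_id: e.expression for e in embryos})
    expression.index.name = "gene_id"
    meta = pd.DataFrame({
        "embryo_id": [e.embryo_id for e in embryos],
        "sire_id": [e.sire_id for e in embryos],
        "group": ["control" if e.sire_id.startswith("ctl") else "perturbed"
                  for e in embryos],
    })
    return StudyData(config=config, genome=genome, probes=probes,
                     intensities=intensities, sperm_samples=samples,
                     embryos=embryos, expression=expression, sample_meta=meta)


# ---------------------------------------------------------------------------
# fixture I/O (plain text, byte-stable under a fixed seed)

def write_fixtures(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Emit the study as plain-text files; re-running with the same config
    reproduces byte-identical output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": outdir / "probes.bed",
        "intensities": outdir / "intensities.tsv",
        "genes": outdir / "genes.tsv",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "sperm_truth": outdir / "sperm_truth.tsv",
        "embryo_truth": outdir / "embryo_truth.tsv",
        "config": outdir / "config.yaml",
    }
    study.probes[["chrom", "start", "end", "probe_id"]].to_csv(
        paths["probes"], sep="\t", header=False, index=False)
    study.probes[["probe_id", "gene_id", "feature"]].to_csv(
        outdir / "probe_annotation.tsv", sep="\t", index=False)
    paths["probe_annotation"] = outdir / "probe_annotation.tsv"
    study.intensities.to_csv(paths["intensities"], sep="\t")
    study.genome.genes.to_csv(paths["genes"], sep="\t", index=False)
    study.expression.to_csv(paths["expression"], sep="\t")
    study.sample_meta.to_csv(paths["samples"], sep="\t", index=False)
    study.sperm_truth().to_csv(paths["sperm_truth"], sep="\t", index=False)
    study.embryo_truth().to_csv(paths["embryo_truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh, sort_keys=True)
    return paths


def read_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def read_probe_table(bed_path: str | Path,
                     annotation_path: str | Path | None = None) -> pd.DataFrame:
    probes = pd.read_csv(bed_path, sep="\t", header=None,
                         names=["chrom", "start", "end", "probe_id"])
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t")
        probes = probes.merge(ann, on="probe_id", how="left")
    return probes


def read_intensities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_genome_table(path: str | Path) -> GenomeModel:
    genes = pd.read_csv(path, sep="\t")
    chrom_lengths = {c: int(genes.loc[genes["chrom"] == c, "cds_end"].max() + 5_000)
                     for c in sorted(set(genes["chrom"]))}
    return GenomeModel(genes=genes, chrom_lengths=chrom_lengths)


def read_fixtures(outdir: str | Path) -> dict:
    """Parse a fixture directory back into in-memory tables."""
    outdir = Path(outdir)
    return {
        "config": read_config(outdir / "config.yaml"),
        "probes": read_probe_table(outdir / "probes.bed",
                                   outdir / "probe_annotation.tsv"),
        "intensities": read_intensities(outdir / "intensities.tsv"),
        "genome": read_genome_table(outdir / "genes.tsv"),
        "expression": read_expression(outdir / "expression.tsv"),
        "sample_meta": pd.read_csv(outdir / "samples.tsv", sep="\t"),
        "sperm_truth": pd.read_csv(outdir / "sperm_truth.tsv", sep="\t"),
        "embryo_truth": pd.read_csv(outdir / "embryo_truth.tsv", sep="\t"),
    }
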