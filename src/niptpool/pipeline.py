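"""End-to-end pipeline: simulate -> preprocess -> call -> validate.

The pipeline is deterministic given (config, seed): every stage draws its
randomness from a seed derived from the global seed by a fixed counter, and
reruns produce byte-identical outputs.  Each stage consumes only the
previous stage's declared outputs and logs in/out counts for every filter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import caller, preprocess, validate
from . import simulate as sim
from .core import (
    GenotypeMatrix,
    NiptpoolError,
    PopulationAFTable,
    ReadSet,
    ToyGenome,
    logger,
    write_cohort_tsv,
    write_truth_vcf,
)

DEFAULT_GENOME = [["chr1", 70_000, "autosome"], ["chrX", 20_000, "X"], ["chrY", 10_000, "Y"]]


class PipelineStageError(NiptpoolError):
    """A pipeline stage failed; ``stage`` names the failing stage and partial
    outputs written before the failure are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulateConfig:
    n_samples: int = 50
    n_sites: int = 300
    genome: list = field(default_factory=lambda: [list(x) for x in DEFAULT_GENOME])
    populations: dict = field(default_factory=lambda: {"main": 0.05, "related": 0.05})
    cohort_population: str = "main"
    sfs_shape: list = field(default_factory=lambda: [0.5, 0.5])
    sfs_bounds: list = field(default_factory=lambda: [0.01, 0.99])
    titv: float = 2.0
    fetal_fraction: Any = sim.DEFAULT_FETAL_FRACTION
    p_male: float = sim.DEFAULT_P_MALE
    depth: Any = sim.DEFAULT_DEPTH
    read_len: int = sim.DEFAULT_READ_LEN
    insert_mean: float = sim.DEFAULT_INSERT_MEAN
    insert_sd: float = sim.DEFAULT_INSERT_SD
    insert_max: int = sim.DEFAULT_INSERT_MAX
    error_rate: float = sim.DEFAULT_ERROR_RATE
    low_mapq_regions: list | None = None


@dataclass
class PreprocessConfig:
    min_mapq: int = preprocess.DEFAULT_MIN_MAPQ
    max_k: int = 5


@dataclass
class CallConfig:
    error_rate: float = caller.DEFAULT_ERROR_RATE
    alpha_site: float | None = None  # default: 0.05 / genome length
    min_alt: int = caller.DEFAULT_MIN_ALT
    strand_p: float = caller.DEFAULT_STRAND_P


@dataclass
class ValidateConfig:
    panel_individuals: int = 99  # size of the primary (same-population) panel
    panel2_individuals: int = 100  # size of the diverged-population panel
    db_fraction: float = 0.95  # fraction of truth sites present in the "database" panel
    min_carriers: int = 2
    n_pseudo_individuals: int = 100
    pca_components: int = 2


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "niptpool_out"
    write_sam: bool = True
    write_plots: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    call: CallConfig = field(default_factory=CallConfig)
    validate: ValidateConfig = field(default_factory=ValidateConfig)

    def validated(self) -> "PipelineConfig":
        s = self.simulate
        if s.n_samples < 1:
            raise NiptpoolError("n_samples must be >= 1")
        if s.n_sites < 1:
            raise NiptpoolError("n_sites must be >= 1")
        if s.cohort_population not in s.populations:
            raise NiptpoolError(f"cohort_population {s.cohort_population!r} not in populations")
        if not 0.0 <= s.error_rate < 0.5:
            raise NiptpoolError("error_rate must lie in [0, 0.5)")
        return self

    # -- YAML round trip ----------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _build(cls, d, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build(cls, d: dict, path: str):
    """Build a (possibly nested) config dataclass, rejecting unknown keys."""
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise NiptpoolError(f"config section {path or '<root>'} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise NiptpoolError(f"unknown config keys in {path or '<root>'}: {sorted(unknown)}")
    kwargs = {}
    for key, value in d.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in ("simulate", "preprocess", "call", "validate"):
            sub_cls = {"simulate": SimulateConfig, "preprocess": PreprocessConfig,
                       "call": CallConfig, "validate": ValidateConfig}.get(f.name)
            kwargs[key] = _build(sub_cls, value, f"{path}.{key}" if path else key) if sub_cls else value
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _seed(config: PipelineConfig, counter: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config.seed, spawn_key=(counter,))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    genome: ToyGenome
    af_table: PopulationAFTable
    cohort: list
    reads: ReadSet


def stage_simulate(config: PipelineConfig, outdir: Path | None = None) -> SimBundle:
    s = config.simulate
    genome = ToyGenome.random([tuple(x) for x in s.genome], seed=_seed(config, 0))
    af_table = sim.simulate_population_afs(
        genome, s.n_sites, dict(s.populations), sfs_shape=tuple(s.sfs_shape),
        sfs_bounds=tuple(s.sfs_bounds), titv=s.titv, seed=_seed(config, 1),
    )
    cohort = sim.simulate_nipt_cohort(
        af_table, s.cohort_population, s.n_samples, genome=genome,
        fetal_fraction=s.fetal_fraction, p_male=s.p_male, depth=s.depth, seed=_seed(config, 2),
    )
    low_mapq = [tuple(r) for r in s.low_mapq_regions] if s.low_mapq_regions else None
    reads = sim.simulate_cohort_reads(
        cohort, genome, af_table, seed=_seed(config, 3), read_len=s.read_len,
        insert_mean=s.insert_mean, insert_sd=s.insert_sd, insert_max=s.insert_max,
        error_rate=s.error_rate, low_mapq_regions=low_mapq,
    )
    logger.info("simulate: %d samples, %d sites, %d reads", len(cohort), af_table.n_sites, len(reads))
    if outdir is not None:
        genome.to_fasta(outdir / "genome.fasta")
        write_truth_vcf(af_table, outdir / "truth.vcf", genome=genome)
        write_cohort_tsv(cohort, outdir / "cohort.tsv")
        if config.write_sam:
            reads.to_sam(outdir / "reads.sam", genome)
    return SimBundle(genome, af_table, cohort, reads)


@dataclass
class PreprocessBundle:
    reads: ReadSet
    coverage_pre: preprocess.CoverageSummary
    coverage_post: preprocess.CoverageSummary


def stage_preprocess(config: PipelineConfig, bundle: SimBundle, outdir: Path | None = None) -> PreprocessBundle:
    p = config.preprocess
    cov_pre = preprocess.coverage_summary(bundle.reads, bundle.genome, max_k=p.max_k)
    filtered = preprocess.deduplicate_overlaps(preprocess.filter_mapq(bundle.reads, p.min_mapq))
    cov_post = preprocess.coverage_summary(filtered, bundle.genome, max_k=p.max_k)
    if outdir is not None:
        cov_pre.to_tsv(outdir / "coverage_pre.tsv")
        cov_post.to_tsv(outdir / "coverage_post.tsv")
        if config.write_sam:
            filtered.to_sam(outdir / "reads.filtered.sam", bundle.genome)
    return PreprocessBundle(filtered, cov_pre, cov_post)


def stage_call(config: PipelineConfig, bundle: SimBundle, pre: PreprocessBundle,
               outdir: Path | None = None) -> pd.DataFrame:
    c = config.call
    pile = caller.pileup(pre.reads, bundle.genome)
    calls = caller.call_pileup(
        pile, error_rate=c.error_rate, alpha_site=c.alpha_site,
        min_alt=c.min_alt, genome_length=bundle.genome.total_length,
    )
    calls = caller.strand_bias_filter(calls, pile, p_threshold=c.strand_p)
    if outdir is not None:
        caller.write_callset(calls, outdir / "calls.vcf", genome=bundle.genome)
        caller.write_call_tsv(calls, outdir / "calls.tsv")
    return calls


def build_panels(config: PipelineConfig, bundle: SimBundle) -> dict[str, Any]:
    """Simulate the reference panels the call set is validated against:

    * ``panel1`` — individual genotypes from the cohort's own population
      (a KHV-style small reference cohort);
    * ``panel2`` — genotypes from the diverged population (EAS-style);
    * ``db`` — a site-only database holding a fixed fraction of all truth
      sites (dbSNP-style).
    """
    v = config.validate
    s = config.simulate
    pops = list(s.populations)
    other = next((p for p in pops if p != s.cohort_population), s.cohort_population)
    panel1 = sim.simulate_genotypes(bundle.af_table, s.cohort_population, v.panel_individuals,
                                    genome=bundle.genome, seed=_seed(config, 4))
    panel1.meta["source"] = "genotypes"
    panel2 = sim.simulate_genotypes(bundle.af_table, other, v.panel2_individuals,
                                    genome=bundle.genome, seed=_seed(config, 5))
    panel2.meta["source"] = "genotypes"
    rng = np.random.default_rng(_seed(config, 6))
    keep = rng.random(bundle.af_table.n_sites) < v.db_fraction
    db_sites = bundle.af_table.site_keys()[keep]
    return {"panel1": panel1, "panel2": panel2, "db_sites": db_sites,
            "panel1_name": s.cohort_population, "panel2_name": other}


def stage_validate(config: PipelineConfig, bundle: SimBundle, pre: PreprocessBundle,
                   calls: pd.DataFrame, outdir: Path | None = None) -> dict[str, Any]:
    v = config.validate
    panels = build_panels(config, bundle)
    panel1: GenotypeMatrix = panels["panel1"]
    panel2: GenotypeMatrix = panels["panel2"]

    passing = calls[calls["filter"] == "PASS"].reset_index(drop=True)
    call_sites = validate.site_index(passing)

    panel1_sites = panel1.site_keys()[panel1.carriers() >= 1]
    panel2_sites = panel2.site_keys()[panel2.carriers() >= 1]
    partition = validate.partition_callset(
        call_sites,
        [("panel1", panel1_sites), ("panel2", panel2_sites), ("db", panels["db_sites"])],
    )

    metrics: dict[str, Any] = {"n_calls": len(calls), "n_pass": len(passing)}
    try:
        metrics["titv"] = caller.titv_ratio(passing)
    except NiptpoolError:
        metrics["titv"] = float("nan")
    metrics["sensitivity_common"] = validate.common_snp_sensitivity(panel1, passing, v.min_carriers)

    panel1_af = panel1.sites[["chrom", "pos", "ref", "alt"]].copy()
    panel1_af["af"] = panel1.allele_frequency()
    merged = passing.rename(columns={"af": "af_est"}).merge(panel1_af, on=["chrom", "pos", "ref", "alt"])
    merged = merged.rename(columns={"af": "af_ref"})
    metrics["af_correlation"] = (
        validate.af_correlation(merged["af_est"], merged["af_ref"]) if len(merged) >= 2 else float("nan")
    )

    # Y-dosage accounting is a property of the raw pooled data; the overlap
    # filter removes proportionally more reads where per-sample depth is
    # higher (autosomes) and would bias the ratio upward.
    metrics["y_depth_ratio"] = (
        validate.y_depth_ratio(bundle.reads, bundle.genome) if bundle.genome.y_chromosome else float("nan")
    )
    ff = config.simulate.fetal_fraction
    if np.isscalar(ff):
        metrics["y_depth_ratio_predicted"] = validate.predicted_y_depth_ratio(float(ff), config.simulate.p_male)

    pseudo = validate.simulate_genotypes_from_af(
        passing, passing["af"].to_numpy(), n_individuals=v.n_pseudo_individuals,
        label="pooled_sim", seed=_seed(config, 7),
    )
    try:
        shared = validate.restrict_to_shared_sites([panel1, panel2, pseudo])
        pca = validate.pca_genotypes(shared, k=v.pca_components)
    except NiptpoolError:
        pca = None

    for name, count in partition.counts.items():
        metrics[f"partition_{name}"] = count
        metrics[f"partition_{name}_pct"] = partition.percentages[name]

    if outdir is not None:
        pd.DataFrame({"metric": list(metrics), "value": [metrics[m] for m in metrics]}).to_csv(
            outdir / "metrics.tsv", sep="\t", index=False
        )
        partition.to_frame().to_csv(outdir / "partition.tsv", sep="\t", index=False)
        if pca is not None:
            pca.to_tsv(outdir / "pca.tsv")
            if config.write_plots:
                validate.plot_pca(pca, outdir / "pca.png")
        if config.write_plots and len(merged) >= 2:
            validate.plot_af_scatter(merged, outdir / "af_scatter.png")
    return {"metrics": metrics, "partition": partition, "pca": pca, "af_merged": merged}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineReport:
    config: PipelineConfig
    sim: SimBundle
    pre: PreprocessBundle
    calls: pd.DataFrame
    metrics: dict[str, Any]
    partition: validate.CallSetPartition
    pca: validate.PCAResult | None
    outdir: Path | None


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineReport:
    """Run all four stages; deterministic given (config, seed).

    When ``outdir`` is given (or set in the config), every stage writes its
    declared outputs there, along with the fully resolved configuration.
    Stage failures raise :class:`PipelineStageError` naming the stage;
    outputs already written are retained.
    """
    config.validated()
    out = Path(outdir) if outdir is not None else (Path(config.outdir) if config.outdir else None)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.resolved.yaml")

    stages = {}
    try:
        stage = "simulate"
        bundle = stage_simulate(config, out)
        stage = "preprocess"
        pre = stage_preprocess(config, bundle, out)
        stage = "call"
        calls = stage_call(config, bundle, pre, out)
        stage = "validate"
        report = stage_validate(config, bundle, pre, calls, out)
    except NiptpoolError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, exc) from exc
    del stages
    return PipelineReport(config, bundle, pre, calls, report["metrics"], report["partition"],
                          report["pca"], out)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_SIZES = {
    "tiny": dict(n_samples=3, n_sites=30,
                 genome=[["chr1", 6_000, "autosome"], ["chrX", 2_500, "X"], ["chrY", 1_500, "Y"]]),
    "small": dict(n_samples=50, n_sites=300,
                  genome=[["chr1", 70_000, "autosome"], ["chrX", 20_000, "X"], ["chrY", 10_000, "Y"]]),
    "paper_like_scaled": dict(n_samples=500, n_sites=5_000, depth=0.15,
                              genome=[["chr1", 450_000, "autosome"], ["chr2", 350_000, "autosome"],
                                      ["chrX", 150_000, "X"], ["chrY", 50_000, "Y"]]),
}


def fixture_config(size: str, seed: int = 0, **overrides) -> PipelineConfig:
    """Pipeline configuration for a named fixture scale."""
    if size not in FIXTURE_SIZES:
        raise NiptpoolError(f"unknown fixture size {size!r}; choose from {sorted(FIXTURE_SIZES)}")
    params = dict(FIXTURE_SIZES[size])
    params.update(overrides)
    return PipelineConfig(seed=seed, simulate=SimulateConfig(**params))


def make_fixtures(size: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Generate an on-disk dataset bundle: genome FASTA, pooled SAM, truth
    VCF, panel site/AF TSVs and cohort metadata."""
    config = fixture_config(size, seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = stage_simulate(config, out)
    panels = build_panels(config, bundle)
    paths = {
        "genome": out / "genome.fasta", "sam": out / "reads.sam",
        "truth_vcf": out / "truth.vcf", "cohort": out / "cohort.tsv",
    }
    for name in ("panel1", "panel2"):
        gm: GenotypeMatrix = panels[name]
        df = gm.sites[["chrom", "pos", "ref", "alt"]].copy()
        df["af"] = gm.allele_frequency()
        df["carriers"] = gm.carriers()
        df = df[df["carriers"] >= 1]
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    db = pd.DataFrame(list(panels["db_sites"]), columns=["chrom", "pos", "ref", "alt"])
    db.to_csv(out / "db_panel.tsv", sep="\t", index=False)
    paths["db"] = out / "db_panel.tsv"
    config.to_yaml(out / "config.resolved.yaml")
    return paths


def configure_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")
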