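import numpy as np
import pandas as pd
import pytest

import niptpool as nt
from niptpool.core import READ_COLUMNS, empty_mismatches
from niptpool.pipeline import fixture_config, run_pipeline


@pytest.fixture(scope="session")
def toy_genome() -> nt.ToyGenome:
    return nt.ToyGenome.random(
        [("chr1", 20_000, "autosome"), ("chr2", 12_000, "autosome"), ("chrX", 8_000, "X"), ("chrY", 4_000, "Y")],
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_af(toy_genome) -> nt.PopulationAFTable:
    return nt.simulate_population_afs(toy_genome, 80, {"main": 0.05, "related": 0.1}, seed=8)


@pytest.fixture(scope="session")
def toy_cohort(toy_genome, toy_af):
    return nt.simulate_nipt_cohort(toy_af, "main", 12, genome=toy_genome, seed=9)


@pytest.fixture(scope="session")
def toy_reads(toy_genome, toy_af, toy_cohort) -> nt.ReadSet:
    return nt.simulate_cohort_reads(toy_cohort, toy_genome, toy_af, seed=10)


@pytest.fixture(scope="session")
def small_report(tmp_path_factory):
    """One full pipeline run on the 'small' scale, reused across tests."""
    cfg = fixture_config("small", seed=5)
    return run_pipeline(cfg, outdir=tmp_path_factory.mktemp("small_run"))


def make_readset(rows, mismatches=None) -> nt.ReadSet:
    """Build a ReadSet from (sample, chrom, start, end) or full-column tuples."""
    full = []
    for r in rows:
        if len(r) == 4:
            sample, chrom, start, end = r
            full.append((sample, chrom, start, end, False, 60, f"{sample}:{start}", 0))
        else:
            full.append(tuple(r))
    df = pd.DataFrame(full, columns=READ_COLUMNS)
    mm = empty_mismatches()
    if mismatches:
        mm = pd.DataFrame(mismatches, columns=["read", "chrom", "pos", "base"])
    return nt.ReadSet(df, mm)


def brute_force_depth(reads: nt.ReadSet, genome: nt.ToyGenome, sample=None) -> dict[str, np.ndarray]:
    """Independent per-position depth counter (loop over reads)."""
    depth = {c.name: np.zeros(c.length, dtype=int) for c in genome.chromosomes}
    df = reads.df if sample is None else reads.df[reads.df["sample"] == sample]
    for row in df.itertuples(index=False):
        depth[row.chrom][row.start - 1 : row.end] += 1
    return depth
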