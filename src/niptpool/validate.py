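"""Validation and population-genetics analyses of the pooled call set.

Mirrors the checks a pooled-NIPT study runs against reference panels:
partitioning the call set by panel membership, sensitivity on common SNPs,
allele-frequency correlation, genotype simulation from estimated AFs
followed by PCA, sex-chromosome/fetal-fraction dosage accounting, and
Hardy–Weinberg carrier frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CHROM_Y,
    GenotypeMatrix,
    NiptpoolError,
    PopulationAFTable,
    ReadSet,
    ToyGenome,
)
from . import simulate as _sim

SiteKeys = pd.Index  # any hashable site identity; we use (chrom, pos, ref, alt)


def site_index(df: pd.DataFrame) -> pd.MultiIndex:
    """(chrom, pos, ref, alt) site-identity keys from a call/panel table."""
    return pd.MultiIndex.from_frame(df[["chrom", "pos", "ref", "alt"]])


# ---------------------------------------------------------------------------
# Call-set partition
# ---------------------------------------------------------------------------


@dataclass
class CallSetPartition:
    """Assignment of each query site to the first panel containing it.

    ``counts``/``percentages`` are ordered dicts over panel names plus the
    terminal ``novel`` category; percentages are relative to the query size.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self.counts), "count": list(self.counts.values()),
             "percent": list(self.percentages.values())}
        )


def partition_callset(query_sites, panels: Sequence[tuple[str, object]]) -> CallSetPartition:
    """Partition a call set against ordered reference panels (first match
    wins); sites matched by no panel are ``novel``.  Percentages are with
    respect to the query call set."""
    query = pd.Index(query_sites)
    if query.has_duplicates:
        raise NiptpoolError("duplicate site keys in query call set")
    total = len(query)
    unassigned = np.ones(total, dtype=bool)
    counts: dict[str, int] = {}
    for name, panel in panels:
        panel_idx = pd.Index(panel)
        hit = unassigned & query.isin(panel_idx)
        counts[name] = int(hit.sum())
        unassigned &= ~hit
    counts["novel"] = int(unassigned.sum())
    percentages = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return CallSetPartition(counts, percentages, total)


# ---------------------------------------------------------------------------
# Sensitivity and AF correlation
# ---------------------------------------------------------------------------


def sensitivity_from_sites(common_sites, called_sites) -> float:
    """Fraction of common truth sites recovered by the call set."""
    common = pd.Index(common_sites)
    if len(common) == 0:
        raise NiptpoolError("sensitivity undefined: empty common-site set")
    return float(common.isin(pd.Index(called_sites)).sum()) / len(common)


def common_snp_sensitivity(
    truth_genotypes: GenotypeMatrix, callset: pd.DataFrame, min_carriers: int = 2
) -> float:
    """Sensitivity on common SNPs: truth sites carried by at least
    ``min_carriers`` individuals (dosage >= 1) that appear in the call set."""
    carriers = truth_genotypes.carriers()
    common = truth_genotypes.site_keys()[carriers >= min_carriers]
    return sensitivity_from_sites(common, site_index(callset))


def af_correlation(estimated_af: np.ndarray, reference_af: np.ndarray) -> float:
    """Pearson product-moment correlation between matched AF vectors."""
    x = np.asarray(estimated_af, dtype=float)
    y = np.asarray(reference_af, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise NiptpoolError("need >= 2 matched sites")
    if np.std(x) == 0 or np.std(y) == 0:
        raise NiptpoolError("AF correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def matched_af(callset: pd.DataFrame, panel_af: pd.DataFrame) -> pd.DataFrame:
    """Inner-join call-set and panel AFs on (chrom, pos, ref, alt); panel_af
    must carry an ``af`` column."""
    return callset.merge(panel_af, on=["chrom", "pos", "ref", "alt"], suffixes=("_est", "_ref"))


# ---------------------------------------------------------------------------
# Genotype simulation from AF + PCA
# ---------------------------------------------------------------------------


def simulate_genotypes_from_af(
    sites: pd.DataFrame,
    af: np.ndarray,
    n_individuals: int = 100,
    label: str = "pooled_sim",
    seed=None,
) -> GenotypeMatrix:
    """Simulate Hardy–Weinberg genotypes from an estimated AF vector.

    This is how a pooled call set (which has no individual genotypes) is
    projected into PCA space: pseudo-individuals are drawn from the
    estimated allele frequencies (the study's "100 sets of genotypes").
    """
    af = np.asarray(af, dtype=float)
    if len(af) != len(sites):
        raise NiptpoolError("af vector must match site table")
    df = sites[["chrom", "pos", "ref", "alt"]].copy()
    df["ancestral_af"] = af
    df[f"af_{label}"] = af
    table = PopulationAFTable(df, {label: 0.0})
    gm = _sim.simulate_genotypes(table, label, n_individuals, sex_assignment="F", seed=seed)
    gm.meta["source"] = "simulated_af"
    return gm


def restrict_to_shared_sites(matrices: Sequence[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Subset genotype matrices to the sites they share (order of the first
    matrix), so cohorts genotyped on different site sets can enter one PCA."""
    shared = matrices[0].site_keys()
    for m in matrices[1:]:
        shared = shared[shared.isin(m.site_keys())]
    if len(shared) == 0:
        raise NiptpoolError("no shared sites between genotype matrices")
    out = []
    for m in matrices:
        locs = m.site_keys().get_indexer(shared)
        out.append(GenotypeMatrix(m.dosage[:, locs], m.sites.iloc[locs].reset_index(drop=True), m.meta.copy()))
    return out


@dataclass
class PCAResult:
    """Top-k principal components of a genotype matrix.

    ``coords`` has one row per individual with ``population`` and ``source``
    labels and ``PC1..PCk`` columns; ``explained`` holds the fraction of
    total (standardized) variance per component, non-increasing.
    """

    coords: pd.DataFrame
    explained: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        self.coords.to_csv(path, sep="\t", index=False)


def pca_genotypes(matrices: Sequence[GenotypeMatrix], k: int = 2) -> PCAResult:
    """PCA on concatenated genotype matrices with PLINK-style standardization.

    Each site column is centered by 2·p̂ and scaled by sqrt(2·p̂·(1-p̂)),
    where p̂ is the pooled sample AF across all individuals in the combined
    matrix; monomorphic sites are excluded.  Coordinates are projections on
    the top-k eigenvectors of the individual covariance.
    """
    combined = GenotypeMatrix.concat(list(matrices)) if len(matrices) > 1 else matrices[0]
    if combined.n_individuals < 2:
        raise NiptpoolError("PCA needs >= 2 individuals")
    g = combined.dosage.astype(float)
    p_hat = g.mean(axis=0) / 2.0
    poly = (p_hat > 0.0) & (p_hat < 1.0)
    if not poly.any():
        raise NiptpoolError("PCA undefined: all sites monomorphic")
    g = g[:, poly]
    p = p_hat[poly]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    u, s, _vt = np.linalg.svd(z, full_matrices=False)
    k = min(k, len(s))
    coords = u[:, :k] * s[:k]
    explained = (s**2) / (s**2).sum()
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "population", combined.meta["population"].to_numpy())
    source = combined.meta["source"].to_numpy() if "source" in combined.meta else ["genotypes"] * len(df)
    df.insert(1, "source", source)
    return PCAResult(df, explained[:k])


# ---------------------------------------------------------------------------
# Sex-chromosome / fetal-fraction accounting
# ---------------------------------------------------------------------------


def male_data_fraction(fetal_fraction: float, p_male: float) -> float:
    """Fraction of pooled read data originating from male genomes: only the
    fetal share of male-fetus pregnancies is male DNA."""
    if not 0.0 <= fetal_fraction <= 1.0 or not 0.0 <= p_male <= 1.0:
        raise NiptpoolError("fetal_fraction and p_male must lie in [0, 1]")
    return fetal_fraction * p_male


def predicted_y_depth_ratio(fetal_fraction: float, p_male: float) -> float:
    """Expected chrY : genome-wide mean depth ratio.

    Male fetuses carry one Y against two copies of each autosome, weighted
    by the fetal fraction: ratio = ff x p_male / 2.
    """
    return male_data_fraction(fetal_fraction, p_male) / 2.0


def y_depth_ratio(reads: ReadSet, genome: ToyGenome) -> float:
    """Empirical mean chrY depth divided by mean genome-wide depth of a
    pooled read set."""
    y = genome.y_chromosome
    if y is None:
        raise NiptpoolError("genome has no Y chromosome")
    lengths = (reads.df["end"] - reads.df["start"] + 1).to_numpy()
    total = float(lengths.sum())
    if total == 0:
        raise NiptpoolError("Y depth ratio undefined: zero genome-wide depth")
    on_y = (reads.df["chrom"] == y.name).to_numpy()
    y_depth = lengths[on_y].sum() / y.length
    genome_depth = total / genome.total_length
    return float(y_depth / genome_depth)


# ---------------------------------------------------------------------------
# Hardy–Weinberg carrier frequency
# ---------------------------------------------------------------------------


def carrier_frequency(af: float) -> float:
    """Heterozygous-carrier frequency 2·p·(1-p) under Hardy–Weinberg
    equilibrium, for a recessive allele at frequency ``af``."""
    if not 0.0 <= af <= 1.0:
        raise NiptpoolError("allele frequency must lie in [0, 1]")
    return 2.0 * af * (1.0 - af)


# ---------------------------------------------------------------------------
# Optional plots
# ---------------------------------------------------------------------------


def plot_af_scatter(merged: pd.DataFrame, path: str | Path) -> None:
    """Scatter of estimated vs reference AF (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(merged["af_ref"], merged["af_est"], s=4, alpha=0.4)
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8)
    ax.set_xlabel("panel AF")
    ax.set_ylabel("pooled estimate AF")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(result: PCAResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (pop, src), grp in result.coords.groupby(["population", "source"]):
        ax.scatter(grp["PC1"], grp["PC2"], s=8, alpha=0.6, label=f"{pop} ({src})")
    ax.set_xlabel(f"PC1 ({result.explained[0]:.1%})")
    if "PC2" in result.coords:
        ax.set_ylabel(f"PC2 ({result.explained[1]:.1%})")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
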