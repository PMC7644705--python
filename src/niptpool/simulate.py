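"""Synthetic multi-population NIPT cohort simulator.

The simulator produces, with full truth records, the statistical structure a
pooled maternal-plasma analysis assumes:

1. per-site population allele frequencies under a Balding–Nichols
   (FST-style) divergence model around an ancestral frequency drawn from a
   configurable site-frequency spectrum;
2. Hardy–Weinberg genotypes (haplotype pairs) for mothers and fathers,
   Mendelian fetal genotypes, and per-sample fetal fraction / sex / depth;
3. ultra-low-coverage paired-end reads from the cfDNA mixture model: each
   fragment originates from one chromosome copy chosen with probability
   proportional to chromosome length x copy weight, where maternal copies
   carry weight (1 - ff) and fetal copies weight ff.

Every stochastic operation takes an explicit seed; cohort-level seeds derive
per-sample seeds deterministically by counter.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AUTOSOME,
    BASES,
    CHROM_X,
    CHROM_Y,
    GenotypeMatrix,
    NIPTSampleSpec,
    NiptpoolError,
    PopulationAFTable,
    ReadSet,
    ToyGenome,
    empty_mismatches,
    write_cohort_tsv,
    write_truth_vcf,
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {b: [x for x in BASES if x != b and x != _TRANSITION[b]] for b in BASES}

# cfDNA fragment-length model: modal plasma fragment ~166 bp
DEFAULT_INSERT_MEAN = 166.0
DEFAULT_INSERT_SD = 40.0
DEFAULT_INSERT_MAX = 500
DEFAULT_READ_LEN = 75
DEFAULT_ERROR_RATE = 0.003
DEFAULT_DEPTH = 0.17
DEFAULT_FETAL_FRACTION = 0.084  # centre of the 8-10% plasma range
DEFAULT_P_MALE = 0.5


# ---------------------------------------------------------------------------
# Population allele frequencies
# ---------------------------------------------------------------------------


def balding_nichols(p, f: float, size=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw population AFs around ancestral frequency ``p`` with divergence ``f``.

    The Balding–Nichols model draws from Beta(p(1-F)/F, (1-p)(1-F)/F), which
    has mean p and variance F·p·(1-p).  F = 0 returns p exactly (no drift);
    F = 1 is degenerate and rejected.
    """
    if not 0.0 <= f < 1.0:
        raise NiptpoolError("divergence parameter F must lie in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    p = np.asarray(p, dtype=float)
    if size is None:
        size = p.shape
    if f == 0.0:
        return np.broadcast_to(p, size).copy()
    scale = (1.0 - f) / f
    out = np.empty(size, dtype=float)
    pb = np.broadcast_to(p, size)
    fixed = (pb == 0.0) | (pb == 1.0)
    out[fixed] = pb[fixed]
    free = ~fixed
    out[free] = rng.beta(pb[free] * scale, (1.0 - pb[free]) * scale)
    return out


def _truncated_beta(rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    from scipy import stats

    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def simulate_population_afs(
    genome: ToyGenome,
    n_sites: int,
    f_per_pop: dict[str, float],
    sfs_shape: tuple[float, float] = (0.5, 0.5),
    sfs_bounds: tuple[float, float] = (0.01, 0.99),
    titv: float = 2.0,
    seed=None,
) -> PopulationAFTable:
    """Generate truth allele frequencies for several diverged populations.

    Sites are placed without collision on non-Y chromosomes; the ancestral
    frequency spectrum defaults to a U-shaped truncated Beta(0.5, 0.5)
    (excess of low-frequency alleles); alt alleles are drawn so the truth
    transition/transversion ratio equals ``titv`` in expectation (2.0, the
    genome-wide value expected of true human SNPs).
    """
    if n_sites < 1:
        raise NiptpoolError("n_sites must be >= 1")
    for pop, f in f_per_pop.items():
        if not 0.0 <= f < 1.0:
            raise NiptpoolError(f"F for population {pop!r} must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    placeable = [c for c in genome.chromosomes if c.cls != CHROM_Y]
    total = sum(c.length for c in placeable)
    if n_sites > total:
        raise NiptpoolError(f"cannot place {n_sites} sites on {total} non-Y bases")
    flat = np.sort(rng.choice(total, size=n_sites, replace=False))
    bounds = np.cumsum([c.length for c in placeable])
    chrom_idx = np.searchsorted(bounds, flat, side="right")
    pos = flat - np.concatenate(([0], bounds[:-1]))[chrom_idx] + 1  # 1-based

    chrom_names = np.array([c.name for c in placeable], dtype=object)[chrom_idx]
    ref = np.array([BASES[placeable[ci].seq[p - 1]] for ci, p in zip(chrom_idx, pos)], dtype=object)

    # alt allele: transition with probability titv/(1+titv), else one of the
    # two transversions uniformly
    is_ti = rng.random(n_sites) < titv / (1.0 + titv)
    tv_pick = rng.integers(0, 2, size=n_sites)
    alt = np.array(
        [_TRANSITION[r] if ti else _TRANSVERSIONS[r][k] for r, ti, k in zip(ref, is_ti, tv_pick)],
        dtype=object,
    )

    lo, hi = sfs_bounds
    ancestral = _truncated_beta(rng, sfs_shape[0], sfs_shape[1], lo, hi, n_sites)

    df = pd.DataFrame({"chrom": chrom_names, "pos": pos.astype(np.int64), "ref": ref, "alt": alt,
                       "ancestral_af": ancestral})
    for pop, f in f_per_pop.items():
        df[f"af_{pop}"] = balding_nichols(ancestral, f, rng=rng)
    return PopulationAFTable(df, dict(f_per_pop))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _site_classes(af_table: PopulationAFTable, genome: ToyGenome | None) -> np.ndarray:
    if genome is None:
        return np.array([AUTOSOME] * af_table.n_sites, dtype=object)
    return af_table.df["chrom"].map(lambda c: genome[c].cls).to_numpy(dtype=object)


def _resolve_sexes(sex_assignment, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(sex_assignment, str):
        if sex_assignment not in ("F", "M"):
            raise NiptpoolError("sex_assignment string must be 'F' or 'M'")
        return np.array([sex_assignment] * n, dtype=object)
    if np.isscalar(sex_assignment):
        return np.where(rng.random(n) < float(sex_assignment), "M", "F").astype(object)
    sexes = np.asarray(sex_assignment, dtype=object)
    if len(sexes) != n or not set(sexes) <= {"F", "M"}:
        raise NiptpoolError("sex_assignment sequence must give 'F'/'M' per individual")
    return sexes


def simulate_genotypes(
    af_table: PopulationAFTable,
    population: str,
    n_individuals: int,
    sex_assignment="F",
    genome: ToyGenome | None = None,
    seed=None,
) -> GenotypeMatrix:
    """Draw Hardy–Weinberg genotypes for one population.

    Autosomal (and female-X) dosage is Binomial(2, p); male-X dosage is
    Binomial(1, p).  ``sex_assignment`` may be 'F'/'M' for a uniform cohort,
    a probability of being male, or an explicit sequence of sexes.
    """
    if n_individuals < 1:
        raise NiptpoolError("n_individuals must be >= 1")
    p = af_table.af(population)
    rng = np.random.default_rng(seed)
    sexes = _resolve_sexes(sex_assignment, n_individuals, rng)
    classes = _site_classes(af_table, genome)
    copies = np.full((n_individuals, af_table.n_sites), 2, dtype=np.int8)
    copies[np.ix_(sexes == "M", classes == CHROM_X)] = 1
    dosage = rng.binomial(copies, p[None, :]).astype(np.int8)
    sites = af_table.df[["chrom", "pos", "ref", "alt"]].copy()
    sites["chrom_cls"] = classes
    meta = pd.DataFrame({"population": [population] * n_individuals, "sex": sexes})
    return GenotypeMatrix(dosage, sites, meta)


# ---------------------------------------------------------------------------
# NIPT cohort
# ---------------------------------------------------------------------------


def _draw_values(dist, n: int, rng: np.random.Generator, lo: float, hi: float, what: str) -> np.ndarray:
    """Resolve a constant / (low, high) uniform range / callable into n values."""
    if callable(dist):
        vals = np.asarray(dist(rng, n), dtype=float)
    elif np.isscalar(dist):
        vals = np.full(n, float(dist))
    else:
        a, b = dist
        vals = rng.uniform(a, b, size=n)
    if np.any((vals < lo) | (vals > hi)):
        raise NiptpoolError(f"{what} values must lie in [{lo}, {hi}]")
    return vals


def simulate_nipt_cohort(
    af_table: PopulationAFTable,
    population: str,
    n_samples: int,
    genome: ToyGenome | None = None,
    fetal_fraction=DEFAULT_FETAL_FRACTION,
    p_male: float = DEFAULT_P_MALE,
    depth=DEFAULT_DEPTH,
    seed=None,
) -> list[NIPTSampleSpec]:
    """Simulate a cohort of pregnancies: maternal haplotypes, a per-sample
    father (drawn and discarded), a Mendelian fetus, fetal sex, fetal
    fraction and target depth.

    ``fetal_fraction`` and ``depth`` accept a constant, a (low, high) uniform
    range, or a callable ``f(rng, n) -> array``.
    """
    if n_samples < 0:
        raise NiptpoolError("n_samples must be >= 0")
    if not 0.0 <= p_male <= 1.0:
        raise NiptpoolError("p_male must lie in [0, 1]")
    p = af_table.af(population)
    n_sites = af_table.n_sites
    classes = _site_classes(af_table, genome)
    is_x = classes == CHROM_X

    rng = np.random.default_rng(seed)
    ffs = _draw_values(fetal_fraction, n_samples, rng, 0.0, 1.0, "fetal_fraction")
    depths = _draw_values(depth, n_samples, rng, 0.0, np.inf, "depth")
    sexes = np.where(rng.random(n_samples) < p_male, "M", "F")

    cohort: list[NIPTSampleSpec] = []
    for i in range(n_samples):
        maternal = (rng.random((2, n_sites)) < p).astype(np.int8)
        father = (rng.random((2, n_sites)) < p).astype(np.int8)
        # maternal gamete: per-site coin flip between the mother's two copies
        gpick = rng.integers(0, 2, size=n_sites)
        fetal0 = maternal[gpick, np.arange(n_sites)]
        if sexes[i] == "F":
            # paternal gamete: autosomes from either paternal copy, X from
            # the father's single X (represented by copy 0)
            ppick = rng.integers(0, 2, size=n_sites)
            ppick[is_x] = 0
            fetal1 = father[ppick, np.arange(n_sites)]
        else:
            ppick = rng.integers(0, 2, size=n_sites)
            fetal1 = father[ppick, np.arange(n_sites)].astype(np.int8)
            fetal1[is_x] = -1  # male fetus has no paternal X
        cohort.append(
            NIPTSampleSpec(
                sample_id=f"S{i:04d}",
                maternal_hap=maternal,
                fetal_hap=np.stack([fetal0, fetal1]).astype(np.int8),
                fetal_fraction=float(ffs[i]),
                fetal_sex=str(sexes[i]),
                target_depth=float(depths[i]),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _chromosome_copies(sample: NIPTSampleSpec, genome: ToyGenome, af_table: PopulationAFTable):
    """Enumerate chromosome copies in the cfDNA mixture for one sample.

    Returns a list of (chrom name, weight, alt positions, alt bases), with
    weight = chromosome length x (1-ff) for maternal copies and x ff for
    fetal copies.  A male fetus contributes a variant-free Y copy.
    """
    ff = sample.fetal_fraction
    site_chrom = af_table.df["chrom"].to_numpy()
    site_pos = af_table.df["pos"].to_numpy()
    site_alt = af_table.df["alt"].to_numpy()
    copies = []
    for c in genome.chromosomes:
        on_c = site_chrom == c.name
        pos_c, alt_c = site_pos[on_c], site_alt[on_c]

        def alt_sites(hap_row: np.ndarray):
            carried = hap_row[on_c] == 1
            return pos_c[carried], alt_c[carried]

        if c.cls in (AUTOSOME, CHROM_X):
            for h in range(2):
                copies.append((c.name, c.length * (1.0 - ff), *alt_sites(sample.maternal_hap[h])))
            copies.append((c.name, c.length * ff, *alt_sites(sample.fetal_hap[0])))
            if c.cls == AUTOSOME or sample.fetal_sex == "F":
                copies.append((c.name, c.length * ff, *alt_sites(sample.fetal_hap[1])))
        elif c.cls == CHROM_Y and sample.fetal_sex == "M":
            copies.append((c.name, c.length * ff, np.empty(0, dtype=np.int64), np.empty(0, dtype=object)))
    return copies


def _multirange(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate ranges lo[i]..hi[i]: returns (owner index, range value)."""
    n = hi - lo
    total = int(n.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    owner = np.repeat(np.arange(len(lo)), n)
    offs = np.arange(total) - np.repeat(np.cumsum(n) - n, n)
    return owner, np.repeat(lo, n) + offs


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_reads(
    sample: NIPTSampleSpec,
    genome: ToyGenome,
    af_table: PopulationAFTable,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    insert_max: int = DEFAULT_INSERT_MAX,
    error_rate: float = DEFAULT_ERROR_RATE,
    low_mapq_regions: Sequence[tuple[str, int, int]] | None = None,
    low_mapq_prob: float = 1.0,
    low_mapq: int = 20,
    n_pairs: int | None = None,
    seed=None,
) -> ReadSet:
    """Simulate paired-end reads for one maternal-plasma sample.

    Fragments are assigned to chromosome copies with probability proportional
    to length x mixture weight; fragment midpoints are uniform along the
    copy; fragment length follows a truncated Normal(insert_mean, insert_sd)
    on [read_len + 1, insert_max]; the two mates of length ``read_len`` are
    taken from the fragment ends.  At covered truth sites the emitted base is
    the copy's haplotype allele; every emitted base is then substituted to a
    uniformly chosen different base with probability ``error_rate``.  MAPQ is
    60 except for reads overlapping designated low-mappability intervals,
    which receive MAPQ ``low_mapq`` with probability ``low_mapq_prob``.
    """
    if read_len < 1:
        raise NiptpoolError("read_len must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise NiptpoolError("error_rate must lie in [0, 0.5)")
    if not genome.chromosomes:
        raise NiptpoolError("genome is empty")
    rng = np.random.default_rng(seed)

    copies = _chromosome_copies(sample, genome, af_table)
    weights = np.array([c[1] for c in copies], dtype=float)
    if n_pairs is None:
        n_pairs = int(round(sample.target_depth * genome.total_length / (2.0 * read_len)))
    if n_pairs == 0 or weights.sum() == 0:
        return ReadSet.empty()
    copy_of_pair = rng.choice(len(copies), size=n_pairs, p=weights / weights.sum())

    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    revs: list[np.ndarray] = []
    mates: list[np.ndarray] = []
    pairs: list[np.ndarray] = []
    hap_read: list[np.ndarray] = []
    hap_pos: list[np.ndarray] = []
    hap_base: list[np.ndarray] = []

    n_reads = 0
    pair_counter = 0
    for ci, (cname, _w, alt_pos, alt_base) in enumerate(copies):
        m = int((copy_of_pair == ci).sum())
        if m == 0:
            continue
        length = genome[cname].length
        flen = np.round(
            _truncated_normal(rng, insert_mean, insert_sd, read_len + 1, insert_max, m)
        ).astype(np.int64)
        flen = np.minimum(flen, length)
        mid = rng.integers(1, length + 1, size=m)
        fstart = np.clip(mid - flen // 2, 1, length - flen + 1)
        rl = min(read_len, length)
        # mate 1 (forward) from the fragment start, mate 2 (reverse) from the end
        s1, e1 = fstart, fstart + rl - 1
        e2 = fstart + flen - 1
        s2 = e2 - rl + 1
        pid = np.arange(pair_counter, pair_counter + m)
        pair_counter += m
        for s, e, rev, mate in ((s1, e1, False, 0), (s2, e2, True, 1)):
            chroms.append(np.full(m, cname, dtype=object))
            starts.append(s)
            ends.append(e)
            revs.append(np.full(m, rev))
            mates.append(np.full(m, mate, dtype=np.int8))
            pairs.append(pid)
            if len(alt_pos):
                lo = np.searchsorted(alt_pos, s)
                hi = np.searchsorted(alt_pos, e, side="right")
                owner, idx = _multirange(lo, hi)
                hap_read.append(owner + n_reads)
                hap_pos.append(alt_pos[idx])
                hap_base.append(alt_base[idx])
            n_reads += m

    df = pd.DataFrame(
        {
            "sample": sample.sample_id,
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts).astype(np.int64),
            "end": np.concatenate(ends).astype(np.int64),
            "reverse": np.concatenate(revs),
            "mapq": np.full(n_reads, 60, dtype=np.int16),
            "pair": [""] * n_reads,
            "mate": np.concatenate(mates),
        }
    )
    df["pair"] = sample.sample_id + "." + pd.Series(np.concatenate(pairs)).astype(str)

    # haplotype-derived non-reference base calls
    emitted: dict[tuple[int, int], str] = {}
    if hap_read:
        for r, p_, b in zip(np.concatenate(hap_read), np.concatenate(hap_pos), np.concatenate(hap_base)):
            emitted[(int(r), int(p_))] = b

    # sequencing errors: uniform over all emitted bases, substituting to one
    # of the three other bases
    if error_rate > 0:
        read_lens = (df["end"] - df["start"] + 1).to_numpy()
        cum = np.cumsum(read_lens)
        total_bases = int(cum[-1])
        n_err = rng.binomial(total_bases, error_rate)
        if n_err:
            flat = rng.choice(total_bases, size=n_err, replace=False)
            ridx = np.searchsorted(cum, flat, side="right")
            offs = flat - (cum[ridx] - read_lens[ridx])
            err_pos = df["start"].to_numpy()[ridx] + offs
            chrom_arr = df["chrom"].to_numpy()
            start_arr = df["start"].to_numpy()
            picks = rng.integers(0, 3, size=n_err)
            for r, p_, k in zip(ridx, err_pos, picks):
                key = (int(r), int(p_))
                ref = BASES[genome[chrom_arr[r]].seq[p_ - 1]]
                cur = emitted.get(key, ref)
                new = [b for b in BASES if b != cur][k]
                if new == ref:
                    emitted.pop(key, None)
                else:
                    emitted[key] = new
            del start_arr

    if emitted:
        items = sorted(emitted.items())
        mm = pd.DataFrame(
            {
                "read": np.array([k[0] for k, _ in items], dtype=np.int64),
                "chrom": df["chrom"].to_numpy()[[k[0] for k, _ in items]],
                "pos": np.array([k[1] for k, _ in items], dtype=np.int64),
                "base": [v for _, v in items],
            }
        )
    else:
        mm = empty_mismatches()

    if low_mapq_regions:
        mapq = df["mapq"].to_numpy()
        for rchrom, rstart, rend in low_mapq_regions:
            hit = ((df["chrom"] == rchrom) & (df["start"] <= rend) & (df["end"] >= rstart)).to_numpy()
            if low_mapq_prob < 1.0:
                hit &= rng.random(len(df)) < low_mapq_prob
            mapq[hit] = low_mapq
        df["mapq"] = mapq

    return ReadSet(df, mm)


def simulate_cohort_reads(
    cohort: Sequence[NIPTSampleSpec],
    genome: ToyGenome,
    af_table: PopulationAFTable,
    seed=None,
    **read_kwargs,
) -> ReadSet:
    """Simulate reads for every sample in a cohort (per-sample seeds derived
    from the cohort seed by counter) and pool them into one read set."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    readsets = [
        simulate_reads(
            s, genome, af_table,
            seed=np.random.SeedSequence(entropy=root.entropy, spawn_key=tuple(root.spawn_key) + (i,)),
            **read_kwargs,
        )
        for i, s in enumerate(cohort)
    ]
    return ReadSet.concat(readsets)


def write_truth(
    af_table: PopulationAFTable,
    cohort: Sequence[NIPTSampleSpec],
    vcf_path,
    tsv_path=None,
    genome: ToyGenome | None = None,
) -> None:
    """Write the truth VCF (per-population AF in INFO) and the per-sample
    metadata TSV (fetal fraction, sex, depth)."""
    write_truth_vcf(af_table, vcf_path, genome=genome)
    if tsv_path is not None:
        write_cohort_tsv(cohort, tsv_path)
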