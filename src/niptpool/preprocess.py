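"""Alignment filtering and coverage/depth accounting.

Pooled allele-frequency estimation assumes each sample contributes at most
one allele (read) at any genome position.  Ultra-low-coverage paired-end
cfDNA data violates this mainly through overlapping mates, so the
preprocessing stage (i) discards low-MAPQ alignments and (ii) keeps a single
read out of any set of overlapping reads within a sample.  Coverage
summaries report the per-sample and pooled depth structure before and after
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import NiptpoolError, ReadSet, ToyGenome, logger

DEFAULT_MIN_MAPQ = 30


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_mapq(reads: ReadSet, min_mapq: int = DEFAULT_MIN_MAPQ) -> ReadSet:
    """Drop alignments with MAPQ below ``min_mapq`` (strictly: MAPQ < threshold
    is discarded, MAPQ == threshold retained).  Read order is preserved."""
    keep = reads.df.index[reads.df["mapq"].to_numpy() >= min_mapq]
    out = reads.subset(keep)
    logger.info("filter_mapq: %d -> %d reads", len(reads), len(out))
    return out


def deduplicate_overlaps(reads: ReadSet) -> ReadSet:
    """Within each sample and chromosome, keep a maximal set of pairwise
    non-overlapping reads so every position receives <= 1 read per sample.

    Reads are processed in a greedy sweep sorted by (start, end, read id): a
    read is kept iff it does not overlap the previously kept read.  The
    result is deterministic and independent of input order; reads from
    different samples never affect each other.  Overlapping mates of the
    same pair are subject to the same rule.
    """
    df = reads.df
    if not len(df):
        return reads
    sample_codes = pd.factorize(df["sample"].to_numpy())[0]
    chrom_codes = pd.factorize(df["chrom"].to_numpy())[0]
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    rid = df.index.to_numpy()
    order = np.lexsort((rid, end, start, chrom_codes, sample_codes))

    keep = np.zeros(len(df), dtype=bool)
    last_sample = last_chrom = -1
    last_end = -1
    s_arr, c_arr = sample_codes[order], chrom_codes[order]
    st_arr, en_arr = start[order], end[order]
    for j in range(len(order)):
        if s_arr[j] != last_sample or c_arr[j] != last_chrom:
            last_sample, last_chrom, last_end = s_arr[j], c_arr[j], -1
        if st_arr[j] > last_end:
            keep[order[j]] = True
            last_end = en_arr[j]
    out = reads.subset(df.index[keep])
    logger.info("deduplicate_overlaps: %d -> %d reads", len(reads), len(out))
    return out


# ---------------------------------------------------------------------------
# Coverage accounting
# ---------------------------------------------------------------------------


@dataclass
class CoverageSummary:
    """Exact per-position coverage/depth accounting.

    ``per_sample`` has one row per sample: ``coverage`` (fraction of
    positions covered), ``mean_depth``, and ``depth_k`` columns for the
    fraction of positions at depth exactly k (k = 1..max_k, with
    ``depth_gt`` an overflow bin).  ``aggregate`` summarises the pooled
    cohort; ``per_chrom_depth`` maps chromosome to pooled mean depth;
    ``depth_hist`` counts genome positions by pooled depth (overflow in the
    last bin).
    """

    per_sample: pd.DataFrame
    aggregate: dict[str, float]
    per_chrom_depth: dict[str, float]
    depth_hist: np.ndarray
    max_k: int

    def to_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


def _mask_arrays(genome: ToyGenome, mask_regions) -> dict[str, np.ndarray] | None:
    if mask_regions is None:
        return None
    masks = {c.name: np.zeros(c.length, dtype=bool) for c in genome.chromosomes}
    for chrom, start, end in mask_regions:
        masks[chrom][start - 1 : end] = True
    return masks


def read_bed_regions(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split()[:3]
            out.append((chrom, int(s) + 1, int(e)))
    return out


def _depth_arrays(df: pd.DataFrame, genome: ToyGenome) -> dict[str, np.ndarray]:
    depth = {c.name: np.zeros(c.length + 1, dtype=np.int32) for c in genome.chromosomes}
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        if chrom not in genome:
            raise NiptpoolError(f"reads reference unknown chromosome {chrom!r}")
        d = depth[chrom]
        np.add.at(d, grp["start"].to_numpy() - 1, 1)
        ends = grp["end"].to_numpy()
        np.add.at(d, ends, -1)
    return {name: np.cumsum(d[:-1]).astype(np.int32) for name, d in depth.items()}


def coverage_summary(
    reads: ReadSet,
    genome: ToyGenome,
    max_k: int = 5,
    mask_regions: Sequence[tuple[str, int, int]] | None = None,
) -> CoverageSummary:
    """Exact depth accounting per sample and pooled over the cohort.

    Positions inside ``mask_regions`` (1-based inclusive intervals, e.g. a
    low-mappability mask) are excluded from numerators and denominators.
    """
    masks = _mask_arrays(genome, mask_regions)
    denom = genome.total_length
    if masks is not None:
        denom -= int(sum(m.sum() for m in masks.values()))
    if denom <= 0:
        raise NiptpoolError("mask covers the whole genome")

    df = reads.df
    total_hist = np.zeros(max_k + 2, dtype=np.int64)
    agg_depth = {c.name: np.zeros(c.length, dtype=np.int32) for c in genome.chromosomes}

    rows = []
    for sample, grp in df.groupby("sample", sort=True, observed=True):
        depth = _depth_arrays(grp, genome)
        hist = np.zeros(max_k + 2, dtype=np.int64)
        for name, d in depth.items():
            agg_depth[name] += d
            if masks is not None:
                d = d[~masks[name]]
            hist += np.bincount(np.minimum(d, max_k + 1), minlength=max_k + 2)
        covered = int(hist[1:].sum())
        total_bases = sum(
            int((d if masks is None else np.where(masks[name], 0, d)).sum())
            for name, d in depth.items()
        )
        row = {"sample": sample, "coverage": covered / denom, "mean_depth": total_bases / denom}
        for k in range(1, max_k + 1):
            row[f"depth_{k}"] = hist[k] / denom
        row["depth_gt"] = hist[max_k + 1] / denom
        rows.append(row)

    per_chrom = {}
    agg_bases = 0
    agg_covered = 0
    for name, d in agg_depth.items():
        if masks is not None:
            d = d[~masks[name]]
        per_chrom[name] = float(d.mean()) if len(d) else 0.0
        agg_bases += int(d.sum())
        agg_covered += int((d > 0).sum())
        total_hist += np.bincount(np.minimum(d, max_k + 1), minlength=max_k + 2)

    cols = ["sample", "coverage", "mean_depth"] + [f"depth_{k}" for k in range(1, max_k + 1)] + ["depth_gt"]
    per_sample = pd.DataFrame(rows, columns=cols)
    aggregate = {
        "coverage": agg_covered / denom,
        "mean_depth": agg_bases / denom,
        "n_samples": float(len(rows)),
    }
    return CoverageSummary(per_sample, aggregate, per_chrom, total_hist, max_k)


# ---------------------------------------------------------------------------
# Depth arithmetic
# ---------------------------------------------------------------------------


def expected_depth(n_read_pairs: float, read_len: float, genome_len: float) -> float:
    """Expected sequencing depth: pairs x 2 x read length / genome length."""
    if n_read_pairs <= 0 or read_len <= 0 or genome_len <= 0:
        raise NiptpoolError("all inputs to expected_depth must be positive")
    return n_read_pairs * 2.0 * read_len / genome_len


def expected_two_read_samples(n_samples: float, per_sample_depth2_fraction: float) -> float:
    """Expected number of samples contributing two reads at a random
    position, given the per-sample fraction of depth-2 positions."""
    if not 0.0 <= per_sample_depth2_fraction <= 1.0:
        raise NiptpoolError("per_sample_depth2_fraction must lie in [0, 1]")
    return n_samples * per_sample_depth2_fraction
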