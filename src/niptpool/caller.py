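"""Pooled SNP calling from aggregated ultra-low-coverage reads.

After preprocessing, every read at a position comes from a different sample,
so the pooled base counts at a site behave like draws from the population:
the alt read fraction k/n estimates the population allele frequency.  The
caller tests, per site and per non-reference base, whether the observed alt
count k out of depth n exceeds what the sequencing-error model explains:

    p_value = P(X >= k),  X ~ Binomial(n, error_rate / 3)

with errors assumed uniform over the three non-reference bases.  A variant
is emitted when the p-value falls below ``alpha_site`` (default: 0.05
Bonferroni-corrected over genome positions).  Called variants are annotated
with ``weak_evidence`` (alt count below ``min_alt``) and ``strand_bias``
(Fisher exact test on per-strand ref/alt counts) filter flags; a call is
PASS iff no flag is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .core import BASES, NiptpoolError, NiptpoolIOError, ReadSet, ToyGenome, logger

DEFAULT_ERROR_RATE = 0.003
DEFAULT_MIN_ALT = 3
DEFAULT_STRAND_P = 1e-3
STRAND_IMBALANCE = 0.9

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: strand-split count columns of a pileup frame
COUNT_COLUMNS = [f"{b}_{s}" for b in BASES for s in ("fwd", "rev")]


def default_alpha_site(genome_length: int) -> float:
    """Bonferroni site-level threshold: 0.05 over all genome positions."""
    return 0.05 / genome_length


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


def pileup(
    reads: ReadSet,
    genome: ToyGenome,
    sites: Sequence[tuple[str, int]] | None = None,
    distinct_samples: bool = False,
) -> pd.DataFrame:
    """Pooled per-position, per-strand base counts.

    Columns with at least one non-reference base call are always reported;
    pure-reference columns are materialized only for explicitly requested
    ``sites`` (with n = 0 when uncovered).  Counts are exact.  ``n_samples``
    equals n under the preprocessing contract (<= 1 read per sample per
    position); pass ``distinct_samples=True`` to count distinct samples
    exactly instead.
    """
    df = reads.df
    mm = reads.mismatches
    if len(mm):
        mm = mm.copy()
        mm["reverse"] = df["reverse"].loc[mm["read"].to_numpy()].to_numpy()

    want: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        pos_list = []
        if len(mm):
            pos_list.append(mm.loc[mm["chrom"] == chrom, "pos"].to_numpy())
        if sites is not None:
            pos_list.append(np.array([p for c, p in sites if c == chrom], dtype=np.int64))
        if pos_list:
            u = np.unique(np.concatenate(pos_list)) if len(pos_list) > 1 else np.unique(pos_list[0])
            if len(u):
                want[chrom] = u
    if sites is not None:
        for c, _p in sites:
            if c not in genome:
                raise NiptpoolError(f"requested site on unknown chromosome {c!r}")

    frames = []
    for chrom, positions in want.items():
        sub = df[df["chrom"] == chrom]
        depth = {}
        for label, strand_df in (("fwd", sub[~sub["reverse"]]), ("rev", sub[sub["reverse"]])):
            starts = np.sort(strand_df["start"].to_numpy())
            ends = np.sort(strand_df["end"].to_numpy())
            depth[label] = np.searchsorted(starts, positions, side="right") - np.searchsorted(
                ends, positions, side="left"
            )
        out = pd.DataFrame({"chrom": chrom, "pos": positions})
        ref_codes = genome[chrom].seq[positions - 1]
        out["ref"] = np.array(list(BASES), dtype=object)[ref_codes]
        cnt = {col: np.zeros(len(positions), dtype=np.int64) for col in COUNT_COLUMNS}
        if len(mm):
            sub_mm = mm[mm["chrom"] == chrom]
            for (b, rev), grp in sub_mm.groupby(["base", "reverse"], observed=True):
                per_pos = grp.groupby("pos").size()
                idx = np.searchsorted(positions, per_pos.index.to_numpy())
                cnt[f"{b}_{'rev' if rev else 'fwd'}"][idx] += per_pos.to_numpy()
        # reference counts = strand depth minus non-reference counts
        ref_arr = out["ref"].to_numpy()
        for label in ("fwd", "rev"):
            nonref = sum(cnt[f"{b}_{label}"] for b in BASES)
            ref_count = depth[label] - nonref
            if (ref_count < 0).any():
                raise NiptpoolError("inconsistent pileup: more mismatches than depth")
            for b in BASES:
                sel = ref_arr == b
                cnt[f"{b}_{label}"][sel] += ref_count[sel]
        for col in COUNT_COLUMNS:
            out[col] = cnt[col]
        out["n"] = depth["fwd"] + depth["rev"]
        if distinct_samples:
            distinct = np.zeros(len(out), dtype=np.int64)
            for _sample, grp in sub.groupby("sample", observed=True):
                starts = np.sort(grp["start"].to_numpy())
                ends = np.sort(grp["end"].to_numpy())
                cov = np.searchsorted(starts, positions, side="right") - np.searchsorted(
                    ends, positions, side="left"
                )
                distinct += cov > 0
            out["n_samples"] = distinct
        else:
            out["n_samples"] = out["n"]
        frames.append(out)

    cols = ["chrom", "pos", "ref", "n"] + COUNT_COLUMNS + ["n_samples"]
    if not frames:
        return pd.DataFrame(columns=cols)
    result = pd.concat(frames, ignore_index=True)
    order = {name: i for i, name in enumerate(genome.names)}
    result = result.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    return result[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    """A called SNP with its pooled allele-frequency estimate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    k: int  # alt read count
    n: int  # pooled depth
    af: float  # k / n
    p_value: float
    filters: set[str] = field(default_factory=set)  # empty = PASS

    def __post_init__(self) -> None:
        if not 0 < self.k <= self.n:
            raise NiptpoolError("alt count must satisfy 0 < k <= n")

    @property
    def is_pass(self) -> bool:
        return not self.filters


def call_site(
    column,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha_site: float = 1e-6,
    min_alt: int = DEFAULT_MIN_ALT,
) -> list[VariantCall]:
    """Test one pileup column for variants against the binomial error model.

    For each non-reference base b with count k >= 1, the p-value is
    P(X >= k) with X ~ Binomial(n, error_rate/3); a call is emitted iff
    p <= alpha_site, flagged ``weak_evidence`` when k < min_alt.  Multiple
    alts at one site are allowed.
    """
    if not 0.0 <= error_rate < 0.5:
        raise NiptpoolError("error_rate must lie in [0, 0.5)")
    n = int(column["n"])
    if n < 1:
        return []
    ref = column["ref"]
    calls = []
    for b in BASES:
        if b == ref:
            continue
        k = int(column[f"{b}_fwd"]) + int(column[f"{b}_rev"])
        if k < 1:
            continue
        p = float(stats.binom.sf(k - 1, n, error_rate / 3.0))
        if p <= alpha_site:
            flags = {"weak_evidence"} if k < min_alt else set()
            calls.append(VariantCall(column["chrom"], int(column["pos"]), ref, b, k, n, k / n, p, flags))
    return calls


def call_pileup(
    pileup_df: pd.DataFrame,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha_site: float | None = None,
    min_alt: int = DEFAULT_MIN_ALT,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Vectorized variant calling over a whole pileup frame.

    Applies exactly the per-column rule of :func:`call_site`.  When
    ``alpha_site`` is omitted it defaults to the Bonferroni threshold
    0.05 / ``genome_length``.  Returns one row per (site, alt) with columns
    chrom, pos, ref, alt, k, n, af, p_value, filter.
    """
    if not 0.0 <= error_rate < 0.5:
        raise NiptpoolError("error_rate must lie in [0, 0.5)")
    if alpha_site is None:
        if genome_length is None:
            raise NiptpoolError("provide alpha_site or genome_length")
        alpha_site = default_alpha_site(genome_length)

    parts = []
    n = pileup_df["n"].to_numpy(dtype=np.int64) if len(pileup_df) else np.empty(0, np.int64)
    for b in BASES:
        if not len(pileup_df):
            continue
        k = (pileup_df[f"{b}_fwd"].to_numpy() + pileup_df[f"{b}_rev"].to_numpy()).astype(np.int64)
        cand = (k >= 1) & (pileup_df["ref"].to_numpy() != b) & (n >= 1)
        if not cand.any():
            continue
        sub = pileup_df.loc[cand, ["chrom", "pos", "ref"]].copy()
        kk, nn = k[cand], n[cand]
        pv = stats.binom.sf(kk - 1, nn, error_rate / 3.0)
        called = pv <= alpha_site
        sub = sub.loc[called]
        sub["alt"] = b
        sub["k"] = kk[called]
        sub["n"] = nn[called]
        sub["af"] = kk[called] / nn[called]
        sub["p_value"] = pv[called]
        sub["filter"] = np.where(kk[called] < min_alt, "weak_evidence", "PASS")
        parts.append(sub)

    cols = ["chrom", "pos", "ref", "alt", "k", "n", "af", "p_value", "filter"]
    if not parts:
        return pd.DataFrame(columns=cols)
    calls = pd.concat(parts, ignore_index=True)[cols]
    calls = calls.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
    logger.info("call_pileup: %d candidate columns -> %d calls", len(pileup_df), len(calls))
    return calls


def strand_bias_filter(
    calls: pd.DataFrame,
    pileup_df: pd.DataFrame,
    p_threshold: float = DEFAULT_STRAND_P,
) -> pd.DataFrame:
    """Flag calls with strand-biased alt evidence.

    A call is flagged ``strand_bias`` iff the two-sided Fisher exact test on
    [[ref_fwd, ref_rev], [alt_fwd, alt_rev]] gives p < ``p_threshold`` AND at
    least 90% of alt reads lie on one strand.
    """
    if not len(calls):
        return calls.copy()
    merged = calls.merge(pileup_df, on=["chrom", "pos", "ref"], how="left", suffixes=("", "_p"))
    flags = []
    for row in merged.itertuples(index=False):
        if pd.isna(getattr(row, f"{row.ref}_fwd")):
            raise NiptpoolError(f"call at {row.chrom}:{row.pos} has no pileup column")
        ref_f = int(getattr(row, f"{row.ref}_fwd"))
        ref_r = int(getattr(row, f"{row.ref}_rev"))
        alt_f = int(getattr(row, f"{row.alt}_fwd"))
        alt_r = int(getattr(row, f"{row.alt}_rev"))
        biased = False
        total_alt = alt_f + alt_r
        if total_alt > 0 and max(alt_f, alt_r) / total_alt >= STRAND_IMBALANCE:
            _odds, p = stats.fisher_exact([[ref_f, ref_r], [alt_f, alt_r]])
            biased = p < p_threshold
        flags.append(biased)
    out = calls.copy()
    updated = []
    for f, biased in zip(out["filter"], flags):
        if not biased:
            updated.append(f)
        elif f == "PASS":
            updated.append("strand_bias")
        else:
            updated.append(f + ";strand_bias")
    out["filter"] = updated
    return out


# ---------------------------------------------------------------------------
# Call-set statistics
# ---------------------------------------------------------------------------


def titv_ratio(variants: pd.DataFrame | Sequence[tuple[str, str]]) -> float:
    """Transition/transversion ratio of a set of ref->alt substitutions.

    Transitions are A<->G and C<->T; everything else is a transversion.
    Raises if the set contains no transversion (ratio undefined).
    """
    if isinstance(variants, pd.DataFrame):
        pairs = list(zip(variants["ref"], variants["alt"]))
    else:
        pairs = list(variants)
    ti = sum((r, a) in _TRANSITIONS for r, a in pairs)
    tv = len(pairs) - ti
    if tv == 0:
        raise NiptpoolError("Ti/Tv undefined: no transversions in call set")
    return ti / tv


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def write_callset(calls: pd.DataFrame, path: str | Path, genome: ToyGenome | None = None) -> None:
    """Write calls as a VCF (one ALT per line) with AF, DP, AD and PV INFO
    fields and the filter flags in FILTER.  Input must be coordinate-sorted."""
    pos = calls["pos"].to_numpy()
    chroms = calls["chrom"].to_numpy()
    for i in range(1, len(calls)):
        if chroms[i] == chroms[i - 1] and pos[i] < pos[i - 1]:
            raise NiptpoolError("calls must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Pooled alt allele frequency (k/n)">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled depth n">')
    header.add_line('##INFO=<ID=AD,Number=R,Type=Integer,Description="Non-alt and alt read counts">')
    header.add_line('##INFO=<ID=PV,Number=1,Type=Float,Description="Binomial error-model tail p-value">')
    header.add_line('##FILTER=<ID=weak_evidence,Description="Alt read count below min_alt">')
    header.add_line('##FILTER=<ID=strand_bias,Description="Alt evidence concentrated on one strand">')
    lengths = genome.lengths() if genome is not None else {}
    for chrom in dict.fromkeys(chroms):
        header.contigs.add(str(chrom), length=lengths.get(chrom))
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for row in calls.itertuples(index=False):
                rec = out.new_record(contig=row.chrom, start=int(row.pos) - 1, stop=int(row.pos),
                                     alleles=(row.ref, row.alt))
                rec.info["AF"] = float(row.af)
                rec.info["DP"] = int(row.n)
                rec.info["AD"] = (int(row.n) - int(row.k), int(row.k))
                rec.info["PV"] = float(row.p_value)
                for flag in str(row.filter).split(";"):
                    rec.filter.add(flag)
                out.write(rec)
    except OSError as exc:
        raise NiptpoolIOError(str(exc)) from exc


def read_callset(path: str | Path) -> pd.DataFrame:
    try:
        with pysam.VariantFile(str(path)) as fh:
            rows = []
            for rec in fh:
                flt = ";".join(rec.filter.keys()) or "PASS"
                af = rec.info["AF"]
                af = af[0] if isinstance(af, tuple) else af
                rows.append(
                    (rec.contig, rec.pos, rec.ref, rec.alts[0], int(rec.info["AD"][1]),
                     int(rec.info["DP"]), float(af), float(rec.info["PV"]), flt)
                )
    except OSError as exc:
        raise NiptpoolIOError(str(exc)) from exc
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "k", "n", "af", "p_value", "filter"])


def write_call_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)
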