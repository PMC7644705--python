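"""Shared containers and file I/O for the NIPT pooled-sequencing toolkit.

Conventions used throughout the package:

* Genomic coordinates are 1-based and inclusive internally (the SAM/VCF
  text convention).  Any half-open or 0-based interface (pysam, BED) is
  converted at the boundary.
* Bases are encoded as ``uint8`` codes 0..3 for A, C, G, T inside numpy
  arrays, and as single-character strings at API boundaries.
* Read sets are stored column-wise (one :class:`pandas.DataFrame` row per
  aligned read plus a sparse table of mismatches against the reference)
  rather than as per-read objects, so that cohorts of ~10^6 reads stay
  cheap; :class:`AlignedRead` objects are available for small-scale use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("niptpool")

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)

AUTOSOME = "autosome"
CHROM_X = "X"
CHROM_Y = "Y"

#: columns of the per-read table inside :class:`ReadSet`
READ_COLUMNS = ["sample", "chrom", "start", "end", "reverse", "mapq", "pair", "mate"]


class NiptpoolError(Exception):
    """Base class for validation errors raised by this package."""


class NiptpoolIOError(NiptpoolError):
    """Raised for file I/O failures, distinct from validation failures."""


def encode_bases(s: str) -> np.ndarray:
    """Encode an A/C/G/T string into uint8 codes 0..3."""
    arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(_BASE_ARR):
        codes[arr == b] = i
    return codes


def decode_bases(codes: np.ndarray) -> str:
    return _BASE_ARR[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cls: str  # AUTOSOME, CHROM_X or CHROM_Y
    seq: np.ndarray = field(repr=False)  # uint8 codes, len == length

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NiptpoolError(f"chromosome {self.name!r} has non-positive length")
        if self.cls not in (AUTOSOME, CHROM_X, CHROM_Y):
            raise NiptpoolError(f"unknown chromosome class {self.cls!r}")
        if len(self.seq) != self.length:
            raise NiptpoolError(f"sequence length mismatch for {self.name!r}")


class ToyGenome:
    """A small synthetic reference genome (stand-in for a real assembly).

    Chromosome classes distinguish autosomes from the X and Y so that
    sex-aware copy numbers can be modelled.  At most one X and one Y are
    allowed and chromosome names must be unique.
    """

    def __init__(self, chromosomes: Sequence[Chromosome]):
        if not chromosomes:
            raise NiptpoolError("genome must contain at least one chromosome")
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise NiptpoolError("chromosome names must be unique")
        for cls in (CHROM_X, CHROM_Y):
            if sum(c.cls == cls for c in chromosomes) > 1:
                raise NiptpoolError(f"at most one {cls} chromosome allowed")
        self.chromosomes: tuple[Chromosome, ...] = tuple(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}

    # -- construction -------------------------------------------------

    @classmethod
    def random(cls, spec: Sequence[tuple[str, int, str]], seed: int | None = None) -> "ToyGenome":
        """Generate random chromosome sequences from (name, length, class) triples."""
        rng = np.random.default_rng(seed)
        chroms = [
            Chromosome(name, length, chrom_cls, rng.integers(0, 4, size=length, dtype=np.uint8))
            for name, length, chrom_cls in spec
        ]
        return cls(chroms)

    # -- accessors ----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise NiptpoolError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def y_chromosome(self) -> Chromosome | None:
        for c in self.chromosomes:
            if c.cls == CHROM_Y:
                return c
        return None

    def base(self, chrom: str, pos: int) -> str:
        """Reference base (A/C/G/T) at a 1-based position."""
        return BASES[self[chrom].seq[pos - 1]]

    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    # -- FASTA I/O ----------------------------------------------------

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f">{c.name} class={c.cls}\n")
                s = decode_bases(c.seq)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ToyGenome":
        """Read a FASTA written by :meth:`to_fasta` (class parsed from the header,
        falling back to name-based inference for plain FASTA)."""
        chroms = []
        name, meta, parts = None, "", []

        def flush():
            if name is None:
                return
            seq = encode_bases("".join(parts))
            if "class=" in meta:
                chrom_cls = meta.split("class=")[1].split()[0]
            elif name.lstrip("chr").upper() == "X":
                chrom_cls = CHROM_X
            elif name.lstrip("chr").upper() == "Y":
                chrom_cls = CHROM_Y
            else:
                chrom_cls = AUTOSOME
            chroms.append(Chromosome(name, len(seq), chrom_cls, seq))

        try:
            with open(path) as fh:
                for line in fh:
                    line = line.rstrip()
                    if line.startswith(">"):
                        flush()
                        fields = line[1:].split(None, 1)
                        name = fields[0]
                        meta = fields[1] if len(fields) > 1 else ""
                        parts = []
                    elif line:
                        parts.append(line)
            flush()
        except OSError as exc:
            raise NiptpoolIOError(str(exc)) from exc
        return cls(chroms)


# ---------------------------------------------------------------------------
# Population allele-frequency table
# ---------------------------------------------------------------------------


class PopulationAFTable:
    """Truth allele frequencies per site and population.

    ``df`` holds one row per site with columns ``chrom, pos, ref, alt,
    ancestral_af`` plus one ``af_<population>`` column per population.
    ``f_per_pop`` maps population name to its divergence parameter F
    (the Balding–Nichols/FST-style drift parameter).
    """

    def __init__(self, df: pd.DataFrame, f_per_pop: dict[str, float]):
        required = {"chrom", "pos", "ref", "alt", "ancestral_af"}
        missing = required - set(df.columns)
        if missing:
            raise NiptpoolError(f"AF table missing columns: {sorted(missing)}")
        for pop in f_per_pop:
            if f"af_{pop}" not in df.columns:
                raise NiptpoolError(f"missing AF column for population {pop!r}")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise NiptpoolError("duplicate (chrom, pos) in AF table")
        if (df["ref"] == df["alt"]).any():
            raise NiptpoolError("ref must differ from alt at every site")
        af_cols = ["ancestral_af"] + [f"af_{p}" for p in f_per_pop]
        vals = df[af_cols].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise NiptpoolError("allele frequencies must lie in [0, 1]")
        self.df = df.reset_index(drop=True)
        self.f_per_pop = dict(f_per_pop)

    @property
    def populations(self) -> list[str]:
        return list(self.f_per_pop)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def af(self, population: str) -> np.ndarray:
        col = f"af_{population}"
        if col not in self.df.columns:
            raise NiptpoolError(f"unknown population {population!r}")
        return self.df[col].to_numpy(dtype=float)

    def site_keys(self) -> pd.MultiIndex:
        """(chrom, pos, ref, alt) site identity keys."""
        return pd.MultiIndex.from_frame(self.df[["chrom", "pos", "ref", "alt"]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationAFTable):
            return NotImplemented
        if self.f_per_pop.keys() != other.f_per_pop.keys():
            return False
        if any(abs(self.f_per_pop[p] - other.f_per_pop[p]) > 1e-9 for p in self.f_per_pop):
            return False
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if a[col].dtype.kind == "f":
                if not np.allclose(a[col], b[col], atol=1e-6):
                    return False
            elif not (a[col] == b[col]).all():
                return False
        return True


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix (individuals x sites) with metadata.

    Dosage is 0/1/2 on autosomes and the female X, 0/1 on the male X;
    variant sites are never placed on the Y.  ``sites`` has columns
    ``chrom, pos, ref, alt``; ``meta`` has ``population`` and ``sex``
    ('F'/'M') per individual (rows align with ``dosage``).
    """

    dosage: np.ndarray  # int8, shape (n_individuals, n_sites)
    sites: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosage.ndim != 2:
            raise NiptpoolError("dosage must be 2-D (individuals x sites)")
        if self.dosage.shape[0] != len(self.meta):
            raise NiptpoolError("meta rows must match dosage rows")
        if self.dosage.shape[1] != len(self.sites):
            raise NiptpoolError("sites rows must match dosage columns")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Empirical alt-allele frequency per site (alt copies / total copies),
        accounting for sex-dependent copy number on the X."""
        copies = self.copy_numbers()
        return self.dosage.sum(axis=0) / copies.sum(axis=0)

    def copy_numbers(self) -> np.ndarray:
        """Per (individual, site) chromosome copy number."""
        is_x = (self.sites["chrom_cls"] == CHROM_X).to_numpy() if "chrom_cls" in self.sites else np.zeros(self.n_sites, bool)
        male = (self.meta["sex"].to_numpy() == "M")
        copies = np.full(self.dosage.shape, 2, dtype=np.int8)
        copies[np.ix_(male, is_x)] = 1
        return copies

    def carriers(self) -> np.ndarray:
        """Number of individuals with dosage >= 1 per site."""
        return (self.dosage >= 1).sum(axis=0)

    def site_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.sites[["chrom", "pos", "ref", "alt"]])

    @staticmethod
    def concat(matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        first = matrices[0]
        for m in matrices[1:]:
            if not first.site_keys().equals(m.site_keys()):
                raise NiptpoolError("genotype matrices must share the same site set")
        return GenotypeMatrix(
            np.vstack([m.dosage for m in matrices]),
            first.sites.copy(),
            pd.concat([m.meta for m in matrices], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# NIPT sample specification
# ---------------------------------------------------------------------------


@dataclass
class NIPTSampleSpec:
    """One simulated maternal-plasma sample: mother + fetus haplotypes,
    fetal fraction and target sequencing depth.

    Haplotype arrays align with the rows of the cohort's
    :class:`PopulationAFTable` and hold 0/1 alt indicators; the second
    fetal haplotype (paternal X gamete) is absent for a male fetus at X
    sites, encoded as -1.
    """

    sample_id: str
    maternal_hap: np.ndarray  # int8 (2, n_sites)
    fetal_hap: np.ndarray  # int8 (2, n_sites), -1 where the copy is absent
    fetal_fraction: float
    fetal_sex: str  # 'M' or 'F'
    target_depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise NiptpoolError("fetal_fraction must lie in [0, 1]")
        if self.fetal_sex not in ("M", "F"):
            raise NiptpoolError("fetal_sex must be 'M' or 'F'")

    @property
    def maternal_dosage(self) -> np.ndarray:
        return self.maternal_hap.sum(axis=0, dtype=np.int8)

    @property
    def fetal_dosage(self) -> np.ndarray:
        h = np.where(self.fetal_hap >= 0, self.fetal_hap, 0)
        return h.sum(axis=0, dtype=np.int8)


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """A single aligned read (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mapq: int
    bases: str  # reference-oriented base calls over [start, end]
    pair_id: str
    mate: int  # 0 = first mate, 1 = second

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise NiptpoolError("read start must be <= end")
        if len(self.bases) != self.end - self.start + 1:
            raise NiptpoolError("base calls must span [start, end]")
        if not 0 <= self.mapq <= 60:
            raise NiptpoolError("MAPQ must lie in [0, 60]")


class ReadSet:
    """A collection of aligned reads stored column-wise.

    ``df`` has one row per read (columns :data:`READ_COLUMNS`) indexed by a
    stable integer read id.  ``mismatches`` records the sparse positions
    where a read's base call differs from the reference: columns
    ``read, chrom, pos, base``.  Bases equal to the reference are implicit,
    which keeps ~10^6-read cohorts small and makes pooled pileups cheap.
    """

    def __init__(self, df: pd.DataFrame, mismatches: pd.DataFrame | None = None):
        if mismatches is None:
            mismatches = empty_mismatches()
        self.df = df
        self.mismatches = mismatches

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    @staticmethod
    def empty() -> "ReadSet":
        df = pd.DataFrame(
            {
                "sample": pd.Series(dtype=object), "chrom": pd.Series(dtype=object),
                "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64),
                "reverse": pd.Series(dtype=bool), "mapq": pd.Series(dtype=np.int16),
                "pair": pd.Series(dtype=object), "mate": pd.Series(dtype=np.int8),
            }
        )
        return ReadSet(df, empty_mismatches())

    @staticmethod
    def concat(readsets: Sequence["ReadSet"]) -> "ReadSet":
        """Concatenate read sets, re-assigning disjoint read ids."""
        dfs, mms, offset = [], [], 0
        for rs in readsets:
            df = rs.df.reset_index(drop=True)
            mm = rs.mismatches.copy()
            old_index = rs.df.index.to_numpy()
            remap = pd.Series(np.arange(len(df)) + offset, index=old_index)
            df.index = pd.RangeIndex(offset, offset + len(df))
            if len(mm):
                mm["read"] = remap.loc[mm["read"].to_numpy()].to_numpy()
            offset += len(df)
            dfs.append(df)
            mms.append(mm)
        if not dfs:
            return ReadSet.empty()
        return ReadSet(pd.concat(dfs), pd.concat(mms, ignore_index=True))

    def subset(self, read_ids: np.ndarray | pd.Index) -> "ReadSet":
        """Restrict to the given read ids, preserving their current order."""
        df = self.df.loc[read_ids]
        if len(self.mismatches):
            keep = self.mismatches["read"].isin(pd.Index(read_ids))
            mm = self.mismatches.loc[keep].reset_index(drop=True)
        else:
            mm = empty_mismatches()
        return ReadSet(df, mm)

    def sorted_by_coordinate(self, genome: ToyGenome) -> "ReadSet":
        order = {name: i for i, name in enumerate(genome.names)}
        key = self.df["chrom"].map(order)
        idx = self.df.index[np.lexsort((self.df["start"].to_numpy(), key.to_numpy()))]
        return ReadSet(self.df.loc[idx], self.mismatches)

    # -- object API ---------------------------------------------------

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead], genome: ToyGenome) -> "ReadSet":
        rows, mm_rows = [], []
        for i, r in enumerate(reads):
            rows.append((r.sample_id, r.chrom, r.start, r.end, r.strand == "-", r.mapq, r.pair_id, r.mate))
            ref = decode_bases(genome[r.chrom].seq[r.start - 1 : r.end])
            for off, (a, b) in enumerate(zip(r.bases.upper(), ref)):
                if a != b:
                    mm_rows.append((i, r.chrom, r.start + off, a))
        df = pd.DataFrame(rows, columns=READ_COLUMNS)
        mm = pd.DataFrame(mm_rows, columns=["read", "chrom", "pos", "base"]) if mm_rows else empty_mismatches()
        return cls(df, mm)

    def iter_reads(self, genome: ToyGenome) -> Iterator[AlignedRead]:
        mm_by_read: dict[int, list[tuple[int, str]]] = {}
        for read, pos, base in zip(self.mismatches.get("read", []), self.mismatches.get("pos", []), self.mismatches.get("base", [])):
            mm_by_read.setdefault(read, []).append((pos, base))
        for rid, row in self.df.iterrows():
            seq = list(decode_bases(genome[row["chrom"]].seq[row["start"] - 1 : row["end"]]))
            for pos, base in mm_by_read.get(rid, []):
                seq[pos - row["start"]] = base
            yield AlignedRead(
                sample_id=row["sample"], chrom=row["chrom"], start=int(row["start"]),
                end=int(row["end"]), strand="-" if row["reverse"] else "+",
                mapq=int(row["mapq"]), bases="".join(seq), pair_id=row["pair"], mate=int(row["mate"]),
            )

    # -- SAM I/O ------------------------------------------------------

    def to_sam(self, path: str | Path, genome: ToyGenome) -> None:
        """Write a coordinate-sorted SAM file; sample identity goes in the
        read group (RG:Z, with SM = sample id)."""
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c.name, "LN": c.length} for c in genome.chromosomes],
            "RG": [{"ID": s, "SM": s} for s in self.samples],
        }
        rs = self.sorted_by_coordinate(genome)
        mm_groups: dict[int, list[tuple[int, str]]] = {}
        for read, pos, base in zip(rs.mismatches.get("read", []), rs.mismatches.get("pos", []), rs.mismatches.get("base", [])):
            mm_groups.setdefault(int(read), []).append((int(pos), base))
        tid = {name: i for i, name in enumerate(genome.names)}
        try:
            with pysam.AlignmentFile(str(path), "w", header=header) as out:
                cols = rs.df[["sample", "chrom", "start", "end", "reverse", "mapq", "pair", "mate"]].to_numpy(dtype=object)
                index = rs.df.index.to_numpy()
                for rid, (sample, chrom, start, end, reverse, mapq, pair, mate) in zip(index, cols):
                    a = pysam.AlignedSegment()
                    a.query_name = str(pair)
                    length = int(end) - int(start) + 1
                    seq = list(decode_bases(genome[chrom].seq[int(start) - 1 : int(end)]))
                    for pos, base in mm_groups.get(int(rid), []):
                        seq[pos - int(start)] = base
                    a.query_sequence = "".join(seq)
                    a.flag = 0x1 | (0x40 if int(mate) == 0 else 0x80) | (0x10 if reverse else 0)
                    a.reference_id = tid[chrom]
                    a.reference_start = int(start) - 1
                    a.mapping_quality = int(mapq)
                    a.cigartuples = [(0, length)]
                    a.query_qualities = pysam.qualitystring_to_array("I" * length)
                    a.set_tag("RG", str(sample))
                    out.write(a)
        except OSError as exc:
            raise NiptpoolIOError(str(exc)) from exc

    @classmethod
    def from_sam(cls, path: str | Path, genome: ToyGenome) -> "ReadSet":
        """Read a SAM/BAM file back into a :class:`ReadSet`.

        The sample id is taken from the RG tag (falling back to the read
        group-less name "pooled").  Base calls outside {A,C,G,T} are skipped
        at their position with a logged count.
        """
        rows, mm_rows, n_skipped = [], [], 0
        try:
            with pysam.AlignmentFile(str(path), "r") as fh:
                for i, a in enumerate(fh.fetch(until_eof=True)):
                    if a.is_unmapped or a.is_secondary or a.is_supplementary:
                        continue
                    chrom = a.reference_name
                    if chrom not in genome:
                        raise NiptpoolError(f"read aligned to unknown chromosome {chrom!r}")
                    start = a.reference_start + 1
                    seq = (a.query_sequence or "").upper()
                    end = start + len(seq) - 1
                    sample = a.get_tag("RG") if a.has_tag("RG") else "pooled"
                    rows.append((sample, chrom, start, end, a.is_reverse, a.mapping_quality,
                                 a.query_name, 1 if a.is_read2 else 0))
                    ref = decode_bases(genome[chrom].seq[start - 1 : end])
                    rid = len(rows) - 1
                    for off in range(len(seq)):
                        if seq[off] not in _BASE_CODE:
                            n_skipped += 1
                        elif seq[off] != ref[off]:
                            mm_rows.append((rid, chrom, start + off, seq[off]))
        except OSError as exc:
            raise NiptpoolIOError(str(exc)) from exc
        if n_skipped:
            logger.info("skipped %d non-ACGT base calls while reading %s", n_skipped, path)
        if not rows:
            return cls.empty()
        df = pd.DataFrame(rows, columns=READ_COLUMNS)
        mm = pd.DataFrame(mm_rows, columns=["read", "chrom", "pos", "base"]) if mm_rows else empty_mismatches()
        return cls(df, mm)


def empty_mismatches() -> pd.DataFrame:
    return pd.DataFrame({"read": pd.Series(dtype=np.int64), "chrom": pd.Series(dtype=object),
                         "pos": pd.Series(dtype=np.int64), "base": pd.Series(dtype=object)})


# ---------------------------------------------------------------------------
# Truth VCF / metadata TSV
# ---------------------------------------------------------------------------


def write_truth_vcf(af_table: PopulationAFTable, path: str | Path, genome: ToyGenome | None = None) -> None:
    """Write the truth AF table as a VCF with per-population AF in INFO.

    The divergence parameter F of each population is stored in the header so
    the table round-trips losslessly through :func:`read_truth_vcf`.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AAF,Number=1,Type=Float,Description="Ancestral alt allele frequency">')
    for pop in af_table.populations:
        header.add_line(f'##INFO=<ID=AF_{pop},Number=1,Type=Float,Description="Truth alt AF in {pop}">')
        header.add_line(f"##niptpool_F={pop}:{af_table.f_per_pop[pop]!r}")
    chrom_lengths: dict[str, int] = {}
    if genome is not None:
        chrom_lengths = genome.lengths()
    for chrom in pd.unique(af_table.df["chrom"]):
        header.contigs.add(str(chrom), length=chrom_lengths.get(chrom))
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for row in af_table.df.itertuples(index=False):
                rec = out.new_record(contig=row.chrom, start=row.pos - 1, stop=row.pos,
                                     alleles=(row.ref, row.alt))
                rec.info["AAF"] = float(row.ancestral_af)
                for pop in af_table.populations:
                    rec.info[f"AF_{pop}"] = float(getattr(row, f"af_{pop}"))
                out.write(rec)
    except OSError as exc:
        raise NiptpoolIOError(str(exc)) from exc


def read_truth_vcf(path: str | Path) -> PopulationAFTable:
    try:
        with pysam.VariantFile(str(path)) as fh:
            f_per_pop: dict[str, float] = {}
            for rec in fh.header.records:
                line = str(rec).strip()
                if line.startswith("##niptpool_F="):
                    pop, val = line.split("=", 1)[1].split(":")
                    f_per_pop[pop] = float(val)
            rows = []
            for rec in fh:
                row = {"chrom": rec.contig, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                       "ancestral_af": float(rec.info["AAF"])}
                for pop in f_per_pop:
                    row[f"af_{pop}"] = float(rec.info[f"AF_{pop}"])
                rows.append(row)
    except OSError as exc:
        raise NiptpoolIOError(str(exc)) from exc
    cols = ["chrom", "pos", "ref", "alt", "ancestral_af"] + [f"af_{p}" for p in f_per_pop]
    df = pd.DataFrame(rows, columns=cols)
    df["pos"] = df["pos"].astype(np.int64) if len(df) else df["pos"]
    return PopulationAFTable(df, f_per_pop)


def write_cohort_tsv(cohort: Sequence[NIPTSampleSpec], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort],
            "fetal_fraction": [s.fetal_fraction for s in cohort],
            "fetal_sex": [s.fetal_sex for s in cohort],
            "target_depth": [s.target_depth for s in cohort],
        }
    )
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise NiptpoolIOError(str(exc)) from exc


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except OSError as exc:
        raise NiptpoolIOError(str(exc)) from exc
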