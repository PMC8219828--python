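"""Readers and writers for the plain-text genomic formats the pipeline touches.

All coordinates are 0-based, half-open internally.  Any dialect that uses a
different convention is converted at the I/O boundary only.  Every writer is
the exact inverse of its reader so that write -> read round-trips are
byte-stable for coordinates, names and values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised when a line of an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """A called peak: genomic interval with a summit and a score.

    ``summit`` is an absolute base coordinate (not an offset) and must lie
    inside the half-open interval ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    name: str
    score: float
    summit: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"peak {self.name}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.name}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValidationError(f"peak {self.name}: negative score {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: require start < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        """TSS base: ``start`` on the + strand, ``end - 1`` on the - strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CountMatrix:
    """Genes x samples count matrix with a two-condition sample map."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids, int values
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts in count matrix")
        missing = set(self.counts.columns) - set(self.condition_of)
        if missing:
            raise ValidationError(f"samples without condition: {sorted(missing)}")
        conds = pd.Series(
            [self.condition_of[s] for s in self.counts.columns], index=self.counts.columns
        )
        for level, n in conds.value_counts().items():
            if n < 2:
                raise ValidationError(
                    f"condition {level!r} has {n} sample(s); need at least 2"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT record)."""

    set_id: str
    description: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id}: empty member list")


# ---------------------------------------------------------------------------
# peaks (BED6 / narrowPeak)
# ---------------------------------------------------------------------------

_N_COLS = {"bed6": 6, "narrowPeak": 10}


def read_peaks(path: str | os.PathLike, dialect: str = "narrowPeak") -> list[Peak]:
    """Read a BED6 or narrowPeak file into a list of :class:`Peak`.

    narrowPeak summits are ``start + column-10 offset``; BED6 files carry no
    summit so the floor midpoint of the interval is used.
    """
    if dialect not in _N_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    want = _N_COLS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < want:
                raise ParseError(
                    f"{path}:{lineno}: expected {want} columns for {dialect}, got {len(fields)}"
                )
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            if dialect == "narrowPeak":
                score = float(fields[6])  # signalValue carries the full-precision score
                offset = int(fields[9])
                summit = start + offset if offset >= 0 else (start + end) // 2
            else:
                score = float(fields[4])
                summit = (start + end) // 2
            peaks.append(Peak(chrom, start, end, name, score, summit))
    return peaks


def write_peaks(path: str | os.PathLike, peaks: Iterable[Peak], dialect: str = "narrowPeak") -> None:
    """Write peaks in the given dialect (inverse of :func:`read_peaks`)."""
    if dialect not in _N_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "narrowPeak":
                bed_score = int(min(1000, round(p.score)))
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{bed_score}\t.\t"
                    f"{p.score}\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t.\n")


# ---------------------------------------------------------------------------
# coverage (bedGraph)
# ---------------------------------------------------------------------------


def read_coverage(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int] | None = None,
):
    """Read a bedGraph file into a :class:`~ctsdimer.coverage_profiles.CoverageTrack`.

    Intervals must be non-overlapping per chromosome; uncovered positions are 0.
    A leading ``# mapped_reads=N`` comment, as written by :func:`write_coverage`,
    populates the track's library size.
    """
    from ctsdimer.coverage_profiles import CoverageTrack

    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    mapped_reads = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "mapped_reads=" in line:
                    mapped_reads = int(line.split("mapped_reads=")[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))

    data: dict[str, np.ndarray] = {}
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            data[chrom] = np.zeros(size, dtype=float)
    for chrom, ivals in per_chrom.items():
        ivals.sort(key=lambda t: t[0])
        for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {s2} < {e1}"
                )
        size = ivals[-1][1]
        if chrom in data:
            if size > data[chrom].size:
                raise ValidationError(
                    f"{path}: interval on {chrom} exceeds declared size {data[chrom].size}"
                )
        else:
            data[chrom] = np.zeros(size, dtype=float)
        arr = data[chrom]
        for s, e, v in ivals:
            arr[s:e] = v
    return CoverageTrack(data=data, mapped_reads=mapped_reads)


def write_coverage(path: str | os.PathLike, track) -> None:
    """Write a coverage track as bedGraph, run-length encoding constant runs.

    Zero-valued runs are omitted (the reader restores them), which keeps files
    compact.  The library size is preserved in a ``# mapped_reads=`` comment.
    """
    with open(path, "w") as fh:
        if track.mapped_reads is not None:
            fh.write(f"# mapped_reads={track.mapped_reads}\n")
        for chrom in sorted(track.data):
            values = track.data[chrom]
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# genes, counts, gene sets, FASTA
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read a gene table (TSV: gene_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_gene_table(path: str | os.PathLike, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_counts(
    path: str | os.PathLike,
    condition_of: Mapping[str, str] | str | os.PathLike,
) -> CountMatrix:
    """Read a genes x samples TSV count matrix.

    ``condition_of`` is either a mapping sample -> condition or the path of a
    two-column TSV (sample_id, condition).  Counts must be non-negative
    integers; an all-zero gene is accepted (filtering happens downstream).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac, _ = np.modf(values.astype(float))
        if np.any(frac != 0):
            bad = df.columns[np.argwhere(frac != 0)[0][1]]
            raise ValidationError(f"{path}: non-integer count in column {bad!r}")
        df = df.astype(np.int64)
    if isinstance(condition_of, (str, os.PathLike)):
        cond_df = pd.read_csv(condition_of, sep="\t", dtype=str)
        condition_of = dict(zip(cond_df.iloc[:, 0], cond_df.iloc[:, 1]))
    df.index = df.index.astype(str)
    return CountMatrix(counts=df, condition_of=dict(condition_of))


def write_counts(path: str | os.PathLike, matrix: CountMatrix, conditions_path: str | os.PathLike | None = None) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")
    if conditions_path is not None:
        with open(conditions_path, "w") as fh:
            fh.write("sample_id\tcondition\n")
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.condition_of[s]}\n")


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read gene sets in GMT format (set id, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: gene set with empty member list")
            members = [m for m in fields[2:] if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set with empty member list")
            sets.append(GeneSet(fields[0], fields[1], frozenset(members)))
    return sets


def write_gmt(path: str | os.PathLike, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(s.set_id + "\t" + s.description + "\t" + "\t".join(sorted(s.members)) + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an (ordered) dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
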