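"""Reading and writing the standard formats the toolkit consumes.

All coordinates inside the package are 0-based half-open intervals.
Conversion to the 1-based closed convention happens only at the GFF3
boundary (delegated to :mod:`pyranges`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED_RESIDUES = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}.

    Topology is recorded (bacterial chromosomes are circular) but scanning
    operations treat the sequence as linear.
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("genome sequence must have length >= 1")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains illegal residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if on another sequence)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class CoverageTrack:
    """Dense per-base occupancy coverage in arbitrary units."""

    seq_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TSSRecord:
    """A transcription start site with its enrichment score.

    ``rank`` is assigned within one promoter: rank 1 is the TSS with the
    highest enrichment score of that promoter.
    """

    position: int
    strand: str
    enrichment_score: float
    assigned_gene: str | None = None
    rank: int | None = None
    seq_id: str = ""


@dataclass(frozen=True)
class Gene:
    """A gene model: interval plus identifier; start codon at the
    strand-dependent 5' end of the interval."""

    seq_id: str
    start: int
    end: int
    strand: str
    gene_id: str

    @property
    def start_codon(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end, self.strand,
                               self.gene_id)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into upper-cased genome sequences.

    Order of records is preserved. Raises :class:`ParseError` on residues
    outside {A, C, G, T, N}, naming the offending record and line.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - ALLOWED_RESIDUES
        if bad:
            line = _find_line(path, rec.id, bad)
            raise ParseError(
                f"{path}:{line}: record {rec.id!r} contains illegal "
                f"residue(s) {sorted(bad)}"
            )
        records.append(GenomeSequence(rec.id, residues))
    return records


def _find_line(path: Path, rec_id: str, bad: set[str]) -> int:
    """Best-effort line number of the first illegal residue in a record."""
    in_record = False
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith(">"):
                in_record = raw[1:].split()[0] == rec_id if raw[1:].strip() else False
                continue
            if in_record and (set(raw.strip().upper()) & bad):
                return i
    return 0


def write_fasta(sequences: Iterable[GenomeSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# bedGraph

_BEDGRAPH_COLS = ["seq_id", "start", "end", "value"]


def read_bedgraph(path: str | os.PathLike, genome_length: int,
                  seq_id: str | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-base coverage vector.

    Bases not covered by any interval are 0. Overlapping intervals with
    conflicting values raise :class:`ParseError`; intervals reaching beyond
    ``genome_length`` raise :class:`ParseError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BEDGRAPH_COLS,
                         comment="#", dtype={"seq_id": str})
    except pd.errors.EmptyDataError:
        return CoverageTrack(seq_id or "", np.zeros(genome_length))
    if df.empty:
        return CoverageTrack(seq_id or "", np.zeros(genome_length))
    if seq_id is None:
        ids = df["seq_id"].unique()
        if len(ids) > 1:
            raise ParseError(f"bedGraph covers several sequences {list(ids)}; "
                             "pass seq_id to select one")
        seq_id = str(ids[0])
    df = df[df["seq_id"] == seq_id]
    if (df["end"] > genome_length).any():
        row = df[df["end"] > genome_length].iloc[0]
        raise ParseError(
            f"bedGraph interval [{row.start}, {row.end}) exceeds genome "
            f"length {genome_length}"
        )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ParseError("bedGraph intervals must satisfy 0 <= start < end")
    values = np.zeros(genome_length)
    seen = np.zeros(genome_length, dtype=bool)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        sl = slice(int(start), int(end))
        clash = seen[sl] & (values[sl] != value)
        if clash.any():
            raise ParseError(
                f"conflicting overlapping bedGraph values at base "
                f"{int(start) + int(np.argmax(clash))}"
            )
        values[sl] = value
        seen[sl] = True
    return CoverageTrack(seq_id, values)


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a dense coverage track as run-length-encoded bedGraph.

    Zero runs are omitted, matching the sparse bedGraph convention."""
    v = track.values
    # run boundaries where the value changes
    change = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(v)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{track.seq_id}\t{s}\t{e}\t{v[s]:g}\n")


# ---------------------------------------------------------------------------
# BED / TSV / GFF3


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike,
              scores: Sequence[float] | None = None) -> None:
    """Write intervals as BED6 (no header). Scores default to 0."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = scores[i] if scores is not None else 0
            name = iv.name or "."
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}"
                     f"\t{iv.strand}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 else "."
        name = "" if len(row) <= 3 or str(row[3]) == "." else str(row[3])
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]),
                                   str(strand), name))
    return out


def write_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gff3_genes(path: str | os.PathLike) -> list[Gene]:
    """Read gene features from GFF3; pyranges converts to 0-based half-open."""
    import pyranges as pr

    gr = pr.read_gff3(str(path)).df
    gr = gr[gr["Feature"] == "gene"]
    genes = []
    for row in gr.itertuples(index=False):
        gid = getattr(row, "ID", None) or getattr(row, "Name", "") or ""
        genes.append(Gene(str(row.Chromosome), int(row.Start), int(row.End),
                          str(row.Strand), str(gid)))
    return genes


def write_gff3_genes(genes: Sequence[Gene], path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.seq_id}\txsilence\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")


def read_tss_table(path: str | os.PathLike) -> list[TSSRecord]:
    df = read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(TSSRecord(
            position=int(row.position),
            strand=str(row.strand),
            enrichment_score=float(row.enrichment_score),
            assigned_gene=(str(row.assigned_gene)
                           if getattr(row, "assigned_gene", None) not in (None, "", float("nan"))
                           and not pd.isna(getattr(row, "assigned_gene", None)) else None),
            seq_id=str(getattr(row, "seq_id", "")),
        ))
    return out


def write_tss_table(records: Sequence[TSSRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame({
        "seq_id": [r.seq_id for r in records],
        "position": [r.position for r in records],
        "strand": [r.strand for r in records],
        "enrichment_score": [r.enrichment_score for r in records],
        "assigned_gene": [r.assigned_gene or "" for r in records],
        "rank": [r.rank if r.rank is not None else "" for r in records],
    })
    write_tsv(df, path)
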