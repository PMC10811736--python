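"""Readers and writers for every external representation the pipeline touches.

FASTA (nucleotide and amino-acid), the 12-column tabular hit format produced
by BLAST-style search tools (``qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore``), the genome->lineage/size map,
binary presence/absence matrices, and partition files in the
``TYPE, name = start-end`` dialect.

Conventions
-----------
* Hit coordinates stay 1-based inclusive (the tabular format's convention);
  all internal interval work in this package is 0-based half-open, and the
  conversion happens only at this boundary.
* Lines beginning ``#`` in tabular files are treated as comments.
* FASTA record ids are the token before the first whitespace; the remainder
  of the header line is the description.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO


@dataclass
class SequenceRecord:
    """A named sequence: id token, free-text description, upper-case residues."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One line of the 12-column tabular search format.

    Coordinates are 1-based inclusive as printed by the search tools.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError(f"alignment length {self.alignment_length} < 1")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")


@dataclass
class LineageMap:
    """genome id -> (lineage label, genome size in bp)."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    def add(self, genome_id: str, lineage: str, genome_size_bp: int) -> None:
        if genome_id in self.entries:
            raise ValueError(f"duplicate genome id {genome_id!r}")
        if genome_size_bp <= 0:
            raise ValueError(
                f"genome {genome_id!r}: size {genome_size_bp} must be > 0"
            )
        self.entries[genome_id] = (lineage, int(genome_size_bp))

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lineage(self, genome_id: str) -> str:
        return self.entries[genome_id][0]

    def size_bp(self, genome_id: str) -> int:
        return self.entries[genome_id][1]

    def size_mb(self, genome_id: str) -> float:
        return self.entries[genome_id][1] / 1e6

    def lineages(self) -> list[str]:
        return sorted({lin for lin, _ in self.entries.values()})

    def genomes_in(self, lineage: str) -> list[str]:
        out = sorted(g for g, (lin, _) in self.entries.items() if lin == lineage)
        if not out:
            raise KeyError(f"unknown lineage {lineage!r}")
        return out

    def mean_size_mb(self, lineage: str) -> float:
        """Average genome size (Mb) over all database genomes of a lineage."""
        sizes = [self.size_mb(g) for g in self.genomes_in(lineage)]
        return sum(sizes) / len(sizes)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are upper-cased and line wrapping is removed. An empty file or
    a record with an empty sequence is an error.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60
) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_hits_table(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column tabular hit file; ``#`` lines are comments."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def write_hits_table(hits: Iterable[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


def read_lineage_map(path: str | os.PathLike) -> LineageMap:
    """Read a 3-column TSV (genome_id, lineage, genome_size_bp)."""
    lmap = LineageMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"line {lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                lmap.add(fields[0], fields[1], int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return lmap


def write_lineage_map(lmap: LineageMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(lmap.entries):
            lin, size = lmap.entries[g]
            fh.write(f"{g}\t{lin}\t{size}\n")


def write_presence_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an OG x genome binary matrix as TSV (first column OG id)."""
    matrix.to_csv(path, sep="\t", index_label="og_id")


def read_presence_matrix(path: str | os.PathLike) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    values = matrix.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        bad = values[(values != 0) & (values != 1)][0]
        raise ValueError(f"non-binary cell value {bad!r} in presence matrix")
    return matrix.astype("int8")


def write_partition_file(
    partitions: Sequence[tuple[str, int, int]],
    path: str | os.PathLike,
    partition_type: str = "AA",
) -> None:
    """Write marker partitions as ``<type>, <name> = <start>-<end>`` lines.

    Partitions must be contiguous 1-based inclusive intervals tiling
    ``1..L`` without gaps or overlaps.
    """
    expected_start = 1
    for name, start, end in partitions:
        if start != expected_start:
            raise ValueError(
                f"partition {name!r} starts at {start}, expected {expected_start} "
                "(gap or overlap)"
            )
        if end < start:
            raise ValueError(f"partition {name!r}: end {end} < start {start}")
        expected_start = end + 1
    with open(path, "w") as fh:
        for name, start, end in partitions:
            fh.write(f"{partition_type}, {name} = {start}-{end}\n")
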