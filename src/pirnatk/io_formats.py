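"""Readers and writers for the external formats the pipeline touches.

Centralizes coordinate conventions: all internal coordinates are 0-based
half-open; GFF3 and the 12-column tabular hit format are 1-based inclusive,
and the conversion happens here and only here.  Also hosts the project
logger and TOML configuration loading.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "TabularHit",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "read_hits",
    "write_hits",
    "write_gff3",
    "write_bed6",
    "load_config",
    "get_logger",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (A/C/G/T/N, upper case)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TabularHit:
    """One row of 12-column tabular similarity-search output.

    Subject coordinates are stored 1-based inclusive with
    ``subject_start <= subject_end``; a raw row with ``sstart > send``
    encodes a minus-strand hit and is normalized at ingestion, with the
    strand made explicit.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    strand: str  # '+' or '-'

    @property
    def span0(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval."""
        return self.subject_start - 1, self.subject_end

    @property
    def span_length(self) -> int:
        return self.subject_end - self.subject_start + 1


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records.

    Sequences are upper-cased and RNA U is converted to T.  Duplicate ids
    and empty files are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_seq(str(rec.seq))))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ reads; qualities are ignored."""
    records = [
        SequenceRecord(rec.id, _normalize_seq(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def read_reads(path: str | Path) -> list[SequenceRecord]:
    """Read small-RNA reads from FASTA or FASTQ, sniffing the first byte."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_hits(path: str | Path) -> list[TabularHit]:
    """Parse 12-column tab-separated similarity-search hits.

    Rows are returned in file order.  Subject coordinates are normalized so
    that start <= end, and the strand is set from the raw coordinate order.
    """
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            sstart, send = int(fields[8]), int(fields[9])
            if sstart > send:
                sstart, send, strand = send, sstart, "-"
            else:
                strand = "+"
            hits.append(
                TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_openings=int(fields[5]),
                    query_start=int(fields[6]),
                    query_end=int(fields[7]),
                    subject_start=sstart,
                    subject_end=send,
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                    strand=strand,
                )
            )
    return hits


def write_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits back to the 12-column format (minus strand re-encoded by coordinate order)."""
    with open(path, "w") as fh:
        for h in hits:
            s, e = h.subject_start, h.subject_end
            if h.strand == "-":
                s, e = e, s
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.percent_identity,
                        h.alignment_length,
                        h.mismatches,
                        h.gap_openings,
                        h.query_start,
                        h.query_end,
                        s,
                        e,
                        h.e_value,
                        h.bit_score,
                    )
                )
                + "\n"
            )


def _check_sorted(insertions: Sequence) -> None:
    keys = [(ins.contig, ins.start) for ins in insertions]
    if keys != sorted(keys):
        raise ValueError("insertions must be sorted by (contig, start)")


def write_gff3(insertions: Sequence, path: str | Path) -> None:
    """Write TE insertions as GFF3 (1-based inclusive coordinates).

    Input spans are 0-based half-open; the +1 shift happens here.
    Insertions must be sorted by (contig, start).
    """
    _check_sorted(insertions)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ins in enumerate(insertions):
            attrs = (
                f"ID=te{i:05d};family={ins.family_id};identity={ins.identity:.2f};"
                f"completeness={ins.completeness:.4f};full_length={str(ins.full_length).lower()};"
                f"n_merged_hits={ins.n_merged_hits}"
            )
            fh.write(
                "\t".join(
                    (
                        ins.contig,
                        "pirnatk",
                        "transposable_element",
                        str(ins.start + 1),
                        str(ins.end),
                        f"{ins.identity:.2f}",
                        ins.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


def write_bed6(insertions: Sequence, path: str | Path) -> None:
    """Write TE insertions as BED6 (0-based half-open, as stored internally)."""
    _check_sorted(insertions)
    with open(path, "w") as fh:
        for ins in insertions:
            fh.write(
                "\t".join(
                    (
                        ins.contig,
                        str(ins.start),
                        str(ins.end),
                        ins.family_id,
                        f"{ins.identity:.2f}",
                        ins.strand,
                    )
                )
                + "\n"
            )


@dataclass(frozen=True)
class BedFeature:
    """One BED6 feature (0-based half-open), name column carrying the TE family."""

    contig: str
    start: int
    end: int
    family_id: str
    score: float
    strand: str


def read_bed6(path: str | Path) -> list[BedFeature]:
    feats: list[BedFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected 6 BED columns, got {len(fields)}")
            feats.append(
                BedFeature(
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    family_id=fields[3],
                    score=float(fields[4]),
                    strand=fields[5],
                )
            )
    return feats


def load_config(path: str | Path) -> dict:
    """Load a TOML configuration file."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def get_logger(name: str = "pirnatk", verbose: bool = False) -> logging.Logger:
    """Project logger writing to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger
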