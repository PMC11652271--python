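"""Sequence and interval data model plus the string primitives shared by the pipeline.

Alpha-satellite annotation is, at bottom, bookkeeping over DNA strings and
genomic intervals: reads and assemblies come in as FASTA/FASTQ, monomer and
HOR tracks go out as BED, and almost every stage scores sequences against each
other with a plain Levenshtein edit distance.  This module fixes those
conventions once:

* coordinates are 0-based half-open everywhere in memory and in BED on disk;
* sequences are uppercase over the alphabet ``{A, C, G, T, N}``;
* edit distance uses unit costs, and ``N`` never matches anything (not even
  another ``N``) so that ambiguous bases behave conservatively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a sequence file cannot be parsed."""


@dataclass
class SequenceRecord:
    """One named DNA sequence, optionally with per-base quality scores."""

    id: str
    bases: str
    description: str = ""
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _clean_bases(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    cleaned = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
    n_mapped = sum(1 for a, b in zip(seq, cleaned) if a != b)
    logger.warning("record %s: mapped %d non-ACGTN characters to N", record_id, n_mapped)
    return cleaned


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise FastaParseError(f"{path}: unrecognized leading line {line[:40]!r}")
    raise FastaParseError(f"{path}: empty file")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA or FASTQ file (dialect auto-detected) into records.

    Lowercase bases are normalized to uppercase and any non-ACGTN character is
    mapped to ``N`` (logged).  Records are returned in file order.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            bases = _clean_bases(str(rec.seq), rec.id)
            if not bases:
                raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
            qual = rec.letter_annotations.get("phred_quality")
            records.append(
                SequenceRecord(
                    id=rec.id,
                    bases=bases,
                    description=rec.description,
                    quality=list(qual) if qual is not None else None,
                )
            )
    except ValueError as exc:  # biopython signals malformed records this way
        raise FastaParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, wrapping lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs.

    ``N`` is treated as matching nothing, including another ``N``: ambiguous
    bases always cost a substitution.
    """
    if not a or not b:
        raise ValueError("edit_distance requires non-empty sequences")
    if "N" in a:
        a = a.replace("N", "!")
    if "N" in b:
        b = b.replace("N", "?")
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def sequence_identity(a: str, b: str) -> float:
    """Identity between two sequences as ``1 - ed(a, b) / max(len(a), len(b))``.

    This is the block-vs-monomer-template identity used throughout HOR
    annotation; it is symmetric and equals 1 iff the sequences are equal.
    """
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path, *, sort: bool = False) -> None:
    """Write intervals as 6-column BED (chrom, start, end, name, score, strand)."""
    rows = list(intervals)
    if sort:
        rows.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file written by :func:`write_bed` (3+ columns accepted)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return out
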