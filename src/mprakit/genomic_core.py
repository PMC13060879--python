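"""Coordinate arithmetic, sequence retrieval and standard-format I/O.

All coordinates in this package are 1-based and inclusive on both ends,
matching the convention in which genomic spans such as
``chr17:45,893,536-45,895,535`` are printed.  BED input/output converts to
0-based half-open coordinates at the file boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "parse_region",
    "reverse_complement",
    "fetch_sequence",
    "interval_length",
    "open_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_interval_table",
    "write_interval_table",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully inclusive genomic span with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1

    def exclusive_width(self) -> int:
        """Width under the exclusive (end - start) convention.

        Spans are sometimes described by this convention in prose (a
        27-base inclusive span becomes "~26 bp"); both are exposed and
        neither is privileged.
        """
        return self.end - self.start

    def midpoint(self) -> int:
        """Middle coordinate; for even lengths, the lower of the two central bases."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Number of bases strictly between two non-overlapping intervals.

        Abutting intervals (e.g. 1-100 and 101-200) have gap 0; overlapping
        intervals have negative gap.
        """
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        lo, hi = sorted((self, other), key=lambda iv: iv.start)
        return hi.start - lo.end - 1

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("union undefined across chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class SequenceRecord:
    """A named uppercase DNA sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError("empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in sequence {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


# Accept both a plain hyphen and the typographic en-dash used in print.
_REGION_RE = re.compile(r"^\s*([^:\s]+):\s*([\d,]+)\s*[-–—]\s*([\d,]+)\s*$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a printed region string like ``chr17:45,893,536-45,895,535``.

    Thousands separators and en/em dashes are accepted.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse region string {text!r}")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    return GenomicInterval(chrom, int(start.replace(",", "")), int(end.replace(",", "")))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


GenomeLike = Union[Mapping[str, str], "pyfaidx.Fasta"]  # noqa: F821


def contig_length(genome: GenomeLike, chrom: str) -> int:
    return len(genome[chrom])


def fetch_sequence(genome: GenomeLike, iv: GenomicInterval) -> SequenceRecord:
    """Extract the sequence of ``iv`` from an indexed FASTA or dict-like genome.

    Minus-strand intervals return the reverse complement.  The genome may be
    a ``pyfaidx.Fasta`` handle or any mapping from contig name to sequence.
    """
    try:
        contig = genome[iv.chrom]
    except KeyError:
        raise KeyError(f"unknown contig {iv.chrom!r}") from None
    n = len(contig)
    if iv.end > n:
        raise ValueError(
            f"interval {iv} exceeds contig {iv.chrom!r} of length {n}"
        )
    seq = str(contig[iv.start - 1 : iv.end]).upper()
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=str(iv), seq=seq)


def interval_length(iv: GenomicInterval) -> int:
    """Inclusive span length (end - start + 1)."""
    return iv.length()


def open_fasta(path: str | Path):
    """Open an indexed FASTA for random access (index built on first use)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3-6 columns), converting to 1-based inclusive coordinates."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(GenomicInterval(chrom, start0 + 1, end0, strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    """Write BED6 (0-based half-open)."""
    ivs = list(intervals)
    names = list(names) if names is not None else [f"iv{i}" for i in range(len(ivs))]
    scores = list(scores) if scores is not None else [0] * len(ivs)
    with open(path, "w") as fh:
        for iv, name, score in zip(ivs, names, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_interval_table(path: str | Path) -> pd.DataFrame:
    """Read a header-bearing TSV with at least chrom/start/end columns (1-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    return df


def write_interval_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
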