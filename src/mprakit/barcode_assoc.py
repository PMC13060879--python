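"""Barcode-to-element association: locus binning for sheared-fragment
libraries and exact-length CIGAR matching for designed-oligo libraries.

A barcode dictionary maps each 15 bp barcode to exactly one element (a
genomic bin for fragment libraries, an oligo id for designed libraries).
Barcodes observed for more than one element are removed outright — no
majority vote — and oligo-mode records must align as a single full-length
match run (``219M``, ``218M``, ...) equal to the designed oligo length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genomic_core import GenomicInterval

__all__ = [
    "AssociationRecord",
    "BarcodeDictionary",
    "FilterReport",
    "bin_locus",
    "assign_fragment",
    "build_dictionary",
    "read_association_tsv",
    "read_association_sam",
]

BARCODE_LEN = 15
_BARCODE_RE = re.compile(r"^[ACGT]{%d}$" % BARCODE_LEN)
_CIGAR_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")


@dataclass(frozen=True)
class AssociationRecord:
    """One barcode observation from association sequencing.

    Fragment mode carries the aligned insert interval; oligo mode carries
    the matched oligo id plus the alignment CIGAR string.
    """

    barcode: str
    aligned_iv: GenomicInterval | None = None
    oligo_id: str | None = None
    cigar: str | None = None
    read_count: int = 1

    def __post_init__(self) -> None:
        if not _BARCODE_RE.match(self.barcode):
            raise ValueError(
                f"barcode must be {BARCODE_LEN} bases over ACGT, got {self.barcode!r}"
            )
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class FilterReport:
    """Record-level accounting for dictionary construction (categories sum to input)."""

    kept: int = 0
    removed_multimap: int = 0
    removed_cigar: int = 0
    removed_support: int = 0
    removed_malformed: int = 0
    removed_unassigned: int = 0

    def total(self) -> int:
        return (
            self.kept
            + self.removed_multimap
            + self.removed_cigar
            + self.removed_support
            + self.removed_malformed
            + self.removed_unassigned
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "removed_multimap": self.removed_multimap,
            "removed_cigar": self.removed_cigar,
            "removed_support": self.removed_support,
            "removed_malformed": self.removed_malformed,
            "removed_unassigned": self.removed_unassigned,
        }


@dataclass
class BarcodeDictionary:
    """Injective-per-barcode mapping barcode -> element, with support counts."""

    mapping: dict[str, str] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    report: FilterReport = field(default_factory=FilterReport)

    def element_barcode_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for element in self.mapping.values():
            counts[element] = counts.get(element, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": list(self.mapping),
                "element_id": [self.mapping[b] for b in self.mapping],
                "support": [self.support[b] for b in self.mapping],
            }
        ).sort_values(["element_id", "barcode"], ignore_index=True)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "BarcodeDictionary":
        df = pd.read_csv(path, sep="\t")
        d = cls()
        for row in df.itertuples(index=False):
            d.mapping[row.barcode] = row.element_id
            d.support[row.barcode] = int(getattr(row, "support", 1))
        return d


def bin_locus(region: GenomicInterval, width: int = 100) -> list[GenomicInterval]:
    """Divide a locus into non-overlapping left-to-right bins of ``width`` bp.

    The terminal bin may be shorter; the union of bins equals the region.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    bins = []
    start = region.start
    while start <= region.end:
        end = min(start + width - 1, region.end)
        bins.append(GenomicInterval(region.chrom, start, end))
        start = end + 1
    return bins


def assign_fragment(
    frag_iv: GenomicInterval, bins: list[GenomicInterval]
) -> GenomicInterval | None:
    """Assign a sheared fragment to the bin containing its midpoint.

    For even-length fragments the midpoint is the lower of the two central
    coordinates.  Returns None when the midpoint falls outside the binned
    locus (the caller counts these as unassigned).
    """
    mid = frag_iv.midpoint()
    for b in bins:
        if b.chrom == frag_iv.chrom and b.start <= mid <= b.end:
            return b
    return None


def _cigar_is_full_match(cigar: str, expected_len: int) -> bool | None:
    """True if CIGAR is a single match run of exactly ``expected_len``;
    None signals a malformed CIGAR."""
    if not cigar or not _CIGAR_RE.match(cigar):
        return None
    return cigar == f"{expected_len}M"


def build_dictionary(
    records: Iterable[AssociationRecord],
    mode: str,
    min_support: int = 1,
    bins: list[GenomicInterval] | None = None,
    oligo_lengths: Mapping[str, int] | None = None,
) -> BarcodeDictionary:
    """Build the barcode dictionary from association records.

    mode="fragment": each record's insert is assigned to the bin containing
    its midpoint (``bins`` required).  mode="oligo": records must carry a
    CIGAR that is a perfect full-length match for the named oligo
    (``oligo_lengths`` maps oligo_id -> designed length).  In both modes,
    barcodes seen for more than one element are removed entirely, then
    barcodes whose total read support is below ``min_support``.  The result
    is independent of record order.
    """
    if mode not in ("fragment", "oligo"):
        raise ValueError(f"mode must be 'fragment' or 'oligo', got {mode!r}")
    if mode == "fragment" and bins is None:
        raise ValueError("fragment mode requires bins")
    if mode == "oligo" and oligo_lengths is None:
        raise ValueError("oligo mode requires oligo_lengths")

    report = FilterReport()
    # barcode -> element -> (reads, records)
    seen: dict[str, dict[str, list[int]]] = {}
    for rec in records:
        if mode == "oligo":
            if rec.oligo_id is None or rec.oligo_id not in oligo_lengths:
                report.removed_malformed += 1
                continue
            ok = _cigar_is_full_match(rec.cigar or "", oligo_lengths[rec.oligo_id])
            if ok is None:
                report.removed_malformed += 1
                continue
            if not ok:
                report.removed_cigar += 1
                continue
            element = rec.oligo_id
        else:
            if rec.aligned_iv is None:
                report.removed_malformed += 1
                continue
            b = assign_fragment(rec.aligned_iv, bins)
            if b is None:
                report.removed_unassigned += 1
                continue
            element = f"bin:{b.chrom}:{b.start}-{b.end}"
        per = seen.setdefault(rec.barcode, {})
        stats = per.setdefault(element, [0, 0])
        stats[0] += rec.read_count
        stats[1] += 1

    d = BarcodeDictionary(report=report)
    for barcode in sorted(seen):
        per = seen[barcode]
        n_records = sum(s[1] for s in per.values())
        if len(per) > 1:
            report.removed_multimap += n_records
            continue
        (element, (reads, nrec)), = per.items()
        if reads < min_support:
            report.removed_support += nrec
            continue
        report.kept += nrec
        d.mapping[barcode] = element
        d.support[barcode] = reads
    return d


def read_association_tsv(path: str | Path) -> list[AssociationRecord]:
    """Read the simplified association TSV dialect.

    Columns: barcode, element_or_chrom, start, end, cigar, reads.  Rows with
    a CIGAR are oligo-mode records (element_or_chrom is an oligo id); rows
    with start/end are fragment-mode records.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cigar": "string"})
    out: list[AssociationRecord] = []
    for row in df.itertuples(index=False):
        reads = int(getattr(row, "reads", 1))
        cigar = getattr(row, "cigar", None)
        if pd.notna(cigar) and str(cigar):
            out.append(
                AssociationRecord(
                    barcode=row.barcode,
                    oligo_id=str(row.element_or_chrom),
                    cigar=str(cigar),
                    read_count=reads,
                )
            )
        else:
            out.append(
                AssociationRecord(
                    barcode=row.barcode,
                    aligned_iv=GenomicInterval(
                        str(row.element_or_chrom), int(row.start), int(row.end)
                    ),
                    read_count=reads,
                )
            )
    return out


def read_association_sam(path: str | Path, mode: str = "fragment") -> list[AssociationRecord]:
    """Read association records from SAM/BAM alignments.

    The barcode is taken from the read name (or the ``BC`` tag when
    present).  Secondary and supplementary alignments are ignored.  In
    fragment mode the record carries the alignment's reference span; in
    oligo mode it carries the reference (oligo) name and CIGAR.
    """
    import pysam

    out: list[AssociationRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            barcode = (
                aln.get_tag("BC") if aln.has_tag("BC") else aln.query_name.split("_")[0]
            )
            if mode == "fragment":
                out.append(
                    AssociationRecord(
                        barcode=barcode,
                        aligned_iv=GenomicInterval(
                            aln.reference_name,
                            aln.reference_start + 1,
                            aln.reference_end,
                        ),
                    )
                )
            else:
                out.append(
                    AssociationRecord(
                        barcode=barcode,
                        oligo_id=aln.reference_name,
                        cigar=aln.cigarstring,
                    )
                )
    return out
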