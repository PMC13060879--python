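"""Oligo library designers: strand tiling, per-base saturation mutagenesis,
known-variant ref/alt pairs, and GC-matched scrambled negative controls.

Design rules implemented here:

* Tiling: fixed-length oligos placed at a fixed step across a region, one
  copy per strand (the minus-strand oligo is the reverse complement of the
  same genomic window).  Defaults of 270 bp every 90 bp on both strands give
  6x per-base coverage away from region edges.
* Saturation: for every base of a target region, one reference oligo with
  that base centered, three single-substitution oligos (every alternate
  base), and one oligo carrying a centered 5 bp deletion.
* Known variants: ref/alt oligo pairs with the variant centered.  SNVs use
  a fixed odd length (default 219 bp).  Deletions of an odd number of bases
  keep the 219 bp reference window; even-length deletions drop to 218 bp so
  the deleted span sits exactly in the middle with equal flanks.  Insertions
  mirror the rule on the alternate sequence.
* Scrambles: seeded per-oligo base permutations, which match GC content of
  the source exactly; at least one scramble per distinct test-oligo length,
  with optional center-base-substituted siblings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genomic_core import (
    GenomeLike,
    GenomicInterval,
    contig_length,
    fetch_sequence,
    reverse_complement,
)

__all__ = [
    "OligoRecord",
    "VariantSpec",
    "VariantDesignResult",
    "design_tiles",
    "design_saturation",
    "design_variant_oligos",
    "replicate_rule",
    "make_scrambles",
]

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

ALLELE_CLASSES = (
    "ref",
    "snv_alt",
    "deletion",
    "insertion",
    "del5",
    "scramble",
    "promoter_ctrl",
    "negative",
)


@dataclass(frozen=True)
class OligoRecord:
    """A designed test sequence with its genomic anchor and allele annotation."""

    oligo_id: str
    seq: str
    anchor: GenomicInterval
    allele_class: str
    focal_pos: int | None = None
    variant_key: str | None = None

    def __post_init__(self) -> None:
        if self.allele_class not in ALLELE_CLASSES:
            raise ValueError(f"unknown allele_class {self.allele_class!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class VariantSpec:
    """A known variant in chrom:pos:ref:alt form with population annotation.

    ``pos`` is the 1-based position of the first base of ``ref_allele``.
    Indels are expected in the left-anchored convention (shared leading
    base), but any shared prefix is stripped internally before windowing.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_count: int = 1
    allele_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - set(BASES):
                raise ValueError(f"invalid allele {allele!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    def indel_size(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def normalized(self) -> tuple[int, str, str]:
        """Strip the shared prefix, returning (first differing pos, ref, alt)."""
        ref, alt, pos = self.ref_allele, self.alt_allele, self.pos
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
            # pure deletion: anchor base shared, deleted bases follow
            ref, alt, pos = ref[1:], "", pos + 1
        elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
            # pure insertion: inserted bases follow the anchor base
            ref, alt = "", alt[1:]
        return pos, ref, alt


def _window_has_n(seq: str) -> bool:
    return "N" in seq


def design_tiles(
    region: GenomicInterval,
    genome: GenomeLike,
    tile_len: int = 270,
    step: int = 90,
    strands: Sequence[str] = ("+", "-"),
) -> list[OligoRecord]:
    """Tile ``region`` with fixed-length oligos at a fixed step on each strand.

    Tiles start at ``region.start`` and advance by ``step`` while the full
    window fits inside the region.  Output is ordered by (start, strand).
    Windows containing N are skipped with a logged warning.
    """
    if region.length() < tile_len:
        raise ValueError(
            f"region length {region.length()} shorter than tile length {tile_len}"
        )
    out: list[OligoRecord] = []
    start = region.start
    while start + tile_len - 1 <= region.end:
        window = GenomicInterval(region.chrom, start, start + tile_len - 1)
        seq = fetch_sequence(genome, window).seq
        if _window_has_n(seq):
            logger.warning("skipping tile window %s: contains N", window)
            start += step
            continue
        for strand in strands:
            tile_seq = reverse_complement(seq) if strand == "-" else seq
            out.append(
                OligoRecord(
                    oligo_id=f"tile:{region.chrom}:{start}:{strand}",
                    seq=tile_seq,
                    anchor=GenomicInterval(region.chrom, start, start + tile_len - 1, strand),
                    allele_class="ref",
                )
            )
        start += step
    return out


def design_saturation(
    region: GenomicInterval,
    genome: GenomeLike,
    oligo_len: int = 219,
    del_len: int = 5,
) -> list[OligoRecord]:
    """Per-base saturation mutagenesis of ``region``.

    For every position p: one reference oligo whose window is p +/- (oligo_len-1)/2,
    three single-substitution oligos (each alternate base at the center), and
    one oligo with the ``del_len`` bases centered on p removed.  Positions
    whose window leaves the contig (or contains N) are skipped, never shifted,
    so the centering invariant always holds.
    """
    if oligo_len % 2 == 0:
        raise ValueError("oligo_len must be odd so a single base can be centered")
    if del_len % 2 == 0:
        raise ValueError("del_len must be odd so the deletion can be centered")
    flank = (oligo_len - 1) // 2
    dflank = (del_len - 1) // 2
    n = contig_length(genome, region.chrom)
    out: list[OligoRecord] = []
    for p in range(region.start, region.end + 1):
        lo, hi = p - flank, p + flank
        if lo < 1 or hi > n:
            logger.warning(
                "skipping saturation position %s:%d: window %d-%d leaves contig",
                region.chrom, p, lo, hi,
            )
            continue
        window = GenomicInterval(region.chrom, lo, hi)
        ref_seq = fetch_sequence(genome, window).seq
        if _window_has_n(ref_seq):
            logger.warning("skipping saturation position %s:%d: N in window", region.chrom, p)
            continue
        center_base = ref_seq[flank]
        key_base = f"{region.chrom}:{p}"
        out.append(
            OligoRecord(
                oligo_id=f"sat:{key_base}:{center_base}:ref",
                seq=ref_seq,
                anchor=window,
                allele_class="ref",
                focal_pos=p,
            )
        )
        for alt in BASES:
            if alt == center_base:
                continue
            out.append(
                OligoRecord(
                    oligo_id=f"sat:{key_base}:{center_base}:{alt}",
                    seq=ref_seq[:flank] + alt + ref_seq[flank + 1 :],
                    anchor=window,
                    allele_class="snv_alt",
                    focal_pos=p,
                    variant_key=f"{region.chrom}:{p}:{center_base}:{alt}",
                )
            )
        del_seq = ref_seq[: flank - dflank] + ref_seq[flank + dflank + 1 :]
        out.append(
            OligoRecord(
                oligo_id=f"sat:{key_base}:{center_base}:del{del_len}",
                seq=del_seq,
                anchor=window,
                allele_class="del5",
                focal_pos=p,
                variant_key=f"{region.chrom}:{p - dflank}:{ref_seq[flank - dflank : flank + dflank + 1]}:-",
            )
        )
    return out


@dataclass
class VariantDesignResult:
    """Designed ref/alt pairs plus an accounting of rejected variants."""

    pairs: list[tuple[OligoRecord, OligoRecord]] = field(default_factory=list)
    rejected: list[tuple[VariantSpec, str]] = field(default_factory=list)

    @property
    def oligos(self) -> list[OligoRecord]:
        return [o for pair in self.pairs for o in pair]


def _centered_window(focus_start: int, focus_len: int, total_len: int) -> tuple[int, int]:
    """Genomic window of ``total_len`` bases centering a focal span.

    Flanks are equal when parity allows; otherwise the extra base falls 3'.
    """
    slack = total_len - focus_len
    left = slack // 2  # extra base, if any, goes to the right (3') flank
    lo = focus_start - left
    hi = lo + total_len - 1
    return lo, hi


def design_variant_oligos(
    variants: Iterable[VariantSpec],
    genome: GenomeLike,
    base_len: int = 219,
    max_indel: int = 10,
) -> VariantDesignResult:
    """Design centered ref/alt oligo pairs for SNVs and small indels.

    Filters: indels over ``max_indel`` bases are rejected ("indel_gt_10");
    variants with allele count 0 are rejected ("ac_zero").  Deletion parity
    rule: the reference window is ``base_len`` (odd deletions) or
    ``base_len - 1`` (even deletions) so the deleted span is centered with
    equal flanks; insertions apply the mirrored rule to the alternate
    sequence.
    """
    result = VariantDesignResult()
    for v in variants:
        if v.indel_size() > max_indel:
            result.rejected.append((v, "indel_gt_10"))
            continue
        if v.allele_count == 0:
            result.rejected.append((v, "ac_zero"))
            continue
        pos, ref, alt = v.normalized()
        n = contig_length(genome, v.chrom)
        if v.is_snv():
            lo, hi = _centered_window(pos, 1, base_len)
            if lo < 1 or hi > n:
                result.rejected.append((v, "window_out_of_bounds"))
                continue
            window = GenomicInterval(v.chrom, lo, hi)
            ref_seq = fetch_sequence(genome, window).seq
            if _window_has_n(ref_seq):
                result.rejected.append((v, "n_in_window"))
                continue
            center = pos - lo
            if ref_seq[center] != ref:
                result.rejected.append((v, "ref_mismatch"))
                continue
            alt_seq = ref_seq[:center] + alt + ref_seq[center + 1 :]
            cls = "snv_alt"
        elif len(ref) > len(alt):  # deletion (alt empty after normalization)
            k = len(ref) - len(alt)
            ref_win_len = base_len if k % 2 == 1 else base_len - 1
            del_start = pos + len(alt)
            lo, hi = _centered_window(del_start, k, ref_win_len)
            if lo < 1 or hi > n:
                result.rejected.append((v, "window_out_of_bounds"))
                continue
            window = GenomicInterval(v.chrom, lo, hi)
            ref_seq = fetch_sequence(genome, window).seq
            if _window_has_n(ref_seq):
                result.rejected.append((v, "n_in_window"))
                continue
            off = del_start - lo
            if ref_seq[off : off + k] != ref[len(alt) :]:
                result.rejected.append((v, "ref_mismatch"))
                continue
            alt_seq = ref_seq[:off] + ref_seq[off + k :]
            cls = "deletion"
        else:  # insertion
            k = len(alt) - len(ref)
            alt_win_len = base_len if k % 2 == 1 else base_len - 1
            inserted = alt[len(ref) :]
            # inserted bases sit between pos and pos+1 after normalization
            ref_win_len = alt_win_len - k
            left = ref_win_len // 2
            lo = pos - left + 1
            hi = lo + ref_win_len - 1
            if lo < 1 or hi > n:
                result.rejected.append((v, "window_out_of_bounds"))
                continue
            window = GenomicInterval(v.chrom, lo, hi)
            ref_seq = fetch_sequence(genome, window).seq
            if _window_has_n(ref_seq):
                result.rejected.append((v, "n_in_window"))
                continue
            split = pos - lo + 1
            alt_seq = ref_seq[:split] + inserted + ref_seq[split:]
            cls = "insertion"

        ref_rec = OligoRecord(
            oligo_id=f"var:{v.key}:ref",
            seq=ref_seq,
            anchor=window,
            allele_class="ref",
            focal_pos=pos,
            variant_key=v.key,
        )
        alt_rec = OligoRecord(
            oligo_id=f"var:{v.key}:alt",
            seq=alt_seq,
            anchor=window,
            allele_class=cls,
            focal_pos=pos,
            variant_key=v.key,
        )
        result.pairs.append((ref_rec, alt_rec))
    return result


def replicate_rule(
    design: VariantDesignResult,
    variants: Iterable[VariantSpec],
    frequency_threshold: float = 1.0,
) -> list[OligoRecord]:
    """Emit the ordered multiset of variant oligos, duplicating common variants.

    Variants whose allele frequency is at or above ``frequency_threshold``
    (default 1.0 on the table's frequency scale) contribute two copies of
    each oligo, with distinct ``:copyN`` ids so downstream joins never rely
    on row order.
    """
    freq = {v.key: v.allele_frequency for v in variants}
    out: list[OligoRecord] = []
    for ref_rec, alt_rec in design.pairs:
        copies = 2 if freq.get(ref_rec.variant_key, 0.0) >= frequency_threshold else 1
        for c in range(1, copies + 1):
            for rec in (ref_rec, alt_rec):
                out.append(
                    OligoRecord(
                        oligo_id=f"{rec.oligo_id}:copy{c}",
                        seq=rec.seq,
                        anchor=rec.anchor,
                        allele_class=rec.allele_class,
                        focal_pos=rec.focal_pos,
                        variant_key=rec.variant_key,
                    )
                )
    return out


def make_scrambles(
    source_oligos: Sequence[OligoRecord],
    n: int,
    gc_tolerance: float = 0.0,
    rng_seed: int = 0,
    with_center_substitutions: bool = False,
) -> list[OligoRecord]:
    """Seeded scrambled negative controls matched to the test oligos.

    Each scramble is a random permutation of one source oligo's bases, which
    preserves base composition (and hence GC fraction) exactly, so any
    ``gc_tolerance`` >= 0 is satisfied by construction.  Every distinct
    source length receives at least one scramble.  With
    ``with_center_substitutions`` each scramble also emits three siblings
    with the middle base replaced by each alternate base.
    """
    if n > len(source_oligos):
        raise ValueError(
            f"requested {n} scrambles but only {len(source_oligos)} source oligos"
        )
    lengths = sorted({len(o.seq) for o in source_oligos})
    if n < len(lengths):
        raise ValueError(
            f"need at least {len(lengths)} scrambles to cover all source lengths"
        )
    rng = np.random.default_rng(rng_seed)
    by_length: dict[int, list[OligoRecord]] = {}
    for o in source_oligos:
        by_length.setdefault(len(o.seq), []).append(o)
    # one source per distinct length first, then fill uniformly
    chosen: list[OligoRecord] = []
    for L in lengths:
        pool = by_length[L]
        chosen.append(pool[int(rng.integers(len(pool)))])
    extra_needed = n - len(chosen)
    if extra_needed > 0:
        idx = rng.choice(len(source_oligos), size=extra_needed, replace=False)
        chosen.extend(source_oligos[int(i)] for i in idx)

    out: list[OligoRecord] = []
    for i, src in enumerate(chosen[:n]):
        perm = rng.permutation(len(src.seq))
        scr = "".join(src.seq[j] for j in perm)
        rec = OligoRecord(
            oligo_id=f"scramble:{i}:{src.oligo_id}",
            seq=scr,
            anchor=src.anchor,
            allele_class="scramble",
        )
        out.append(rec)
        if with_center_substitutions:
            mid = (len(scr) - 1) // 2
            for alt in BASES:
                if alt == scr[mid]:
                    continue
                out.append(
                    OligoRecord(
                        oligo_id=f"scramble:{i}:{src.oligo_id}:center{alt}",
                        seq=scr[:mid] + alt + scr[mid + 1 :],
                        anchor=src.anchor,
                        allele_class="scramble",
                    )
                )
    return out


def design_manifest(oligos: Iterable[OligoRecord]):
    """Tabulate designed oligos as a manifest DataFrame."""
    import pandas as pd

    rows = []
    for o in oligos:
        rows.append(
            {
                "oligo_id": o.oligo_id,
                "allele_class": o.allele_class,
                "chrom": o.anchor.chrom,
                "start": o.anchor.start,
                "end": o.anchor.end,
                "strand": o.anchor.strand,
                "focal_pos": o.focal_pos,
                "variant_key": o.variant_key,
                "length": len(o.seq),
            }
        )
    return pd.DataFrame(rows)
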