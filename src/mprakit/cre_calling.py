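"""Joining significant elements into CREs, cross-cell-type comparison, and
annotation against cCRE classes.

Overlapping or consecutive (abutting, or within a configurable gap)
significant bins/oligos are merged into a single candidate cis-regulatory
element by a left-to-right sweep.  CREs are compared to external cCRE
annotations by any-overlap, resolving multiple hits with a fixed
promoter-first precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic_core import GenomicInterval

__all__ = [
    "CRE",
    "ANNOTATION_PRECEDENCE",
    "call_cres",
    "compare_cell_types",
    "annotate_cres",
]

# promoter-most class wins when a CRE overlaps several cCREs
ANNOTATION_PRECEDENCE = (
    "PLS",
    "pELS",
    "dELS",
    "CA-H3K4me3",
    "CA-TF",
    "CA-CTCF",
    "CA",
    "TF",
)


@dataclass
class CRE:
    """A merged run of significant elements with summary statistics."""

    iv: GenomicInterval
    member_ids: list[str] = field(default_factory=list)
    peak_log_alpha: float = float("-inf")
    min_pval_mad: float = 1.0
    cell_type: str | None = None
    annotation_class: str = "unannotated"

    def n_members(self) -> int:
        return len(self.member_ids)


def call_cres(
    significant_elements: Sequence[tuple[GenomicInterval, Mapping]],
    adjacency_gap: int = 0,
    cell_type: str | None = None,
) -> list[CRE]:
    """Merge significant element intervals into CREs.

    ``significant_elements`` is a sequence of (interval, stats) where stats
    supplies ``element_id``, ``log_alpha`` and ``pval_mad``.  Elements whose
    intervals overlap, or whose gap is at most ``adjacency_gap`` bases, join
    the same CRE (gap 0 merges abutting 100 bp bins; tiles at a 90 bp step
    already overlap).  Significance filtering happens upstream.
    """
    if not significant_elements:
        return []
    items = sorted(significant_elements, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    cres: list[CRE] = []
    cur: CRE | None = None
    for iv, info in items:
        if (
            cur is not None
            and iv.chrom == cur.iv.chrom
            and iv.start - cur.iv.end - 1 <= adjacency_gap
        ):
            cur.iv = cur.iv.union(GenomicInterval(iv.chrom, iv.start, iv.end))
        else:
            cur = CRE(iv=GenomicInterval(iv.chrom, iv.start, iv.end), cell_type=cell_type)
            cres.append(cur)
        cur.member_ids.append(str(info.get("element_id", str(iv))))
        la = float(info.get("log_alpha", float("-inf")))
        cur.peak_log_alpha = max(cur.peak_log_alpha, la)
        cur.min_pval_mad = min(cur.min_pval_mad, float(info.get("pval_mad", 1.0)))
    return cres


def compare_cell_types(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    threshold: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Classify each element's activity sharing across two cell types.

    Both frames need element_id and pval_mad.  An element is significant in
    a cell type when pval_mad <= ``threshold``; the sharing class is
    ``shared`` (both), ``<label>_only`` (exactly one), or ``neither``.
    """
    a = results_a[["element_id", "pval_mad"]].rename(columns={"pval_mad": "p_a"})
    b = results_b[["element_id", "pval_mad"]].rename(columns={"pval_mad": "p_b"})
    merged = a.merge(b, on="element_id", how="outer")
    sig_a = merged["p_a"].le(threshold).fillna(False)
    sig_b = merged["p_b"].le(threshold).fillna(False)
    la, lb = labels
    cls = pd.Series("neither", index=merged.index, dtype=object)
    cls[sig_a & sig_b] = "shared"
    cls[sig_a & ~sig_b] = f"{la}_only"
    cls[~sig_a & sig_b] = f"{lb}_only"
    merged["sharing"] = cls
    return merged


def annotate_cres(
    cres: Iterable[CRE],
    ccres: Sequence[tuple[GenomicInterval, str]],
) -> list[CRE]:
    """Assign each CRE the class of any overlapping cCRE annotation.

    Zero overlap leaves the CRE ``unannotated``; multiple overlapping cCREs
    are resolved by the fixed precedence PLS > pELS > dELS > CA-H3K4me3 >
    CA-TF > CA-CTCF > CA > TF.  Modifies and returns the CRE list.
    """
    rank = {cls: i for i, cls in enumerate(ANNOTATION_PRECEDENCE)}
    for cre in cres:
        best: str | None = None
        for iv, cls in ccres:
            if cls not in rank:
                raise ValueError(f"unknown cCRE class {cls!r}")
            if cre.iv.overlaps(iv) and (best is None or rank[cls] < rank[best]):
                best = cls
        cre.annotation_class = best if best is not None else "unannotated"
    return list(cres)


def cres_to_frame(cres: Sequence[CRE]) -> pd.DataFrame:
    rows = []
    for cre in cres:
        rows.append(
            {
                "chrom": cre.iv.chrom,
                "start": cre.iv.start,
                "end": cre.iv.end,
                "n_members": cre.n_members(),
                "peak_log_alpha": cre.peak_log_alpha,
                "min_pval_mad": cre.min_pval_mad,
                "cell_type": cre.cell_type,
                "annotation_class": cre.annotation_class,
            }
        )
    return pd.DataFrame(rows)
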