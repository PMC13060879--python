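"""Per-element reporter activity and significance against a scrambled null.

The activity of an element is the ratio of its RNA to DNA barcode counts
(alpha), computed per replicate as a ratio of sums over the element's
barcodes after counts-per-million library normalization, then combined
across replicates by geometric mean.  Significance is a robust z-score
(mad.score) of log-activity against the median/MAD of scrambled negative
controls, with a standard-normal upper tail probability (pval.mad) floored
at 2.2e-16 and Benjamini-Hochberg adjustment across tested elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PVAL_FLOOR",
    "normalize_counts",
    "element_activity",
    "mad_test",
    "combine_strands",
    "count_columns",
]

PVAL_FLOOR = 2.2e-16

MIN_NULL_ELEMENTS = 20


def count_columns(cm: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Paired DNA/RNA replicate columns of a count table.

    Columns are matched by name: ``DNA_<rep>`` pairs with ``RNA_<rep>``.
    """
    dna = sorted(c for c in cm.columns if c.startswith("DNA_"))
    rna = sorted(c for c in cm.columns if c.startswith("RNA_"))
    reps_d = [c[4:] for c in dna]
    reps_r = [c[4:] for c in rna]
    if reps_d != reps_r:
        raise ValueError(f"unpaired replicate columns: DNA {reps_d} vs RNA {reps_r}")
    if not dna:
        raise ValueError("no DNA_/RNA_ count columns found")
    return dna, rna


def normalize_counts(cm: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million scaling of every DNA/RNA column (input unchanged)."""
    dna, rna = count_columns(cm)
    out = cm.copy()
    for col in dna + rna:
        total = cm[col].sum()
        if total <= 0:
            raise ValueError(f"column {col!r} has zero total count")
        out[col] = cm[col] * (1e6 / total)
    return out


def element_activity(
    cm_norm: pd.DataFrame,
    dictionary: pd.DataFrame | None = None,
    pseudocount: float = 1.0,
    min_barcodes: int = 1,
) -> pd.DataFrame:
    """Per-element activity ratios from a normalized barcode count table.

    ``cm_norm`` needs columns barcode, element_id (or a ``dictionary`` frame
    mapping barcode -> element_id) plus DNA_/RNA_ replicate columns.  Per
    replicate, alpha is a ratio of sums over the element's barcodes
    (robust to individual low-DNA barcodes); the element-level alpha is the
    geometric mean over replicates.

    Returns one row per element: element_id, n_barcodes, alpha_<rep>...,
    alpha, log_alpha.
    """
    cm = cm_norm
    if "element_id" not in cm.columns:
        if dictionary is None:
            raise ValueError("need element_id column or a barcode dictionary")
        cm = cm.merge(dictionary[["barcode", "element_id"]], on="barcode", how="inner")
    dna, rna = count_columns(cm)
    grouped = cm.groupby("element_id", sort=True)
    sums = grouped[dna + rna].sum()
    n_bc = grouped.size()

    rows = []
    for element_id, row in sums.iterrows():
        if n_bc[element_id] < min_barcodes:
            continue
        alphas = {}
        for dcol, rcol in zip(dna, rna):
            rep = dcol[4:]
            alphas[f"alpha_{rep}"] = (row[rcol] + pseudocount) / (row[dcol] + pseudocount)
        vals = np.array(list(alphas.values()), dtype=float)
        alpha = float(np.exp(np.mean(np.log(vals))))
        rows.append(
            {
                "element_id": element_id,
                "n_barcodes": int(n_bc[element_id]),
                **alphas,
                "alpha": alpha,
                "log_alpha": float(np.log(alpha)),
            }
        )
    return pd.DataFrame(rows)


def mad_test(
    elements: pd.DataFrame,
    null_elements: pd.DataFrame,
    alpha_threshold: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Robust z-test of element log-activity against scrambled controls.

    mad_score = (log_alpha - median(null)) / (1.4826 * MAD(null)); pval_mad
    is the standard-normal upper-tail probability (two-tailed optional),
    floored at 2.2e-16; adj_p is Benjamini-Hochberg over all tested
    elements.  Elements with pval_mad <= ``alpha_threshold`` are flagged
    active.
    """
    null_la = np.asarray(null_elements["log_alpha"], dtype=float)
    if null_la.size < MIN_NULL_ELEMENTS:
        raise ValueError(
            f"need >= {MIN_NULL_ELEMENTS} null elements, got {null_la.size}"
        )
    center = float(np.median(null_la))
    scale = float(stats.median_abs_deviation(null_la, scale="normal"))
    if scale == 0:
        raise ValueError(
            "MAD of null log-activities is zero; provide more varied negative controls"
        )
    out = elements.copy()
    z = (np.asarray(out["log_alpha"], dtype=float) - center) / scale
    out["mad_score"] = z
    if two_sided:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = stats.norm.sf(z)
    p = np.maximum(p, PVAL_FLOOR)
    out["pval_mad"] = p
    out["adj_p"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    out["active"] = out["pval_mad"] <= alpha_threshold
    return out


def combine_strands(
    results: pd.DataFrame,
    null_elements: pd.DataFrame | None = None,
    alpha_threshold: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Collapse per-(window, strand) activity results to one row per window.

    ``results`` needs columns window, strand, log_alpha, n_barcodes.  For
    windows observed on both strands the combined log_alpha is the mean of
    the strand values and barcodes are pooled; single-strand windows pass
    through with ``strands="single"``.  When ``null_elements`` is given,
    significance is recomputed on the combined log_alpha.
    """
    required = {"window", "strand", "log_alpha", "n_barcodes"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for window, grp in results.groupby("window", sort=True):
        rows.append(
            {
                "element_id": window,
                "window": window,
                "log_alpha": float(grp["log_alpha"].mean()),
                "alpha": float(np.exp(grp["log_alpha"].mean())),
                "n_barcodes": int(grp["n_barcodes"].sum()),
                "strands": "both" if len(grp) > 1 else "single",
            }
        )
    combined = pd.DataFrame(rows)
    if null_elements is not None and len(combined):
        combined = mad_test(
            combined, null_elements, alpha_threshold=alpha_threshold, two_sided=two_sided
        )
    return combined
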