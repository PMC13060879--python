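"""Per-variant regulatory effect estimation and classification.

A variant's effect is the log fold change of alternate-allele activity over
its matched reference oligo: per replicate r, d_r = log_alpha(alt, r) -
log_alpha(ref, r); logFC is the mean of d_r with a one-sample two-sided t
test (or a seeded sign-flip permutation test).  P values are
Benjamini-Hochberg adjusted separately for SNVs and indels, since the two
are analyzed as separate families.  A variant is a gain when adj_p <= 0.05
and logFC > 0.1, a loss when adj_p <= 0.05 and logFC < -0.1, else ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_core import GenomicInterval, reverse_complement

__all__ = [
    "PWM",
    "variant_logfc",
    "call_effects",
    "classify_sharing",
    "window_summary",
    "motif_delta",
    "score_agreement",
]

LFC_CUTOFF = 0.1
ALPHA = 0.05


def variant_logfc(
    ref_rep_log_alpha: Sequence[float],
    alt_rep_log_alpha: Sequence[float],
    test: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Estimate a single variant's logFC and raw p value.

    Inputs are matched per-replicate log activities for the reference and
    alternate oligos (natural-log scale; convert downstream for log2
    reporting).  ``test="t"`` runs a one-sample two-sided t test on the
    replicate differences; ``test="permutation"`` a seeded sign-flip
    permutation test, exact for small replicate counts.
    """
    ref = np.asarray(ref_rep_log_alpha, dtype=float)
    alt = np.asarray(alt_rep_log_alpha, dtype=float)
    if ref.shape != alt.shape or ref.size < 2:
        raise ValueError("need >= 2 matched replicates for ref and alt")
    d = alt - ref
    logfc = float(np.mean(d))
    se = float(np.std(d, ddof=1) / np.sqrt(d.size))
    if test == "t":
        if np.allclose(d, d[0]):
            # zero-variance differences: degenerate t; p decided by the shift
            p = 1.0 if np.isclose(d[0], 0.0) else 0.0
        else:
            p = float(stats.ttest_1samp(d, 0.0).pvalue)
    elif test == "permutation":
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, d.size))
        null = np.abs((signs * np.abs(d)).mean(axis=1))
        p = float((np.sum(null >= abs(logfc)) + 1) / (n_permutations + 1))
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"logFC": logfc, "se": se, "p": p}


def call_effects(
    effects: pd.DataFrame,
    lfc_cutoff: float = LFC_CUTOFF,
    alpha: float = ALPHA,
    by_class: bool = True,
    log_base: str = "e",
) -> pd.DataFrame:
    """BH-adjust raw variant p values and call gain/loss/ns per variant.

    ``effects`` needs columns variant_key, var_class (``SNV``/``InDel``),
    logFC, p.  Adjustment runs separately per var_class (SNVs and indels
    are distinct test families).  Calls use strict inequalities on the
    effect size: gain iff adj_p <= alpha and logFC > lfc_cutoff, loss iff
    adj_p <= alpha and logFC < -lfc_cutoff.  ``log_base="2"`` rescales the
    reported logFC column to log2 (thresholds apply on the reported scale).
    """
    out = effects.copy()
    if log_base == "2":
        out["logFC"] = out["logFC"] / np.log(2)
        if "se" in out.columns:
            out["se"] = out["se"] / np.log(2)
    elif log_base != "e":
        raise ValueError("log_base must be 'e' or '2'")
    out["adj_p"] = np.nan
    groups = out.groupby("var_class").groups if by_class else {"all": out.index}
    for _, idx in groups.items():
        p = out.loc[idx, "p"].to_numpy(dtype=float)
        if len(p):
            out.loc[idx, "adj_p"] = multipletests(p, method="fdr_bh")[1]
    call = np.where(
        (out["adj_p"] <= alpha) & (out["logFC"] > lfc_cutoff),
        "gain",
        np.where((out["adj_p"] <= alpha) & (out["logFC"] < -lfc_cutoff), "loss", "ns"),
    )
    out["call"] = call
    return out


def classify_sharing(call_a: str, call_b: str, labels: tuple[str, str] = ("A", "B")) -> str:
    """Sharing class of one variant across two cell types.

    shared: called (gain or loss) in both with the same direction;
    discordant: called in both with opposite directions; ``<label>_only``:
    called in exactly one; none: called in neither.
    """
    for c in (call_a, call_b):
        if c not in ("gain", "loss", "ns"):
            raise ValueError(f"unknown call {c!r}")
    a_called = call_a != "ns"
    b_called = call_b != "ns"
    if a_called and b_called:
        return "shared" if call_a == call_b else "discordant"
    if a_called:
        return f"{labels[0]}_only"
    if b_called:
        return f"{labels[1]}_only"
    return "none"


def window_summary(effects: pd.DataFrame, window: GenomicInterval) -> dict:
    """Count called variant effects whose focal position falls in a window.

    ``effects`` needs columns chrom, focal_pos, call.  Membership is by
    1-based inclusive coordinates.  Returns gain/loss/total_called/
    total_tested counts and the called fraction inside the window.
    """
    inside = effects[
        (effects["chrom"] == window.chrom)
        & (effects["focal_pos"] >= window.start)
        & (effects["focal_pos"] <= window.end)
    ]
    gain = int((inside["call"] == "gain").sum())
    loss = int((inside["call"] == "loss").sum())
    total_called = gain + loss
    total_tested = int(len(inside))
    return {
        "gain": gain,
        "loss": loss,
        "total_called": total_called,
        "total_tested": total_tested,
        "fraction_called": total_called / total_tested if total_tested else 0.0,
    }


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A/C/G/T columns."""

    name: str
    matrix: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.matrix) < 4:
            raise ValueError("PWM must have length >= 4")
        for col in self.matrix:
            if abs(sum(col) - 1.0) > 1e-9:
                raise ValueError(f"PWM column does not sum to 1: {col}")

    def __len__(self) -> int:
        return len(self.matrix)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _best_hit(log_odds: np.ndarray, seq: str) -> float:
    """Best log-odds score over all offsets and both strands."""
    L = log_odds.shape[0]
    best = -np.inf
    for s in (seq, reverse_complement(seq)):
        idx = np.array([_BASE_IDX.get(b, -1) for b in s])
        for off in range(len(s) - L + 1):
            window = idx[off : off + L]
            if (window < 0).any():  # N bases cannot be scored
                continue
            best = max(best, float(log_odds[np.arange(L), window].sum()))
    if not np.isfinite(best):
        raise ValueError("sequence shorter than motif or unscorable")
    return best


def motif_delta(
    pwm: PWM,
    ref_seq: str,
    alt_seq: str,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudo: float = 1e-4,
) -> float:
    """Best-hit log-odds difference of a motif between alt and ref sequences.

    Scores each sequence by the maximum PWM log-odds over all offsets and
    both strands; returns score(alt) - score(ref).  Negative values mean the
    alternate allele disrupts the motif's best binding site.
    """
    bg = np.asarray(background, dtype=float)
    mat = np.asarray(pwm.matrix, dtype=float)
    log_odds = np.log2((mat + pseudo) / (bg + pseudo))
    return _best_hit(log_odds, alt_seq.upper()) - _best_hit(log_odds, ref_seq.upper())


def score_agreement(
    effects: pd.DataFrame,
    external_scores: pd.DataFrame,
    score_col: str = "score",
) -> dict:
    """Agreement between measured variant effects and an external score table.

    Joins on variant_key, reports Spearman's rho with average ranks for
    ties (t-approximation p value), the fraction of called effects whose
    logFC sign matches the external score's sign, and any unmatched keys.
    """
    merged = effects.merge(
        external_scores[["variant_key", score_col]], on="variant_key", how="inner"
    )
    unmatched = sorted(set(effects["variant_key"]) - set(merged["variant_key"]))
    if len(merged) < 3:
        raise ValueError("need >= 3 matched variants for a rank correlation")
    rho, p = stats.spearmanr(merged["logFC"], merged[score_col])
    called = merged[merged["call"] != "ns"] if "call" in merged.columns else merged
    if len(called):
        conc = float(
            np.mean(np.sign(called["logFC"]) == np.sign(called[score_col]))
        )
    else:
        conc = float("nan")
    return {
        "rho": float(rho),
        "approx_p": float(p),
        "sign_concordance": conc,
        "n_matched": int(len(merged)),
        "unmatched_keys": unmatched,
    }
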