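"""Synthetic inputs for every pipeline stage: toy genomes, variant tables,
barcode dictionaries and DNA/RNA count tables from a declared noise model
over a known activity landscape.

The generative model for counts:

* each element receives ``Poisson(lambda_bc)`` barcodes, truncated to >= 1;
* each barcode has a log-normal plasmid abundance (sigma ``sigma_d``)
  shared across replicates, normalized to a sampling probability;
* per replicate, DNA counts are Poisson(depth x abundance);
* RNA counts are negative binomial (gamma-Poisson) with mean proportional
  to abundance x exp(activity) at the element, renormalized so each RNA
  library has the same expected depth, and dispersion ``phi``
  (variance = m + phi m^2);
* per-replicate depth factors are log-normal with a small sigma.

Truth tables are first-class outputs: every planted activity and variant
effect is recorded so recovery can be scored without reading generator
internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval, SequenceRecord

__all__ = [
    "ActivityLandscape",
    "NoiseModel",
    "make_toy_genome",
    "make_variant_table",
    "simulate_counts",
]

BASES = np.array(list("ACGT"))


@dataclass
class ActivityLandscape:
    """Ground-truth log-activity per element, with planted effects recorded.

    ``baseline`` is the log-activity of inert sequence; ``enhancers`` maps
    planted intervals to added log-activity; ``variant_lfc`` maps a variant
    key to the log fold change its alternate allele adds over its reference
    oligo.  ``cell_types`` allows per-cell-type overrides of either map.
    """

    baseline: float = 0.0
    enhancers: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    variant_lfc: dict[str, float] = field(default_factory=dict)
    cell_types: dict[str, "ActivityLandscape"] = field(default_factory=dict)

    def element_activity(
        self,
        anchor: GenomicInterval | None,
        allele_class: str,
        variant_key: str | None,
    ) -> float:
        """Log-activity of an element under this landscape.

        Scrambled/negative controls sit at baseline regardless of anchor.
        Reference-class elements gain each planted enhancer effect their
        anchor overlaps; alternate alleles additionally gain the planted
        variant logFC.
        """
        act = self.baseline
        if allele_class in ("scramble", "negative"):
            return act
        if anchor is not None:
            for iv, effect in self.enhancers:
                if anchor.overlaps(iv):
                    act += effect
        if variant_key is not None and allele_class not in ("ref",):
            act += self.variant_lfc.get(variant_key, 0.0)
        return act


@dataclass
class NoiseModel:
    """Parameters of the barcode-count generative model."""

    sigma_d: float = 0.5  # log-normal sd of per-barcode plasmid abundance
    phi: float = 0.1  # RNA negative-binomial dispersion (var = m + phi m^2)
    lambda_bc: float = 10.0  # mean barcodes per element (truncated Poisson, min 1)
    depth: float = 1e6  # expected library depth per fraction and replicate
    depth_sigma: float = 0.1  # log-normal sd of per-replicate depth factors

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.phi <= 0 or self.lambda_bc <= 0:
            raise ValueError("sigma_d, phi and lambda_bc must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def make_toy_genome(
    length: int,
    gc: float = 0.41,
    seed: int = 0,
    contig: str = "chrT",
) -> SequenceRecord:
    """A deterministic random genome with the requested GC fraction.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2, so the realized GC
    converges to the request (within ~2% for >= 10 kb).
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=length, p=probs))
    return SequenceRecord(id=contig, seq=seq)


def make_variant_table(
    region: GenomicInterval,
    genome: Mapping[str, str],
    n_snv: int,
    n_indel: int,
    max_indel: int = 10,
    af_beta: tuple[float, float] = (0.2, 2.0),
    n_filter_violators: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic known-variant table (chrom, pos, ref, alt, AC, AF).

    Positions are uniform over the region; indel sizes uniform on
    1..max_indel (left-anchored VCF convention); allele frequencies are
    Beta-distributed.  ``n_filter_violators`` appends records engineered to
    fail the design filters (allele count 0, indel over ``max_indel``).
    """
    rng = np.random.default_rng(seed)
    contig = str(genome[region.chrom])
    rows = []

    def af_ac():
        af = float(rng.beta(*af_beta))
        ac = max(1, int(round(af * 2000)))
        return af, ac

    pos_pool = rng.integers(region.start, region.end + 1, size=n_snv)
    for pos in pos_pool:
        ref = contig[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        af, ac = af_ac()
        rows.append(dict(chrom=region.chrom, pos=int(pos), ref=ref, alt=alt, AC=ac, AF=af))

    for _ in range(n_indel):
        size = int(rng.integers(1, max_indel + 1))
        pos = int(rng.integers(region.start, region.end - size))
        anchor = contig[pos - 1]
        if rng.random() < 0.5:  # deletion
            ref = contig[pos - 1 : pos + size]
            alt = anchor
        else:  # insertion
            ref = anchor
            alt = anchor + "".join(rng.choice(BASES, size=size))
        af, ac = af_ac()
        rows.append(dict(chrom=region.chrom, pos=pos, ref=ref, alt=alt, AC=ac, AF=af))

    for i in range(n_filter_violators):
        pos = int(rng.integers(region.start, region.end - 20))
        if i % 2 == 0:  # allele count zero
            ref = contig[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append(dict(chrom=region.chrom, pos=pos, ref=ref, alt=alt, AC=0, AF=0.0))
        else:  # indel over the size cap
            size = max_indel + 1 + int(rng.integers(0, 5))
            ref = contig[pos - 1 : pos + size]
            rows.append(
                dict(chrom=region.chrom, pos=pos, ref=ref, alt=ref[0], AC=5, AF=0.001)
            )
    return pd.DataFrame(rows)


def write_variant_vcf(table: pd.DataFrame, path, contig_lengths: Mapping[str, int]) -> None:
    """Write a variant table as minimal VCF with AC/AF INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"AC={row.AC};AF={row.AF:.6g}\n"
            )


def simulate_counts(
    manifest: pd.DataFrame,
    landscape: ActivityLandscape,
    noise: NoiseModel,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a barcode-level DNA/RNA count table for a designed library.

    ``manifest`` is a design manifest (oligo_id, allele_class, chrom, start,
    end, focal_pos, variant_key, length).  Returns (counts, truth):
    counts has one row per barcode with element_id and DNA_/RNA_ columns per
    replicate; truth has one row per element with its planted log-activity.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    elements = []
    for row in manifest.itertuples(index=False):
        anchor = None
        if not pd.isna(row.start):
            anchor = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        variant_key = None if pd.isna(row.variant_key) else str(row.variant_key)
        act = landscape.element_activity(anchor, str(row.allele_class), variant_key)
        elements.append((str(row.oligo_id), str(row.allele_class), variant_key, act))

    truth = pd.DataFrame(
        elements, columns=["element_id", "allele_class", "variant_key", "true_log_activity"]
    )

    n_bc = np.maximum(1, rng.poisson(noise.lambda_bc, size=len(elements)))
    total_bc = int(n_bc.sum())
    abundance = rng.lognormal(mean=0.0, sigma=noise.sigma_d, size=total_bc)
    element_idx = np.repeat(np.arange(len(elements)), n_bc)
    activity = np.array([e[3] for e in elements])[element_idx]

    # DNA sampling probabilities; RNA probabilities tilted by activity
    p_dna = abundance / abundance.sum()
    rna_weight = abundance * np.exp(activity)
    p_rna = rna_weight / rna_weight.sum()

    counts = pd.DataFrame(
        {
            "barcode": _random_barcodes(rng, total_bc),
            "element_id": [elements[i][0] for i in element_idx],
        }
    )
    for r in range(1, n_replicates + 1):
        depth_d = noise.depth * rng.lognormal(0.0, noise.depth_sigma)
        depth_r = noise.depth * rng.lognormal(0.0, noise.depth_sigma)
        dna = rng.poisson(depth_d * p_dna)
        m = depth_r * p_rna
        # gamma-Poisson mixture => negative binomial with dispersion phi
        rate = rng.gamma(shape=1.0 / noise.phi, scale=m * noise.phi)
        rna = rng.poisson(rate)
        counts[f"DNA_r{r}"] = dna
        counts[f"RNA_r{r}"] = rna
    return counts, truth


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 15) -> list[str]:
    """Distinct random barcodes of the standard association length."""
    out: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            out.add("".join(BASES[row]))
            if len(out) == n:
                break
    return sorted(out)
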