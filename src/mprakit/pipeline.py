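"""End-to-end orchestration: a validated run configuration and a pipeline
that chains simulation, design, association, quantification, CRE calling
and variant-effect classification into one run directory.

All randomness flows from the single top-level seed; stage seeds are spawned
from it so stages stay independently reproducible.  The summary report is
recomputed from the stage output tables, never cached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity_quant, barcode_assoc, cre_calling, library_design, synthetic_data, variant_effects
from .genomic_core import GenomicInterval, write_fasta
from .library_design import design_manifest

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

PRESETS = ("tiling", "promoter-satmut", "variants")


@dataclass
class RunConfig:
    """All stage parameters of a synthetic end-to-end run, in one document."""

    preset: str = "tiling"
    seed: int = 0
    out_dir: str = "mprakit_run"
    # synthetic genome
    genome_length: int = 30_000
    gc: float = 0.41
    # design
    tile_len: int = 270
    step: int = 90
    oligo_len: int = 219
    del_len: int = 5
    region_length: int = 10_000
    n_scrambles: int = 100
    n_snv: int = 150
    n_indel: int = 30
    max_indel: int = 10
    af_duplicate_threshold: float = 1.0
    # simulation
    n_replicates: int = 3
    sigma_d: float = 0.5
    phi: float = 0.1
    lambda_bc: float = 10.0
    depth: float = 1e6
    n_enhancers: int = 5
    enhancer_effect: float = 2.0
    variant_effect: float = 0.5
    variant_effect_fraction: float = 0.2
    # inference
    pseudocount: float = 1.0
    min_barcodes: int = 1
    alpha_threshold: float = 0.05
    lfc_cutoff: float = 0.1
    adjacency_gap: int = 0
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}, got {self.preset!r}")
        if self.lfc_cutoff <= 0:
            raise ValueError("lfc_cutoff must be positive (sign is applied internally)")
        if not 0 < self.alpha_threshold < 1:
            raise ValueError("alpha_threshold must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for variant testing")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> design -> quantify -> call-cres -> effects end to end.

    Writes stage outputs (FASTA, manifest TSV, counts TSV, activity TSV, CRE
    TSV, effects TSV), the resolved config, and a JSON summary report into
    ``config.out_dir``.  Returns the report as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    # --- synthetic genome and target region ------------------------------
    genome_rec = synthetic_data.make_toy_genome(
        config.genome_length, gc=config.gc, seed=seeds[0]
    )
    genome = {genome_rec.id: genome_rec.seq}
    write_fasta([genome_rec], out / "genome.fa")
    pad = (config.oligo_len - 1) // 2 + config.tile_len
    region_len = min(config.region_length, config.genome_length - 2 * pad)
    region = GenomicInterval(genome_rec.id, pad + 1, pad + region_len)

    # --- design ----------------------------------------------------------
    rng = np.random.default_rng(seeds[1])
    landscape_n = synthetic_data.ActivityLandscape()
    landscape_h = synthetic_data.ActivityLandscape()
    if config.preset == "tiling":
        oligos = library_design.design_tiles(
            region, genome, tile_len=config.tile_len, step=config.step
        )
        starts = rng.choice(
            np.arange(region.start, region.end - 500), size=config.n_enhancers, replace=False
        )
        for i, s in enumerate(sorted(starts)):
            iv = GenomicInterval(region.chrom, int(s), int(s) + 299)
            landscape_n.enhancers.append((iv, config.enhancer_effect))
            if i % 2 == 0:  # shared with the second cell type
                landscape_h.enhancers.append((iv, config.enhancer_effect))
    elif config.preset == "promoter-satmut":
        sat_region = GenomicInterval(
            region.chrom, region.start, region.start + min(400, region_len) - 1
        )
        oligos = library_design.design_saturation(
            sat_region, genome, oligo_len=config.oligo_len, del_len=config.del_len
        )
        n_eff = max(1, int(config.variant_effect_fraction * sat_region.length()))
        keys = [o.variant_key for o in oligos if o.variant_key and o.allele_class == "snv_alt"]
        chosen = rng.choice(len(keys), size=min(n_eff, len(keys)), replace=False)
        for j in chosen:
            eff = config.variant_effect * (1 if rng.random() < 0.5 else -1)
            landscape_n.variant_lfc[keys[int(j)]] = eff
            if rng.random() < 0.5:
                landscape_h.variant_lfc[keys[int(j)]] = eff
    else:  # variants
        table = synthetic_data.make_variant_table(
            region,
            genome,
            n_snv=config.n_snv,
            n_indel=config.n_indel,
            max_indel=config.max_indel,
            n_filter_violators=4,
            seed=seeds[2],
        )
        table.to_csv(out / "variants.tsv", sep="\t", index=False)
        specs = [
            library_design.VariantSpec(
                chrom=r.chrom, pos=int(r.pos), ref_allele=r.ref, alt_allele=r.alt,
                allele_count=int(r.AC), allele_frequency=float(r.AF),
            )
            for r in table.itertuples(index=False)
        ]
        design = library_design.design_variant_oligos(
            specs, genome, base_len=config.oligo_len, max_indel=config.max_indel
        )
        pd.DataFrame(
            [(v.key, reason) for v, reason in design.rejected],
            columns=["variant_key", "reason"],
        ).to_csv(out / "rejected_variants.tsv", sep="\t", index=False)
        oligos = library_design.replicate_rule(
            design, specs, frequency_threshold=config.af_duplicate_threshold
        )
        keys = sorted({o.variant_key for o in oligos if o.variant_key})
        n_eff = max(1, int(config.variant_effect_fraction * len(keys)))
        for j in rng.choice(len(keys), size=n_eff, replace=False):
            eff = config.variant_effect * (1 if rng.random() < 0.5 else -1)
            landscape_n.variant_lfc[keys[int(j)]] = eff
            if rng.random() < 0.5:
                landscape_h.variant_lfc[keys[int(j)]] = eff

    scramble_sources = [o for o in oligos if o.allele_class == "ref"] or list(oligos)
    scrambles = library_design.make_scrambles(
        scramble_sources,
        n=min(config.n_scrambles, len(scramble_sources)),
        rng_seed=seeds[3],
    )
    all_oligos = list(oligos) + scrambles
    manifest = design_manifest(all_oligos)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    from .genomic_core import SequenceRecord

    write_fasta([SequenceRecord(o.oligo_id, o.seq) for o in all_oligos], out / "design.fa")

    # --- simulate counts and quantify per cell type ----------------------
    noise = synthetic_data.NoiseModel(
        sigma_d=config.sigma_d, phi=config.phi,
        lambda_bc=config.lambda_bc, depth=config.depth,
    )
    results = {}
    truth_tables = {}
    for cell, landscape, cseed in (
        ("neuron", landscape_n, seeds[4]),
        ("hek", landscape_h, seeds[5]),
    ):
        counts, truth = synthetic_data.simulate_counts(
            manifest, landscape, noise, n_replicates=config.n_replicates, seed=cseed
        )
        counts.to_csv(out / f"counts_{cell}.tsv", sep="\t", index=False)
        truth.to_csv(out / f"truth_{cell}.tsv", sep="\t", index=False)
        truth_tables[cell] = truth
        norm = activity_quant.normalize_counts(counts)
        activity = activity_quant.element_activity(
            norm, pseudocount=config.pseudocount, min_barcodes=config.min_barcodes
        )
        activity = activity.merge(
            manifest[["oligo_id", "allele_class", "chrom", "start", "end", "focal_pos", "variant_key"]],
            left_on="element_id", right_on="oligo_id", how="left",
        ).drop(columns=["oligo_id"])
        nulls = activity[activity["allele_class"] == "scramble"]
        tested = activity[activity["allele_class"] != "scramble"]
        scored = activity_quant.mad_test(
            tested, nulls, alpha_threshold=config.alpha_threshold
        )
        scored.to_csv(out / f"activity_{cell}.tsv", sep="\t", index=False)
        results[cell] = scored

    # --- CRE calling ------------------------------------------------------
    cre_frames = {}
    for cell, scored in results.items():
        sig = scored[scored["active"] & scored["start"].notna()]
        elements = [
            (
                GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                {"element_id": r.element_id, "log_alpha": r.log_alpha, "pval_mad": r.pval_mad},
            )
            for r in sig.itertuples(index=False)
        ]
        cres = cre_calling.call_cres(elements, adjacency_gap=config.adjacency_gap, cell_type=cell)
        frame = cre_calling.cres_to_frame(cres)
        frame.to_csv(out / f"cres_{cell}.tsv", sep="\t", index=False)
        cre_frames[cell] = frame
    sharing_elements = cre_calling.compare_cell_types(
        results["neuron"], results["hek"],
        threshold=config.alpha_threshold, labels=("neuron", "hek"),
    )
    sharing_elements.to_csv(out / "element_sharing.tsv", sep="\t", index=False)

    # --- variant effects --------------------------------------------------
    effects_by_cell = {}
    if config.preset in ("promoter-satmut", "variants"):
        for cell, scored in results.items():
            effects_by_cell[cell] = _variant_effect_table(scored, config)
        eff_n, eff_h = effects_by_cell["neuron"], effects_by_cell["hek"]
        merged = eff_n.merge(
            eff_h, on=["variant_key", "var_class"], suffixes=("_neuron", "_hek")
        )
        merged["sharing"] = [
            variant_effects.classify_sharing(a, b, labels=("neuron", "hek"))
            for a, b in zip(merged["call_neuron"], merged["call_hek"])
        ]
        merged.to_csv(out / "effects.tsv", sep="\t", index=False)
    else:
        merged = pd.DataFrame()

    # --- report -----------------------------------------------------------
    report = {
        "preset": config.preset,
        "seed": config.seed,
        "n_oligos": int(len(manifest)),
        "n_scrambles": int((manifest["allele_class"] == "scramble").sum()),
        "active_elements": {
            cell: int(df["active"].sum()) for cell, df in results.items()
        },
        "n_cres": {cell: int(len(df)) for cell, df in cre_frames.items()},
        "element_sharing": sharing_elements["sharing"].value_counts().to_dict(),
    }
    if len(merged):
        report["variant_calls"] = {
            cell: df["call"].value_counts().to_dict() for cell, df in effects_by_cell.items()
        }
        report["variant_sharing"] = merged["sharing"].value_counts().to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _variant_effect_table(scored: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-variant logFC table from per-oligo activity results.

    Pairs each alternate-allele oligo with the reference oligo sharing its
    variant_key (saturation) or its ``var:`` id stem (known variants), then
    runs the replicate-level t test and per-class BH adjustment.
    """
    alpha_cols = [c for c in scored.columns if c.startswith("alpha_r")]
    rows = []
    df = scored.set_index("element_id")
    # reference lookup: for saturation oligos the ref shares the id prefix
    ref_by_prefix: dict[str, pd.Series] = {}
    for eid, row in df.iterrows():
        if row["allele_class"] == "ref":
            ref_by_prefix[_pair_stem(eid)] = row
    for eid, row in df.iterrows():
        if row["allele_class"] not in ("snv_alt", "deletion", "insertion", "del5"):
            continue
        ref_row = ref_by_prefix.get(_pair_stem(eid))
        if ref_row is None:
            logger.warning("no reference partner for %s; marked untestable", eid)
            continue
        res = variant_effects.variant_logfc(
            np.log(ref_row[alpha_cols].to_numpy(dtype=float)),
            np.log(row[alpha_cols].to_numpy(dtype=float)),
        )
        key = eid if pd.isna(row["variant_key"]) else str(row["variant_key"])
        rows.append(
            {
                "variant_key": key,
                "var_class": "SNV" if row["allele_class"] == "snv_alt" else "InDel",
                "chrom": row["chrom"],
                "focal_pos": row["focal_pos"],
                **res,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["variant_key", "var_class", "chrom", "focal_pos", "logFC", "se", "p", "adj_p", "call"]
        )
    table = pd.DataFrame(rows).drop_duplicates(subset="variant_key", keep="first")
    return variant_effects.call_effects(
        table, lfc_cutoff=config.lfc_cutoff, alpha=config.alpha_threshold,
        log_base=config.log_base,
    )


def _pair_stem(element_id: str) -> str:
    """Shared stem of a ref/alt oligo pair's ids.

    ``sat:chrT:205:A:ref`` and ``sat:chrT:205:A:G`` share ``sat:chrT:205:A``;
    ``var:<key>:ref:copy1`` and ``var:<key>:alt:copy1`` share ``var:<key>``.
    """
    parts = element_id.split(":")
    if parts[0] == "sat":
        return ":".join(parts[:4])
    if parts[0] == "var":
        return ":".join(p for p in parts if not (p in ("ref", "alt") or p.startswith("copy")))
    return element_id
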