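# mprakit

A design-and-analysis toolkit for massively parallel reporter assays
(MPRAs) used to map cis-regulatory elements (CREs) and regulatory variant
effects across a genomic locus. It covers the full computational path of a
tiling / saturation-mutagenesis reporter screen:

1. **Oligo library design** — strand-tiled oligos (270 bp every 90 bp on
   both strands, 6x interior coverage), per-base saturation mutagenesis
   (219 bp oligos centered on every base, all three alternate bases plus a
   centered 5 bp deletion), centered ref/alt pairs for known SNVs and small
   indels with the odd/even parity rule (219 bp reference windows for odd
   deletions, 218 bp for even ones), and GC-matched scrambled negative
   controls.
2. **Barcode association** — barcode → element dictionaries from
   association sequencing: 100 bp locus bins with midpoint assignment for
   sheared-fragment libraries, exact full-length CIGAR matching (`219M`,
   `218M`, ...) for designed-oligo libraries, and absolute removal of
   barcodes observed for more than one element.
3. **Activity quantification** — per-element RNA/DNA activity ratios
   (ratio of CPM-normalized sums over barcodes, geometric mean over
   replicates) tested against scrambled controls with a robust MAD
   z-score:

   ```
   mad.score = (log α − median(log α_null)) / (1.4826 · MAD(log α_null))
   pval.mad  = upper-tail N(0,1) probability, floored at 2.2e-16
   ```

   with Benjamini–Hochberg adjustment; elements with pval.mad ≤ 0.05 are
   called active.
4. **CRE calling** — overlapping or consecutive significant bins/oligos
   merged into single CREs, cross-cell-type sharing classes, and
   annotation against ENCODE-style cCRE classes (PLS, pELS, dELS, CA-*,
   TF) with a promoter-first precedence.
5. **Variant effects** — per-variant logFC = mean over replicates of
   log α(alt) − log α(ref), replicate-level t test (or seeded sign-flip
   permutation), BH per variant class (SNVs and indels separately), and
   the gain/loss call rule adj_p ≤ 0.05 with |logFC| > 0.1; sharing across
   cell types requires calls of the same direction in both. Utilities for
   genomic-window summaries, PWM motif-disruption deltas, and rank
   agreement with external per-variant scores (e.g. sequence-model
   predictions) round out the analysis surface.
6. **Synthetic data** — every pipeline input can be generated from a
   declared noise model (log-normal barcode abundance, Poisson DNA counts,
   negative-binomial RNA counts) over a known activity landscape, with
   ground-truth tables as first-class outputs.

## Worked example

Run the fully synthetic tiling screen end to end (two simulated cell
types, planted enhancers, scrambled-control null):

```sh
mprakit run --preset tiling --seed 7 --out demo
```

which prints the run report:

```json
{
  "active_elements": {"hek": 43, "neuron": 65},
  "element_sharing": {"hek_only": 7, "neither": 146, "neuron_only": 29, "shared": 36},
  "n_cres": {"hek": 8, "neuron": 7},
  "n_oligos": 318,
  "n_scrambles": 100,
  "preset": "tiling",
  "seed": 7
}
```

318 oligos were designed (270 bp tiles on both strands of a 10 kb region
plus 100 scrambles); 65 tiles were significantly active in the simulated
neuron-like cell type at pval.mad ≤ 0.05 and merged into 7 CREs, against
planted enhancers shared or specific per cell type — hence the mix of
`shared`, `neuron_only` and `hek_only` elements. All stage outputs
(design FASTA/manifest, counts, per-element activity with mad.score and
adjusted p, CRE table, sharing table, ground truth) land in `demo/`
alongside the resolved configuration. `--preset promoter-satmut` and
`--preset variants` run the saturation-mutagenesis and known-variant
versions, adding a per-variant effects table with gain/loss calls and
cell-type sharing.

Each stage is also available as a library function
(`mprakit.library_design.design_tiles`, `mprakit.activity_quant.mad_test`,
...) and as an individual subcommand (`mprakit design tiles`,
`mprakit associate`, `mprakit quantify`, `mprakit call-cres`).

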