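# Methods

## Coordinates and formats

All internal coordinates are 1-based and inclusive on both ends; BED I/O
converts to 0-based half-open at the file boundary only. This matches how
genomic spans are printed (`chr17:45,893,536-45,895,535` is a 2,000 bp
region under inclusive arithmetic) and keeps every designer's centering
rule expressible without off-by-one adjustments. Both width conventions
are exposed on intervals (`length()` inclusive, `exclusive_width()`
end − start) because prose descriptions of short windows often use the
exclusive width; neither is asserted as canonical.

Genomes are read through `pyfaidx` (or any mapping contig → sequence for
in-memory use); alignments through `pysam`; tables through pandas TSV.

## Library design rules

**Tiling.** Fixed-length oligos (default 270 bp) at a fixed step
(default 90 bp), one per strand per window, starting at the region start
and advancing while the window fits. Interior per-base coverage is
2·tile_len/step = 6 at the defaults. Windows containing N are skipped
with a logged warning — alternate-base enumeration and activity
attribution are undefined over N.

**Saturation mutagenesis.** For every base p of the target region: one
reference oligo on the window p ± (oligo_len−1)/2 (oligo_len must be odd),
three single-substitution oligos at the center, and one oligo with the
del_len bases centered on p removed (del_len odd; focal ± (del_len−1)/2).
"Centered" means equal flanks — the only symmetric choice. Positions
whose window would leave the contig are skipped, never shifted: shifting
would silently break the centering invariant that downstream pairing
relies on.

**Known variants.** SNVs get ref/alt pairs of the fixed odd base length
(default 219 bp) with the variant base centered. Deletions of k bases use
a reference window of 219 bp (k odd) or 218 bp (k even) so the deleted
span has equal flanks; the alternate oligo is the reference minus the
span. Insertions mirror the rule on the alternate sequence: the alternate
is 219 bp for odd k and 218 bp for even k with the insert centered, and
the reference is that length minus k. For even-length windows the extra
flank base falls 3′. Indels are normalized by stripping the shared
left-anchor prefix before windowing. Filters: indels over 10 bp
(`indel_gt_10`) and variants with allele count 0 (`ac_zero`) are rejected
with machine-readable reasons. Variants at or above a configurable
frequency threshold (default 1.0 on the table's frequency scale — the
threshold is configurable because frequency scales differ between
sources) are represented twice, with distinct `:copyN` oligo ids so joins
never rely on row order.

**Scrambles.** Each scramble is a seeded permutation of a source oligo's
bases, so base composition — and therefore GC content — is matched
exactly rather than approximately. At least one scramble is emitted per
distinct test-oligo length, and optionally three center-base-substituted
siblings per scramble.

All designers are pure functions of (genome, parameters, seed); repeated
runs are byte-identical, which the suite asserts.

## Barcode association

Fragment libraries: the locus is divided into non-overlapping 100 bp bins
(shorter terminal bin allowed) and each fragment is assigned to the bin
containing its midpoint. For even-length fragments the midpoint is the
lower of the two central coordinates — a deterministic, strand-free
tie-break. Oligo libraries: a record is kept only when its CIGAR is a
single match run equal to the designed oligo length (`219M`, `218M`,
...). In both modes barcodes observed for more than one element are
removed absolutely — no plurality rescue — and barcodes below a
configurable read support (default 1) are dropped. The filter report's
categories sum to the input record count, and the build is independent of
record order.

## Activity model

Counts are library-normalized to CPM per column. Per replicate r, an
element's activity is a ratio of sums over its barcodes:

    α_r = (Σ_b RNA_norm[b, r] + c) / (Σ_b DNA_norm[b, r] + c)

with pseudocount c = 1 (CPM units). Ratio-of-sums rather than
mean-of-ratios: single low-DNA barcodes cannot dominate, and the
estimator is invariant to splitting an element's material across more
barcodes. The element activity α is the geometric mean of the α_r
(replicates weighted equally), and log α is natural-log.

Significance is a robust z against scrambled controls:

    mad.score = (log α − median(log α_null)) / (1.4826·MAD(log α_null))

(the consistency constant is 1/Φ⁻¹(0.75) as implemented by scipy). The p
value (pval.mad) is the standard-normal upper tail of mad.score, one-sided
toward activation by default (a two-sided flag exists), floored at
2.2×10⁻¹⁶; the parametric tail is what makes p values below 1/n_null
meaningful at all — an empirical percentile could never reach the floor.
Adjustment is Benjamini–Hochberg across all tested elements. At least 20
null elements are required, and a zero null MAD is an error instructing
the caller to provide more varied controls. Forward/reverse oligos over
the same window are combined by averaging strand log α and pooling
barcodes, then re-testing; single-strand windows pass through flagged.

Calibration: on pure-null synthetic data (2,000 tested elements, 2,000
scrambled nulls, default noise), the empirical false-positive rate at
nominal q ∈ {0.01, 0.05, 0.1} sits within binomial 99% bounds — the suite
asserts this, and also that elements planted five robust SD above the
null are all detected.

## CRE calling and annotation

Significant elements (pval.mad ≤ 0.05 upstream) are sorted and merged by
a single left-to-right sweep; elements whose intervals overlap or whose
gap is at most `adjacency_gap` join one CRE. The default gap of 0 merges
abutting 100 bp bins ("consecutive"); 90 bp-step tiles already overlap so
overlap-merging suffices. The sweep is verified against an independent
per-base painting oracle on 1,000 random instances and is idempotent.
cCRE annotation is any-overlap with precedence PLS > pELS > dELS >
CA-H3K4me3 > CA-TF > CA-CTCF > CA > TF — promoter-most class wins; the
order is this package's own tie rule, since class tallies alone do not
determine one.

## Variant effects

Per replicate, d_r = log α(alt, r) − log α(ref, r); logFC = mean(d_r);
p from a one-sample two-sided t test on {d_r}, or a seeded sign-flip
permutation test (note the permutation p has granularity 2/2ⁿ for n
replicates, so with 3 replicates the t test is the usable default). BH
runs separately for SNVs and indels — altering oligo sizes in indels
should not influence the SNV family. Calls: gain iff adj_p ≤ 0.05 and
logFC > 0.1; loss iff adj_p ≤ 0.05 and logFC < −0.1; strict inequalities
at the cutoff. logFC is natural-log by default with a log2 switch
(thresholds apply on the reported scale; the choice is recorded in the
output). Sharing across two cell types: shared = called in both with the
same direction, discordant = called in both with opposite directions,
cell-specific = called in exactly one.

Motif disruption is a simplified PWM screen: the delta between the best
log₂-odds hit (all offsets, both strands, uniform background with a small
pseudoprobability) on the alternate versus the reference sequence;
negative deltas mean disruption. It is invariant to uniform background
shifts and returns exactly 0 for uninformative motifs. Agreement with
external per-variant score tables is Spearman's ρ with average ranks and
a t-approximation p, plus the fraction of called effects whose logFC sign
matches the external score; unmatched keys are reported, never silently
dropped.

With 3 replicates the paired t test has 2 degrees of freedom, so
individually strong effects can fail BH at desk-scale family sizes; the
logFC *estimates* are nonetheless accurate (see calibration below). This
is a deliberate conservatism of the replicate-level test relative to
barcode-level mixed models, which are out of scope.

## Synthetic data generator

The generator emulates a barcoded reporter screen: each element gets
Poisson(λ_bc) barcodes (truncated to ≥ 1); each barcode a log-normal
plasmid abundance (σ_d) shared across replicates (the plasmid pool is
common); DNA counts are Poisson(depth × abundance-probability); RNA
counts are negative binomial via a gamma–Poisson mixture with mean
proportional to abundance × exp(activity), renormalized so each RNA
library has the same expected depth, and dispersion φ (variance
m + φm²); per-replicate depth factors are log-normal (σ = 0.1).

Defaults: σ_d = 0.5, φ = 0.1, λ_bc = 10, depth = 10⁶, 3 replicates.
These produce realistic overdispersion and barcode-count spread for a
desk-scale screen. Planted effects live in an `ActivityLandscape`
(baseline, enhancer intervals with log-unit effects, per-variant logFC
map, optional per-cell-type maps) and are emitted in a ground-truth
table, so recovery is always scored against declared truth rather than
generator internals. Enhancer effects default to +2 log-units (an
unambiguously active element); planted variant effects to ±0.5 log-units
(five times the 0.1 call threshold).

Under these defaults the suite verifies: planted ±0.5 logFC over 200
variants is recovered with sign accuracy ≥ 0.98 and RMSE ≤ 0.15; type-I
error is calibrated as above; all counts and truth tables are
byte-reproducible given (manifest, parameters, seed).

What the generator does **not** emulate: sequencing error and barcode
misassignment, PCR jackpotting beyond the log-normal abundance spread,
position-dependent synthesis error in long oligos, cross-contamination
between fractions, or any cell biology (integration-site effects,
cell-state heterogeneity). Passing tests therefore demonstrate that the
estimators are correct and calibrated under the declared model — not that
the model captures every failure mode of real screens.

## Pipeline and problem sizes

The `run` orchestrator chains simulate → design → quantify → call-cres →
effects from one validated configuration (unknown keys rejected; the
resolved config is written beside the outputs; report numbers are always
recomputed from the stage tables). All randomness descends from the
single top-level seed via spawned seed sequences, keeping stages
independently reproducible.

Test and demonstration runs use desk-scale sizes chosen to exercise every
code path with comfortable margins: 10–30 kb toy genomes, 2–10 kb design
regions, 50–100 scrambled controls per run, 2,000 + 2,000 elements for
the calibration suite, and 200 variants for effect-recovery checks.

## Known limitations

* The replicate-level t test is conservative at 3 replicates (df = 2);
  barcode-level generative models (GLM/mixed-model estimators) are
  deliberately out of scope, with the estimator fully specified here
  instead.
* One-sided testing toward activation is the default; repressive elements
  require the two-sided flag.
* The insertion parity convention (alternate oligo 219 bp for odd
  inserts) is the mirror of the explicit deletion rule; other conventions
  exist and the choice is recorded in output metadata.
* cCRE annotation uses any-overlap with a fixed precedence; fractional
  overlap or reciprocal-overlap criteria are not implemented.
* No liftover, chromosome aliasing, or multi-assembly support.
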