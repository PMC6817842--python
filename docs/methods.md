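# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generators emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and data model

All coordinates are 0-based half-open (BED convention); summits are single
0-based positions; two regions overlap when they share at least one base
pair, so abutting half-open intervals do not overlap. Strand is ignored
for interval arithmetic; gene TSSs are taken strand-aware from the gene
model. Signal tracks are piecewise-constant (bedGraph semantics); for
read-coverage tracks the segment value is reads per base, so the
region-weighted sum is a read count and RPM = reads × 10⁶ / library size,
RPKM = RPM × 1000 / region length. RPM, RP10M and RPKM usage varies by
analysis in this field; the aggregation `mode` parameter selects the
normalization per call rather than imposing one global choice.

### Replicate reconciliation

Biological replicates are reduced to one reproducible peak set by
overlap: each cross-replicate overlapping pair emits the summit ± 100 bp
window of the member with the larger signal (ties keep the first
replicate, deterministically). This is an overlap-based stand-in for
IDR-style reproducibility analysis — it keeps the reproducible events and
the ±100 bp summit representation but does not model the IDR copula.
Peaks with no cross-replicate partner are dropped.

## Co-occupancy calling

Pooled summits are clustered by single-linkage: two summits join when
their positions differ by ≤ d (default 300 bp), and clusters are the
transitive closure, so a chain may span more than d overall. The default
is the distance at which the pooled inter-summit distance histogram
separates into a clustered (< 300 bp) mode and a dispersed mode near the
uniform-background spacing (~10 kb at realistic summit densities).
Same-TF summits within d stay as multiple members of one region; the
membership pattern and n_tf count distinct TF labels only, because
pattern semantics depend on distinct factors. A panel of n TFs is
reported as admitting 2^n patterns (128 for 7, 64 for 6). That count
includes the empty subset even though a bound region carries ≥ 1 TF; the
convention of counting all subsets is kept and noted here. Distances to
genes use the region midpoint and the nearest TSS, with an optional
distal (> 2 kb) filter.

Correctness of the merge is checked against two independent oracles: an
O(n²) union-find in the unit tests and graph connected components
(scipy) in the acceptance suite, with exact set equality over random
instances at d ∈ {0, 50, 300, 1000}.

## Cardiac H3K27ac score (CHS)

Over the merged union of heart/liver/forebrain H3K27ac peak regions,
CHS = (heart + ε) / (max(liver, forebrain) + ε) on RPM signal. The
pseudocount ε = 0.5 RPM is this package's choice: the procedure it
follows does not specify zero-denominator handling, and a small additive
constant stabilizes low-count regions while leaving well-measured
regions essentially unchanged (ε = 0 is available and raises on a zero
denominator). Regions are ranked by CHS with ties broken by genomic
coordinate (reproducible quintile edges), split into five equal-count
bins with remainders assigned to the lower bins, and the top two
quintiles are called cardiac H3K27ac regions (cHRs). Quintile membership
is invariant under any strictly monotone transform of CHS.
Co-binding/CHS association uses per-cell 2×2 Fisher exact tests
(two-sided); zero cells get the Haldane–Anscombe +0.5 correction for the
odds-ratio point estimate only, never for the p-value.

## Motif analysis

PWMs are position probability matrices with a background composition;
scanning computes log₂ odds per window on both strands and calls a hit at
score ≥ threshold. The default threshold is 60% of the PWM's maximum
achievable log-odds — the upstream toolchain this mirrors delegates
thresholding to an external scanner without stating a value, so the
fraction is exposed as a parameter. N-containing windows are skipped.

Composite motifs concatenate two PWMs in the four strand orientations
(++ , +−, −+, −−; '−' reverse-complements that block) with 0–8 uniform
spacer rows: 4 × 9 = 36 arrangements by default. One printed account of
this construction gives 32 composite arrangements without stating which
four are dropped or collapsed; the package keeps the full 36 and makes
the spacer range configurable rather than hard-coding either count.

Arrangement preference is the dispersion of the per-arrangement
enrichment vector (fraction of co-bound sequences with ≥ 1 composite
hit, optionally normalized by a matched background). The statistic is
variance²/mean with sample variance (n−1): this is the printed form of
the source procedure's "Fano factor" and is deliberately kept as the
default even though the standard Fano factor is variance/mean
(`printed_form=False` switches). Note the printed form scales cubically
under multiplication of the enrichment vector by a constant, the standard
form linearly — a unit test pins the implemented behavior. Significance
is assessed against an empirical null of no-preference datasets (both
motifs present, arrangement random), not against an analytic
distribution.

Backgrounds for single-motif enrichment default to per-sequence
dinucleotide shuffles (seeded Eulerian-path shuffle preserving exact
dinucleotide counts), matching the GC/dinucleotide-matched intent of
motif-enrichment backgrounds. Central enrichment compares hit density in
a ±50 bp window at the sequence center against the flanks of
summit-centered ±500 bp sequences, with a one-sided binomial p-value;
zero total hits yields a flagged NaN ratio rather than an error.

## Permutation enrichment

The placement universe is the genome minus low-mappability runs: maximal
runs with mappability < 0.3 are excluded only when longer than 500 bp.
Randomization re-places each region uniformly among valid start positions
(length preserved, wholly inside one allowed interval). Enrichment of a
query set near gene TSS ± d windows counts query regions overlapping ≥ 1
window (region-wise: one region counts once however many windows it
hits); fold = observed / mean over permutations, and
p = (1 + #{perm ≥ obs}) / (1 + n_perm) (add-one rule, one-sided for
enrichment by default; depletion and two-sided via flag). The add-one
estimator never reports p below 1/(1+n_perm) and is conservative under
ties. Query sets above 5,000 regions are split into random 5,000-region
subsets whose results are averaged — fold arithmetically, p on the
−log₁₀ scale.

## Gene association

Genes are annotated with the maximal distinct-TF count among co-bound
regions whose midpoint lies within TSS ± 100 kb (midpoint-based distance
is this package's reading; the source rule does not specify edge vs
midpoint), and H3K27ac is 'present' iff any region tied at that maximum
overlaps a cHR. DEG selection uses strict inequalities exactly as
printed: |log2FC| > 2 and −log₁₀ p > 3, direction by sign of log2FC;
boundary genes are excluded. Expression-by-annotation comparisons use
Wilcoxon rank-sum tests with Holm correction — a nonparametric all-pairs
control standing in for the Steel–Dwass procedure, identical in role.
DEG-proximity enrichment delegates to the permutation module per
(stratum, distance) cell and drops strata with fewer than 100 regions.

## MPRA quantification

Fragments are kept when their template length is between 395 and 405 bp
inclusive (400 bp elements ± 5; a flag switches to exclusive bounds).
Fragments map to the element covering ≥ 50% of their length. DNA
abundance is the mean of per-replicate RPMs; elements below 5 RPM are
excluded. Activity is the mean over RNA samples of the per-sample
RNA-RPM : DNA ratio (per-sample ratios then mean — whether multi-sample
RNA was pooled or averaged upstream is unstated, so the averaging order
is fixed here and disclosed). The activity threshold is the 95th
percentile (linear interpolation between order statistics — documented
because negative-control counts are small) of the ESC negative-control
activities; active means strictly above it, which bounds the
negative-control call rate at 5% + 1/n by construction. Class summaries
report mean, SD, normal-approximation 95% CI and active fraction;
all-pairs comparisons are rank-sum + Holm as above. The single-enhancer
qPCR-style assay is reduced to the same ratio utility; amplification is
not modeled.

## Enhancer-feature evaluation

Binary enhancer labels are evaluated against chromatin features by
recall/precision at a fixed threshold and by threshold-swept ROC curves
with trapezoidal AUC, which equals the midrank Mann–Whitney statistic
(ties averaged). Min–max normalization maps each feature to [0, 1];
constant features map to zero with a warning. The downstream
gradient-boosted classifier is intentionally not re-implemented: it is
standard off-the-shelf machinery and depends on external curated data, so
the module exports the normalized feature matrix + labels as TSV for any
learner, and only the evaluation metrics are in scope.

## Synthetic data

All generators are pure functions of a `SimConfig`; one global seed fans
out to independent per-generator streams, so adding a generator never
perturbs the others, and every dataset ships with a truth table so
recovery tests never re-derive truth from the data.

Default scale: 2 chromosomes × 10 Mb, 7 TFs, 800 summits per TF,
cluster fraction 0.8, within-cluster gaps 5 + Exp(60 bp) capped below
300 bp. These values were chosen so that the pooled density of dispersed
summits and cluster anchors is about one per 9 kb, reproducing both
regimes of the inter-summit distance distribution (a clustered mode
below 300 bp and a dispersed mode near 10⁴ bp) while every stage runs in
seconds; at much higher summit densities on a toy genome the dispersed
mode would collapse toward 10³ bp and the bimodality benchmark would be
meaningless. Summit signal grows with planted cluster size (emulating
higher ChIP signal at multi-TF regions). H3K27ac tracks plant a
configurable fraction of heart-specific regions (strong heart, weak
liver/forebrain signal) with Poisson read noise at 10⁷ total reads;
planted CHS in the truth table uses the scorer's pseudocount convention
so noise-free recovery is exact. Motif sequences plant a sampled
composite instance in a known fraction of sequences; all other sequences
still contain both motifs at random arrangement, so only the fixed
arrangement is enriched. MPRA counts use log-normal library
representation, Poisson sampling, and a per-class activity map (default:
≥5TF classes 8×, H3K27ac-only and negative controls 1×). The
enrichment-calibration generator computes the analytic null hit
probability p₀ from interval arithmetic and plants overlaps at fold × p₀,
with 200-region query sets for null calibration — large enough that the
discrete overlap-count statistic spreads and permutation p-values are
close to uniform despite the conservative add-one/tie convention.

What the generators do **not** emulate: raw reads, fragment-length
models, realistic genome composition (repeats, CpG islands), correlated
tissue backgrounds, or linkage between the motif, ChIP and expression
layers beyond what each benchmark needs. Passing recovery tests
therefore demonstrates correctness of the implemented statistics under
their stated models, not performance on real chromatin data.

## Numerical conventions and degenerate inputs

Jaccard similarity of two empty region sets is an error, not 0. Empty
query/target sets, all-below-floor MPRA tables, single-class label
vectors, and regions off the end of a track raise informative errors;
zero-hit central enrichment and constant features are flagged results.
Quintile and ranking ties break by genomic coordinate; replicate-signal
ties keep the first replicate; odds-ratio zero cells use +0.5 for the
point estimate only. Permutation and shuffle routines take explicit
seeds or Generators and are deterministic given them.

## Known limitations

- The IDR replacement is overlap-based; peak sets with many marginal,
  partially overlapping calls will differ from true IDR output.
- The composite-arrangement null is simulation-based; its power depends
  on the number of null datasets (200 by default).
- Chunked permutation averaging (−log₁₀ p scale) is a heuristic for very
  large query sets, kept for fidelity to the mirrored procedure.
- MPRA fragment assignment resolves overlap ties to the larger overlap
  and does not split fragments across abutting elements.
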