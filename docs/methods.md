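# Methods

This note documents the models, parameters and numerical choices behind
clipsite, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and
BED/bedGraph (0-based half-open) are converted only at I/O boundaries, so
the composition GFF3 → internal → BED is exercised as an identity in tests.
Positional analyses (windows, metaprofiles, k-mer scans) operate in
transcript orientation: minus-strand windows are reversed and sequence
windows reverse-complemented on extraction. Crosslink tracks are sparse
`position → count` maps per (chromosome, strand); iCLIP signal is sparse and
the contract — not the representation — is what downstream code relies on.

## Binding-site definition

The caller follows the established iCLIP post-processing recipe: two
pseudo-replicates (sums of replicate pairs), single-nucleotide candidates,
region merging (<5 nt), isolation filtering (no neighbor within 4 nt),
iterative center selection at the crosslink maximum, ±2 nt widening to 5-nt
sites, a center-score maximality filter, and a 2-of-4 reproducibility
filter at the 0.05 quantile of positive per-site counts per replicate.

Choices the recipe leaves open, resolved here:

* **Candidate caller.** The HMM-based external caller is deliberately not
  re-implemented; scored candidates can be supplied as BED6, or the
  built-in stand-in emits positions covered in *both* pseudo-replicates
  with log2 fold enrichment over a local 501-nt background (center ±2 nt
  excluded) of at least `candidate_min_fold` (default 4).
* **Center ties** break 5′-most in transcript orientation (deterministic
  and orientation-aware).
* **Overlap resolution.** Removing only the candidates inside a widened
  site would allow the next center to sit 3–4 nt away and emit an
  overlapping site. A chosen center therefore consumes every candidate
  within 2·half_width (4 nt) of itself: candidates inside the site define
  it, and the flanking band cannot seed an overlapping site. This
  guarantees per-strand non-overlap and termination; an independent naive
  reference implementation with the same semantics backs the oracle tests.
* **Sites failing the center-score rule** are discarded outright and their
  candidates stay consumed; they are not re-centered.
* **Support comparison** is closed (count ≥ threshold), so the degenerate
  all-equal-counts case stays supported; a strict mode is available.
  A replicate with no positive per-site counts gets threshold 1 and a
  warning. The "0.05 percentile" is read as the 0.05 quantile (5th
  percentile); a 0.05th percentile would exclude essentially nothing.
* Sites whose widened window would cross position 0 are discarded and
  counted (`n_boundary_discarded`).

## Transcript assignment

Level-3 genes are dropped when overlapped by a level-1/2 gene; level-NA
transcripts are dropped when the gene has any level-1–3 transcript. A site
overlapping two eligible same-strand genes is assigned uniformly at random
from a seeded generator (the seed is recorded, so reruns reproduce the
choice). Region conflicts between isoforms resolve by
3′UTR > 5′UTR > CDS > intron; noncoding genes map to `noncoding`; a coding
gene's site with no feature overlap (a boundary artifact) falls back to
`intron` and is logged. *Strength* is the relative count (site events /
gene events) — ranking by raw counts is available behind a flag — and
strongest-site ties break by raw count, then 5′-most position. For
transcript coordinates each gene uses its longest kept transcript; which
isoform the original protocol used is not specified, and longest maximizes
mappable sites. Sites spanning an exon junction of that transcript are
dropped and counted.

## Sequence analyses

5-mer windows are [−7,+7] (site plus 5-nt flanks), [−27,−8] and [+8,+27]
relative to the site center on the spliced transcript; the background is a
count-matched uniform draw of 5-nt windows (scanned with the same ±5-nt
context width as the foreground center window) from transcripts carrying at
least one crosslink. Enrichment is reported as the (foreground, background)
frequency pair and their ratio — no per-k-mer test, matching the
descriptive use of these plots. Sequences are normalized to the RNA
alphabet; k-mers spanning non-ACGU symbols are skipped and counted. Logos
are computed on 51-nt windows with information content 2 − H (plug-in
entropy); the 21-nt display slice is a view of the same matrix, and both
are emitted. An optional additive uridine bias in the generator's
background placement (default off) lets motif analyses be exercised with
and without the known UV-crosslinking U preference as a confounder.

## Accessibility

Unpaired probabilities come from one of three backends: `external` shells
out to the installed RNAplfold binary (sliding window w=100 nt, maximum
span l=30 nt, u=1); `precomputed` reads a per-position TSV; `toy` — the
test default — is a deterministic heuristic (logistic squash of one minus
the local Watson–Crick complementarity density within the pairing span)
that rewards the same qualitative structure (stems less accessible than
loops) without a thermodynamics dependency. Probabilities are clamped to
[1e−10, 1−1e−10] before the log-odds transform, which is undefined at 0/1.
The z-score per relative position compares the foreground mean log-odds
with the mean and SD of background-draw means; draws sample
`n_regions_per_draw` windows without replacement within a draw and with
replacement across draws. p = 2·Φ(−|z|); BH runs across the displayed
central 201 positions only, where edge-of-sequence single-strandedness bias
is absent. A zero background SD at any position raises an error naming the
position. Full-scale defaults are 501-nt windows and 1000×1000 draws; the
bundled end-to-end configuration uses 201-nt windows with 200×200 draws,
the problem size at which the null calibration checks
(|mean z| < 0.1, |sd − 1| < 0.1) are also run.

## Profiles

Min-max normalization maps constant vectors to zeros. Smoothing uses a
cubic smoothing spline; the 0–1 `smooth_param` maps exponentially onto the
roughness-penalty weight (λ = 256^(3·spar−1)/n³ on unit-interval abscissae,
calibrated so 0.5 visibly smooths unit-variance noise while preserving
isolated peaks — the original toolchain's parameter is implementation-
defined, so the correspondence is approximate by design). Profiles shorter
than 4 points fall back to linear interpolation with a warning. Heatmaps
take the first 300 nt of each region 5′→3′, keep windows with 10²–10⁶
events, normalize, smooth to 500 columns and sort rows by argmax (ordering
is unstated upstream; argmax makes banded patterns visible). Site
metaprofiles average min-max-normalized 65-nt windows around centers.
Scaled metaprofiles kernel-density-estimate event positions rescaled to
[0,1] with Silverman bandwidth and boundary reflection.

## Proteomics and integration

For the 4-vs-4 label-free design: a condition with all four values missing
(and ≥3 present in the other) yields an infinite ratio signed by the
observed condition; two or three missing in either condition is
non-quantifiable; at most one missing per condition gives the log2 mean
difference over present samples. The edge case with one condition fully
missing and the other with ≥2 missing is classified non-quantifiable, since
no quantifiable reference exists. Ratios operate on log2 intensities;
readers expose `log2_transform` for raw matrices. Infinite-ratio proteins
count as significant regulation for set membership but are excluded from
numeric fold-change concordance. Protein significance p-values are consumed
(the upstream moderated-statistics fit is out of scope); the synthetic
tables supply them.

Overlaps use Fisher's exact test (two-sided); the odds ratio is the
cross-product with a Haldane–Anscombe 0.5 correction iff a cell is zero,
and the 95% CI is Woolf's on the corrected table (the CI method is
unstated upstream). Shift tests are two-sided Wilcoxon rank-sum with tie
correction. Published-transcriptome membership is FDR < 0.01 and l2fc > 0;
the dendritic consensus keeps genes enriched in ≥3 of 8 studies after
ortholog and expression filters. Hypergeometric enrichment restricts each
term to the background, tests P(X ≥ k) (over-representation only), defines
the gene ratio as k/|restricted term|, BH-adjusts across terms and exports
the top 25. Heatmap rows are z-scored with the sample SD; constant rows
become zeros with a warning.

## Synthetic data: what it emulates, and what it does not

The generator lays out 100 genes (default) on one chromosome: 5′UTR + CDS
(+ one optional intron) + 3′UTR, ~30% of genes with a second, 3′-truncated
isoform, 5% noncoding, a configurable fraction of overlapping gene pairs
(level-3/level-2 mix, same strand) to exercise the level filter and the
random-gene rule. Planted 5-nt purine motifs (a fixed nameable 5-mer,
GAAGA by default; per-site draws from a purine-skewed base bias when
`planted_motif=None`) go preferentially to CDS/3′UTR (weights
0.05/0.45/0.45/0.05). Counts are negative binomial (dispersion 10;
`dispersion=None` gives the Poisson limit) with background mean
0.01/nt × a log-normal per-gene expression factor, and a peak of mean 50 at
each planted center with a decaying ±1/±2-nt shoulder so the center is the
crosslink maximum. Every artifact draws from a named RNG substream of the
master seed, so adding outputs never perturbs existing ones and equal
configs give byte-identical files.

Omics tables: 30% of genes are RNA-regulated (|log2FC| ~ N(1, 0.25), padj
10⁻⁸–10⁻³), ~70% of those also protein-regulated; LFQ intensities are
log2-normal with logistic missingness increasing at low abundance; granule
(P-body/stress-granule-like) membership is drawn with a 3× weight toward
bound genes and P-body-like RNAs get a +0.4 log2FC shift, emulating the
observed binding/granule association and the granule-RNA upregulation the
integration stage measures. Exact label counts (⌊fraction·n⌋) are
guaranteed.

What passing on this data does **not** show: real iCLIP has
sequence-dependent crosslinking bias, PCR duplication, mappability gaps and
antisense signal, none of which are modeled; the toy accessibility backend
is not a thermodynamic model; the DE/LFQ tables are draws from the assumed
significance model, not fits. The tests establish that the implementation
executes the stated rules exactly and recovers planted structure under
realistic count noise — not that the rules are optimal on real libraries.

## Problem sizes

The default test and acceptance conditions are 100 genes × 4 replicates
(~200 planted sites), accessibility at 201-nt windows with a 600-window
background pool and 200×200 draws, and calibration suites at 10³
simulations; these sizes were fixed as the package's desk-scale study
conditions. The full-scale parameters (501-nt windows, 1000×1000 draws)
remain the defaults of `AccessParams` for real-data use.
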