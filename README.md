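# clipsite

**clipsite** is a desk-scale re-implementation of the standard iCLIP
(individual-nucleotide resolution UV crosslinking and immunoprecipitation)
downstream analysis stack for an RNA-binding protein: it turns per-nucleotide
crosslink-event tracks into reproducible 5-nt binding sites, characterizes
the sites' transcript context, sequence and structural accessibility, and
intersects the bound genes with differential RNA-seq and shotgun-proteomics
results to nominate high-confidence regulatory targets.

It is aimed at computational biologists who want a tested, scriptable
version of this pipeline that runs end to end on synthetic data with planted
ground truth — so every stage can be validated without multi-gigabyte
sequencing archives — and that accepts the same plain-text formats
(bedGraph, BED6, GFF3, FASTA, TSV, GMT) real datasets arrive in.

## The method

**Binding-site definition.** Crosslink events c(i) from four biological
replicates are merged into two pseudo-replicates and subjected to
peak calling (an external PureCLIP-style caller via `--candidates`, or the
built-in fold-enrichment stand-in with score
log2((c(i)+ε)/(b(i)+ε)), b = local 501-nt background). Candidate sites
closer than 5 nt are merged into regions and isolated candidates are
discarded. Within each region, centers are picked iteratively at the
position with the most crosslink events and widened by ±2 nt into 5-nt
sites; a site is kept only if its center carries the maximal peak-calling
score within the site. Finally a site must be supported by sufficient
crosslink coverage — the 0.05 quantile of each replicate's positive per-site
counts — in ≥2 of 4 replicates.

**Transcript context.** Sites are assigned to genes (annotation-level
filtering; uniform random choice between two overlapping genes), and to
regions by the hierarchy 3′UTR > 5′UTR > CDS > intron across isoforms.
Site *strength* is the site's crosslink count relative to its gene total;
transcripts are grouped by the region of their strongest site, and
binding-site densities are normalized by summed mean region lengths.

**Sequence and structure.** On spliced-transcript coordinates the pipeline
computes 5-mer frequencies in three windows around the site center
([−7,+7], [−27,−8], [+8,+27]) against a count-matched random background from
crosslinked transcripts, 51-nt sequence logos (2 − H bits), purine
statistics, and a structural-accessibility profile: per-nucleotide unpaired
probabilities p in 501-nt windows (RNAplfold w=100/l=30, or a deterministic
toy backend), transformed to log-odds log(p/(1−p)) and standardized into
z-scores against the mean/SD of resampled background draws (1000 windows ×
1000 draws at full scale), with p = 2·Φ(−|z|) and Benjamini–Hochberg
correction over the central 201 nt.

**Integration.** Differential-RNA (padj < 0.01) and protein (padj < 0.05,
after 4-vs-4 missing-value/ratio rules) significance sets are intersected
with the bound genes into validated targets; overlaps with published
granule transcriptomes (FDR < 0.01 & l2fc > 0 membership) are scored by
Fisher's exact test with odds ratios, fold-change shifts by Wilcoxon
rank-sum, and functional enrichment by a background-restricted
hypergeometric test with BH correction.

## Worked example

```bash
clipsite run-all --seed 17 --outdir demo
```

runs simulate → callsites → annotate → motif → access → profile → integrate
on a 100-gene synthetic transcriptome and prints:

```
pipeline complete; report at demo/report.json
stages: simulate, callsites, annotate, motif, access, profile, integrate
```

`demo/report.json` records the per-stage ledger. For seed 17 the run plants
178 sites (each a purine 5-mer, GAAGA by default, with a mean crosslink peak
of 50 events over an expression-scaled 0.01/nt background) and the caller
recovers all 178 centers within ±2 nt with no site farther than 2 nt from a
planted center; the reproducibility thresholds, region assignments, k-mer
table (`demo/motif_kmers.tsv`, where GAAGA ranks among the top enriched
center-window 5-mers), accessibility z profile and validated-target sets are
written as TSV next to the report. Two runs with the same seed produce
byte-identical outputs.

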