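# Methods

## Overview

`lncscreen` models the computational core of a focused CRISPRi drop-off
screen for growth-relevant lncRNAs: candidate prioritization from
expression and histone-mark data, TSS-window guide design with
specificity scoring, and depletion scoring of guide-count time courses.
All stages are exercised against a synthetic-data generator with planted
truth; this note records the models, the defaults and why, and what the
synthetic benchmarks do and do not demonstrate.

## Candidate cascade

A gene is a candidate when it passes six per-gene conditions in
conjunction — so the outcome is independent of filter order by
construction:

| filter | rule | default | status |
|---|---|---|---|
| significance | BH-adjusted p ≤ `fdr` in every comparison | 0.05 | published cascade setting |
| effect size | \|log₂ fc\| > `logfc`, consistent direction | 0.75 | published cascade setting |
| expression | mean CPM ≥ `cpm` in the higher-expressed group | 1 | published cascade setting |
| promoter mark | H3K4me3/H3K27ac peak overlapping [TSS−w, TSS+w) in the high-expression cell type | w = 2,000 bp | window unpublished; package default |
| structure | ≥ 1 multi-exonic transcript | — | published rule |
| cell line | log₂ fc ≥ `cellline_logfc` in any screenable line | 0.5 | published cascade setting |

The differential test is a Welch t-test on log₂(CPM + 0.5) with BH
adjustment per comparison. This is a deliberate simplification: the
cascade's thresholds, not the test engine, are the contract, and
`select_candidates` accepts externally computed tables so NB-based
engines (DESeq2, edgeR) can be substituted. Whether the CPM ≥ 1 rule
applies per sample or to the group mean is unspecified in the source
material; the group mean is used. The "higher-expressed group" is the
one with the larger mean CPM for that gene. Down-regulated genes are
evaluated and reported with full provenance, but only up-regulated
candidates feed library design.

Coordinates are 0-based half-open throughout; GTF (1-based closed) is
converted at the I/O boundary. The TSS of a multi-transcript gene is the
5′-most transcript start on the gene's strand.

## Guide design

Protospacers are 20-mers adjacent to an NGG PAM on either strand. The
window rule is applied to the **cut site** — the blunt cut between
protospacer positions 17 and 18 — not the protospacer start, because
CRISPRi efficacy is positioned relative to the TSS; the window
[−300, +50] is interpreted in transcription orientation. Specificity is

    score = 100 · ∏_h (1 − s_h),   s_h = ∏_{p ∈ mismatches(h)} (1 − w_p)

over off-target sites h (NGG-adjacent, ≤ 3 mismatches, the on-target
site excluded) with the Hsu 2013 per-position single-mismatch weight
vector w (spelled out in `config.MISMATCH_WEIGHTS`). A second
perfect-match site gives s_h = 1 and zeroes the score; a guide with no
off-target site scores 100. The published screen used a commercial
designer whose score is opaque; this transparent aggregate makes the
≥ 70 threshold reproducible. Site enumeration is brute force over the
reference (vectorised sliding windows), which is exact and fast at the
genome sizes the package targets; tests compare it against a naive
string-comparison oracle.

Per gene, guides with score ≥ 70 are ranked by (score desc, |cut offset|
asc, guide id asc) — the id tie-break makes selection deterministic —
and the top 10 kept. Genes with fewer passing guides are retained with a
shortfall record; genes with none go to an exclusions report. Scrambled
controls are random 20-mers with GC in [40%, 60%], no homopolymer > 4,
and no genomic site within 2 mismatches (verified by brute force).
Positive-control genes are designed like any target and flagged
`positive_control`. The library writer reports composition and never
asserts a fixed total.

## Screen scoring

Counts are CPM-normalized with a pseudocount of 0.5 on raw counts,
which keeps every fold change finite for dropout guides. Per-guide
log₂ fold changes are taken against the **matched replicate's**
screening-start sample; the reference is a labeled sample role, not a
hard-coded day, because induction protocols differ in when the start
sample is taken. Replicate fold changes are averaged per guide before
gene scoring (configurable; score averaging is the alternative).

The gene statistic is the aggregate of the k = 3 most depleted guides
at the requested day (default: latest). Median and mean are both
computed and stored because both appear in common usage; the median is
the default and the hit caller takes an aggregator flag. Ties in fold
change are broken by guide id so the selected guide set is
deterministic. A gene is a hit when its aggregate is ≤ −1 — the
threshold is quoted in the literature as "mean log₂ fc > −1" while
describing depleted hits; the depletion direction (≤ −1, boundary
inclusive) is implemented and documented here. Genes with fewer than k
guides are scored over what they have and flagged.

QC: pairwise Pearson R on log₂(CPM + 0.5) (scale unstated in the source;
recorded in output), Z-scoring per guide across samples with
zero-variance rows dropped and counted, hierarchical clustering
(Euclidean, average linkage — recorded in output metadata) and PCA of
the Z-scored matrix, and a no-induction drift check that lists guides
with replicate-mean |fc| > 1 and passes when they are ≤ 1% of guides.
The empirical null resamples `guides_per_gene` fold changes with
replacement from the scrambled pool, takes the top-k aggregate, and
reports p = (1 + #{null ≤ observed})/(1 + n_resample) with BH
adjustment. Cross-screen reproducibility is measured as the overlap of
top-50 most-depleted ranks (ascending aggregate, id tie-break).

## Synthetic-data generator

The generator's defaults describe the screen conditions the package
targets; every generator is a pure function of (config, seed), with one
named RNG substream per stage so adding a generator never perturbs
another.

**Annotation.** Genes at fixed spacing on 1–2 chromosomes of random
sequence, random strand, 1–2 transcripts, exactly
round(`mono_exonic_fraction`·n) genes with only single-exon transcripts.
Promoters are genome slices (450 nt: 350 up / 100 down of the TSS) so
design and off-target scoring share one reference.

**Expression.** Per-gene base means are log-normal around
`expr_base_mean` = 200 (σ = 1); counts are NB with biological dispersion
`expr_dispersion` = 0.01, the replicate variability of well-controlled
cultured samples. Cohort sizes default to the emulated study (4
melanocyte, 5 brain-metastasis, 4 lymph-node samples). Planted genes are
4-fold up (`expr_logfc` = 2) in every tumor group and are drawn from
genes that are multi-exonic **and** well expressed (base mean ≥ 2× the
cohort scale): the planted truth is meant to be recoverable, and
candidates of this kind are, by the cascade's own rationale, not
low-expression genes. With small cohorts the Welch test is fat-tailed,
so planting truth in weakly expressed genes would make "exact recovery"
an incoherent benchmark rather than a stringent one.

**Peaks.** Planted genes receive a TSS-spanning peak in every tumor cell
type with probability `peak_at_true_tss_prob` (default 1); other genes
receive background peaks at rate 0.3 in a random cell type.

**Screen.** Plasmid abundance a_g is log-normal (σ = 0.4, a modeling
default — plasmid dispersion is not published); each replicate passes
through a Poisson(`coverage` = 1,000) cell bottleneck; the population
carrying guide g decays as 2^(−s_g·t) — exponential in days, the
simplest model consistent with sustained depletion; reads are NB
(dispersion 0.05) around each guide's CPM share at `depth` = 1,000 reads
per guide. For planted genes, 7 of 10 guides are active (partial guide
efficacy) with s_g Gamma-distributed around `effect_mean` = 2/21 per day,
i.e. an expected day-21 guide fold change of −2. The no-induction arm
(all s_g = 0) is sampled at the end time point. The configured MOI is
recorded as experiment metadata; it constrains the wet protocol, not the
count model.

## What the benchmarks show — and what they don't

The planted-recovery and null-calibration results demonstrate that the
statistics and thresholds behave as designed **under the generator's
assumptions**: independent NB counts, no PCR amplification bias, no
guide-level efficacy structure beyond the active/inactive split, no
batch effects, library-size artifacts only through CPM composition.
Real screens violate several of these (notably overdispersion
heterogeneity and amplification jackpotting), so passing tests here
validate the arithmetic and its calibration, not performance on any
particular real dataset. Problem sizes in the test and acceptance runs
(500 genes for the cascade, ~2,760 guides for the screen, a ~100 kb
genome for design) are the package's desk-scale defaults — large enough
for the asymptotics that matter (BH denominators, CPM composition,
off-target enumeration) while keeping a full run in seconds.

## Numerical conventions and degenerate inputs

- Pseudocounts: 0.5 on raw counts before CPM and on CPM means before
  log-ratios; all outputs finite by construction.
- All rankings and top-k selections break ties lexicographically by id.
- Constant samples yield missing correlation values, never 0;
  zero-variance genes are excluded from Z-score testing and reported.
- An all-zero sample, a missing reference sample, a group with fewer
  than two replicates, and a guide without a gene mapping are errors
  naming the offender; a missing no-induction arm is a skipped check
  with a warning.
- Seeds must be non-negative; every CLI run writes a provenance file
  (parameters + seed + versions) sufficient to reproduce it.

## Known limitations

No read-level simulation (FASTQ), no PCR-bias model, no copy-number
correction, no transcript assembly, no batch correction, and no
full-likelihood screen frameworks (MAGeCK/BAGEL-style); the empirical
null is a resampling convenience, not a calibrated error model for real
screens.
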