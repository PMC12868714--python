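# Methods

This note documents the models implemented in `hgscreen`, the defaults and
why they were chosen, what the synthetic-data generator emulates, and the
numerical decisions a maintainer would want written down.

## Screen design assumed throughout

A hybrid guide RNA (hgRNA) couples one Cas9 spacer (20 nt) and one Cas12a
spacer (23 nt) on a single transcript; the pair defines one perturbation.
The library design mirrors a targeted exon-deletion screen: each cassette
exon targeted by three independent guide pairs cutting the flanking
introns, each gene knockout by two pairs, plus 40 intergenic cutting
controls and 40 non-targeting controls. Intergenic hgRNAs are the baseline
class for every comparison; non-targeting cells are excluded from analysis
(cutting controls match the DNA-damage response of targeting guides, which
pure non-targeting guides do not). Guides act as biological replicates in
all replicate-level statistics.

## Synthetic screen generator

The generator (`hgscreen.simulate`) produces the matrices the pipeline
consumes plus a hidden truth table, and is itself part of the tested
surface.

**Expression.** Counts are negative binomial via a gamma–Poisson draw with
per-gene baseline mean and dispersion. Baselines are log-normal with log-sd
2.0 and median 1 UMI/cell, so relative abundances span orders of magnitude
as in droplet data and most genes fall inside the standard highly-variable
mean window after normalization to 10,000 counts. Dispersions are
log-normal around 0.15 (typical cell-level overdispersion). A per-cell
log-normal(0, 0.3) library-size factor multiplies all means. Each
non-control target carries a Poisson-sized set of affected genes with
log2 fold-changes symmetric about zero (magnitude uniform in
[0.5, 1.5] × `lfc_scale`); escaping cells (per-target fraction) use
baseline means. Cell-cycle structure: each cell draws a phase from a
global 3-simplex (default (0.18, 0.52, 0.30) ≈ the control phase mix of a
rapidly cycling near-haploid line), and its own phase's marker genes gain
`phase_effect_lfc` (default 1.0) in log2. A per-target override of the
phase simplex lets phase-redistribution phenotypes be planted — that is
how the G1-shift and phase-driven-divergence scenarios are constructed.
Synthetic phase markers are taken from the 55th–80th percentile of baseline
expression: real cycling markers sit at moderate expression in their off
phase and are induced a few-fold, and marker sets drawn from the heavy
log-normal tail would break the expression-matched control scoring that the
phase caller relies on.

**Guide capture.** A carried hgRNA's Cas9 and Cas12a guide features are
detected independently with probabilities `p_detect_cas9`,
`p_detect_cas12a`; detected features receive 1 + Poisson(20) UMIs, and up
to two random guide features per cell receive ambient Poisson(0.1)
background, giving the detector something to threshold. Doublets (rate
parameter) sum two cells' expression vectors and emit both hgRNAs;
decoupled cells (rate parameter) emit the Cas12a guide of a random other
hgRNA, emulating lentiviral template switching. All draws flow from one
`numpy` Generator, so outputs are bit-identical for a fixed seed.

**What the generator does not emulate:** ambient mRNA contamination,
batch/replicate structure, empty droplets and cell calling, UMI collapsing
errors, gene–gene co-expression modules beyond the planted programs, and
continuous cell-cycle progression (phases are discrete). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to artefacts the model omits.

## Guide detection and assignment

Within a modality, every guide with UMI ≥ `min_umi` (default 5) is a
candidate; all co-detections are reported so doublets stay visible, while a
lone candidate must also exceed `dominance_ratio` (default 3) times the
next-highest count, suppressing calls just above ambient background. The
defaults are deliberately conservative and exposed in config; upstream
vendor counting heuristics are not replicated. A cell is assigned when the
union of hgRNAs implied by both modalities is a single library hgRNA —
single-modality evidence is accepted by default (`require_dual=False`)
since dual detection rates are a property of capture, not of identity
confidence. Two or more hgRNAs within a modality → doublet; exactly one
hgRNA per modality but different → decoupled. Decoupled cells are dropped,
not reassigned: once the designed pairing is lost the perturbation identity
is unknowable.

## QC and transform chain

Filters run cell-first then gene (single pass; an iterate-to-fixed-point
mode exists). Mitochondrial genes are identified by a configurable name
prefix (default `MT-`). Normalization is total-count to 10,000 followed by
natural log1p, computed in float64 so row sums are exact. The
highly-variable-gene rule uses dispersion = variance/mean of expm1 of the
log-normalized values, z-scored within 20 equal-frequency mean bins
(degenerate bins fall back to zero offset); genes qualify with mean in
(0.0125, 3) and normalized dispersion > 0.5. Covariate regression replaces
each gene by the residual of an OLS fit on intercept + total counts +
mitochondrial percentage (a closed-form least-squares on the full matrix,
not per-gene loops); residuals are centered, scaled to unit variance and
clipped at +10 only — the stated limit is an upper one, and the lower tail
carries real signal for strongly downregulated genes. Residual standard
deviations below 1e-10 × the data scale are treated as zero-variance and
the gene's scaled column set to 0.

## Perturbation signature and escaping-cell classification

The signature of a cell is its scaled HVG expression minus the mean of its
`n_neighbors` (20) nearest control cells, with neighbours found in a
40-component PCA of the scaled HVG layer. Control cells exclude themselves
from their own neighbour set; otherwise control signatures would have
systematically lower variance than target signatures and miscalibrate the
classifier below.

Per target, signatures are projected onto the difference axis (mean target
signature − mean control signature) and a two-component univariate Gaussian
mixture is fit by EM: the control component's mean and sd are estimated
from control cells and held fixed (the anchor), while the perturbed
component's mean, sd and the mixing weight are re-estimated from soft
responsibilities (weight clipped to [0.01, 0.99]; initialisation from the
upper half of target scores; tolerance 1e-4 on responsibilities, max 100
iterations). Cells with responsibility ≤ 0.5 are *escaping* (ties break
conservatively toward escaping). A target is declared undetectable — all
cells escaping — unless two gates pass: (i) the squared norm of its mean
signature shift exceeds the 99th percentile of a 200-draw control bootstrap
at the same group size (the empirical mean-difference norm sums sampling
noise over every HVG dimension and is biased upward under the null, so a
raw threshold would not be calibrated); and (ii) the standardized component
separation, after subtracting the analytic no-effect expectation of the
squared shift, stays ≥ 0.5. Targets with fewer than 10 cells are left
unclassified and retained with a warning. Control cells are never labelled
perturbed; downstream perturbed-only aggregation therefore keeps
control-class cells unconditionally and applies the flag only to target
cells.

## Pseudobulk differential expression

Counts are summed over a group's member cells (guide- or target-level).
Size factors are median-of-ratios against the geometric-mean reference over
genes positive in all groups (falling back to per-group positive genes with
a warning). Dispersions are per-gene method-of-moments on normalized
counts, `max((s² − m)/m², 1e-8)`, shrunk in log space toward a lowess trend
of log dispersion on log mean (frac = 0.5) with weight 0.7 on the trend —
with ~43 replicate groups the gene-wise estimator is noisy and the trend is
stable, so strong shrinkage trades a little flexibility for much better
error control; all-zero genes are excluded. The test is a per-gene NB
log-linear model `log μ = log sf + β₀ + β₁·condition` fit by a vectorised
IRLS (2×2 weighted normal equations per gene, coefficients clipped to ±30,
50 iterations, tolerance 1e-8), with a Wald z-test on β₁ and log2FC
= β₁/ln 2. Degenerate fits (non-positive or infinite standard error) get
p = 1. Genes with mean normalized count < 1 are excluded before BH
adjustment (independent filtering; configurable). DEG = BH-adjusted
p < 0.05 and |log2FC| > 0.5. The same engine serves guide-level runs for
replicate concordance (mean pairwise Pearson r of log2FC over a supplied
gene set); a second DE framework is deliberately not pulled in for that
pass since only log2FC correlations are consumed, and the engine is
cross-checked against an independent DESeq2-style implementation in the
test suite.

## Cell-cycle scoring and enrichment

Program scores follow the binned-control convention: genes are cut into 25
equal-frequency bins by mean expression; for each bin containing a marker,
up to 50 non-marker genes are sampled from it without replacement
(seeded); score = marker mean − control mean per cell. Marker genes are
excluded from the control pool so that a gene set equal to its own control
pool scores exactly zero. Phase: G1 iff both scores ≤ 0, else argmax (ties
at positive scores go to S). A canonical human S/G2M marker list ships as
package data for real data; any list can be supplied.

Enrichment per target and phase uses two kinds of evidence. Cell-level: a
one-sided Fisher's exact test on the 2×2 table of in-phase/out-of-phase ×
target/pooled-intergenic cells, alternative = enrichment. Replicate-level:
a one-sided Mann–Whitney comparing the target's per-guide phase fractions
(n = guides) to the 40 per-group intergenic fractions, normal
approximation with tie correction and no continuity correction. Each test
family is BH-adjusted across all (target, phase) pairs of the run — the
family could equally have been defined per phase; per-run is the more
conservative and simpler choice. Exon targets are significant only if both
gates pass (Fisher BH < 0.01 and MW BH < 0.05); knockout targets use the
Fisher gate alone at BH < 0.01. When two phases pass, the phase with the
lowest Fisher adjusted p is called (MW adjusted p breaks exact ties) — the
Fisher statistic is the one both modes share. Targets with fewer than two
guides cannot be assessed by the MW gate and are reported unassessable in
exon mode.

## Divergence and phase-conditioned re-analysis

Exon-vs-knockout concordance is the Pearson correlation of the two
comparisons' log2FC vectors over the union of their DEG sets; concordant
iff r > 0.4, with the threshold strict (r = 0.4 exactly is not
concordant). Fewer than three usable genes → unassessable. The shared-DEG
matrix keeps genes that are DEGs in ≥ 30 perturbations (non-significant
log2FCs retained for those genes); perturbation profiles are clustered on
distance 1 − r with average linkage (the linkage was an open choice;
average is the least shape-biased default). Phase-conditioned DE re-runs
the full aggregation + test on cells of one phase only; groups losing all
cells in that phase are dropped and reported, and the per-phase pseudobulk
tables partition the unrestricted table exactly.

## Exon annotation

Coordinates are GTF convention (1-based, inclusive) end to end. Inclusion
requires an exon record with exactly matching start/end — overlap is not
enough, preventing misattribution to alternative 5′/3′ splice-site
variants. Skipping requires an intron fully spanning the exon. Frame:
deleted coding length = overlap of the exon with the transcript's CDS;
preserved iff divisible by 3; fully-UTR exons preserve frame with zero
coding loss; transcripts without CDS are reported unassessable. Strict
skipping transcripts have a CDS equal (as genomic coordinate sets) to an
inclusion transcript's CDS with the exon's overlap spliced out — or, for
declared mutually-exclusive-exon pairs, with the partner exon substituted.
Coordinate-set equality on one genome implies coding-sequence equality, so
no genome FASTA is needed; UTR differences do not disqualify a strict
transcript (strictness is a statement about the coding sequence). The
longest skipping transcript is chosen by summed exon length alone.

## Orchestration and reproducibility

`run_pipeline` executes simulate → assign → qc → signature → de →
cellcycle → compare from a single validated config (unknown keys rejected
before any stage runs), echoes every parameter into a JSON run manifest
with SHA-256 hashes of all outputs, and derives each stage's seed as
`sha256(seed:stage_name) mod 2³¹` so toggling one stage never shifts
another's random stream. Seeded runs are bit-identical.

## Problem sizes used in tests and the acceptance script

Property checks run at desk scale chosen to make the statistics sharp but
cheap: 5,000–10,000 cells for assignment/capture calibration, 3 guide
groups × 200 cells vs 40 intergenic groups for DE recovery, 500 simulated
null exon targets (multinomial phase counts) for dual-gate calibration,
and 4 targets × 180 cells for escape-rate recovery. These sizes are the
package's own choices; all scale linearly if larger runs are wanted.

## Known limitations

- The escape-rate estimator needs the perturbation signal to reach the
  highly-variable gene set; programs confined to very low- or very
  high-expression genes (outside the HVG mean window) are undetectable by
  construction, and such targets are reported as fully escaping rather
  than guessed at.
- The Wald test is anti-conservative at very small replicate counts
  compared to exact or quasi-likelihood tests; with the 40-control-group
  design this is immaterial, but with few controls the p-values should be
  read cautiously.
- The mixture classifier assumes a roughly unimodal perturbed population
  per target; heterogeneous perturbation outcomes (e.g. bimodal effect
  strength) will be split along the responsibility boundary.
- Strict-skipping calls are coordinate-based and assume a single reference
  genome; they do not model genomic variants within the exon.
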