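# Methods

This note documents the statistical procedures implemented in `her2het`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical conventions that make results
reproducible to the byte.

## Single-cell FISH heterogeneity

Input is one row per tumor cell: patient, timepoint (pre/post), tumor-area
identifier, and the two probe counts — *ERBB2* (gene) and CEP17
(chromosome-17 centromere control). All areas of a patient-timepoint are
pooled before any index is computed; area identifiers are provenance only,
and profiles are invariant to cell order and area partitioning (tested).

**Amplification rule.** A cell is amplified iff *ERBB2*/CEP17 ≥ 2.0 or
*ERBB2* ≥ 6 copies. The rule is a disjunction, so cells with CEP17 = 0
(undefined ratio) are decided by the copy-number arm alone. Boundary
conventions everywhere are deterministic: ratio exactly 2.0 and copy number
exactly 6 are amplified.

**HET classification.** HET requires the amplified fraction to be strictly
between 5% and 50%; ties go to the adjacent class (5% → non-amplified,
50% → non-heterogeneous amplified). Tumor-level *ERBB2*/CEP17 ratio is the
ratio of summed signals (equivalently of per-cell means), which stays
defined when individual cells have CEP17 = 0; the high-gain group is
ratio ≥ 6, inclusive.

**Diversity indices.** Each distinct (erbb2, cep17) tuple is a species.
With species frequencies p (counts over total cells N), the Shannon index
is H = −Σ p ln p (nats). Two normalizations of H are computed:

- `equitability_cells` = H / ln N — the package's primary equitability.
  Defining frequencies as counts over N and normalizing H by the log of
  that same total is the single self-consistent convention when one
  denominator quantity is used for both; it is bounded by
  H ≤ ln S ≤ ln N. Under the clonal survival model below it also
  reproduces the observed direction of treatment effect (equitability of
  residual tumors rises when the amplified clone is preferentially killed)
  in essentially all simulations, which Pielou evenness does not.
- `equitability_species` = H / ln S (Pielou evenness) — the classical
  ecology normalization by maximum entropy at the observed richness S;
  available as `denominator="species"` and always reported alongside.

Degenerate cases: a single species gives H = 0 and E = 0 by convention
(the 0/0 limit from near-degenerate distributions); an all-distinct sample
gives E = 1 (clamped against ≤ 1e-15 float overshoot). An optional
copy-number cap bins counts above a configurable maximum because imaging
platforms saturate; the default applies no cap.

Both index implementations are checked against an independent brute-force
summation over the raw cell list (math.fsum over an explicit tally) to
1e-12 on 1,000 random samples.

**Transitions.** Patients with profiles at both timepoints yield a
transition record (post − pre deltas of equitability, amplified fraction,
aggregate ratio) and one entry in a 3×3 class matrix (rows pre, columns
post). Patients present at only one timepoint are reported explicitly,
never dropped; duplicate patient-timepoint profiles are an error.

## Transcriptomic normalization, QC, and distances

**Normalization.** Genes with zero counts across all samples are removed.
TMM factors follow the canonical trimmed-mean-of-M-values algorithm: the
reference is the sample whose 75th count/library-size percentile is closest
to the cohort mean; per sample, gene-wise M = log2((x/N)/(r/N_ref)) and
A = ½·log2((x/N)(r/N_ref)) over genes nonzero in both libraries are doubly
trimmed (30% of M, 5% of A, rank-based with average ranks for ties) and
averaged with inverse approximate-variance weights
(N−x)/(Nx) + (N_ref−r)/(N_ref·r); factors are rescaled to geometric mean 1.
The implementation agrees with Bioconductor edgeR's `calcNormFactors` to
≈1e-12 (cross-checked in the test suite via Rscript) and with an
independent direct-formula reimplementation to 1e-9. Note two exact
consequences of the formula: doubling every count of a library doubles its
library size and leaves its factor at 1, and scaling a library by a
constant perturbs its factor only through the count-dependent weights
(percent-level, not machine precision). Expression values are
log2(count/(N·factor)·1e6 + 1).

**Sample QC.** PCA on gene-centered (not variance-scaled) expression;
component signs are fixed by making each component's largest-magnitude gene
loading positive, so scores are backend-independent. Samples whose PC2
score lies strictly more than 5 SD from the mean are excluded in a single
pass (mean and SD over all samples, candidates included; no iteration).
PC2 is the default because treatment perturbation typically dominates PC1
in pre/post designs, so gross technical artifacts surface on
treatment-unrelated components; the component is configurable. QC runs
once, before every downstream analysis.

**Distances and responders.** All comparisons are patient-level: the
expression of a patient's pretreatment tumor is the arithmetic mean of the
available (1 or 2) pretreatment biopsies. The pre-to-post distance is the
Euclidean distance between that mean and the residual-tumor sample over all
retained genes in log2(TMM-CPM+1) space (a top-k principal-component space
is available via `space="pcs"`; the gene-space default avoids a hidden
parameter). The intra-pair distance is between the two pretreatment
biopsies; single-biopsy patients yield NA and are reported. Patients are
weak transcriptomic responders iff their distance is ≤ the 25th percentile
(linear-interpolation quantile) — ties at the threshold are weak, so all-
equal distances degenerate to all-weak (documented, deterministic). For
distinct distances this labels exactly ⌈n/4⌉ patients weak.

**Association tests.** Continuous covariates: Pearson correlation with
t-based two-sided p. Two groups: Mann–Whitney U. Paired: Wilcoxon
signed-rank. Rank tests use the exact null when each group has ≤ 25
observations and no ties, otherwise the normal approximation with
continuity correction. The differential-expression cutoffs used by
companion DESeq2 analyses (padj < 0.05 with |FC| > 8 pre/post or > 1.5
between pretreatment groups) are recorded as constants only; DE testing is
out of scope.

## Marker exclusivity

Per-cell HER2 and CK5 intensities are dichotomized at the median over all
quantified cells pooled across tumors (per-tumor medians optional); ties at
the median are LO, strict > is HI, so even-sized continuous samples split
exactly in half. The 2×2 HI/LO table is tested with Fisher's exact test —
two-sided by the probability-mass method (sum of hypergeometric
probabilities at fixed margins no larger than the observed table's),
verified against exact rational-arithmetic enumeration for every table
with total ≤ 40. The reported odds ratio is the sample ratio ad/bc
(infinite when bc = 0 and ad > 0); mutual exclusivity appears as OR < 1
with a negative Pearson correlation of the raw intensities. The test runs
on counts; percentages are display-only elsewhere and statistically
invalid input.

## Hotspot screen

Screening operates on tabulated allele counts rather than visual
inspection of alignments, which requires an explicit evidence rule:
NO_COVERAGE below depth 10; otherwise MUTANT iff alt reads ≥ 3 and
VAF ≥ 0.05; all three thresholds configurable. Calls are monotone in alt
evidence at fixed depth. The shipped registry lists *PIK3CA* N345, C420,
E542, E545, H1047 and *ERBB2* L755, V777 by codon label; exon labels are
opaque registry text because transcript numbering schemes disagree, and a
YAML registry can substitute coordinates for any genome build. Cohort
summaries exclude NO_COVERAGE samples from denominators, count a patient
mutant if any biopsy is mutant, flag patients with mutant and wildtype
calls at the same codon as discordant, and report the per-codon
distribution over mutant patients.

## Synthetic cohorts

The generators produce data with the statistical structure the analyses
assume, with ground truth emitted alongside, deterministic under a fixed
seed (single RNG stream per generator, seed logged in output headers).

**FISH.** Default cohort: three groups of 64 (non-HET, pCR), 51 (non-HET,
no pCR), and 14 (HET, no pCR) patients; designed amplified fractions
f_true drawn uniformly from (0.60, 0.95), (0.55, 0.95), and (0.10, 0.45)
respectively; 6 areas × 75 cells per patient. The amplified clone draws
*ERBB2* from a negative binomial (mean 12, dispersion 8) truncated ≥ 6 and
CEP17 from Poisson(2) truncated ≥ 1; the non-amplified clone draws CEP17
the same way and *ERBB2* from Poisson(2.2) resampled until the cell fails
the amplification rule, so calling error is zero by construction and an
optional untruncated mode isolates rule-level misclassification. The
number of amplified cells is exact — round(f_true·N), shuffled across
areas — rather than Bernoulli-mixed, so f_true is the designed fraction
and recovery error reflects only the caller, not binomial sampling (at
450 cells, Bernoulli mixing alone would exceed a ±0.03 recovery band in
~16% of draws at f = 0.3). Treatment retains each cell independently with
clone-specific survival (defaults 0.55 amplified / 0.80 non-amplified,
chosen so a small minority of near-boundary non-HET tumors shift to HET
and equitability rises modestly after treatment); if no cell survives,
survival is redrawn up to 100 times, then one uniformly chosen cell is
retained, so posttreatment samples are never empty.

**Expression.** 2,000 genes in blocks: a 40-gene amplicon block whose
log2-mean scales with f_true (gain 1.5), a 40-gene basal block elevated
(+1.0) in the HET group, a 100-gene treatment-shift direction, a 100-gene
orthogonal outlier direction, and null background. Baseline log2-means are
N(5, 1.2²); patients add a N(0, 0.3²) per-gene random effect shared by
their samples; each biopsy adds N(0, 0.1²) noise; counts are negative
binomial (dispersion 60) around composition-normalized means with
log-normal library sizes (mean 2e6, log-SD 0.25) — a deliberately
deep-coverage, moderate-dispersion regime in which the Euclidean noise
floor is small enough that planted shift magnitudes are rank-recoverable.
Residual tumors exist for 66% of no-pCR patients; their log2-mean is the
patient mean displaced by θ along the unit shift direction, with θ ~
U(6, 18) for non-HET and U(1, 6) for HET patients (minimal treatment
response in heterogeneous tumors). Two pretreatment samples are displaced
by 40 log2-units along the orthogonal outlier direction, sized so they
exceed the 5-SD PC2 rule while the treatment direction retains the larger
variance and stays on PC1. 87.7% of patients have two pretreatment
biopsies. Hotspot-mutation ground truth is planted per patient at rates
13.5% (*PIK3CA*, 70.6% of those at H1047) and 3.2% (*ERBB2* V777).

**Immunofluorescence.** A two-clone log-normal mixture (HER2-high/CK5-low
vs the reverse), clone separation = strength × 2.0 on the log scale with
log-SD 0.5; strength 0 collapses to a single component (the null).

**Allele counts.** Depth ~ Poisson(80) per site-sample (zero-depth
site-samples producible on demand); alt counts binomial at the planted VAF
or at the 0.1% sequencing error rate.

**What the generators do not emulate.** Real FISH artifacts (nuclear
truncation, signal colocalization, reader disagreement between manual and
software counting), spatial structure within and between tumor areas,
RNA-seq batch effects, gene-gene correlation beyond the planted blocks,
GC/length bias, and the mixture of biological and technical causes behind
real QC outliers. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure under the stated
noise model — not robustness to every artifact of clinical material.

## Problem sizes and numerics

Acceptance-style properties run at: 1,000 random samples for the index
oracles; 200 seeds for fraction recovery (±0.03 band) and the
treatment-direction property; 100 random matrices for the TMM oracle;
100 cohorts of 120 samples for QC exactness; every 2×2 table with total
≤ 40 for the Fisher sweep; 500 samples for screen operating
characteristics. These sizes keep the full suite under ~2 minutes on one
CPU while leaving binomial slack far beyond the asserted rates. All
tabular output is UTF-8 TSV with "NA" for missing and ≥ 10 significant
digits, so writer/reader pairs round-trip losslessly and identical
configurations reproduce outputs byte-for-byte (hashes and seeds are
embedded as `#` comments). Validation distinguishes hard schema errors
(named file, column, and row) from warnings; pipelines abort on the first
failing stage, naming it, and never write partial files silently.

## Known limitations

- The equitability-denominator question is convention, not mathematics;
  both normalizations are always reported so either can be compared
  against external values.
- TMM reference selection can switch under small count perturbations when
  two samples tie for the closest upper quartile; factors remain
  well-defined but not continuous in the inputs.
- The hotspot screen has no strand, mapping-quality, or germline
  information — it is a screen over pre-tabulated counts, not a variant
  caller.
- Association helpers assume one observation per patient; they do not
  model within-patient correlation beyond the pre-biopsy averaging rule.
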