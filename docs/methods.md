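# Methods

`zwdosage` analyses a female-heterogametic (ZZ/ZW) system in three linked
stages: (i) identify Z-linked scaffolds and pseudoautosomal regions (PARs)
from DNA evidence, (ii) diagnose dosage balance and dosage compensation
from RNA evidence, and (iii) relate dosage balance to the strength of
selection on expression via expression variability. A synthetic-data
module generates every input under known truth so each inference can be
tested as a recovery problem.

## Sex-linkage from depth and heterozygosity

**Model.** Males carry two Z chromosomes, females one, so the
female-to-male ratio of length-normalized mapped-read counts is ~1 for
autosomes and ~0.5 for fully Z-linked scaffolds. Reads from the diverged
W gametologs of Z genes mismap onto Z scaffolds in females and are called
as heterozygous sites; genuinely hemizygous females should otherwise have
essentially no Z heterozygosity. A scaffold is called a candidate Z when
both signals agree:

- F/M depth ratio ≤ `ratio_max` (default 0.8 — midway between the
  copy-number-2 cluster at 1.0 and the copy-number-1 cluster at 0.5,
  conservative toward the 1.0 side because partial PARs raise the ratio);
- female/male heterozygosity (heterozygous sites per bp) ratio ≥
  `het_ratio_min` (default 5; the mismapping artifact produces an order
  of magnitude or more);
- size filters: length ≥ 500 kb and > 10 annotated transcripts, so weak
  single-signal scaffolds are flagged rather than silently dropped.

Two distinct heterozygosity summaries are computed and reported. The
*heterozygous rate* (het / non-reference genotypes per sample) is the
within-sample fraction; it discriminates poorly between sexes because it
is bounded. The *heterozygosity* (het sites per bp per sex) carries the
artifact signal and is what the candidate threshold applies to.

**Variant hard filters.** Site-wide MQ ≥ 30 and QD > 2 remove the site;
per-genotype DP ≥ 10 and GQ ≥ 30 set only that genotype to missing.
Missing INFO annotations error by default (`strict`) so unfiltered input
cannot pass silently.

**PAR detection.** Depth is windowed (5 kb, 0-based half-open), the
per-window log2(F/M) ratio (with an epsilon of 1e-6 guarding zero-depth
windows, which are flagged rather than dropped so coordinates stay
contiguous) is smoothed with LOESS (tricube weights, local quadratic,
span 0.25), and windows are classified balanced (> −0.25) or sex-linked
(< −0.6), with intermediate windows taking the label of the nearest
decided window. A terminal balanced run of ≥ 20 windows is a PAR. Because
smoothing displaces the crossing point of any threshold by up to half the
smoothing window, the interior PAR edge is then *refined* on the raw
ratios by a two-level least-squares step fit within the smoothing
neighbourhood; with a 1-unit log2 step and realistic window noise this
pins the boundary to within a window or two, which the automated
replacement for visual inspection of transition regions needs to achieve.

**Z/A diversity theory.** With Nm breeding males and Nf breeding females,
Ne_A = 4·Nm·Nf/(Nm+Nf) and Ne_Z = 9·Nm·Nf/(4·Nm+2·Nf). The ratio is 0.75
at an even sex ratio and rises toward 9/8 = 1.125 as the sex ratio becomes
female-biased — never reaching 1.2. Observed female Z/A heterozygosity
ratios an order of magnitude above this bound are therefore diagnostic of
an artifact, not demography.

## Dosage balance and compensation

**Definitions.** *Balance* is equality of Z expression between the sexes.
*Compensation* is restoration of female Z expression to the ancestral
(proto-autosomal) level, proxied by outgroup ortholog expression. The two
are independent axes: a Z that halves female expression with unchanged
males lacks both; a Z upregulated in both sexes can be compensated but
unbalanced.

**Rank tests.** Per-transcript log2(F/M) ratios and within-sex Z-vs-A
levels are compared by two-sided Mann–Whitney U tests (exact null by
enumeration for n1+n2 ≤ 12 without ties, otherwise normal approximation
with tie and continuity corrections), Bonferroni-adjusted within the
family of comparisons, alongside a Bayesian rank-sum test. The Bayesian
test Gibbs-samples latent normal scores consistent with the observed
ranks (group means ∓δ/2, Cauchy(0, 1/√2) prior on δ as a normal scale
mixture) and evaluates BF10 by Savage–Dickey at δ = 0, with the posterior
ordinate Rao-Blackwellized (the average of the exact normal conditional
density of δ at zero) for stability. Chains are seeded and split-chain
R̂ > 1.05 raises a flag; the Monte-Carlo SE of log BF10 is reported.
Support tiers: *** p ≤ 0.001 / BF > 30, ** ≤ 0.01 / 10–30,
* ≤ 0.05 / 1–10, none otherwise.

**Mixed models.** FPKM is normalized by ordered quantile normalization
(rank → Φ⁻¹(r/(n+1)), average ranks on ties; a log2 option exists and is
what the β-recovery tests use because the generative truth is exact on
that scale). For each condition a ladder of five fixed-effect structures
(intercept; +sex; +Z; +sex+Z; +sex×Z) is fitted by **maximum likelihood**
— not REML, since likelihoods must be comparable across different fixed
effects — with crossed random intercepts for transcript and individual,
plus, for the compensation condition, one level per distinct (ancestral
male mean, ancestral female mean) pair. Models are ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n the number of transcript×sample
rows and k = fixed effects + variance components + residual; ΔAICc ≤ 2
counts as equal support, and Akaike weights are reported. Fixed-effect
inference is by Wald z tests.

Two fitting routes share one interface. For the complete transcript ×
individual layout the pipeline produces, the two crossed covariance
structures are simultaneously diagonalized by Helmert bases, reducing
each likelihood evaluation to a weighted least squares with four distinct
weights — exact, and fast enough for thousands of fits (the fit agrees
with lme4's ML fit to ~1e-6 in both coefficients and log-likelihood on
test fixtures). Unbalanced data fall back to a dense Woodbury-identity
evaluation. Variance ratios are optimized on the log scale by Nelder-Mead
from multiple starts; ratios below e⁻³⁰ are treated as boundary
(singular) fits and flagged, not suppressed. When the ancestral grouping
has exactly one level per transcript — the generic case with continuous
outgroup means — its variance is not separately identified from the
transcript variance; the fit merges the two, reports the merged value
under transcript with the ancestral component at zero, and flags
`anc_confounded_with_transcript`. k still counts the declared components,
identically across the ladder, so rankings are unaffected.

**Classification.** Let m_FM be the median Z log2(F/M) and m_FA the
median Z log2(female mean / ancestral mean), with margin 0.25 (half the
log2 distance between "balanced" and "halved"):

- *balance absent* iff the best balance model carries a significant
  (α = 0.05) male-positive sex×Z interaction **and** m_FM ≤ −margin;
- *compensation not complete* iff the ancestral-controlled model shows
  that same gated interaction **or** m_FA < −margin;
- when not complete, *incomplete* vs *absent* is decided by whether the
  relevant median (m_FM when unbalanced, m_FA when balanced) clears
  −1 + margin — a fully uncompensated Z halves female expression
  (log2 = −1).

The effect-size gates matter: a significance-only rule misfires on a few
percent of null replicates (Wald p < 0.05 with AICc concurring), and no
interaction-based rule at all can separate "balanced at the ancestral
level" from "balanced below it", which only the ancestral-level check
sees. Labels follow the standard typology: Type I = balanced and
compensated; Type II = neither; Type III = unbalanced with gene-by-gene
(incomplete) compensation; Type IV = complete compensation without
balance. Balance without compensation has no canonical number and is
labelled `balanced-uncompensated`. The conflict flag marks the
scientifically incoherent cell (balance present, compensation absent).

## Expression variability and selection

Per-sex, per-transcript negative-binomial dispersions are estimated from
counts on library-size-normalized means by Cox–Reid adjusted profile
likelihood on a fixed dispersion grid (φ ∈ [1e-6, 30], 140 log-spaced
points; the transcript mean is profiled out by Newton steps), with
empirical-Bayes shrinkage: tagwise estimates maximize
APL_g + G0·mean(APL) with G0 = prior_df/(n−1) and prior_df = 10. BCV =
√φ. With three samples per sex the estimates are strongly
shrinkage-dominated — individual-transcript BCVs are effectively the
common dispersion plus noise, and only medians and contrasts between
groups of transcripts should be interpreted.

Sexes are compared by a Wilcoxon signed-rank test on paired log2 BCV
(female − male orientation; zero differences dropped; V = sum of positive
ranks, so V = 0 means every female value sits below its male pair). A PCA
of the centered (female, male) log2 BCV pairs splits correlated
variability into PC1 (concordant intensity; loadings forced non-negative)
and PC2 (sex bias; oriented with positive female / negative male loading
so larger scores mean relatively tighter male constraint). An OLS of
per-transcript log2(F/M) expression on PC1 + PC2 + PC1×PC2, restricted to
non-PAR Z transcripts expressed in both sexes, asks whether dosage
balance tracks either selection axis.

## The synthetic-data generator

Defaults are the study conditions: 3 males vs 3 females; 8 autosomes and
4 Z scaffolds (3 Mb, PAR host 5 Mb); PAR = first 1,750,000 bp of the
first Z scaffold; 30× diploid depth in 5 kb windows with NB overdispersion
0.05; true variant sites at 1e-3/bp (diploid genotypes 35% het / 30%
hom-alt) and W-mismapping artifact sites at 8e-3/bp on non-PAR Z where
females are called het with probability 0.8 (yielding a ~18× female
heterozygosity excess on Z, within the observed 13–35× band, while male
Z/A stays ≈ 1); a configurable fraction of each site's quality fields
(default 2%) fails each hard filter. Expression: lognormal per-transcript
baselines (median 20 FPKM, log-sd 1.0), per-individual effects (log-sd
0.1) and per-observation noise (log-sd 0.25), all multiplicative.
Individual effects are centered to geometric mean 1 within each sex
because FPKM is per-library normalized — global per-sample scale factors
do not survive into real FPKM matrices, and leaving them in would
superimpose a common offset on every transcript's F/M ratio at small
sample sizes. Four regimes set the Z sex factors: `no_compensation`
(F = μ/2), `complete_compensation` (F = M = μ), `incomplete_compensation`
(a compensated_fraction of genes at parity, the rest halved),
`complete_balance` (F = M = 0.7μ). Ancestral expression is the shared
baseline μ_g with independent lognormal noise (log-sd 0.1) per outgroup
sex. Counts are NB around the per-sex expected FPKM × transcript kb ×
library size/1e6 with dispersion bcv_true² (default BCV 0.4); anchoring
at the sex-level expectation makes bcv_true the *total* biological CV
rather than stacking on the FPKM matrix's own noise. All randomness flows
from one seed through named sub-streams, so partial reruns of one
component are reproducible.

The truth table records scaffold classes, PAR boundaries, per-gene
compensation status for Z non-PAR transcripts, and the expected sex×Z
interaction on the log2 scale (1.0, 0, 1−compensated_fraction, 0 for the
four regimes respectively).

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real data: no read-level artifacts beyond
the single het-rate parameter, no mappability or GC structure in depth,
no W-chromosome sequence, no tissue effects, no length biases in FPKM, no
ortholog misassignment, and lognormal rather than empirically heavy-tailed
expression noise. Recovery results say the *inference chain* is correct
under its stated assumptions, not that those assumptions hold for any
particular genome.

## Problem sizes and numerical choices

Recovery tests use 25 replicates per regime with 500 transcripts (250
autosomal, 250 Z) and 3v3 samples for classification, 25 replicates of
the full 12-scaffold genome for candidate-Z calling, and 50 replicates of
a single Z scaffold for PAR boundary accuracy; these sizes keep the whole
suite within a few minutes while leaving the binomial wobble of the
gene-by-gene regime well inside the classification margins. The
incomplete-compensation median sits between two clusters and becomes
unstable below roughly 150 Z transcripts — a known limitation for small
annotation sets. Other numerical conventions: window coordinates are
0-based half-open (BED) and VCF positions 1-based, with conversions at
the I/O boundary only; report floats are written at %.6g so
re-serialization is byte-identical; Gibbs chains default to 2 × 2000
draws after 500 warmup.
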