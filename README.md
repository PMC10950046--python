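# zwdosage

Sex-linkage and dosage-compensation analysis for ZZ/ZW systems —
identifying Z-linked scaffolds and pseudoautosomal regions (PARs) from
sequencing depth and genotype data, and diagnosing dosage balance and
dosage compensation from male/female expression data.

In female-heterogametic taxa (females ZW, males ZZ), fully Z-linked
scaffolds show a female/male depth ratio near 0.5, and mismapped reads
from the diverged W gametologs inflate *apparent* female heterozygosity
on Z scaffolds by an order of magnitude. On the expression side, a Z
chromosome with no dosage response halves female expression
(log2 F/M ≈ −1), while compensation restores it toward the ancestral
level — often gene by gene. `zwdosage` implements this whole inference
chain as a tested library with a thin CLI, plus a synthetic-data
generator that produces every input format with ground-truth labels, so
each step is verifiable as a recovery problem.

## The statistics at the core

- **Candidate Z calling:** scaffold is a candidate iff F/M depth ratio
  ≤ 0.8 *and* female/male heterozygosity (het sites/bp) ratio ≥ 5, with
  size filters (≥ 500 kb, > 10 transcripts) flagged separately.
- **PAR detection:** LOESS-smoothed (tricube, local quadratic) per-window
  log2 F/M depth; terminal runs of balanced windows (> −0.25) of ≥ 20
  windows, boundary refined by a least-squares step fit on raw ratios.
- **Z/A diversity theory:** Ne_A = 4NmNf/(Nm+Nf),
  Ne_Z = 9NmNf/(4Nm+2Nf); the ratio is 0.75 at an even sex ratio and
  never reaches 1.2 (supremum 9/8), so a female Z/A ratio of ~27 can
  only be an artifact.
- **Dosage tests:** Mann–Whitney U (exact for small no-tie samples,
  Bonferroni-corrected) and a Bayesian rank-sum Bayes factor
  (latent-normal Gibbs sampler, Cauchy(0, 1/√2) prior, Savage–Dickey).
- **Mixed models:** normalized FPKM ~ sex × Z-linkage with crossed random
  intercepts for transcript and individual (compensation models add an
  ancestral male:female grouping), fitted by ML and ranked by AICc; the
  sex×Z interaction β is the dosage signal.
- **Classification:** balance/compensation status maps to the standard
  dosage types (Type I–IV; e.g. lack of balance with incomplete,
  gene-by-gene compensation is Type III).
- **Selection axis:** per-sex biological coefficient of variation
  (BCV = √NB-dispersion, Cox–Reid adjusted profile likelihood with
  empirical-Bayes shrinkage), Wilcoxon signed-rank sex comparison, PCA
  into concordant-intensity and sex-bias axes, and an OLS of log2 F/M on
  those axes.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a full study (8 autosomes, 4 Z scaffolds with a 1.75 Mb PAR,
3 males vs 3 females, gene-by-gene compensation) and run the whole chain:

```python
import zwdosage as z

cfg = z.PipelineConfig(
    simulate=z.SimulationConfig(regime="incomplete_compensation"),
    seed=7, outdir="demo_out")
report = z.run_pipeline(cfg)
z.write_report(report, "demo_out")
print(open("demo_out/summary.txt").read())
```

prints

```
config 9edeb7b2ba2f0762 seed 7
candidate Z scaffolds: Z1, Z2, Z3, Z4
PAR on Z1: [0, 1,755,000)
dosage balance absent, compensation incomplete -> Type III
```

All four simulated Z scaffolds are recovered with no autosomal false
positives, the detected PAR edge lands within one window (5 kb) of the
simulated 1,750,000 bp boundary, and the diagnosis matches the simulated
regime: females express Z genes below males (balance absent) but above
the halved level a fully uncompensated Z would give (compensation
incomplete) — Type III. The model-selection table
(`demo_out/model_selection_balance.tsv`) shows why:

```
                            model     intercept  delta_aicc       weight
Sex + Z_linkage + Sex * Z_linkage  5.271050e-02       0.000 1.000000e+00
                        Z_linkage  4.692870e-02     204.553 3.817820e-45
                             Null -1.075740e-16     205.004 3.048040e-45
                  Sex + Z_linkage  2.123770e-03     205.613 2.247270e-45
                              Sex -4.480500e-02     206.062 1.795250e-45
```

the sex×Z interaction model wins by ΔAICc > 200 — sex matters *only* on
the Z. The accompanying rank tests agree (`demo_out/dosage_tests.tsv`):

```
   comparison  p_bonferroni         BF10   tier_p tier_bf
log2FM_Z_vs_A  4.434130e-13 8.659420e+10   strong  strong
  male_Z_vs_A  1.000000e+00 1.056600e-01     none    none
female_Z_vs_A  6.141960e-03 6.583940e+00 moderate  modest
```

Z-linked F/M ratios sit far below autosomal ones (first row), male Z
expression is indistinguishable from autosomal (second), and female Z
expression is reduced (third).

The same stages are scriptable from the shell:

```
zwdosage simulate --outdir data --seed 7
zwdosage sexlink call-z --summary data/scaffold_summary.tsv --vcf data/variants.vcf
zwdosage sexlink par-scan --windows data/window_depth.tsv --samples data/samples.tsv --scaffold Z1
zwdosage run-all --seed 7 --outdir demo_out
```

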