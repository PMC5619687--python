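# Methods

## Model

The analysis targets the association between a gene's genetically
regulated expression (GReX) and a binary disease phenotype, using only
per-SNP GWAS summary statistics and a reference transcriptome panel.

**Expression prediction.** In the reference panel, expression of gene *g*
is regressed on the dosages of cis SNPs (within 1 Mb of the TSS, minor
allele frequency strictly greater than 0.05) with an elastic net. The
mixing parameter is 0.5 — an equal blend of ridge and lasso, chosen for
robustness of the weight set to missing or low-quality genotypes in
downstream studies — and the penalty is selected on a 100-point log-scale
grid by 10-fold cross-validation minimizing mean squared error (fold
assignment is seeded, so training is deterministic). The nonzero-weight
SNPs form the prediction model. The reported cross-validated R² is
1 − CV-MSE/Var(y), clipped at zero; models with CV R² ≤ 0.01 are flagged
untestable and yield missing gene-level records, mirroring the
restriction of genome-wide scans to genes with usable predictors.

**Gene-level statistic.** For each study the per-SNP Wald z-scores
z_l = β_l/se_l of the model SNPs are combined as

    Z_g = Σ_l w_lg (σ_l/σ_g) z_l,   σ_l = √Γ_ll,   σ_g = √(wᵀΓw),

with Γ the sample covariance (denominator n−1) of the model SNPs'
dosages in the **training panel**, not the GWAS cohort — the defining
approximation of the summary-statistic setting. p = 2Φ(−|Z_g|). The
statistic is exactly invariant to rescaling all of a gene's weights, to
permuting SNP order, and to relabeling a summary SNP's alleles (after
harmonization); these invariances are asserted in the test suite. Per-SNP
z is always taken as β/se from the study, never re-derived from the
p-value, so no sign information is lost.

**Harmonization and reduction.** Summary rows are aligned to the model's
effect allele: swapped alleles negate β and mirror the frequency;
incompatible allele pairs are dropped with a logged reason.
Strand-ambiguous (A/T, C/G) SNPs are kept with a flag by default — the
synthetic data is strand-consistent — and can be dropped by option; how a
real mixed-platform analysis should treat them is data-dependent, which
is why both behaviours are exposed. SNPs absent from a study, or
monomorphic / below the MAF filter there, are removed from the model and
Γ is restricted to the survivors; a gene that loses all SNPs in a study
yields a missing record and is silently omitted from that gene's
meta-analysis (a six-SNP predictor with one cohort-monomorphic SNP is
scored there on five).

**Meta-analysis.** Gene-level results are combined across studies by
sample-size-weighted Z combination with the case-control effective size
Neff = 4/(1/Ncases + 1/Nctrls) as the weight. The effective (rather than
total) N is a derived identification: it reproduces the published
trans-ethnic totals (−5.013, 4.300, −4.180, −4.127, 2.81) to printed
precision, whereas raw N does not (−5.00 for the top gene). SNP-level
meta-analysis is fixed-effect inverse-variance weighting with Cochran's Q
(χ², K−1 df) for heterogeneity. Printed odds-ratio tables carry only OR
and 95% CI, so the log-scale SE is reconstructed as
(ln hi − ln lo)/(2·1.96); 1.96 rather than a higher-precision normal
quantile is used throughout CI arithmetic to match printed intervals.

**Post-processing.** Bonferroni threshold α/m; Benjamini–Hochberg step-up
FDR that can adjust a truncated top-k list against the full genome-wide
test count m (valid when unlisted p-values are all larger, as for a
published top-genes table); QQ coordinates −log10 p against
−log10((i−0.5)/n); and locus enrichment as a Pearson χ² without
continuity correction on the 2×2 (near/far × significant/not) table.
The χ² variant is itself a derived identification: it is the standard
2×2 test that reproduces both published enrichment p-values (0.044 and
0.75) from the published counts. Proximity uses gene-body distance with
an inclusive window (default 250 kb); whether the original analyses
measured from gene body, TSS, or midpoint is unstated, so the choice is
declared here rather than inferred.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not sequence-level realism.

* **Genotypes.** Each gene owns one LD block of evenly spaced cis SNPs
  (default 5 kb spacing) with ancestral allele frequencies drawn
  Uniform(0.1, 0.9). Dosages are sums of two haplotypes obtained by
  thresholding a latent AR(1) Gaussian with per-block correlation ρ
  (default 0.3), giving corr ≈ ρ^|i−j| on the latent scale — simple,
  tunable LD for covariance tests.
* **Ancestry divergence.** Cohort frequencies follow the Balding–Nichols
  construction: Beta with mean p and variance p(1−p)·Fst. Cohort-level
  frequencies are clipped to [0.005, 0.995] so that monomorphism occurs
  only when requested explicitly through a cohort's `monomorphic_snps`
  list (those SNPs are forced to frequency 0, hence zero dosage
  variance). A per-ancestry `pc_shift` enters the liability linearly and
  is echoed in a covariate column as a PC surrogate.
* **Expression.** GReX is Σ effect × centred dosage over the gene's
  causal eQTLs; Gaussian noise is scaled so the genetic fraction of
  expression variance equals h2_cis. h2_cis = 0 genes are pure noise.
* **Disease.** logit P(case) = intercept + Σ_g γ_g · standardized GReX_g
  + pc_shift, with the intercept set to a population prevalence of 10%
  and GReX standardization calibrated on a throwaway batch of 2,000
  draws. Cases and controls are collected by rejection sampling with a
  budget of 100× the requested cohort size; exceeding it raises a typed
  error. The liability acts on GReX rather than total expression so that
  the generative γ is exactly the estimand of the predicted-expression
  test.
* **Determinism.** All randomness flows from one integer seed through
  numpy Generators; identical (spec, seed) gives byte-identical outputs.

What the generator does **not** emulate: recombination maps and realistic
LD decay, imputation uncertainty, genotyping error, X chromosome,
cryptic relatedness, trans-eQTLs, or covariate confounding beyond a
single ancestry offset. Passing tests therefore demonstrate correctness
of the statistical machinery under its stated assumptions, not
performance on real genotype data.

## Problem sizes used by the simulation checks

The repository's own simulation-based checks use one shared reference
panel of 900 individuals and 250 single-eQTL genes (5 SNPs per gene,
h2_cis = 0.3, block ρ = 0.3), with predictors trained once:

* oracle equivalence — one cohort of 2,000 with per-gene γ drawn from
  {0, ±0.15, ±0.3}; the summary-based Z is compared with the Z from
  logistic regression of case status on individually predicted
  expression (same weights, same covariates) over ≥ 200 genes;
* null calibration — four independent γ = 0 cohorts of 2,000, pooling
  ~1,000 gene-level and ~5,000 SNP-level p-values;
* effect recovery — twenty cohorts of 4,000 (Fst 0.05), each with a
  single causal gene at |γ| = 0.3 of alternating sign, scanned against
  100 genes.

These sizes were chosen to match the regimes the method is used in while
keeping the whole suite comfortably reproducible on a laptop.

## Numerical notes

* Per-SNP logistic fits use Newton/IRLS with log-likelihood tolerance
  1e-8 and at most 50 iterations; separation or non-convergence yields a
  missing-value summary row (excluded downstream), never an exception.
  Constant covariate columns are dropped as collinear with the
  intercept. Wald p-values are computed as 2Φ(−|β/se|).
* MAF comparisons round min(f, 1−f) to 12 decimals before the strict
  `> threshold` test so that f = 0.95 is excluded at threshold 0.05.
* Genotype PCA standardizes dosage columns, drops invariant ones, and
  takes leading left singular vectors; the LD pruning and outlier
  removal of dedicated population-structure software are deliberately
  not reproduced — the eigenvectors serve only as covariates.
* The elastic-net objective is not homogeneous under rescaling y with a
  single penalty: for y → c·y the ℓ1 term needs α → c·α while the ℓ2
  term needs α unchanged. The exact matched-penalty mapping
  α′ = α(cρ + 1 − ρ), ρ′ = cαρ/α′ (under which weights scale exactly
  by c) is what the scale-equivariance test uses; `train_elastic_net`
  accepts a fixed `penalty` for this purpose.
* Published per-study ORs/CIs are printed to two decimals; recombining
  them can drift from the printed meta rows by up to ~0.03 for the
  widest-CI rows. The reproduction tests bound every cell at ±0.035 and
  the well-determined rows at ±0.01.
* Missing values are serialized as `NA`; all tabular outputs are TSVs
  with `# key=value` provenance headers (config hash, seed, version).

## Known limitations

* Single-tissue, single-reference weights only; no multi-tissue joint
  tests, conditional analysis, colocalization, or fine-mapping.
* No random-effects or Bayesian trans-ethnic meta-analysis; the
  fixed-effect and sample-size-weighted combinations assume effect
  homogeneity, which Cochran's Q only partially probes.
* The reference covariance comes from the training panel; under strong
  ancestry mismatch between panel and study the Z-scores are only
  approximately calibrated. The recovery checks run at modest Fst
  (≤ 0.15); behaviour at large divergence is not characterised here.
* The 2×2 enrichment test treats genes as independent units; clustered
  genes sharing eQTLs (common near known loci) violate this, so the
  enrichment p-value is descriptive rather than strictly inferential.
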