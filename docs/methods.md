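# Methods

## The question and the estimand

Two complex disorders can co-occur less (or more) often than chance in
epidemiological data.  This package separates two explanations: a
*shared genetic substrate* (risk alleles for trait A shifting liability
to trait B) versus non-genetic mechanisms.  The genetic arm asks how
much variance in trait-B case-control status is explained by a
polygenic risk score (PRS) built from trait-A GWAS results; the
epidemiological arm pools 2×2 prevalence tables across studies.

## Polygenic scoring pipeline

Stage order: read summary statistics → INFO filter → long-range-LD
region exclusion → allele harmonization → p-value-informed clumping →
threshold-indexed scoring → standardization → ancestry PCs →
per-threshold logistic association.

**QC and harmonization.**  SNPs with imputation INFO < 0.7 are removed
(absent INFO is treated as directly genotyped).  The MHC/HLA block
(chr6, 26–33 Mb, half-open in 1-based coordinates) is excluded except
for its most significant SNP: the region's extended LD would otherwise
contribute many effectively duplicate signals, while its top SNP
preserves the region's (large) contribution.  Records are matched to
the genotype panel by SNP id; weights ln(OR) are oriented to the
panel's counted allele, trying the strand complement before giving up;
A/T and C/G SNPs are dropped by default since their strand cannot be
verified without allele frequencies.

**Clumping.**  Greedy: the unclaimed SNP with smallest p becomes an
index and claims all unclaimed same-chromosome SNPs within the window
having r² at or above the threshold with it (ties on p broken by
chromosome, then position).  Defaults are a 250 kb window and r² ≥
0.25, common practice for threshold-based PRS; both are configurable
and logged.  r² is the squared Pearson correlation of dosages
(composite LD) over pairwise-complete observations — phase is never
required, and a zero-variance comparison is "undefined LD" and never
claims a neighbour.

**Scoring.**  Scores are weighted *sums* (not averages over SNP count)
with strict `p < p_T` inclusion; missing dosages are mean-imputed per
SNP so samples with different missingness remain comparable.
Standardization is to mean 0, SD 1 with the sample (n−1) SD, cases and
controls pooled.

**Association.**  Logistic regression is fitted by Newton–Raphson with
step-halving (convergence: max |score| < 1e−8 or relative
log-likelihood change < 1e−12, plus one final polishing step so
closed-form cases are exact to float precision); Wald standard errors
come from the observed information, and divergent coefficients (|β| >
30) raise an explicit separation error.  The explained-variance scale
is Nagelkerke's pseudo-R²: Cox–Snell R² = 1 − exp(2(ℓ₀ − ℓ₁)/n)
rescaled by its maximum 1 − exp(2ℓ₀/n); the reported quantity is the
increment ΔNR² between the covariates+PRS model and the
covariates-only model.  The Wald test is two-sided.  Ancestry
covariates are the top-k principal components of the LD-pruned,
standardized (by √(2f(1−f)), missing → 0 after centering) genotype
matrix; PCA was chosen over identity-by-state MDS as the modern default
for "ancestry-informative dimensions", with signs fixed by making each
component's largest-magnitude SNP loading positive.  Tail reports use
the controls' empirical 5% and 95% quantiles (linear interpolation).

## Direction-of-effect sign test

Two GWAS are merged on SNP id, study B's OR re-oriented to study A's
effect allele (reciprocal on swapped alleles; strand complement
attempted; ambiguous SNPs dropped).  Within the clumped,
threshold-passing set, a SNP is concordant when both ORs sit on the
same side of 1; ORs exactly 1 carry no direction and are excluded from
n (counted and logged).  The statistic is Pearson's
χ² = (n_same − n_diff)²/n on 1 df, without continuity correction.

## Meta-analysis

Per-study log ORs use the Haldane–Anscombe correction (0.5 added to all
four cells when any cell is zero); studies with no OR information
(events in neither arm, or in every cell of both arms) are excluded
with a log entry.  The default fixed-effect estimator is
Mantel–Haenszel with the Robins–Breslow–Greenland variance (matching
standard meta-analysis software defaults); inverse-variance weighting
is available by flag.  Random effects are DerSimonian–Laird:
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) from the IV weights, with
pooled weights 1/(se² + τ²).  Heterogeneity is Cochran's Q (χ², k−1
df) and I² = max(0, (Q − df)/Q).  CIs use the normal 1.96 quantile
throughout; no small-sample t correction.  The engine reproduces R
`metafor` (rma.mh / rma FE / rma DL) to ~1e−10 on fixture tables (the
frozen cross-check lives in the test suite).

## Synthetic data generator

The generator emulates the study design, not any particular dataset.

- **LD**: haplotypes are thresholded latent Gaussians with AR(1)
  correlation ρ^|i−j| inside fixed-size blocks and exact independence
  across blocks; a genotype is the sum of two independent haplotypes.
  Block boundaries are exact linkage-equilibrium points, which the
  clumping and pruning tests exploit.  Defaults: 20-SNP blocks, ρ = 0.9,
  one SNP per kb.
- **Allele frequencies**: uniform on [0.05, 0.5], shared between
  cohorts; with ≥2 subpopulations, per-subpopulation frequencies are
  Balding–Nichols Beta(f(1−F)/F, (1−f)(1−F)/F) perturbations.
- **Effects**: a fraction π of SNPs (default 0.01) receives effects for
  both traits from a bivariate normal with correlation r_g and marginal
  variances h²/n_causal on the standardized-genotype scale, making the
  liability-heritability bookkeeping exact under linkage equilibrium
  (block LD inflates realized genetic variance slightly; accepted).
  Defaults mirror the motivating disorders: h² 0.81/0.65, prevalences
  0.46%/0.6%, discovery 3,322/3,587, test 1,989/1,588, r_g 0.078.
- **Ascertainment**: liability = standardized-genotype score +
  N(0, 1−h²); cases exceed Φ⁻¹(1−prevalence); cohorts are
  rejection-sampled to exact case/control counts (budget 10⁷
  individuals).  Only LD blocks containing causal SNPs are generated
  for the rejection pool; remaining blocks are drawn afterwards for
  retained individuals — exact, because non-causal blocks are
  independent of case status given the causal blocks.
- **Discovery GWAS**: per-SNP univariate logistic regression (batched
  Newton with closed-form 2×2 solves), Wald p, constant INFO = 1.
  Monomorphic SNPs and SNPs with (quasi-)separated fits are dropped
  with logged counts, never imputed.

What the generator does **not** emulate: realistic recombination maps or
MAF spectra, imputation error beyond a constant INFO, X-chromosome
dosage conventions, genotyping batch effects, or linkage between causal
status and allele frequency.  Passing tests therefore demonstrate the
statistical machinery, not robustness to those real-data artefacts.

## Simulation scales and the finite-polygenicity caveat

Test-suite and driver simulations use reduced problem sizes chosen to
keep full runs in minutes on one CPU: typically 1,000–2,000 SNPs,
300–600 cases and controls per cohort, and cohorts ascertained at 10%
prevalence (ascertainment at sub-1% prevalences is possible but
wasteful at these cohort sizes).

One genuinely scientific subtlety governs the null-calibration
experiments.  Under the shared-causal-set model, a draw with
r_g = 0 still has a nonzero *realized* effect correlation with
standard deviation 1/√n_causal.  The PRS association test correctly
detects that realized correlation, so with few causal SNPs (e.g. 20)
the r_g = 0 condition shows median ΔNR² ≈ 0.006 and ~60% nominal
rejections — not a defect of the test but a property of finite
polygenicity; the regime in which "r_g = 0 implies a well-calibrated
null" is the deeply polygenic one (the motivating analyses assume
effects at 1% of ~10⁷ SNPs, i.e. ~10⁵ causal variants).  The
pure-noise null — the test trait given zero heritability, making
status independent of genotype by construction — is therefore used
wherever a calibration claim (uniform p-values, type-I error = α) is
asserted, while the effect-correlation response is checked as a
monotonicity of ΔNR² medians and of power across r_g ∈ {0, 0.25, 0.5}
with the causal fraction at its stated value.

## Numerical and design choices

- Strict inequalities at every threshold (`p < p_T`, INFO `< 0.7`
  removal, proxy `r² > 0.6`).
- Clump/prune tie-breaks and PCA signs are deterministic; all
  randomness descends from a single integer seed through named
  `SeedSequence` children, so identical configs give byte-identical
  outputs.
- The power estimator uses one fixed p_T per run (no best-threshold
  search), avoiding the optimism a threshold sweep would inject, and a
  Wilson 95% interval for the power estimate (better small-count
  behaviour than Wald).
- The LD reference for clumping and proxy search is the analysis panel
  itself; no external reference panels are managed.
- Output tables carry a header comment with package version, config
  hash and seed.

## Known limitations

- Liability-scale conversions are not provided: ΔNR² is on the
  observed (case-control ascertained) scale and depends on the
  case-control ratio.
- The profile-scoring proxy search requires the target SNP to be
  present in some reference panel with the candidates; orientation of a
  proxy relative to an untyped target is delegated to the caller's
  proxy map.
- Mantel–Haenszel weights are reported as the conventional Σ(bc/n)
  shares; forest tables display IV percentages for the fixed model.
- The meta-analysis drivers ship no real per-study tables; the
  synthetic ten-study set (seeded, true OR 0.5, τ ≈ 0.35) is labelled
  as such everywhere it appears.
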