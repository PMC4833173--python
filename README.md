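# crosstrait

Cross-disorder genetic epidemiology toolkit: does genetic risk for one
disorder shift the risk of another?  The package implements the full
analysis chain used to ask that question for pairs of complex diseases
(the motivating case is schizophrenia vs rheumatoid arthritis, where a
long-standing epidemiological puzzle is an apparent *protective* effect
of one on the other):

- **Polygenic risk scoring (PRS)** — from discovery-GWAS summary
  statistics, score each test-cohort individual as
  `S_i(p_T) = Σ_{j: p_j < p_T} ln(OR_j) · d_ij`, the risk-allele dosage
  weighted by log odds ratio, over SNPs passing a p-value threshold
  `p_T`, after imputation-quality (INFO < 0.7) filtering, long-range-LD
  (MHC) region exclusion, allele harmonization and p-value-informed LD
  clumping.
- **Association sweep** — per threshold, logistic regression of
  case-control status on the standardized PRS plus ancestry-informative
  principal components; the headline statistic is the increment in
  Nagelkerke's pseudo-R², ΔNR² = NR²(covariates + PRS) − NR²(covariates),
  with a two-sided Wald p for the PRS term and 5% tail comparisons
  against the control score distribution.
- **Genetic profile scoring** — weighted scores over a fixed external
  SNP panel, with LD-proxy resolution (r² > 0.6) for untyped SNPs.
- **Direction-of-effect sign test** — orient two GWAS to shared
  alleles, clump, and test whether the proportion of near-independent
  SNPs with concordant OR direction deviates from ½ using Pearson's
  χ² = (n_same − n_diff)²/n on 1 df.
- **Meta-analysis** — Mantel-Haenszel and inverse-variance fixed-effect
  and DerSimonian-Laird random-effects pooling of 2×2 prevalence
  tables, with Cochran's Q, I², and forest-plot tables.
- **Power analysis** — Monte-Carlo power of the PRS association as a
  function of the cross-trait genetic effect correlation r_g.
- **Synthetic data** — a liability-threshold generator producing paired
  case-control cohorts whose per-SNP causal effects have a specified
  correlation, with block-AR(1) LD, uniform allele frequencies,
  optional Balding-Nichols population structure, and PLINK
  BED/BIM/FAM + summary-statistic output, so the entire pipeline is
  testable without access to controlled genotype data.

## Worked example

The numbered drivers under `analysis/` replay the study design on
synthetic data (2,000 SNPs in 20-SNP LD blocks, 600/600 case-control
cohorts for both traits, liability h² = 0.5, causal effects at 1% of
SNPs with cross-trait correlation 0.5):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_prs_association.py
```

prints the threshold sweep (`results/prs/prs_association.tsv`):

```
 threshold  n_snps  delta_nagelkerke_r2            p
     0.001      23             0.112362 2.469387e-22
     0.010      48             0.104339 5.307019e-21
     0.100     148             0.099640 3.559343e-20
     0.500     545             0.078277 1.855451e-16
```

With r_g = 0.5 the discovery-trait PRS explains ~8-11% of test-trait
status (ΔNR²) and is overwhelmingly significant — at r_g = 0 the same
sweep returns ΔNR² near zero.  `analysis/03_direction_of_effect.py`
shows the matching sign-test picture (concordant share 0.68 at p < 0.01,
decaying toward ½ at lenient thresholds);
`analysis/04_meta_analysis.py` pools a seeded synthetic ten-study 2×2
set with a true protective OR of 0.5 and prints

```
fixed (MH):  OR 0.71 (95% CI 0.62-0.81)
random (DL): OR 0.60 (95% CI 0.42-0.87), tau2 0.277
heterogeneity: Q=59.05 (df 9), p=0.0000, I2=85%
```

(the random-effects model, appropriate under the significant
heterogeneity, recovers the generating OR); and
`analysis/05_power_curve.py` estimates power 0.23 / 0.80 / 0.95 at
r_g = 0 / 0.25 / 0.5 for the reduced-scale design.

The same stages are scriptable via the CLI with a YAML config:

```bash
crosstrait simulate --config config.yaml
crosstrait prs      --config config.yaml
crosstrait signtest --config config.yaml
crosstrait meta     --config config.yaml
crosstrait power    --config config.yaml
```

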