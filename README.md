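# lipidgps

Genetic predisposition scores (GPS) for plasma lipids in a stratified
dietary-intervention cohort: SNP quality control, unweighted risk-allele
scoring, covariate-adjusted association models for baseline lipids and for
the lipid response to a reduced-saturated-fat diet, DerSimonian–Laird
random-effects pooling across ethnic strata, gene–diet interaction tests,
and analytic per-allele power — plus a synthetic cohort generator so the
whole pipeline is testable without access to participant-level data.

**Who it is for:** nutritional-genomics and genetic-epidemiology analysts
working with candidate-SNP panels and lipid phenotypes from intervention
trials, and anyone who wants to re-pool published stratified summary
statistics or run power calculations for per-allele effects.

## The model

For individual *i* in ethnic stratum *s*, with trait-specific GPS
`G_i = Σ_j g_ij` (the unweighted count of risk alleles over the trait's SNP
panel, mean-imputed within stratum when genotypes are missing):

* baseline: `y_i = α_s + β G_i + γ₁ age + γ₂ gender + γ₃ BMI + ε`
  (triglycerides analysed as lnTG; LDL-C by Friedewald,
  `LDL = TC − HDL − TG/2.2`, undefined at TG ≥ 4.49 mmol/L)
* change after 24 weeks:
  `Δy_i = α_s + β G_i + λ y_i(baseline) + γ'covariates + δ_LF I(LF) + δ_MUFA I(MUFA) + ε`,
  REF diet as reference; interactions add `G_i × diet` product terms.

Stratum estimates (β̂_s, se_s) are pooled by DerSimonian–Laird:
`Q = Σ w_s (β̂_s − β̄_FE)²` with `w_s = 1/se_s²`,
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, pooled effect
`Σ β̂_s/(se_s²+τ²) / Σ 1/(se_s²+τ²)`; the pooled estimate is suppressed
when the heterogeneity test rejects at 0.05.  Power for a per-allele
effect of β SD per allele at risk-allele frequency p uses the noncentral
χ²₁ with `λ = n·2p(1−p)·β²`.

## Worked example

Pool three published stratum estimates of the TC-GPS effect on baseline
total cholesterol (White 0.09 ± 0.04, S,SE-Asian 0.13 ± 0.12,
Black-African −0.04 ± 0.13 mM per allele), and check the power to detect a
0.2 SD-per-allele effect for a MAF-47% SNP in 395 individuals:

```python
from lipidgps import dl_meta, analytic_power

res = dl_meta([(0.09, 0.04), (0.13, 0.12), (-0.04, 0.13)])
print(f"pooled = {res.pooled_effect:.3f} mM/allele "
      f"(95% CI {res.ci_low:.3f} to {res.ci_high:.3f})")
print(f"p = {res.p_value:.3f}   Q = {res.q:.2f}  tau2 = {res.tau2:.3f}  "
      f"het p = {res.het_p:.2f}")
print(f"power = {analytic_power(0.47, 395, 0.2):.3f}")
```

prints

```
pooled = 0.083 mM/allele (95% CI 0.012 to 0.155)
p = 0.022   Q = 1.08  tau2 = 0.000  het p = 0.58
power = 0.801
```

Each additional TC risk allele is associated with ~0.08 mM higher total
cholesterol; the strata are homogeneous (het p = 0.58, τ² = 0, so the
pooling reduces to inverse-variance fixed effect), and a common variant
with a 0.2 SD effect would be detected with ~80% power at this sample
size.

An end-to-end run on a synthetic study-scale cohort (three strata, 39
SNPs, genotype missingness, QC, GPS, all models, pooling):

```sh
lipidgps run --seed 1 --out report/
```

writes `stratum_results.tsv`, `meta_results.tsv`, `interaction_results.tsv`,
`qc_report.tsv`, `gps.tsv` and a `run.log` recording thresholds, seeds and
the number of hypothesis tests performed.  `lipidgps simulate`, `qc`,
`gps`, `meta` and `power` expose the individual stages; `lipidgps meta`
pools any TSV of (label, stratum, effect, se) rows without genotype data.

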