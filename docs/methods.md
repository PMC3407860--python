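# Methods

`lipidgps` implements a genetic-predisposition-score (GPS) analysis of
plasma lipids in a stratified dietary-intervention cohort: unweighted
risk-allele scores built from GWAS-selected SNPs, covariate-adjusted linear
models for baseline lipid levels and for the change after 24 weeks on a
reduced-saturated-fat diet, DerSimonian–Laird random-effects pooling across
ethnic strata, gene–diet interaction tests, and analytic per-allele power.
Because the underlying participant data are not public, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes; every stage is tested against that generator and against
closed-form oracles.

## Data model and trait derivations

Six traits are analysed: total cholesterol (TC), LDL-C, HDL-C and
triglycerides (TG) in mmol/L, and apolipoproteins B and A-I in g/L.  Each
of TC, LDL-C, HDL-C and TG has its own SNP panel and hence its own GPS; the
apo B analysis reuses the LDL-C panel and the apo A-I analysis the HDL-C
panel, reflecting the tight biological coupling between LDL particles and
apo B and between HDL particles and apo A-I.

LDL-C is calculated by the Friedewald rule in the mmol/L convention,
`LDL = TC − HDL − TG/2.2`, and is treated as undefined at fasting TG ≥ 4.49
mmol/L (the rule's validity ceiling in these units) or when the formula
yields a non-positive value, which is an artifact of the approximation
rather than a concentration.  Baseline TG is analysed on the natural-log
scale (`lnTG`); effects on TG are therefore approximately proportional
changes.

Genotypes are risk-allele dosages 0/1/2, where the risk allele is the one
associated in prior GWAS with higher TC/LDL-C/TG or lower HDL-C.  Dosages
can be read from TSV (digits or allele pairs such as `A/G`) or imported
from a VCF's GT field, oriented to the annotated risk allele; no strand
flipping or reference lookup is attempted — alleles are taken as annotated.

## Quality control

Filters run in a fixed order, because the earlier ones change what the
later ones see:

1. **SNP call rate** — a SNP is kept only if its non-missing fraction is
   strictly above 0.95.
2. **Individual missingness** — an individual is removed if strictly more
   than 10% of the retained SNPs are missing.
3. **Hardy–Weinberg equilibrium** — per-SNP likelihood-ratio (G) test,
   `G = 2·Σ O·ln(O/E)` against a χ²₁ reference, exclusion at p < 0.001.
   By default HWE is tested in the largest ethnic stratum: deviation in a
   pooled multi-ethnic sample can be a pure stratification artifact
   (Wahlund effect).  Pooled and any-stratum-fails modes are available.
   Monomorphic SNPs yield G = 0 and are flagged, not excluded.

SNP *selection* (distinct from QC) applies the GWAS-evidence filters:
discovery sample ≥ 1000, genome-wide significance p < 5×10⁻⁸, pairwise LD
pruning at r² ≥ 0.3 keeping the smaller GWAS p (ties broken to the
lexicographically smaller rsID for determinism), and at most three SNPs per
gene.  LD r² values are annotation inputs, not computed from genotypes.

## GPS construction

A trait's GPS is the plain sum of risk-allele dosages over its panel — no
effect-size weighting, both for interpretability and because baseline
effect sizes need not carry over to change-on-diet effects.  Missing
genotypes are mean-imputed per SNP **within ethnic stratum** (the analysis
is stratified; a cohort-wide mean would leak allele-frequency differences
between strata); a cohort-wide mode exists behind a flag.  Imputed scores
are fractional; for the published HDL-C grouping (≤11, 12–13, 14–15, ≥16
risk alleles) bins are implemented with half-integer edges (11.5, 13.5,
15.5) so integer scores match the printed labels exactly and fractional
scores fall in the enclosing interval.

## Association models

All models are complete-case OLS per ethnic stratum, with two-sided
t-based p-values and no multiple-testing correction (the run log reports
the number of tests performed so the multiplicity is explicit).

* **Baseline**: `trait ~ predictor + age + gender + BMI` (gender coded
  F=0/M=1; TG as lnTG).
* **Change**: `Δtrait ~ predictor + baseline trait + age + gender + BMI +
  I(LF) + I(MUFA)`, with Δ = week-24 − baseline and the high-saturated-fat
  REF arm as reference.  The two diet indicators enter jointly in one
  model.  Adjusting for the baseline value controls regression to the mean;
  the test suite demonstrates that omitting it biases the genetic effect by
  roughly −ρ·β.  For TG the change is on the natural scale while the
  baseline covariate enters as lnTG.
* **Interactions**: predictor×diet product terms (LF and MUFA vs REF) on
  the change model, or a predictor×gender term on either model; the
  product-term p-values are returned per non-reference level.

A stratum with fewer than 10 complete cases or a constant predictor yields
a flagged "unestimable" result rather than an exception, so report row
counts stay accountable.  Rank-deficient designs are an error naming the
collinear columns.  An optional weight-change covariate supports the
sensitivity analysis of re-running change models with and without it.

## Random-effects pooling

Stratum effects are pooled by DerSimonian–Laird: fixed-effect weights
`w_i = 1/se_i²`, Cochran's `Q = Σ w_i (e_i − ē)²`,
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, re-weighting by
`1/(se_i² + τ²)`.  The CI uses the normal 1.96 quantile and the pooled p a
normal z, as in standard DL practice; the heterogeneity p comes from
χ²_{k−1} on Q.  When the heterogeneity test rejects at 0.05 the pooled
columns are blanked in reports (the strata should not be combined) while
per-stratum rows are retained.  When Q ≤ k−1 the estimator reduces exactly
to inverse-variance fixed-effect pooling; the suite verifies this identity
and cross-checks τ² and the pooled estimate against statsmodels'
`combine_effects` (whose untruncated τ² is clamped at 0 for the
comparison).  No REML/Paule–Mandel estimators and no Hartung–Knapp
adjustment are provided.

Published pooled effects are checked after rounding to the printed 2-dp
precision, because the per-stratum inputs are themselves printed rounded;
extreme printed pooled p-values (≈10⁻⁹) are not recomputable from 2-dp
SEs and are excluded from the oracle set.

## Analytic power

For a two-sided per-allele test at level α, an additive genotype at
risk-allele frequency p contributes variance `2p(1−p)`, giving
noncentrality `λ = n·2p(1−p)·β²` for an effect of β phenotype-SD per
allele; power is the upper tail of a noncentral χ²₁ at the central χ²₁
critical value.  Covariate adjustment is ignored — under randomization the
covariates are orthogonal to genotype in expectation, so this is a mild
approximation (verified against Monte-Carlo power within simulation
error).  β = 0 returns exactly α.

## Synthetic cohort generator

The generator emulates a three-stratum cohort at the study's scale (White
n=395, S,SE-Asian n=46, Black-African n=38) with the observed covariate
distributions (e.g. White: age 53.0 ± 9.9 y, BMI 29.0 ± 4.8 kg/m², 59%
male) and baseline trait means (TC 5.74 mM, HDL-C 1.41 mM, TG geometric
mean 1.41 mM, apo B 0.99 g/L, apo A-I 1.23 g/L per the White stratum, with
stratum-specific values for the others).  Defaults are configuration, not
code constants.

* Genotypes: Binomial(2, p) per SNP — exactly the Hardy–Weinberg
  proportions — with per-stratum risk-allele frequencies; no LD between
  SNPs (the selection step prunes high-LD pairs) and no admixture.  The
  default panel has 39 SNPs (5 TC, 12 LDL, 14 HDL, 10 TG memberships, two
  SNPs dual-trait) with deterministic MAFs spread over [0.08, 0.50].
* Baseline: stratum mean + Σ β_j·dosage_j + centered covariate terms +
  Gaussian noise.  TG is generated on the ln scale and exponentiated.
  Per-allele LDL effects act through the TC component, since LDL-C is
  Friedewald-derived rather than generated.
* Change: diet-arm main effect + (γ + θ_diet)·GPS − ρ·(baseline −
  stratum mean) + noise, where γ is a per-allele main effect on change and
  θ a GPS-by-diet interaction; final = baseline + change.  The
  regression-to-mean coefficient defaults to ρ = 0.2, chosen to make the
  baseline adjustment non-trivial in tests.
* Diet assignment is independent of genotype (randomized trial) with arm
  probabilities matching the observed arm sizes (REF 76, MUFA 198, LF 195
  of 469).
* Genotype missingness (default 2%) is applied only to the emitted
  genotype matrix — phenotypes are generated from complete genotypes, as
  assay dropout does not alter biology.

Default per-allele effects sit at the observed scale (e.g. TC 0.09 mM,
HDL-C −0.03 mM, lnTG 0.04, apo B 0.02 g/L, apo A-I −0.02 g/L at baseline;
apo A-I −0.01 g/L on change), diet main effects match the reported
intervention responses (TC/apo B reduced on both diets, HDL-C/apo A-I on
the low-fat diet only, TG unchanged), and the default interaction is zero,
matching the reported absence of diet×GPS interactions.  Residual SDs are
not published for change scores; the defaults (e.g. TC 0.90 baseline /
0.50 change) were chosen once to reproduce the observed baseline SDs and
plausible change variability, and are documented assumptions.  Generated
concentrations are floored at 0.01 to keep extreme noise draws physical;
at the default means/SDs this affects a negligible fraction of draws.

Seeding: one global seed spawns per-stratum substreams keyed by a CRC of
the ethnicity label, so adding or reordering strata leaves other strata's
draws bit-identical; the same seed and config reproduce outputs exactly.

What the generator does **not** emulate: linkage disequilibrium, genotype
measurement error correlated with phenotype, non-Gaussian trait tails,
diet non-compliance, dropout/informative missingness, or admixture within
strata.  Passing calibration and recovery tests therefore demonstrates
correctness of the estimators under the assumed generative model, not
robustness to these real-data complications.

## Problem sizes and numerical choices

The statistical test suite runs at sizes chosen to make its Monte-Carlo
bands tight while staying desk-scale: parameter recovery uses 100 seeded
cohorts of n = 5000 (coverage criterion ≥ 93/100 nominal-95% CIs); type-I
calibration of the diet×GPS interaction uses 2000 null cohorts of n = 200
(band 5% ± 3 MC-SE); HWE p-value uniformity uses 10⁴ replicates of n =
1000 genotype draws, where the χ² approximation to the G statistic is
accurate (at n = 200 the approximation itself fails a KS test at that
replicate count).  OLS agrees with a closed-form normal-equations oracle
to 1e-10 relative; DL pooling is exact arithmetic on the input summaries.
Ties and degenerate cases are deterministic: LD pruning breaks p-value
ties lexicographically, diet indicators constant within a stratum are
dropped with a warning, and a constant factor in an interaction test is an
error naming the factor.

## Known limitations

Per-stratum OLS uses classical (non-robust) SEs and strictly additive
genotype coding, matching the source analysis; no mixed models, dominance
terms or SNP×SNP interactions.  The meta-analysis treats stratum estimates
as independent normals with known variances, which is the standard DL
approximation and is optimistic for the two small strata (n=46 and n=38).
The power formula ignores covariates and imputation-induced dosage
shrinkage.  The pipeline does not compute LD, perform liftover, or look up
annotations; all SNP metadata are user inputs.
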