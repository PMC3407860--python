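"""Synthetic dietary-intervention cohorts with known genetic architecture.

Generates the data structure the downstream analysis assumes: a
multi-ethnic cohort (three analysis strata) with Hardy-Weinberg genotypes
at configurable risk-allele frequencies, additive per-allele effects on
baseline lipids, covariate (age, gender, BMI) effects, randomized diet-arm
assignment with arm-specific main effects on the 24-week change, optional
GPS main and GPS-by-diet interaction effects on change, a
regression-to-the-mean term, and assay-style genotype missingness.

Baseline trait values follow

    baseline = stratum mean + sum_j beta_j g_j + covariate terms + N(0, sigma)

and 24-week changes follow

    change = delta_diet + (gamma + theta_diet) * GPS
             - rho * (baseline - stratum mean) + N(0, sigma_change),

with final = baseline + change.  Triglycerides are generated on the
natural-log scale and exponentiated; LDL-C is derived from TC, HDL-C and TG
by the Friedewald rule, so per-allele LDL effects are injected through the
TC component.

One global seed drives deterministic per-stratum substreams (keyed by a
hash of the ethnicity label), so adding or reordering strata leaves the
other strata's draws untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    DIETS,
    ETHNICITIES,
    CohortTable,
    GenotypeMatrix,
    SnpAnnotation,
    TraitName,
)

#: traits generated directly (TG on the ln scale); LDL-C is derived.
GENERATED_TRAITS = ("TC", "HDL", "TG", "APOB", "APOA1")

#: floor applied to generated concentrations so that extreme noise draws
#: cannot produce non-positive lipid values (documented distortion is
#: negligible at the default means/SDs).
CONCENTRATION_FLOOR = 0.01


@dataclass
class StratumSpec:
    """Sample size, covariate distributions and trait means for one stratum."""

    ethnicity: str
    n: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_fraction: float
    #: baseline means: TC/HDL in mM, TG as geometric mean in mM (the
    #: generator works with ln TG), apo B / apo A-I in g/L.
    trait_means: Dict[str, float] = field(default_factory=dict)


@dataclass
class SnpSpec:
    """One simulated SNP: alleles, trait panel membership and MAF per stratum."""

    rsid: str
    gene: str
    traits: Tuple[str, ...]
    maf: Union[float, Dict[str, float]]
    risk_allele: str = "A"
    other_allele: str = "G"

    def maf_for(self, ethnicity: str) -> float:
        if isinstance(self.maf, Mapping):
            return float(self.maf[ethnicity])
        return float(self.maf)


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic cohort."""

    seed: int
    strata: List[StratumSpec]
    snps: List[SnpSpec]
    #: per-allele effect on the baseline trait (trait units per risk allele;
    #: TG on the ln scale).  The "LDL" key acts through the TC component,
    #: since LDL-C is Friedewald-derived.
    beta: Dict[str, float] = field(default_factory=dict)
    #: per-allele main effect of the trait's GPS on the 24-week change.
    change_beta: Dict[str, float] = field(default_factory=dict)
    #: trait -> {"age": .., "gender": .., "bmi": ..} covariate slopes.
    covariate_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    residual_sd: Dict[str, float] = field(default_factory=dict)
    change_residual_sd: Dict[str, float] = field(default_factory=dict)
    diet_probs: Dict[str, float] = field(default_factory=lambda: {
        "REF": 1 / 3, "MUFA": 1 / 3, "LF": 1 / 3})
    #: trait -> {"MUFA": delta, "LF": delta}; REF is the reference (0).
    diet_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    #: trait -> {"MUFA": theta, "LF": theta}: GPS-by-diet interaction.
    interaction: Dict[str, Dict[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    #: regression-to-the-mean coefficient in [0, 1).
    rho: float = 0.0

    def validate(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum required")
        for s in self.strata:
            if s.ethnicity not in ETHNICITIES:
                raise ValueError(f"unknown ethnicity {s.ethnicity!r}")
            if s.n <= 0:
                raise ValueError(f"{s.ethnicity}: n must be positive")
            if not (0.0 <= s.male_fraction <= 1.0):
                raise ValueError(f"{s.ethnicity}: male_fraction out of [0,1]")
            for t in GENERATED_TRAITS:
                if t not in s.trait_means:
                    raise ValueError(f"{s.ethnicity}: missing trait mean for {t}")
        if not self.snps:
            raise ValueError("at least one SNP required")
        seen = set()
        for snp in self.snps:
            if snp.rsid in seen:
                raise ValueError(f"duplicate rsid {snp.rsid}")
            seen.add(snp.rsid)
            for s in self.strata:
                maf = snp.maf_for(s.ethnicity)
                if not (0.0 <= maf <= 1.0):
                    raise ValueError(f"{snp.rsid}: MAF {maf} out of [0,1] "
                                     f"for {s.ethnicity}")
        probs = [self.diet_probs.get(d, 0.0) for d in DIETS]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("diet probabilities must be non-negative and sum to 1")
        for name, sds in (("residual_sd", self.residual_sd),
                          ("change_residual_sd", self.change_residual_sd)):
            for t, sd in sds.items():
                if sd < 0:
                    raise ValueError(f"{name}[{t}] must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")


def stratum_rng(seed: int, ethnicity: str) -> np.random.Generator:
    """Deterministic per-stratum substream keyed by the ethnicity label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(ethnicity.encode())]))


def simulate_genotypes(maf: float, n: int, missing_rate: float = 0.0,
                       seed: Optional[Union[int, np.random.Generator]] = None
                       ) -> np.ndarray:
    """Risk-allele dosages under Hardy-Weinberg proportions.

    Dosages are drawn with genotype probabilities ((1-p)^2, 2p(1-p), p^2)
    for risk-allele frequency ``p`` (equivalently Binomial(2, p)); a
    ``missing_rate`` fraction of entries is set to NaN.
    """
    if not (0.0 <= maf <= 1.0):
        raise ValueError(f"maf must be in [0, 1], got {maf}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dosage = rng.binomial(2, maf, size=n).astype(float)
    if missing_rate > 0:
        dosage[rng.random(n) < missing_rate] = np.nan
    return dosage


def _panel_indices(snps: Sequence[SnpSpec], trait: str) -> np.ndarray:
    return np.array([i for i, s in enumerate(snps) if trait in s.traits],
                    dtype=int)


def _genetic_component(dosage: np.ndarray, snps: Sequence[SnpSpec],
                       trait: str, beta: Mapping[str, float]) -> np.ndarray:
    """Additive genetic contribution to a baseline trait.

    apo B and apo A-I are driven by the LDL and HDL panels respectively
    (the panels their analyses use)."""
    contrib = np.zeros(dosage.shape[0])
    b = beta.get(trait, 0.0)
    if b:
        idx = _panel_indices(snps, _GPS_PANEL.get(trait, trait))
        if idx.size:
            contrib += b * dosage[:, idx].sum(axis=1)
    if trait == "TC":
        # LDL-raising alleles raise TC mechanically (LDL-C is a TC component)
        b_ldl = beta.get("LDL", 0.0)
        if b_ldl:
            idx = _panel_indices(snps, "LDL")
            if idx.size:
                contrib += b_ldl * dosage[:, idx].sum(axis=1)
    return contrib


#: which SNP panel drives a generated trait's GPS for change/interaction terms
_GPS_PANEL = {"TC": "TC", "HDL": "HDL", "TG": "TG", "APOB": "LDL",
              "APOA1": "HDL"}


def simulate_cohort(config: SimulationConfig
                    ) -> Tuple[GenotypeMatrix, CohortTable]:
    """Draw a full cohort (genotypes + phenotypes) from the generative model.

    Deterministic given the config (same seed -> bit-identical outputs).
    Phenotypes are generated from the complete genotypes; missingness is an
    assay artifact applied only to the returned genotype matrix.
    """
    config.validate()
    dosage_blocks = []
    phenotype_blocks = []
    for spec in config.strata:
        rng = stratum_rng(config.seed, spec.ethnicity)
        n = spec.n
        dosage = np.column_stack([
            simulate_genotypes(snp.maf_for(spec.ethnicity), n, 0.0, rng)
            for snp in config.snps]) if config.snps else np.empty((n, 0))

        age = rng.normal(spec.age_mean, spec.age_sd, n)
        gender_num = (rng.random(n) < spec.male_fraction).astype(float)
        bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, n)
        diet = rng.choice(DIETS, size=n,
                          p=[config.diet_probs.get(d, 0.0) for d in DIETS])

        block = pd.DataFrame({
            "id": [f"{spec.ethnicity}_{i + 1:04d}" for i in range(n)],
            "ethnicity": spec.ethnicity,
            "age": age,
            "gender": np.where(gender_num == 1, "M", "F"),
            "bmi": bmi,
            "diet": diet,
        })

        for trait in GENERATED_TRAITS:
            mean = spec.trait_means[trait]
            if trait == "TG":
                mean = float(np.log(mean))  # configured as geometric mean (mM)
            cov = config.covariate_effects.get(trait, {})
            cov_part = (cov.get("age", 0.0) * (age - spec.age_mean)
                        + cov.get("gender", 0.0) * (gender_num
                                                    - spec.male_fraction)
                        + cov.get("bmi", 0.0) * (bmi - spec.bmi_mean))
            genetic = _genetic_component(dosage, config.snps, trait,
                                         config.beta)
            sigma = config.residual_sd.get(trait, 0.0)
            noise = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
            base_lin = mean + genetic + cov_part + noise

            panel = _panel_indices(config.snps, _GPS_PANEL[trait])
            gps = dosage[:, panel].sum(axis=1) if panel.size else np.zeros(n)
            delta = np.array([config.diet_effects.get(trait, {}).get(d, 0.0)
                              for d in diet])
            theta = np.array([config.interaction.get(trait, {}).get(d, 0.0)
                              for d in diet])
            gamma = config.change_beta.get(trait, 0.0)
            sigma_c = config.change_residual_sd.get(trait, 0.0)
            noise_c = rng.normal(0.0, sigma_c, n) if sigma_c > 0 else np.zeros(n)
            change = (delta + (gamma + theta) * gps
                      - config.rho * (base_lin - mean) + noise_c)
            final_lin = base_lin + change

            col = trait.lower()
            if trait == "TG":
                block[f"{col}_baseline"] = np.exp(base_lin)
                block[f"{col}_final"] = np.exp(final_lin)
            else:
                block[f"{col}_baseline"] = np.maximum(base_lin,
                                                      CONCENTRATION_FLOOR)
                block[f"{col}_final"] = np.maximum(final_lin,
                                                   CONCENTRATION_FLOOR)

        if config.missing_rate > 0 and dosage.size:
            mask = rng.random(dosage.shape) < config.missing_rate
            dosage = dosage.copy()
            dosage[mask] = np.nan

        dosage_blocks.append(pd.DataFrame(
            dosage, index=block["id"], columns=[s.rsid for s in config.snps]))
        phenotype_blocks.append(block)

    gm = GenotypeMatrix(pd.concat(dosage_blocks))
    gm.dosage.index.name = "id"
    cohort = CohortTable(pd.concat(phenotype_blocks,
                                   ignore_index=True)).derive_ldl()
    return gm, cohort


def annotations_from_config(config: SimulationConfig) -> List[SnpAnnotation]:
    """Annotation records matching the simulated SNP panel."""
    anns = []
    for snp in config.snps:
        raf = None
        if isinstance(snp.maf, Mapping):
            raf = {k: float(v) for k, v in snp.maf.items()}
        anns.append(SnpAnnotation(
            rsid=snp.rsid, gene=snp.gene,
            risk_allele=snp.risk_allele, other_allele=snp.other_allele,
            traits=frozenset(TraitName(t) for t in snp.traits),
            gwas_discovery_n=10000, gwas_p=1e-9,
            raf_by_ethnicity=raf))
    return anns


# ---------------------------------------------------------------------------
# default study conditions


def default_snp_panel() -> List[SnpSpec]:
    """A 39-SNP synthetic panel: 5 TC, 12 LDL, 14 HDL and 10 TG SNPs in or
    near distinct synthetic genes, two of them dual-trait (TC+LDL, TC+TG),
    with deterministic MAFs spread over [0.08, 0.50] and small per-stratum
    frequency offsets."""
    memberships: List[Tuple[str, ...]] = (
        [("TC",)] * 3 + [("TC", "LDL")] + [("TC", "TG")]
        + [("LDL",)] * 11 + [("HDL",)] * 14 + [("TG",)] * 9)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    snps = []
    for i, traits in enumerate(memberships):
        base_maf = 0.08 + 0.42 * ((i * 17) % 39) / 38
        maf = {
            "White": round(base_maf, 3),
            "S_SE_Asian": round(min(0.95, max(0.02, base_maf + 0.04
                                              * (-1) ** i)), 3),
            "Black_African": round(min(0.95, max(0.02, base_maf + 0.06
                                                 * (-1) ** (i // 2))), 3),
        }
        risk, other = alleles[i % 4]
        snps.append(SnpSpec(rsid=f"rs9{i + 1:05d}", gene=f"GENE{i + 1:02d}",
                            traits=traits, maf=maf,
                            risk_allele=risk, other_allele=other))
    return snps


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-scale defaults: a 3-stratum cohort (White n=395, S,SE-Asian
    n=46, Black-African n=38) with covariate distributions and trait means
    at their observed values, per-allele effects at the observed
    baseline/change scale, diet main effects matching the reported
    intervention responses, no GPS-by-diet interaction, 2% genotype
    missingness and a 0.2 regression-to-the-mean coefficient."""
    strata = [
        StratumSpec("White", 395, age_mean=53.0, age_sd=9.9,
                    bmi_mean=29.0, bmi_sd=4.8, male_fraction=0.59,
                    trait_means={"TC": 5.74, "HDL": 1.41, "TG": 1.41,
                                 "APOB": 0.99, "APOA1": 1.23}),
        StratumSpec("S_SE_Asian", 46, age_mean=50.5, age_sd=8.7,
                    bmi_mean=28.0, bmi_sd=4.2, male_fraction=0.64,
                    trait_means={"TC": 5.19, "HDL": 1.28, "TG": 1.21,
                                 "APOB": 0.96, "APOA1": 1.22}),
        StratumSpec("Black_African", 38, age_mean=50.5, age_sd=9.5,
                    bmi_mean=30.1, bmi_sd=5.4, male_fraction=0.59,
                    trait_means={"TC": 5.23, "HDL": 1.29, "TG": 1.25,
                                 "APOB": 0.91, "APOA1": 1.23}),
    ]
    return SimulationConfig(
        seed=seed,
        strata=strata,
        snps=default_snp_panel(),
        beta={"TC": 0.09, "LDL": 0.06, "HDL": -0.03, "TG": 0.04,
              "APOB": 0.02, "APOA1": -0.02},
        change_beta={"TC": -0.03, "HDL": -0.01, "APOA1": -0.01},
        covariate_effects={
            "TC": {"age": 0.015, "gender": -0.10, "bmi": 0.010},
            "HDL": {"age": 0.003, "gender": -0.25, "bmi": -0.010},
            "TG": {"age": 0.003, "gender": 0.10, "bmi": 0.015},
            "APOB": {"age": 0.003, "gender": 0.00, "bmi": 0.005},
            "APOA1": {"age": 0.002, "gender": -0.12, "bmi": -0.003},
        },
        residual_sd={"TC": 0.90, "HDL": 0.28, "TG": 0.45,
                     "APOB": 0.28, "APOA1": 0.24},
        change_residual_sd={"TC": 0.50, "HDL": 0.15, "TG": 0.30,
                            "APOB": 0.12, "APOA1": 0.12},
        diet_probs={"REF": 76 / 469, "MUFA": 198 / 469, "LF": 195 / 469},
        diet_effects={
            "TC": {"MUFA": -0.30, "LF": -0.30},
            "HDL": {"LF": -0.08},
            "APOB": {"MUFA": -0.05, "LF": -0.05},
            "APOA1": {"LF": -0.05},
        },
        interaction={},
        missing_rate=0.02,
        rho=0.2,
    )


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_yaml(config: SimulationConfig, path) -> None:
    payload = asdict(config)
    for snp in payload["snps"]:
        snp["traits"] = list(snp["traits"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    strata = [StratumSpec(**s) for s in payload.pop("strata")]
    snps = [SnpSpec(**{**s, "traits": tuple(s["traits"])})
            for s in payload.pop("snps")]
    config = SimulationConfig(strata=strata, snps=snps, **payload)
    config.validate()
    return config
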