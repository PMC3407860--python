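"""Domain types for the lipid-GPS analysis.

The analysis works on three tables: a SNP annotation table (which allele of
each SNP raises total/LDL cholesterol or triglycerides, or lowers HDL
cholesterol), a genotype matrix of risk-allele dosages, and a per-individual
phenotype table from a three-arm dietary intervention (REF / MUFA / LF) with
lipid panels at baseline and after 24 weeks.

Also provides the two trait derivations used throughout: LDL cholesterol by
the Friedewald rule (mmol/L convention, valid only below a triglyceride
ceiling) and the natural-log transform applied to baseline triglycerides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

ETHNICITIES = ("White", "S_SE_Asian", "Black_African", "Other")
#: strata entering the stratified analysis; "Other" individuals are carried
#: in the data but excluded from modelling.
ANALYSIS_STRATA = ("White", "S_SE_Asian", "Black_African")

DIETS = ("REF", "MUFA", "LF")
GENDERS = ("M", "F")

#: Friedewald rule is only applied below this fasting triglyceride level (mM).
FRIEDEWALD_TG_LIMIT = 4.49


class TraitName(str, Enum):
    """Lipid traits analysed against genetic predisposition scores."""

    TC = "TC"
    LDL = "LDL"
    HDL = "HDL"
    TG = "TG"
    APOB = "APOB"
    APOA1 = "APOA1"


#: Traits that have their own SNP panel (and hence their own GPS).
SCORED_TRAITS = (TraitName.TC, TraitName.LDL, TraitName.HDL, TraitName.TG)

#: Which SNP panel supplies the GPS for each analysed trait.  Apolipoprotein B
#: is analysed against the LDL-C score and apolipoprotein A-I against the
#: HDL-C score; the lipid traits use their own panels.
GPS_SOURCE_TRAIT: Mapping[TraitName, TraitName] = {
    TraitName.TC: TraitName.TC,
    TraitName.LDL: TraitName.LDL,
    TraitName.HDL: TraitName.HDL,
    TraitName.TG: TraitName.TG,
    TraitName.APOB: TraitName.LDL,
    TraitName.APOA1: TraitName.HDL,
}


class UndefinedLdl:
    """Sentinel for an LDL-C value outside the Friedewald validity range."""

    _instance: Optional["UndefinedLdl"] = None

    def __new__(cls) -> "UndefinedLdl":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED"


UNDEFINED = UndefinedLdl()


@dataclass(frozen=True)
class SnpAnnotation:
    """One SNP's alleles, trait links and selection metadata.

    ``risk_allele`` is the allele associated in prior GWAS with raised TC,
    LDL-C or TG, or with lowered HDL-C.  ``traits`` lists the scored traits
    the SNP contributes to (a SNP may contribute to several panels).
    """

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str
    traits: frozenset
    gwas_discovery_n: int = 1000
    gwas_p: float = 5e-9
    raf_by_ethnicity: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        for name, allele in (("risk_allele", self.risk_allele),
                             ("other_allele", self.other_allele)):
            if allele not in NUCLEOTIDES:
                raise ValueError(
                    f"{self.rsid}: {name} {allele!r} is not one of A,C,G,T")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele are identical")
        traits = frozenset(TraitName(t) for t in self.traits)
        object.__setattr__(self, "traits", traits)
        if not traits:
            raise ValueError(f"{self.rsid}: traits must be non-empty")
        bad = traits - set(SCORED_TRAITS)
        if bad:
            raise ValueError(f"{self.rsid}: traits {sorted(t.value for t in bad)} "
                             "are not scored traits (TC, LDL, HDL, TG)")
        if self.gwas_discovery_n <= 0:
            raise ValueError(f"{self.rsid}: gwas_discovery_n must be positive")
        if not (0.0 < self.gwas_p <= 1.0):
            raise ValueError(f"{self.rsid}: gwas_p must be in (0, 1]")
        if self.raf_by_ethnicity is not None:
            for eth, raf in self.raf_by_ethnicity.items():
                if not (0.0 <= raf <= 1.0):
                    raise ValueError(
                        f"{self.rsid}: risk-allele frequency for {eth} "
                        f"out of [0, 1]: {raf}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.risk_allele, self.other_allele))


def encode_dosage(allele_pair: Sequence[str], ann: SnpAnnotation) -> int:
    """Count risk alleles in an unordered allele pair (0, 1 or 2).

    Raises ``ValueError`` if either allele is foreign to the SNP.
    """
    a, b = allele_pair
    for allele in (a, b):
        if allele not in ann.alleles:
            raise ValueError(
                f"{ann.rsid}: allele {allele!r} not in "
                f"{{{ann.risk_allele},{ann.other_allele}}}")
    return int(a == ann.risk_allele) + int(b == ann.risk_allele)


def decode_dosage(dosage: int, ann: SnpAnnotation) -> tuple:
    """Inverse of :func:`encode_dosage` up to allele order."""
    if dosage not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1 or 2, got {dosage!r}")
    r, o = ann.risk_allele, ann.other_allele
    return {0: (o, o), 1: (r, o), 2: (r, r)}[dosage]


class GenotypeMatrix:
    """Individuals x SNPs matrix of risk-allele dosages.

    Stored as a float DataFrame with ``NaN`` for missing genotypes.  Before
    imputation every non-missing entry is 0, 1 or 2; after mean imputation
    (``imputed=True``) entries may be fractional in [0, 2].
    """

    def __init__(self, dosage: pd.DataFrame, imputed: bool = False):
        dosage = dosage.astype(float)
        if dosage.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        if dosage.columns.has_duplicates:
            raise ValueError("duplicate SNP ids")
        values = dosage.to_numpy()
        finite = values[~np.isnan(values)]
        if imputed:
            if finite.size and (finite.min() < 0 or finite.max() > 2):
                raise ValueError("imputed dosages must lie in [0, 2]")
        else:
            if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
                raise ValueError("non-missing dosages must be 0, 1 or 2")
        self.dosage = dosage
        self.imputed = imputed

    @property
    def individual_ids(self) -> list:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list:
        return list(self.dosage.columns)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> pd.Series:
        """Per-SNP fraction of non-missing genotypes."""
        return self.dosage.notna().mean(axis=0)

    def individual_missing_fraction(self) -> pd.Series:
        """Per-individual fraction of missing genotypes."""
        return self.dosage.isna().mean(axis=1)

    def genotype_counts(self, rsid: str,
                        mask: Optional[pd.Series] = None) -> tuple:
        """(n0, n1, n2) genotype counts for one SNP, ignoring missing cells."""
        col = self.dosage[rsid]
        if mask is not None:
            col = col[mask.reindex(col.index, fill_value=False)]
        col = col.dropna()
        return (int((col == 0).sum()), int((col == 1).sum()),
                int((col == 2).sum()))

    def subset_snps(self, rsids: Iterable[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[list(rsids)], imputed=self.imputed)

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[list(ids)], imputed=self.imputed)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.dosage.equals(other.dosage) and self.imputed == other.imputed


#: phenotype columns required on read; LDL columns are derivable.
TRAIT_COLUMNS = {
    TraitName.TC: ("tc_baseline", "tc_final"),
    TraitName.HDL: ("hdl_baseline", "hdl_final"),
    TraitName.TG: ("tg_baseline", "tg_final"),
    TraitName.APOB: ("apob_baseline", "apob_final"),
    TraitName.APOA1: ("apoa1_baseline", "apoa1_final"),
    TraitName.LDL: ("ldl_baseline", "ldl_final"),
}

REQUIRED_PHENOTYPE_COLUMNS = ("id", "ethnicity", "age", "gender", "bmi", "diet",
                              "tc_baseline", "tc_final",
                              "hdl_baseline", "hdl_final",
                              "tg_baseline", "tg_final",
                              "apob_baseline", "apob_final",
                              "apoa1_baseline", "apoa1_final")


def baseline_column(trait: TraitName) -> str:
    return TRAIT_COLUMNS[trait][0]


def final_column(trait: TraitName) -> str:
    return TRAIT_COLUMNS[trait][1]


@dataclass
class CohortTable:
    """Per-individual covariates, diet arm and lipid panel values.

    Wraps a DataFrame indexed by individual id with columns ``ethnicity``,
    ``age`` (years), ``gender`` (M/F), ``bmi`` (kg/m2), ``diet`` (REF, MUFA
    or LF) and baseline/final values for TC, HDL-C, TG (mM), apo B and
    apo A-I (g/L).  LDL-C (mM) may be supplied or derived by
    :meth:`derive_ldl`; it is NaN where the Friedewald rule does not apply.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "id":
            if "id" in df.columns:
                df = df.set_index("id")
            else:
                raise ValueError("phenotype table needs an 'id' column or index")
        if df.index.has_duplicates:
            raise ValueError("duplicate individual ids in phenotype table")
        missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS
                   if c != "id" and c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        bad_eth = set(df["ethnicity"]) - set(ETHNICITIES)
        if bad_eth:
            raise ValueError(f"unknown ethnicity labels: {sorted(bad_eth)}")
        bad_diet = set(df["diet"]) - set(DIETS)
        if bad_diet:
            raise ValueError(f"unknown diet labels: {sorted(bad_diet)}")
        bad_gender = set(df["gender"]) - set(GENDERS)
        if bad_gender:
            raise ValueError(f"unknown gender labels: {sorted(bad_gender)}")
        for trait, cols in TRAIT_COLUMNS.items():
            for col in cols:
                if col in df.columns:
                    vals = df[col].to_numpy(dtype=float)
                    if np.any(vals[~np.isnan(vals)] <= 0):
                        raise ValueError(
                            f"non-positive concentration in column {col}")
        self.table = df

    @property
    def ids(self) -> list:
        return list(self.table.index)

    def ethnicity(self) -> pd.Series:
        return self.table["ethnicity"]

    def gender_numeric(self) -> pd.Series:
        """Gender coded for modelling: F=0, M=1."""
        return (self.table["gender"] == "M").astype(float)

    def derive_ldl(self) -> "CohortTable":
        """Fill LDL-C columns from TC, HDL-C and TG via the Friedewald rule.

        Existing LDL columns are overwritten; entries where fasting TG is at
        or above the validity ceiling become NaN.
        """
        df = self.table.copy()
        for when in ("baseline", "final"):
            df[f"ldl_{when}"] = friedewald_ldl_series(
                df[f"tc_{when}"], df[f"hdl_{when}"], df[f"tg_{when}"])
        return CohortTable(df)

    def analysis_subset(self, stratum: str) -> pd.DataFrame:
        if stratum not in ANALYSIS_STRATA:
            raise ValueError(f"{stratum!r} is not an analysis stratum")
        return self.table[self.table["ethnicity"] == stratum]

    def subset_individuals(self, ids: Iterable[str]) -> "CohortTable":
        return CohortTable(self.table.loc[list(ids)].copy())


def friedewald_ldl(tc: float, hdl: float, tg: float):
    """LDL cholesterol by the Friedewald rule, mmol/L convention.

    ``LDL = TC - HDL - TG / 2.2``, defined only for fasting TG below
    4.49 mM; returns the :data:`UNDEFINED` sentinel otherwise.  All inputs
    are concentrations in mM and must be positive.
    """
    for name, v in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    if tg >= FRIEDEWALD_TG_LIMIT:
        return UNDEFINED
    return tc - hdl - tg / 2.2


def friedewald_ldl_series(tc: pd.Series, hdl: pd.Series,
                          tg: pd.Series) -> pd.Series:
    """Vectorised Friedewald rule; NaN where TG >= the validity ceiling or
    where the formula yields a non-positive (artifactual) concentration."""
    ldl = tc - hdl - tg / 2.2
    return ldl.where((tg < FRIEDEWALD_TG_LIMIT) & (ldl > 0))


def log_tg(tg: float) -> float:
    """Natural logarithm of a triglyceride concentration (must be > 0)."""
    if not tg > 0:
        raise ValueError(f"tg must be positive, got {tg!r}")
    return math.log(tg)
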