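"""Shared fixtures: tiny annotation/genotype tables and config factories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from lipidgps.data_model import GenotypeMatrix, SnpAnnotation, TraitName
from lipidgps.simulate import SimulationConfig, SnpSpec, StratumSpec

TRAIT_MEANS = {"TC": 5.74, "HDL": 1.41, "TG": 1.41, "APOB": 0.99,
               "APOA1": 1.23}


def make_stratum(ethnicity="White", n=200, **kw):
    defaults = dict(age_mean=53.0, age_sd=9.9, bmi_mean=29.0, bmi_sd=4.8,
                    male_fraction=0.59, trait_means=dict(TRAIT_MEANS))
    defaults.update(kw)
    return StratumSpec(ethnicity=ethnicity, n=n, **defaults)


def make_config(seed=0, strata=None, snps=None, **overrides):
    """Single-stratum, single-SNP null config unless overridden."""
    if strata is None:
        strata = [make_stratum()]
    if snps is None:
        snps = [SnpSpec("rs900001", "GENE01", ("TC",), 0.3)]
    cfg = SimulationConfig(seed=seed, strata=strata, snps=snps)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture
def annotations():
    return [
        SnpAnnotation("rs1", "CETP", "A", "G", frozenset({TraitName.HDL})),
        SnpAnnotation("rs2", "LDLR", "C", "T", frozenset({TraitName.LDL})),
        SnpAnnotation("rs3", "APOB", "G", "A",
                      frozenset({TraitName.TC, TraitName.LDL})),
        SnpAnnotation("rs4", "GCKR", "T", "C", frozenset({TraitName.TG})),
    ]


@pytest.fixture
def tiny_genotypes():
    dosage = pd.DataFrame(
        {"rs1": [0, 1, 2, np.nan], "rs2": [1, 1, 0, 2],
         "rs3": [2, np.nan, 1, 0], "rs4": [0, 0, 1, 1]},
        index=pd.Index(["i1", "i2", "i3", "i4"], name="id"), dtype=float)
    return GenotypeMatrix(dosage)


@pytest.fixture
def tiny_cohort_frame():
    rng = np.random.default_rng(7)
    n = 4
    return pd.DataFrame({
        "id": ["i1", "i2", "i3", "i4"],
        "ethnicity": ["White", "White", "S_SE_Asian", "Black_African"],
        "age": [45.0, 52.0, 61.0, 38.0],
        "gender": ["M", "F", "F", "M"],
        "bmi": [27.0, 31.5, 29.2, 25.8],
        "diet": ["REF", "MUFA", "LF", "LF"],
        "tc_baseline": 5.7 + rng.normal(0, 0.5, n),
        "tc_final": 5.4 + rng.normal(0, 0.5, n),
        "hdl_baseline": 1.4 + rng.normal(0, 0.1, n),
        "hdl_final": 1.35 + rng.normal(0, 0.1, n),
        "tg_baseline": [1.2, 1.5, 4.49, 0.9],
        "tg_final": [1.1, 1.6, 4.0, 1.0],
        "apob_baseline": 0.99 + rng.normal(0, 0.1, n),
        "apob_final": 0.95 + rng.normal(0, 0.1, n),
        "apoa1_baseline": 1.23 + rng.normal(0, 0.1, n),
        "apoa1_final": 1.20 + rng.normal(0, 0.1, n),
    })
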