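"""Covariate-adjusted linear models per ethnic stratum.

Baseline models regress a lipid trait on a genetic predictor (GPS or single
SNP dosage) adjusting for age, gender and BMI; change models regress the
24-week change (final minus baseline) on the predictor plus the baseline
value of the trait, age, gender, BMI and diet-arm indicators (REF is the
reference level).  Triglycerides are analysed as lnTG at baseline, and the
change model adjusts for the ln-scale baseline.  Interaction tests augment
the relevant model with predictor-by-factor product terms.

All models are complete-case ordinary least squares with t-based two-sided
p-values.  No multiple-testing correction is applied (by design: the source
analysis is exploratory); callers can count tests via the returned results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .data_model import CohortTable, TraitName, baseline_column, final_column

MIN_COMPLETE_CASES = 10
BASE_COVARIATES = ("age", "gender", "bmi")


@dataclass
class RegressionResult:
    """Per-allele effect of one predictor on one trait in one stratum."""

    trait: TraitName
    predictor: str
    model: str  # "baseline" or "change"
    stratum: str
    effect: float
    se: float
    p_value: float
    n: int
    estimable: bool = True
    reason: str = ""
    covariate_effects: Dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {"trait": self.trait.value, "predictor": self.predictor,
                "model": self.model, "stratum": self.stratum,
                "effect": self.effect, "se": self.se, "p": self.p_value,
                "n": self.n, "estimable": self.estimable}


@dataclass(frozen=True)
class OlsFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    df_resid: int
    resid_var: float


def fit_ols(y, X) -> OlsFit:
    """Ordinary least squares with t-based two-sided p-values.

    ``X`` must contain an intercept column and be full rank; a rank-deficient
    design raises an error naming the dependent columns (found by pivoted QR).
    Rows must already be complete cases.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("fit_ols requires complete cases (no NaN)")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        _, _, piv = qr(X.to_numpy(), pivoting=True)
        culprits = [str(X.columns[i]) for i in sorted(piv[rank:])]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"column(s): {culprits}")
    res = sm.OLS(y, X).fit()
    return OlsFit(params=res.params, bse=res.bse, pvalues=res.pvalues,
                  n=n, df_resid=int(res.df_resid),
                  resid_var=float(res.mse_resid))


def _response(df: pd.DataFrame, trait: TraitName, model: str) -> pd.Series:
    trait = TraitName(trait)
    base = df[baseline_column(trait)]
    if model == "baseline":
        return np.log(base) if trait is TraitName.TG else base
    delta = df[final_column(trait)] - base
    delta.name = f"delta_{trait.value.lower()}"
    return delta


def _baseline_covariate(df: pd.DataFrame, trait: TraitName) -> pd.Series:
    trait = TraitName(trait)
    base = df[baseline_column(trait)]
    if trait is TraitName.TG:
        base = np.log(base)
        base.name = "ln_tg_baseline"
    return base


def _assemble(cohort: CohortTable, predictor: pd.Series, trait: TraitName,
              stratum: str, model: str,
              extra_covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Complete-case modelling frame for one stratum."""
    df = cohort.analysis_subset(stratum)
    frame = pd.DataFrame(index=df.index)
    frame["y"] = _response(df, trait, model)
    frame["predictor"] = predictor.reindex(df.index)
    if model == "change":
        frame["baseline_trait"] = _baseline_covariate(df, trait)
    frame["age"] = df["age"]
    frame["gender"] = (df["gender"] == "M").astype(float)
    frame["bmi"] = df["bmi"]
    for col in extra_covariates:
        frame[col] = df[col]
    if model == "change":
        for diet in ("LF", "MUFA"):
            frame[f"diet_{diet}"] = (df["diet"] == diet).astype(float)
    return frame.dropna()


def _drop_constant_diet_dummies(frame: pd.DataFrame) -> pd.DataFrame:
    dropped = [c for c in ("diet_LF", "diet_MUFA")
               if c in frame.columns and frame[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"diet indicator(s) {dropped} constant in stratum; "
                      "dropped from the model")
        frame = frame.drop(columns=dropped)
    return frame


def _unestimable(trait, predictor_name, model, stratum, n, reason):
    return RegressionResult(TraitName(trait), predictor_name, model, stratum,
                            effect=float("nan"), se=float("nan"),
                            p_value=float("nan"), n=n,
                            estimable=False, reason=reason)


def _fit_frame(frame: pd.DataFrame, trait, predictor_name, model, stratum
               ) -> RegressionResult:
    n = len(frame)
    if n < MIN_COMPLETE_CASES:
        return _unestimable(trait, predictor_name, model, stratum, n,
                            f"only {n} complete cases")
    if frame["predictor"].nunique() <= 1:
        return _unestimable(trait, predictor_name, model, stratum, n,
                            "predictor constant within stratum")
    X = sm.add_constant(frame.drop(columns="y"), has_constant="add")
    fit = fit_ols(frame["y"], X)
    covar = {c: float(fit.params[c]) for c in X.columns if c != "predictor"}
    return RegressionResult(
        TraitName(trait), predictor_name, model, stratum,
        effect=float(fit.params["predictor"]), se=float(fit.bse["predictor"]),
        p_value=float(fit.pvalues["predictor"]), n=n,
        covariate_effects=covar)


def baseline_association(cohort: CohortTable, predictor: pd.Series,
                         trait: TraitName, stratum: str,
                         predictor_name: Optional[str] = None,
                         extra_covariates: Sequence[str] = ()
                         ) -> RegressionResult:
    """Per-allele effect on the baseline trait, adjusted for age, gender, BMI.

    ``predictor`` is a per-individual GPS or dosage series aligned by id.
    TG is modelled as lnTG.  Too few complete cases or a constant predictor
    yield a flagged, unestimable result rather than an exception.
    """
    name = predictor_name or str(predictor.name) or "predictor"
    frame = _assemble(cohort, predictor, trait, stratum, "baseline",
                      extra_covariates)
    return _fit_frame(frame, trait, name, "baseline", stratum)


def change_association(cohort: CohortTable, predictor: pd.Series,
                       trait: TraitName, stratum: str,
                       predictor_name: Optional[str] = None,
                       extra_covariates: Sequence[str] = ()
                       ) -> RegressionResult:
    """Per-allele effect on the 24-week change in the trait.

    Model: (final - baseline) ~ predictor + baseline trait + age + gender +
    BMI + I(LF) + I(MUFA), with the REF arm as reference.  Diet indicators
    constant within the stratum are dropped with a warning.
    """
    name = predictor_name or str(predictor.name) or "predictor"
    frame = _assemble(cohort, predictor, trait, stratum, "change",
                      extra_covariates)
    frame = _drop_constant_diet_dummies(frame)
    return _fit_frame(frame, trait, name, "change", stratum)


def interaction_test(cohort: CohortTable, predictor: pd.Series,
                     trait: TraitName, stratum: str,
                     factor: str = "diet", model: str = "change",
                     predictor_name: Optional[str] = None
                     ) -> Dict[str, float]:
    """p-values for predictor-by-factor product terms.

    ``factor`` is "diet" (two product terms, LF and MUFA vs REF, on the
    change model) or "gender" (one product term, on either model).  Returns
    a mapping from non-reference factor level to the product-term p-value.
    A factor constant within the stratum is an error naming the factor.
    """
    name = predictor_name or str(predictor.name) or "predictor"
    if factor == "gender" and model not in ("baseline", "change"):
        raise ValueError(f"unknown model {model!r}")
    base_model = "change" if factor == "diet" else model
    frame = _assemble(cohort, predictor, trait, stratum, base_model)
    if factor == "diet":
        frame = _drop_constant_diet_dummies(frame)
        levels = [c.split("_", 1)[1] for c in frame.columns
                  if c.startswith("diet_")]
        if not levels:
            raise ValueError(f"factor 'diet' is constant in stratum {stratum}")
        for level in levels:
            frame[f"predictor_x_{level}"] = (frame["predictor"]
                                             * frame[f"diet_{level}"])
        terms = {level: f"predictor_x_{level}" for level in levels}
    elif factor == "gender":
        if frame["gender"].nunique() <= 1:
            raise ValueError(f"factor 'gender' is constant in stratum {stratum}")
        frame["predictor_x_M"] = frame["predictor"] * frame["gender"]
        terms = {"M": "predictor_x_M"}
    else:
        raise ValueError(f"unknown interaction factor {factor!r}")
    if len(frame) < MIN_COMPLETE_CASES or frame["predictor"].nunique() <= 1:
        return {level: float("nan") for level in terms}
    X = sm.add_constant(frame.drop(columns="y"), has_constant="add")
    fit = fit_ols(frame["y"], X)
    return {level: float(fit.pvalues[col]) for level, col in terms.items()}


def results_to_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Tidy table of per-stratum results (one row per trait/predictor/model)."""
    return pd.DataFrame([r.as_row() for r in results])
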