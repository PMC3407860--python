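"""DerSimonian-Laird random-effects pooling and analytic per-allele power.

Stratum-specific per-allele effects are pooled with the moment-based
DerSimonian-Laird estimator: Cochran's Q is computed with fixed-effect
(inverse-variance) weights, the between-stratum variance is
``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))``, and the pooled
effect re-weights each stratum by ``1 / (se_i^2 + tau2)``.  The 95% CI and
pooled p use normal quantiles, the heterogeneity p a chi-square with k-1
df.  A pooled estimate is flagged as suppressed when the heterogeneity test
rejects at 0.05, mirroring the reporting rule that heterogeneous strata
should not be combined.

Analytic power for a per-allele additive effect treats the 1-df Wald test
as a noncentral chi-square with noncentrality
``lambda = n * 2p(1-p) * beta_sd^2`` where ``p`` is the risk-allele
frequency and ``beta_sd`` the effect in phenotype-SD units per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

DEFAULT_HET_ALPHA = 0.05
_Z975 = 1.96  # normal 95% quantile, as used by standard DL reporting


@dataclass(frozen=True)
class MetaResult:
    """DerSimonian-Laird pooled effect with heterogeneity diagnostics."""

    pooled_effect: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    q: float
    df: int
    tau2: float
    het_p: float
    suppressed: bool = False
    k: int = 0

    def as_row(self) -> dict:
        return {"effect": self.pooled_effect, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p_value, "q": self.q, "tau2": self.tau2,
                "het_p": self.het_p, "suppressed": self.suppressed,
                "k": self.k}


def dl_meta(estimates: Sequence[Tuple[float, float]],
            alpha_het: float = DEFAULT_HET_ALPHA) -> MetaResult:
    """Pool (effect, se) pairs by the DerSimonian-Laird method.

    With a single stratum the input is returned unchanged (Q = 0, tau2 = 0,
    heterogeneity p = 1).  Any non-positive SE is an error.
    """
    if len(estimates) == 0:
        raise ValueError("at least one (effect, se) pair required")
    effects = np.array([e for e, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)) or np.any(~np.isfinite(effects)):
        raise ValueError("all effects must be finite and all SEs positive")
    k = len(effects)
    w = 1.0 / ses ** 2
    fe_mean = float(np.sum(w * effects) / np.sum(w))
    q = float(np.sum(w * (effects - fe_mean) ** 2))
    df = k - 1
    if k == 1:
        tau2 = 0.0
        het_p = 1.0
    else:
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q - df) / denom)
        het_p = float(stats.chi2.sf(q, df))
    w_star = 1.0 / (ses ** 2 + tau2)
    pooled = float(np.sum(w_star * effects) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = pooled / se
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    result = MetaResult(
        pooled_effect=pooled, se=se,
        ci_low=pooled - _Z975 * se, ci_high=pooled + _Z975 * se,
        z=z, p_value=min(p_value, 1.0), q=q, df=df, tau2=tau2,
        het_p=het_p, k=k)
    return heterogeneity_gate(result, alpha_het)


def heterogeneity_gate(result: MetaResult,
                       alpha_het: float = DEFAULT_HET_ALPHA) -> MetaResult:
    """Set the suppression flag: pooled columns are blanked in reports when
    the heterogeneity test rejects (het_p < ``alpha_het``); per-stratum rows
    are always retained."""
    return replace(result, suppressed=bool(result.het_p < alpha_het))


def analytic_power(maf: float, n: int, beta_sd: float,
                   alpha: float = 0.05) -> float:
    """Power of the two-sided per-allele test for an additive effect.

    ``maf`` is the risk-allele frequency (0 < maf < 1), ``n`` the stratum
    size and ``beta_sd`` the true effect in phenotype-SD units per allele.
    The additive genotype contributes variance 2p(1-p) per allele, giving
    noncentrality ``lambda = n * 2p(1-p) * beta_sd^2`` for the 1-df
    chi-square test.  An effect explaining >= 100% of the phenotype variance
    is an error.
    """
    if not (0.0 < maf < 1.0):
        raise ValueError(f"maf must be in (0, 1), got {maf}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    var_g = 2.0 * maf * (1.0 - maf)
    explained = var_g * beta_sd ** 2
    if explained >= 1.0:
        raise ValueError("effect would explain >= 100% of trait variance")
    lam = n * explained
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))
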