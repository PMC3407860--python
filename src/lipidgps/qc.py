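"""SNP and individual quality control and SNP-selection filters.

Mirrors a standard candidate-SNP QC pipeline: per-SNP call-rate filter
(strict > 95%), per-individual missingness filter (strict <= 10% retained),
Hardy-Weinberg equilibrium screening by the log-likelihood-ratio (G) test
with exclusion at p < 0.001, and the GWAS-based selection filters
(discovery size, genome-wide significance, LD pruning at r^2 >= 0.3, at most
three SNPs per gene).  The filter order is fixed — call rate, then
individual missingness, then HWE — because the earlier filters change the
counts the later ones see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ANALYSIS_STRATA, GenotypeMatrix, SnpAnnotation

DEFAULT_CALL_RATE = 0.95
DEFAULT_INDIVIDUAL_MISSINGNESS = 0.10
DEFAULT_HWE_ALPHA = 0.001
DEFAULT_LD_R2 = 0.3
DEFAULT_MAX_SNPS_PER_GENE = 3
GWAS_P_THRESHOLD = 5e-8
GWAS_MIN_DISCOVERY_N = 1000


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg G-test for one SNP's genotype counts in one stratum."""

    rsid: str
    stratum: str
    counts: Tuple[int, int, int]
    g_statistic: float
    p_value: float
    monomorphic: bool = False


@dataclass
class Exclusion:
    entity_id: str
    entity_type: str  # "snp" or "individual"
    reason: str       # "call_rate", "missingness" or "hwe"
    value: float
    threshold: float


@dataclass
class QcReport:
    """Record of every QC exclusion together with the thresholds applied."""

    exclusions: List[Exclusion] = field(default_factory=list)
    thresholds: Dict[str, float] = field(default_factory=dict)

    @property
    def excluded_snps(self) -> List[Exclusion]:
        return [e for e in self.exclusions if e.entity_type == "snp"]

    @property
    def excluded_individuals(self) -> List[Exclusion]:
        return [e for e in self.exclusions if e.entity_type == "individual"]

    def merge(self, other: "QcReport") -> "QcReport":
        merged = QcReport(list(self.exclusions) + list(other.exclusions),
                          {**self.thresholds, **other.thresholds})
        return merged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.entity_id, e.entity_type, e.reason, e.value, e.threshold)
             for e in self.exclusions],
            columns=["entity_id", "entity_type", "reason", "value", "threshold"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def snp_call_rate_filter(gm: GenotypeMatrix,
                         min_rate: float = DEFAULT_CALL_RATE
                         ) -> Tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs whose call rate is not strictly above ``min_rate``."""
    if gm.n_snps == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    rates = gm.call_rate()
    keep = rates > min_rate
    report = QcReport(thresholds={"snp_call_rate": min_rate})
    for rsid, rate in rates[~keep].items():
        report.exclusions.append(
            Exclusion(rsid, "snp", "call_rate", float(rate), min_rate))
    if not keep.any():
        raise ValueError("call-rate filter removed every SNP")
    return gm.subset_snps(rates.index[keep]), report


def individual_missingness_filter(gm: GenotypeMatrix,
                                  max_fraction: float = DEFAULT_INDIVIDUAL_MISSINGNESS
                                  ) -> Tuple[GenotypeMatrix, QcReport]:
    """Drop individuals with genotype missingness strictly above ``max_fraction``.

    Applied after the SNP call-rate filter so missingness is measured over
    the retained SNP panel.
    """
    fractions = gm.individual_missing_fraction()
    keep = fractions <= max_fraction
    report = QcReport(thresholds={"individual_missingness": max_fraction})
    for iid, frac in fractions[~keep].items():
        report.exclusions.append(
            Exclusion(str(iid), "individual", "missingness",
                      float(frac), max_fraction))
    return gm.subset_individuals(fractions.index[keep]), report


def hwe_g_test(counts: Sequence[int], rsid: str = "",
               stratum: str = "") -> HweResult:
    """Likelihood-ratio (G) test of Hardy-Weinberg proportions.

    Given genotype counts (n0, n1, n2) for risk-allele dosage 0/1/2, the
    allele frequency is estimated from the counts, expected counts follow
    the HWE proportions ((1-p)^2, 2p(1-p), p^2), and
    ``G = 2 * sum(O * ln(O/E))`` with the 0*ln(0) = 0 convention is compared
    to a chi-square with 1 df.  A monomorphic SNP yields G = 0, p = 1 and a
    flag rather than an error.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("at least one genotype observation required")
    p_hat = (n1 + 2 * n2) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HweResult(rsid, stratum, (n0, n1, n2), 0.0, 1.0,
                         monomorphic=True)
    expected = n * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat),
                             p_hat ** 2])
    observed = np.array([n0, n1, n2], dtype=float)
    nz = observed > 0
    g = 2.0 * float(np.sum(observed[nz] * np.log(observed[nz] / expected[nz])))
    g = max(g, 0.0)
    p_value = float(stats.chi2.sf(g, df=1))
    return HweResult(rsid, stratum, (n0, n1, n2), g, max(p_value, 0.0) or 0.0,
                     monomorphic=False)


def hwe_g_statistics(counts: np.ndarray) -> np.ndarray:
    """Vectorised G statistics for an (m, 3) array of genotype counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    p = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
    expected = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p ** 2],
                        axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / expected)
    terms = np.where(counts > 0, terms, 0.0)
    g = 2.0 * terms.sum(axis=1)
    return np.where((p == 0) | (p == 1), 0.0, np.maximum(g, 0.0))


def hwe_exclusion(gm: GenotypeMatrix,
                  ethnicity: Optional[pd.Series] = None,
                  alpha: float = DEFAULT_HWE_ALPHA,
                  mode: str = "largest",
                  ) -> Tuple[GenotypeMatrix, QcReport, List[HweResult]]:
    """Remove SNPs deviating from Hardy-Weinberg equilibrium at ``p < alpha``.

    ``mode`` picks the stratum in which HWE is tested: "largest" (default)
    tests in the biggest analysis stratum, because deviation in a pooled
    multi-ethnic sample can be a stratification artifact; "pooled" tests all
    individuals together; "any" tests every analysis stratum and excludes on
    any failure.
    """
    if ethnicity is None:
        ethnicity = pd.Series("White", index=gm.dosage.index)
    ethnicity = ethnicity.reindex(gm.dosage.index)
    analysis_mask = ethnicity.isin(ANALYSIS_STRATA)
    if mode == "pooled":
        strata = [("pooled", analysis_mask)]
    elif mode == "largest":
        sizes = ethnicity[analysis_mask].value_counts()
        if sizes.empty:
            raise ValueError("no individuals in any analysis stratum")
        label = sizes.idxmax()
        strata = [(label, ethnicity == label)]
    elif mode == "any":
        strata = [(label, ethnicity == label)
                  for label in ANALYSIS_STRATA
                  if (ethnicity == label).any()]
    else:
        raise ValueError(f"unknown HWE mode {mode!r}")

    report = QcReport(thresholds={"hwe_alpha": alpha})
    results: List[HweResult] = []
    failed = set()
    for label, mask in strata:
        for rsid in gm.snp_ids:
            res = hwe_g_test(gm.genotype_counts(rsid, mask), rsid, label)
            results.append(res)
            if not res.monomorphic and res.p_value < alpha:
                if rsid not in failed:
                    failed.add(rsid)
                    report.exclusions.append(
                        Exclusion(rsid, "snp", "hwe", res.p_value, alpha))
    keep = [s for s in gm.snp_ids if s not in failed]
    return gm.subset_snps(keep), report, results


def _ld_r2(ld: Optional[Mapping], a: str, b: str) -> float:
    if ld is None:
        return 0.0
    for key in ((a, b), (b, a), frozenset((a, b))):
        if key in ld:
            return float(ld[key])
    return 0.0


def select_snps(annotations: Sequence[SnpAnnotation],
                ld: Optional[Mapping] = None,
                max_gwas_p: float = GWAS_P_THRESHOLD,
                min_discovery_n: int = GWAS_MIN_DISCOVERY_N,
                max_r2: float = DEFAULT_LD_R2,
                max_per_gene: int = DEFAULT_MAX_SNPS_PER_GENE,
                ) -> List[SnpAnnotation]:
    """Apply the GWAS-based SNP selection filters.

    Keeps SNPs reaching genome-wide significance (gwas_p < ``max_gwas_p``)
    from discovery samples of at least ``min_discovery_n``; within every
    pair in linkage disequilibrium at r^2 >= ``max_r2`` the SNP with the
    smaller GWAS p is kept (ties broken toward the lexicographically smaller
    rsid); finally at most ``max_per_gene`` SNPs per gene are retained,
    keeping the smallest GWAS p-values.  Absent LD pairs count as r^2 = 0.
    """
    kept = [a for a in annotations
            if a.gwas_p < max_gwas_p and a.gwas_discovery_n >= min_discovery_n]

    def rank(a: SnpAnnotation):
        return (a.gwas_p, a.rsid)

    # pairwise LD pruning: repeatedly drop the weaker member of the worst pair
    changed = True
    while changed:
        changed = False
        kept_sorted = sorted(kept, key=rank)
        for i, a in enumerate(kept_sorted):
            for b in kept_sorted[i + 1:]:
                if _ld_r2(ld, a.rsid, b.rsid) >= max_r2:
                    kept.remove(b)  # b has the larger (p, rsid) rank
                    changed = True
                    break
            if changed:
                break

    by_gene: Dict[str, List[SnpAnnotation]] = {}
    for a in sorted(kept, key=rank):
        by_gene.setdefault(a.gene, []).append(a)
    selected = [a for gene_snps in by_gene.values()
                for a in gene_snps[:max_per_gene]]
    order = {a.rsid: i for i, a in enumerate(annotations)}
    return sorted(selected, key=lambda a: order[a.rsid])
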