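"""Trait-specific genetic predisposition scores (GPS).

A GPS is the unweighted count of risk alleles an individual carries across
the SNP panel of one trait.  Missing genotypes are mean-imputed per SNP —
by default within ethnic stratum, since the analysis is stratified and a
cohort-wide mean would leak allele-frequency differences between strata —
so imputed scores can be fractional.  The apo B analysis uses the LDL-C
panel and the apo A-I analysis the HDL-C panel.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_model import (
    GPS_SOURCE_TRAIT,
    SCORED_TRAITS,
    GenotypeMatrix,
    SnpAnnotation,
    TraitName,
)

#: Default HDL-C GPS grouping: <=11, 12-13, 14-15, >=16 risk alleles.
#: Half-integer edges make fractional (imputed) scores fall into the
#: interval their integer neighbours would print.
HDL_GPS_BIN_EDGES = (11.5, 13.5, 15.5)


def impute_missing_dosage(gm: GenotypeMatrix,
                          strata: Optional[pd.Series] = None) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean of the observed dosages.

    With ``strata`` given (individual id -> stratum label), means are taken
    within stratum; otherwise cohort-wide.  A SNP with no observed genotype
    in some stratum is an error naming the SNP and stratum.
    """
    df = gm.dosage.copy()
    if strata is None:
        groups = [("all", pd.Series(True, index=df.index))]
    else:
        strata = strata.reindex(df.index)
        groups = [(label, strata == label) for label in strata.dropna().unique()]
    for label, mask in groups:
        block = df.loc[mask]
        means = block.mean(axis=0, skipna=True)
        empty = means[means.isna()].index
        if len(empty):
            raise ValueError(
                f"SNP {empty[0]} has no observed genotypes in stratum {label}")
        df.loc[mask] = block.fillna(means)
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValueError(f"individuals outside all strata left unimputed for "
                         f"SNPs {missing}")
    return GenotypeMatrix(df, imputed=True)


def trait_snp_panel(annotations: Sequence[SnpAnnotation],
                    trait: TraitName) -> list:
    """rsIDs contributing to a trait's GPS (apo traits map to LDL/HDL panels)."""
    source = GPS_SOURCE_TRAIT[TraitName(trait)]
    return [a.rsid for a in annotations if source in a.traits]


def compute_gps(gm: GenotypeMatrix, annotations: Sequence[SnpAnnotation],
                trait: TraitName) -> Tuple[pd.Series, int]:
    """Sum of (possibly imputed) risk-allele dosages over a trait's panel.

    Returns the per-individual score and the panel size k; scores lie in
    [0, 2k].  No per-SNP weighting is applied.
    """
    panel = trait_snp_panel(annotations, trait)
    panel = [r for r in panel if r in gm.dosage.columns]
    if not panel:
        raise ValueError(f"no SNPs available for trait {TraitName(trait).value}")
    scores = gm.dosage[panel].sum(axis=1)
    scores.name = f"gps_{TraitName(trait).value.lower()}"
    return scores, len(panel)


def compute_gps_table(gm: GenotypeMatrix,
                      annotations: Sequence[SnpAnnotation],
                      strata: Optional[pd.Series] = None,
                      impute: bool = True) -> pd.DataFrame:
    """GPS table for all scored traits with panel sizes.

    Columns: gps_tc, gps_ldl, gps_hdl, gps_tg and k_tc, k_ldl, k_hdl, k_tg.
    Missing dosages are mean-imputed first (within stratum when ``strata``
    is provided).
    """
    if impute and gm.dosage.isna().any().any():
        gm = impute_missing_dosage(gm, strata)
    out = pd.DataFrame(index=gm.dosage.index)
    for trait in SCORED_TRAITS:
        try:
            scores, k = compute_gps(gm, annotations, trait)
        except ValueError:
            continue
        out[f"gps_{trait.value.lower()}"] = scores
        out[f"k_{trait.value.lower()}"] = k
    return out


def bin_gps(scores, edges: Sequence[float] = HDL_GPS_BIN_EDGES):
    """Assign scores to 1-based bins defined by strictly increasing edges.

    With the default HDL scheme, integer scores map exactly to the printed
    groups (<=11 -> 1, 12-13 -> 2, 14-15 -> 3, >=16 -> 4) and fractional
    imputed scores fall into the enclosing interval.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be non-empty and strictly increasing")
    arr = np.asarray(scores, dtype=float)
    bins = np.searchsorted(edges, arr, side="left") + 1
    if isinstance(scores, pd.Series):
        return pd.Series(bins, index=scores.index, name="gps_bin")
    if np.isscalar(scores):
        return int(bins)
    return bins
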