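"""Configuration-driven orchestration: inputs (or simulation) to reports.

``run_pipeline`` executes the full chain — read or simulate, QC (call rate,
individual missingness, Hardy-Weinberg), stratum-wise mean imputation and
GPS construction, per-stratum baseline/change associations for every GPS
(and optionally every SNP), diet-by-predictor interaction tests, and
DerSimonian-Laird pooling across strata with heterogeneity gating — and
writes tidy TSV reports plus a plain-text run log recording thresholds,
seeds, exclusions and the total number of hypothesis tests performed.

``meta_from_summaries`` is a meta-only entry point that pools an externally
supplied table of per-stratum (effect, SE) summaries, so published
stratified results can be combined without individual-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .association import (
    RegressionResult,
    baseline_association,
    change_association,
    interaction_test,
    results_to_frame,
)
from .data_model import (
    ANALYSIS_STRATA,
    GPS_SOURCE_TRAIT,
    CohortTable,
    GenotypeMatrix,
    SnpAnnotation,
    TraitName,
    baseline_column,
    final_column,
)
from .gps import (
    HDL_GPS_BIN_EDGES,
    bin_gps,
    compute_gps_table,
    impute_missing_dosage,
    trait_snp_panel,
)
from .meta import MetaResult, dl_meta
from .qc import (
    DEFAULT_CALL_RATE,
    DEFAULT_HWE_ALPHA,
    DEFAULT_INDIVIDUAL_MISSINGNESS,
    QcReport,
    hwe_exclusion,
    individual_missingness_filter,
    snp_call_rate_filter,
)
from .simulate import SimulationConfig, annotations_from_config, simulate_cohort

DEFAULT_TRAITS = (TraitName.TC, TraitName.LDL, TraitName.HDL, TraitName.TG,
                  TraitName.APOB, TraitName.APOA1)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Exactly one of ``simulation`` or the three input paths must be given.
    """

    output_dir: Path
    simulation: Optional[SimulationConfig] = None
    annotation_path: Optional[Path] = None
    genotype_path: Optional[Path] = None
    phenotype_path: Optional[Path] = None
    traits: Sequence[TraitName] = DEFAULT_TRAITS
    strata: Sequence[str] = ANALYSIS_STRATA
    per_snp: bool = True
    interactions: bool = True
    call_rate: float = DEFAULT_CALL_RATE
    individual_missingness: float = DEFAULT_INDIVIDUAL_MISSINGNESS
    hwe_alpha: float = DEFAULT_HWE_ALPHA
    hwe_mode: str = "largest"
    meta_alpha_het: float = 0.05
    gps_bin_edges: Sequence[float] = HDL_GPS_BIN_EDGES

    def __post_init__(self) -> None:
        have_sim = self.simulation is not None
        have_paths = all(p is not None for p in
                         (self.annotation_path, self.genotype_path,
                          self.phenotype_path))
        if have_sim == have_paths:
            raise ValueError("provide either a simulation config or all three "
                             "input paths (annotation, genotypes, phenotypes)")
        self.output_dir = Path(self.output_dir)


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run (also written to output_dir)."""

    annotations: List[SnpAnnotation]
    genotypes: GenotypeMatrix
    cohort: CohortTable
    qc_report: QcReport
    gps_table: pd.DataFrame
    stratum_results: pd.DataFrame
    meta_results: pd.DataFrame
    interaction_results: pd.DataFrame
    n_tests: int
    log_lines: List[str] = field(default_factory=list)


def _log(lines: List[str], msg: str) -> None:
    lines.append(msg)


def _gather_inputs(config: PipelineConfig, log: List[str]
                   ) -> Tuple[List[SnpAnnotation], GenotypeMatrix, CohortTable]:
    if config.simulation is not None:
        sim = config.simulation
        _log(log, f"simulated cohort: seed={sim.seed}, "
                  f"strata={[(s.ethnicity, s.n) for s in sim.strata]}, "
                  f"snps={len(sim.snps)}")
        gm, cohort = simulate_cohort(sim)
        anns = annotations_from_config(sim)
        out = config.output_dir
        lio.write_snp_annotation(anns, out / "annotation.tsv")
        lio.write_genotypes(gm, out / "genotypes.tsv")
        lio.write_phenotypes(cohort, out / "phenotypes.tsv")
        return anns, gm, cohort
    anns = lio.read_snp_annotation(config.annotation_path)
    gm = lio.read_genotypes(config.genotype_path, anns)
    cohort = lio.read_phenotypes(config.phenotype_path)
    _log(log, f"inputs: {len(anns)} SNPs annotated, "
              f"{gm.n_individuals} individuals genotyped, "
              f"{len(cohort.ids)} phenotyped")
    return anns, gm, cohort


def _run_qc(config: PipelineConfig, gm: GenotypeMatrix, cohort: CohortTable,
            log: List[str]) -> Tuple[GenotypeMatrix, QcReport]:
    gm, report = snp_call_rate_filter(gm, config.call_rate)
    _log(log, f"call-rate filter (> {config.call_rate}): "
              f"{len(report.excluded_snps)} SNP(s) removed")
    gm, rep2 = individual_missingness_filter(gm, config.individual_missingness)
    _log(log, f"individual-missingness filter (> "
              f"{config.individual_missingness}): "
              f"{len(rep2.excluded_individuals)} individual(s) removed")
    report = report.merge(rep2)
    ethnicity = cohort.table["ethnicity"].reindex(gm.dosage.index)
    gm, rep3, _ = hwe_exclusion(gm, ethnicity, config.hwe_alpha,
                                config.hwe_mode)
    _log(log, f"HWE filter (p < {config.hwe_alpha}, mode={config.hwe_mode}): "
              f"{len(rep3.excluded_snps)} SNP(s) removed")
    return gm, report.merge(rep3)


def _meta_rows(stratum_df: pd.DataFrame, alpha_het: float
               ) -> pd.DataFrame:
    rows = []
    keys = ["trait", "predictor", "model"]
    for (trait, predictor, model), grp in stratum_df.groupby(keys, sort=False):
        grp = grp[grp["estimable"] & grp["se"].gt(0)]
        if grp.empty:
            continue
        res = dl_meta(list(zip(grp["effect"], grp["se"])), alpha_het)
        row = {"trait": trait, "predictor": predictor, "model": model,
               **res.as_row()}
        if res.suppressed:
            # reporting rule: blank the pooled columns, keep diagnostics
            for col in ("effect", "se", "ci_low", "ci_high", "p"):
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write reports under ``output_dir``."""
    config.output_dir.mkdir(parents=True, exist_ok=True)
    log: List[str] = []
    anns, gm, cohort = _gather_inputs(config, log)

    gm, qc_report = _run_qc(config, gm, cohort, log)
    kept_ids = [i for i in gm.individual_ids if i in cohort.table.index]
    cohort = cohort.subset_individuals(kept_ids)
    gm = gm.subset_individuals(kept_ids)
    anns = [a for a in anns if a.rsid in set(gm.snp_ids)]

    strata_series = cohort.table["ethnicity"]
    gps_table = compute_gps_table(gm, anns, strata=strata_series)
    _log(log, f"GPS panels: " + ", ".join(
        f"{c[2:].upper()}={int(gps_table[f'k_{c[2:]}'].iloc[0])} SNPs"
        for c in ("k_tc", "k_ldl", "k_hdl", "k_tg") if c in gps_table))

    results: List[RegressionResult] = []
    inter_rows: List[dict] = []
    n_tests = 0
    present_strata = [s for s in config.strata
                      if (strata_series == s).any()]
    gm_imp = (impute_missing_dosage(gm, strata_series)
              if gm.dosage.isna().any().any() else gm)

    for trait in config.traits:
        trait = TraitName(trait)
        source = GPS_SOURCE_TRAIT[trait]
        gps_col = f"gps_{source.value.lower()}"
        if gps_col not in gps_table:
            continue
        predictors = [(f"GPS_{source.value}", gps_table[gps_col])]
        if config.per_snp:
            for rsid in trait_snp_panel(anns, trait):
                if rsid in gm_imp.dosage.columns:
                    predictors.append((rsid, gm_imp.dosage[rsid]))
        for name, series in predictors:
            for stratum in present_strata:
                for model_fn, model in ((baseline_association, "baseline"),
                                        (change_association, "change")):
                    res = model_fn(cohort, series, trait, stratum,
                                   predictor_name=name)
                    results.append(res)
                    n_tests += int(res.estimable)
                if config.interactions:
                    try:
                        pvals = interaction_test(cohort, series, trait,
                                                 stratum, factor="diet",
                                                 predictor_name=name)
                    except ValueError:
                        continue
                    for level, p in pvals.items():
                        inter_rows.append({"trait": trait.value,
                                           "predictor": name,
                                           "stratum": stratum,
                                           "factor": "diet",
                                           "level": level, "p": p})
                        n_tests += int(np.isfinite(p))

    stratum_df = results_to_frame(results)
    meta_df = _meta_rows(stratum_df, config.meta_alpha_het)
    inter_df = pd.DataFrame(inter_rows)
    _log(log, f"models fitted: {len(stratum_df)} stratum results, "
              f"{len(meta_df)} pooled; hypothesis tests performed: {n_tests} "
              "(no multiple-testing correction applied)")

    out = config.output_dir
    qc_report.write(out / "qc_report.tsv")
    gps_table.to_csv(out / "gps.tsv", sep="\t", na_rep="NA")
    stratum_df.to_csv(out / "stratum_results.tsv", sep="\t", index=False,
                      na_rep="NA")
    meta_df.to_csv(out / "meta_results.tsv", sep="\t", index=False,
                   na_rep="NA")
    if not inter_df.empty:
        inter_df.to_csv(out / "interaction_results.tsv", sep="\t",
                        index=False, na_rep="NA")
    (out / "run.log").write_text("\n".join(log) + "\n")

    return ReportBundle(annotations=anns, genotypes=gm, cohort=cohort,
                        qc_report=qc_report, gps_table=gps_table,
                        stratum_results=stratum_df, meta_results=meta_df,
                        interaction_results=inter_df, n_tests=n_tests,
                        log_lines=log)


def meta_from_summaries(summaries: pd.DataFrame,
                        alpha_het: float = 0.05) -> pd.DataFrame:
    """Pool a table of per-stratum summaries without individual-level data.

    ``summaries`` has columns (label, stratum, effect, se); one pooled row
    per label is returned with the DL effect, 95% CI, p, heterogeneity p
    and suppression flag.  This lets published stratified tables be
    re-pooled directly.
    """
    required = {"label", "stratum", "effect", "se"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    rows = []
    for label, grp in summaries.groupby("label", sort=False):
        res = dl_meta(list(zip(grp["effect"].astype(float),
                               grp["se"].astype(float))), alpha_het)
        rows.append({"label": label, **res.as_row()})
    return pd.DataFrame(rows)


def summarize_gps_bins(cohort: CohortTable, gps: pd.Series, trait: TraitName,
                       edges: Sequence[float] = HDL_GPS_BIN_EDGES,
                       by_diet: bool = False) -> pd.DataFrame:
    """Per-bin n, mean and SE of a trait before and after intervention.

    Bins partition all scores; an empty bin is reported with n=0 and no
    mean, and a single-individual bin has an undefined (NaN) SE.
    """
    trait = TraitName(trait)
    bins = bin_gps(gps, edges)
    n_bins = len(edges) + 1
    df = cohort.table
    groups = [("all", pd.Series(True, index=df.index))]
    if by_diet:
        groups = [(d, df["diet"] == d) for d in ("REF", "MUFA", "LF")]
    rows = []
    for group_label, mask in groups:
        for b in range(1, n_bins + 1):
            members = df.index[mask & (bins.reindex(df.index) == b)]
            for when, col in (("baseline", baseline_column(trait)),
                              ("final", final_column(trait))):
                vals = df.loc[members, col].dropna()
                n = len(vals)
                rows.append({
                    "group": group_label, "bin": b, "timepoint": when,
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "se": float(vals.std(ddof=1) / np.sqrt(n))
                          if n > 1 else np.nan,
                })
    return pd.DataFrame(rows)


def plot_gps_distribution(gps: pd.Series, values: pd.Series, path,
                          bin_width: int = 1) -> None:
    """Histogram of GPS counts with per-score mean +/- SE of a trait overlaid
    on a secondary axis (optional figure output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.round(gps).astype(int)
    levels = np.arange(scores.min(), scores.max() + 1, bin_width)
    counts = [(scores == s).sum() for s in levels]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(levels, counts, color="lightgrey", edgecolor="grey")
    ax.set_xlabel("risk alleles (GPS)")
    ax.set_ylabel("individuals")
    ax2 = ax.twinx()
    means, ses = [], []
    for s in levels:
        v = values[scores == s].dropna()
        means.append(v.mean() if len(v) else np.nan)
        ses.append(v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan)
    ax2.errorbar(levels, means, yerr=ses, fmt="s", color="black", capsize=3)
    ax2.set_ylabel(values.name or "trait")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
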