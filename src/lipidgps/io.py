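"""Readers and writers for the annotation, genotype and phenotype tables.

All tabular interchange is plain TSV/CSV.  Missing genotypes are written as
"NA"; both "NA" and the empty cell are accepted on read.  Genotype cells may
hold dosage digits (0/1/2) or unphased allele pairs such as "A/G", which are
converted to risk-allele dosage using the annotation.  Dosages can also be
imported from an (uncompressed or bgzipped) VCF via cyvcf2, orienting the GT
field to the annotated risk allele.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CohortTable,
    GenotypeMatrix,
    SnpAnnotation,
    TraitName,
    encode_dosage,
)

MISSING_TOKEN = "NA"

_ANNOTATION_COLUMNS = ["rsid", "gene", "risk_allele", "other_allele", "traits",
                       "gwas_discovery_n", "gwas_p"]
_RAF_COLUMNS = {"raf_white": "White", "raf_asian": "S_SE_Asian",
                "raf_black": "Black_African"}


def read_snp_annotation(path) -> List[SnpAnnotation]:
    """Read a SNP annotation TSV into validated records.

    Duplicate rsids and invalid alleles are hard errors naming the offending
    row.  The optional per-ethnicity risk-allele frequency columns
    (raf_white, raf_asian, raf_black) populate ``raf_by_ethnicity``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate rsid(s) in annotation: {sorted(set(dup))}")
    records = []
    for i, row in df.iterrows():
        raf = {}
        for col, eth in _RAF_COLUMNS.items():
            if col in df.columns and row[col] not in ("", MISSING_TOKEN):
                raf[eth] = float(row[col])
        try:
            records.append(SnpAnnotation(
                rsid=row["rsid"],
                gene=row["gene"],
                risk_allele=row["risk_allele"],
                other_allele=row["other_allele"],
                traits=frozenset(TraitName(t.strip())
                                 for t in row["traits"].split(",") if t.strip()),
                gwas_discovery_n=int(row["gwas_discovery_n"]),
                gwas_p=float(row["gwas_p"]),
                raf_by_ethnicity=raf or None,
            ))
        except ValueError as exc:
            raise ValueError(f"annotation row {i} ({row['rsid']!r}): {exc}") from exc
    return records


def write_snp_annotation(annotations: Sequence[SnpAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        row = {
            "rsid": ann.rsid,
            "gene": ann.gene,
            "risk_allele": ann.risk_allele,
            "other_allele": ann.other_allele,
            "traits": ",".join(sorted(t.value for t in ann.traits)),
            "gwas_discovery_n": ann.gwas_discovery_n,
            "gwas_p": repr(ann.gwas_p),
        }
        raf = ann.raf_by_ethnicity or {}
        for col, eth in _RAF_COLUMNS.items():
            row[col] = repr(raf[eth]) if eth in raf else MISSING_TOKEN
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_genotype_cell(cell: str, ann: SnpAnnotation) -> float:
    cell = cell.strip()
    if cell in ("", MISSING_TOKEN):
        return np.nan
    if cell in ("0", "1", "2"):
        return float(cell)
    for sep in ("/", "|"):
        if sep in cell:
            pair = cell.split(sep)
            if len(pair) != 2:
                raise ValueError(f"malformed allele pair {cell!r}")
            return float(encode_dosage(pair, ann))
    raise ValueError(f"cannot parse genotype cell {cell!r}")


def read_genotypes(path, annotations: Sequence[SnpAnnotation]) -> GenotypeMatrix:
    """Read a genotype TSV (first column individual id, then one rsID column
    per SNP) into a risk-allele dosage matrix.

    Columns not present in the annotation are reported via a warning and
    dropped.  Allele pairs containing a base foreign to the SNP's annotated
    alleles are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    by_rsid = {a.rsid: a for a in annotations}
    unknown = [c for c in df.columns if c not in by_rsid]
    if unknown:
        warnings.warn(f"dropping {len(unknown)} genotype column(s) not in the "
                      f"annotation: {unknown}")
        df = df.drop(columns=unknown)
    out = {}
    for rsid in df.columns:
        ann = by_rsid[rsid]
        try:
            out[rsid] = [_parse_genotype_cell(c, ann) for c in df[rsid]]
        except ValueError as exc:
            raise ValueError(f"SNP {rsid}: {exc}") from exc
    dosage = pd.DataFrame(out, index=df.index.astype(str))
    dosage.index.name = "id"
    return GenotypeMatrix(dosage)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.dosage.copy()
    if not gm.imputed:
        # keep integral dosages as 0/1/2, not 0.0/1.0/2.0
        df = df.astype(object).where(df.isna(), df.astype("Int64"))
    df.index.name = df.index.name or "id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_genotypes_vcf(path, annotations: Sequence[SnpAnnotation],
                       sample_ids: Optional[Iterable[str]] = None) -> GenotypeMatrix:
    """Import risk-allele dosages from a VCF's GT field.

    Records are matched to annotations by ID; REF/ALT must equal the
    annotated allele pair (no strand flipping).  Genotypes are oriented so
    that the dosage counts the annotated risk allele; half-missing or
    missing GT becomes NaN.
    """
    from cyvcf2 import VCF

    by_rsid = {a.rsid: a for a in annotations}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns = {}
    for variant in vcf:
        ann = by_rsid.get(variant.ID)
        if ann is None:
            continue
        alts = variant.ALT or []
        if len(alts) != 1:
            raise ValueError(f"{variant.ID}: expected a biallelic record")
        if {variant.REF, alts[0]} != ann.alleles:
            raise ValueError(
                f"{variant.ID}: VCF alleles {variant.REF}/{alts[0]} do not "
                f"match annotation {ann.risk_allele}/{ann.other_allele}")
        # gt_types/gt counts ALT copies; flip if the risk allele is REF
        alt_dosage = np.asarray(variant.gt_types, dtype=float)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.select([alt_dosage == 0, alt_dosage == 1, alt_dosage == 3],
                           [0.0, 1.0, 2.0], default=np.nan)
        if ann.risk_allele == variant.REF:
            dosage = 2.0 - dosage
        columns[variant.ID] = dosage
    df = pd.DataFrame(columns, index=pd.Index(samples, name="id"))
    if sample_ids is not None:
        df = df.loc[list(sample_ids)]
    return GenotypeMatrix(df)


def read_phenotypes(path, sep: Optional[str] = None,
                    derive_ldl: bool = True) -> CohortTable:
    """Read a phenotype CSV/TSV into a :class:`CohortTable`.

    The separator is sniffed from the extension unless given.  When LDL
    columns are absent (or ``derive_ldl``), LDL-C is computed by the
    Friedewald rule.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN, ""])
    df["id"] = df["id"].astype(str)
    cohort = CohortTable(df)
    if derive_ldl or "ldl_baseline" not in cohort.table.columns:
        cohort = cohort.derive_ldl()
    return cohort


def write_phenotypes(cohort: CohortTable, path, sep: str = "\t") -> None:
    cohort.table.to_csv(path, sep=sep, na_rep=MISSING_TOKEN)
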