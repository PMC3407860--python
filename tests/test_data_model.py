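"""Domain types, dosage coding, Friedewald rule and file round-trips."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidgps.data_model import (
    UNDEFINED,
    CohortTable,
    GenotypeMatrix,
    SnpAnnotation,
    TraitName,
    decode_dosage,
    encode_dosage,
    friedewald_ldl,
    log_tg,
)
from lipidgps.io import (
    read_genotypes,
    read_genotypes_vcf,
    read_snp_annotation,
    write_genotypes,
    write_snp_annotation,
)
from lipidgps.simulate import annotations_from_config, default_config


class TestSnpAnnotation:
    def test_minimal_record_valid(self):
        ann = SnpAnnotation("rs1", "G1", "A", "G", frozenset({TraitName.HDL}))
        assert ann.alleles == {"A", "G"}

    @pytest.mark.parametrize("kwargs,match", [
        (dict(risk_allele="X"), "not one of A,C,G,T"),
        (dict(other_allele="A"), "identical"),
        (dict(traits=frozenset()), "non-empty"),
        (dict(gwas_p=0.0), "gwas_p"),
        (dict(gwas_discovery_n=0), "positive"),
        (dict(raf_by_ethnicity={"White": 1.2}), "out of"),
    ])
    def test_invalid_records_rejected(self, kwargs, match):
        base = dict(rsid="rs1", gene="G1", risk_allele="A", other_allele="G",
                    traits=frozenset({TraitName.HDL}))
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            SnpAnnotation(**base)


class TestDosageCoding:
    def test_exhaustive_unordered_pairs(self, annotations):
        ann = annotations[0]  # risk A, other G
        outcomes = {encode_dosage(pair, ann)
                    for pair in itertools.product("AG", repeat=2)}
        assert outcomes == {0, 1, 2}
        assert encode_dosage(("A", "A"), ann) == 2
        assert encode_dosage(("G", "G"), ann) == 0

    def test_order_insensitive(self, annotations):
        ann = annotations[0]
        assert encode_dosage(("A", "G"), ann) == encode_dosage(("G", "A"), ann) == 1

    def test_foreign_allele_rejected(self, annotations):
        with pytest.raises(ValueError, match="rs1.*'T'"):
            encode_dosage(("A", "T"), annotations[0])

    def test_decode_is_inverse(self, annotations):
        ann = annotations[1]
        for d in (0, 1, 2):
            assert encode_dosage(decode_dosage(d, ann), ann) == d


class TestFriedewald:
    def test_cohort_mean_values(self):
        # direct evaluation: 5.74 - 1.41 - 1.41/2.2
        assert friedewald_ldl(5.74, 1.41, 1.41) == pytest.approx(
            3.6890909090909, abs=1e-10)

    def test_tg_ceiling_is_excluded(self):
        assert friedewald_ldl(5.0, 1.3, 4.49) is UNDEFINED
        assert friedewald_ldl(5.0, 1.3, 4.4899) is not UNDEFINED

    def test_degenerate_near_zero(self):
        assert friedewald_ldl(2.0, 2.0, 1e-9) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [(0.0, 1.0, 1.0), (5.0, -1.0, 1.0),
                                     (5.0, 1.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            friedewald_ldl(*bad)

    @settings(max_examples=50, deadline=None)
    @given(tc=st.floats(3.0, 9.0), hdl=st.floats(0.5, 2.5),
           tg=st.floats(0.3, 4.0), eps=st.floats(0.01, 0.3))
    def test_monotonicity(self, tc, hdl, tg, eps):
        base = friedewald_ldl(tc, hdl, tg)
        assert friedewald_ldl(tc + eps, hdl, tg) > base
        assert friedewald_ldl(tc, hdl + eps, tg) < base
        if tg + eps < 4.49:
            assert friedewald_ldl(tc, hdl, tg + eps) < base


class TestLogTg:
    def test_known_values(self):
        assert log_tg(1.0) == 0.0
        assert log_tg(math.e) == pytest.approx(1.0)
        assert log_tg(1.41) == pytest.approx(0.3435897, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_tg(0.0)


class TestAnnotationIo:
    def test_single_row_file(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("rsid\tgene\trisk_allele\tother_allele\ttraits\t"
                        "gwas_discovery_n\tgwas_p\n"
                        "rs1\tCETP\tA\tG\tHDL\t20000\t1e-12\n")
        (ann,) = read_snp_annotation(path)
        assert ann.rsid == "rs1" and ann.traits == {TraitName.HDL}

    def test_invalid_allele_names_row(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("rsid\tgene\trisk_allele\tother_allele\ttraits\t"
                        "gwas_discovery_n\tgwas_p\n"
                        "rsbad\tCETP\tX\tG\tHDL\t20000\t1e-12\n")
        with pytest.raises(ValueError, match="rsbad"):
            read_snp_annotation(path)

    def test_duplicate_rsid_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        row = "rs1\tCETP\tA\tG\tHDL\t20000\t1e-12\n"
        path.write_text("rsid\tgene\trisk_allele\tother_allele\ttraits\t"
                        "gwas_discovery_n\tgwas_p\n" + row + row)
        with pytest.raises(ValueError, match="duplicate"):
            read_snp_annotation(path)

    def test_roundtrip_of_full_panel(self, tmp_path):
        # the default simulated panel has 39 SNPs with per-stratum frequencies
        anns = annotations_from_config(default_config())
        path = tmp_path / "panel.tsv"
        write_snp_annotation(anns, path)
        assert read_snp_annotation(path) == anns


class TestGenotypeIo:
    def _write(self, tmp_path, body):
        path = tmp_path / "geno.tsv"
        path.write_text("id\trs1\trs2\n" + body)
        return path

    def test_allele_pairs_and_dosages(self, tmp_path, annotations):
        path = self._write(tmp_path, "i1\tA/A\t1\ni2\tG/G\tNA\ni3\tA/G\t\n")
        gm = read_genotypes(path, annotations)
        assert gm.dosage.loc["i1", "rs1"] == 2      # homozygous risk
        assert gm.dosage.loc["i2", "rs1"] == 0      # homozygous non-risk
        assert gm.dosage.loc["i3", "rs1"] == 1
        assert np.isnan(gm.dosage.loc["i2", "rs2"])
        assert np.isnan(gm.dosage.loc["i3", "rs2"])

    def test_foreign_allele_in_pair_rejected(self, tmp_path, annotations):
        path = self._write(tmp_path, "i1\tA/T\t1\n")
        with pytest.raises(ValueError, match="rs1"):
            read_genotypes(path, annotations)

    def test_unknown_column_dropped_with_warning(self, tmp_path, annotations):
        path = tmp_path / "geno.tsv"
        path.write_text("id\trs1\trs999\ni1\t1\t2\n")
        with pytest.warns(UserWarning, match="rs999"):
            gm = read_genotypes(path, annotations)
        assert gm.snp_ids == ["rs1"]

    def test_write_read_roundtrip(self, tmp_path, annotations, tiny_genotypes):
        path = tmp_path / "geno.tsv"
        write_genotypes(tiny_genotypes, path)
        gm2 = read_genotypes(path, annotations)
        pd.testing.assert_frame_equal(gm2.dosage, tiny_genotypes.dosage,
                                      check_names=False)

    def test_matrix_invariants(self):
        with pytest.raises(ValueError, match="0, 1 or 2"):
            GenotypeMatrix(pd.DataFrame({"rs1": [0.5]}, index=["i1"]))
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(pd.DataFrame({"rs1": [0, 1]}, index=["i1", "i1"]))


class TestVcfImport:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\ti2\ti3
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.\t0/1
"""

    def test_gt_oriented_to_risk_allele(self, tmp_path, annotations):
        path = tmp_path / "small.vcf"
        path.write_text(self.VCF)
        gm = read_genotypes_vcf(path, annotations)
        # rs1: risk A is ALT -> dosage counts ALT copies
        assert list(gm.dosage["rs1"]) == [0, 1, 2]
        # rs2: risk C is REF -> dosage flipped; missing GT -> NaN
        assert gm.dosage.loc["i1", "rs2"] == 0
        assert np.isnan(gm.dosage.loc["i2", "rs2"])
        assert gm.dosage.loc["i3", "rs2"] == 1


class TestCohortTable:
    def test_validation(self, tiny_cohort_frame):
        cohort = CohortTable(tiny_cohort_frame)
        assert cohort.ids == ["i1", "i2", "i3", "i4"]
        bad = tiny_cohort_frame.copy()
        bad.loc[0, "diet"] = "KETO"
        with pytest.raises(ValueError, match="diet"):
            CohortTable(bad)
        bad2 = tiny_cohort_frame.copy()
        bad2.loc[0, "tc_baseline"] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            CohortTable(bad2)

    def test_derive_ldl_respects_tg_ceiling(self, tiny_cohort_frame):
        cohort = CohortTable(tiny_cohort_frame).derive_ldl()
        ldl = cohort.table["ldl_baseline"]
        assert np.isnan(ldl.loc["i3"])  # TG at the 4.49 ceiling
        expected = (tiny_cohort_frame.set_index("id").loc["i1"])
        assert ldl.loc["i1"] == pytest.approx(
            expected["tc_baseline"] - expected["hdl_baseline"]
            - expected["tg_baseline"] / 2.2)

    def test_gender_numeric_coding(self, tiny_cohort_frame):
        cohort = CohortTable(tiny_cohort_frame)
        assert list(cohort.gender_numeric()) == [1.0, 0.0, 0.0, 1.0]
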