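import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ptvherit as ph
from ptvherit.annotation import (
    ELIGIBLE,
    LAST_EXON,
    NOT_PTV,
    PENULTIMATE_50BP,
    AnnotatedVariant,
    AnnotationError,
    classify_ptv,
    collapse_carriers,
    count_strata,
    eligible_variants,
    read_annotation_tsv,
    read_vcf_genotypes,
)
from ptvherit.core import DataError, Stratum, counts_to_matrix


def V(consequence, exon_index=None, exon_total=None, dist=None, af=None, gene="G1"):
    return AnnotatedVariant("v", gene, consequence, exon_index, exon_total, dist, af)


class TestClassifyPtv:
    def test_internal_stop_gain_is_eligible(self):
        assert classify_ptv(V("stop_gained", 3, 10)) == (True, ELIGIBLE)

    def test_last_exon_frameshift_escapes_nmd(self):
        assert classify_ptv(V("frameshift_variant", 10, 10)) == (False, LAST_EXON)

    def test_penultimate_exon_50bp_boundary_is_half_open(self):
        # 49 bp from the penultimate exon 3' end: excluded; 50 bp: kept
        assert classify_ptv(V("stop_gained", 9, 10, dist=49)) == (False, PENULTIMATE_50BP)
        assert classify_ptv(V("stop_gained", 9, 10, dist=50)) == (True, ELIGIBLE)
        assert classify_ptv(V("stop_gained", 9, 10, dist=0)) == (False, PENULTIMATE_50BP)

    def test_non_truncating_consequences_rejected(self):
        assert classify_ptv(V("missense_variant", 2, 5)) == (False, NOT_PTV)
        assert classify_ptv(V("splice_region_variant")) == (False, NOT_PTV)

    def test_canonical_splice_without_exon_context_is_eligible(self):
        assert classify_ptv(V("splice_donor_variant")) == (True, ELIGIBLE)

    def test_exonic_ptv_without_exon_fields_raises(self):
        with pytest.raises(AnnotationError):
            classify_ptv(V("stop_gained"))
        with pytest.raises(AnnotationError):
            classify_ptv(V("frameshift_variant", 9, 10, dist=None))

    def test_vep_style_compound_terms_and_aliases(self):
        assert classify_ptv(V("stop_gained&NMD_transcript_variant", 2, 8))[0]
        assert classify_ptv(V("frameshift", 2, 8))[0]

    @given(
        exon_total=st.integers(2, 30),
        exon_index=st.integers(1, 30),
        dist=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_pure_function_and_last_exon_rule(self, exon_total, exon_index, dist):
        if exon_index > exon_total:
            return
        v = V("stop_gained", exon_index, exon_total, dist=dist)
        first = classify_ptv(v)
        assert classify_ptv(v) == first  # idempotent / pure
        if exon_index == exon_total:
            assert first == (False, LAST_EXON)
        elif exon_index == exon_total - 1 and dist < 50:
            assert first == (False, PENULTIMATE_50BP)
        else:
            assert first == (True, ELIGIBLE)

    def test_eligible_set_never_grows_when_exon_total_decreases(self):
        # a variant eligible in a shorter transcript is eligible in a longer one
        for total in range(3, 12):
            ok_short, _ = classify_ptv(V("stop_gained", 2, total, dist=100))
            ok_long, _ = classify_ptv(V("stop_gained", 2, total + 1, dist=100))
            assert ok_long or not ok_short

    def test_allele_frequency_ceiling(self):
        variants = [V("stop_gained", 2, 5, af=0.0005), V("stop_gained", 2, 5, af=0.01)]
        kept, report = eligible_variants(variants, max_af=0.001)
        assert len(kept) == 1
        assert (report["reason"] == "allele_freq_above_maximum").sum() == 1


class TestCollapseCarriers:
    def test_matches_brute_force_or_over_variants(self):
        rng = np.random.default_rng(21)
        samples = [f"S{i}" for i in range(5)]
        variants = {f"v{j}": ("GA" if j < 3 else "GB") for j in range(6)}
        gt = pd.DataFrame(
            rng.choice([0, 1, 2, np.nan], p=[0.6, 0.2, 0.1, 0.1], size=(5, 6)),
            index=samples, columns=list(variants),
        )
        out = collapse_carriers(gt, variants)
        wide = out.pivot(index="sample", columns="gene", values="carrier")
        for s in samples:
            for gene, vs in [("GA", ["v0", "v1", "v2"]), ("GB", ["v3", "v4", "v5"])]:
                expect = int(any(gt.loc[s, v] > 0 for v in vs if not np.isnan(gt.loc[s, v])))
                assert wide.loc[s, gene] == expect

    def test_zero_genotypes_and_missing_count_as_non_carrier(self):
        gt = pd.DataFrame({"v0": [0, np.nan], "v1": [0, 0]}, index=["a", "b"])
        out = collapse_carriers(gt, {"v0": "G", "v1": "G"})
        assert (out["carrier"] == 0).all()

    def test_unknown_variants_raise(self):
        gt = pd.DataFrame({"v0": [1]}, index=["a"])
        with pytest.raises(DataError):
            collapse_carriers(gt, {"nope": "G"})


class TestCountStrata:
    def _toy(self):
        pheno = pd.DataFrame(
            {
                "sample": [f"S{i}" for i in range(10)],
                "sex": ["F"] * 6 + ["M"] * 4,
                "case": [1, 1, 0, 0, 0, 0, 1, 0, 0, 0],
            }
        )
        lay = ph.CohortLayout(
            (Stratum("F", 1), Stratum("F", 0), Stratum("M", 1), Stratum("M", 0)),
            (2, 4, 1, 3),
        )
        return pheno, lay

    def test_hand_tallied_counts(self):
        pheno, lay = self._toy()
        carriers = pd.DataFrame(
            {"sample": ["S0", "S2", "S6", "S9"], "gene": ["G"] * 4, "carrier": [1] * 4}
        )
        counts = count_strata(carriers, pheno, lay)
        _, M = counts_to_matrix(counts, lay)
        np.testing.assert_array_equal(M[0], [1, 1, 1, 1])
        assert counts["total"].tolist() == [2, 4, 1, 3]

    def test_all_zero_carriers(self):
        pheno, lay = self._toy()
        carriers = pd.DataFrame(
            {"sample": pheno["sample"], "gene": "G", "carrier": 0}
        )
        counts = count_strata(carriers, pheno, lay)
        assert (counts["carriers"] == 0).all()
        assert counts["total"].sum() == 10

    def test_unknown_sample_raises_with_offender(self):
        pheno, lay = self._toy()
        carriers = pd.DataFrame({"sample": ["GHOST"], "gene": ["G"], "carrier": [1]})
        with pytest.raises(DataError, match="GHOST"):
            count_strata(carriers, pheno, lay)

    def test_sex_specific_layout_has_no_male_case_stratum(self):
        # ovarian-like: males contribute controls only
        pheno = pd.DataFrame(
            {"sample": ["a", "b", "c"], "sex": ["F", "F", "M"], "case": [1, 0, 0]}
        )
        lay = ph.CohortLayout(
            (Stratum("F", 1), Stratum("F", 0), Stratum("M", 0)), (1, 1, 1)
        )
        carriers = pd.DataFrame({"sample": ["c"], "gene": ["G"], "carrier": [1]})
        counts = count_strata(carriers, pheno, lay)
        assert not ((counts["sex"] == "M") & (counts["case"] == 1)).any()


class TestFileInput:
    def test_annotation_tsv_with_column_map(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "ID\tSYMBOL\tCsq\texon_index\texon_total\t"
            "distance_to_penultimate_exon_end\tAF\n"
            "v1\tBRCA2\tstop_gained\t5\t27\tNA\t0.0001\n"
            "v2\tBRCA2\tframeshift_variant\t27\t27\tNA\t0.0001\n"
        )
        variants = read_annotation_tsv(
            path, {"variant": "ID", "gene": "SYMBOL", "consequence": "Csq",
                   "allele_freq": "AF"}
        )
        kept, report = eligible_variants(variants)
        assert [v.variant_id for v in kept] == ["v1"]
        assert report.loc[report["variant"] == "v2", "reason"].item() == LAST_EXON

    def test_vcf_genotypes(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tv1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t./.\n"
            "1\t200\tv2\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1\n"
        )
        gt = read_vcf_genotypes(vcf)
        assert list(gt.index) == ["S1", "S2", "S3"]
        assert gt.loc["S1", "v1"] == 1 and gt.loc["S1", "v2"] == 2
        assert np.isnan(gt.loc["S3", "v1"])
        out = collapse_carriers(gt, {"v1": "G", "v2": "G"})
        wide = out.pivot(index="sample", columns="gene", values="carrier")
        assert wide["G"].tolist() == [1, 0, 1]
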