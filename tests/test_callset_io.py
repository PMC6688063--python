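"""VCF dialect harmonization, comment exclusion, masking and candidate tables."""

import pytest

from somatosift.callset_io import (
    CallSet,
    GenomicMask,
    SiteCall,
    SiteKey,
    apply_mask,
    comment_matches,
    exclude_commented_calls,
    genome_order_key,
    read_bed_mask,
    read_candidates_tsv,
    read_vcf_calls,
    write_candidates_tsv,
)
from somatosift.errors import BedFormatError, ConfigurationError, VcfFormatError
from somatosift.somatic_filter import consensus, evaluate_criteria, PairedSiteCounts

MUTECT2_VCF = """
##fileformat=VCFv4.2
##FILTER=<ID=t_lod_fstar,Description="Tumor LOD below threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT BRAIN BLOOD
chr1 207461994 . C T . PASS . GT:AD 0/1:997,10 0/0:1472,0
chr1 207461999 . C CT . PASS . GT:AD 0/1:100,5 0/0:100,0
"""

MUTECT1_VCF = """
##fileformat=VCFv4.1
##FILTER=<ID=possible_contamination,Description="Contamination">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT BRAIN BLOOD
chr1 207461994 . C T . possible_contamination . GT:AD 0/1:582,6 0/0:794,0
"""

STRELKA2_VCF = """
##fileformat=VCFv4.2
##FILTER=<ID=LowEVS,Description="Low empirical variant score">
##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier counts">
##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier counts">
##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier counts">
##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier counts">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT NORMAL TUMOR
chr1 207461994 . C T . LowEVS . AU:CU:GU:TU 0,0:1476,1480:0,0:0,0 0,0:1002,1006:0,0:10,10
"""

VARSCAN2_VCF = """
##fileformat=VCFv4.1
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference depth">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alternate depth">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT NORMAL TUMOR
chr1 207461994 . C T . PASS . GT:DP:RD:AD 0/0:1478:1477:1 0/1:1011:1001:10
"""

EMPTY_VCF = """
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT BRAIN BLOOD
"""

MULTIALLELIC_VCF = """
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT BRAIN BLOOD
chr1 100 . C T,G . PASS . GT:AD 0/1:90,5,5 0/0:100,0,0
chr1 200 . C T . PASS . GT:AD 0/1:90,6 0/0:100,0
"""

SINGLE_SAMPLE_VCF = """
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=248956422>
#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT BRAIN
chr1 100 . C T . PASS . GT:AD 0/1:90,5
"""


def _mk_call(pos=100, caller="varscan2", comments=(), individual="i1", chrom="chr1"):
    return SiteCall(
        key=SiteKey(chrom, pos, "C", "T"),
        individual=individual,
        caller=caller,
        brain_ref=400,
        brain_alt=6,
        blood_ref=400,
        blood_alt=0,
        comments=frozenset(comments),
    )


class TestReadVcfCalls:
    @pytest.mark.parametrize(
        "text,dialect,expected",
        [
            (MUTECT2_VCF, "mutect2", (997, 10, 1472, 0)),
            (MUTECT1_VCF, "mutect1", (582, 6, 794, 0)),
            (STRELKA2_VCF, "strelka2", (1002, 10, 1476, 0)),
            (VARSCAN2_VCF, "varscan2", (1001, 10, 1477, 1)),
        ],
    )
    def test_dialect_count_extraction(self, write_vcf, text, dialect, expected):
        """Each dialect's canonical count fields yield the same harmonized record."""
        cs = read_vcf_calls(write_vcf(text), dialect, "i1")
        assert len(cs) == 1
        c = cs.calls[0]
        assert (c.brain_ref, c.brain_alt, c.blood_ref, c.blood_alt) == expected
        assert c.key == SiteKey("chr1", 207461994, "C", "T")

    def test_indels_and_multiallelics_skipped(self, write_vcf):
        cs = read_vcf_calls(write_vcf(MUTECT2_VCF), "mutect2", "i1")
        assert len(cs) == 1  # the indel record is dropped
        assert cs.provenance["skipped_non_snv"] == 1
        cs = read_vcf_calls(write_vcf(MULTIALLELIC_VCF), "mutect2", "i1")
        assert [c.key.pos for c in cs.calls] == [200]

    def test_empty_vcf(self, write_vcf):
        cs = read_vcf_calls(write_vcf(EMPTY_VCF), "mutect2", "i1")
        assert len(cs) == 0

    def test_filter_values_kept_as_comments_not_used_to_drop(self, write_vcf):
        cs = read_vcf_calls(write_vcf(MUTECT1_VCF), "mutect1", "i1")
        assert len(cs) == 1
        assert "possible_contamination" in cs.calls[0].comments

    def test_missing_sample_column_is_format_error(self, write_vcf):
        path = write_vcf(SINGLE_SAMPLE_VCF)
        with pytest.raises(VcfFormatError, match="test.vcf"):
            read_vcf_calls(path, "mutect2", "i1")

    def test_unknown_dialect_is_configuration_error(self, write_vcf):
        with pytest.raises(ConfigurationError, match="dialect"):
            read_vcf_calls(write_vcf(MUTECT2_VCF), "deepvariant", "i1")

    def test_explicit_sample_override(self, write_vcf):
        # deliberately swap: treat BLOOD column as tumor
        cs = read_vcf_calls(
            write_vcf(MUTECT2_VCF), "mutect2", "i1",
            tumor_sample="BLOOD", normal_sample="BRAIN",
        )
        c = cs.calls[0]
        assert (c.brain_ref, c.brain_alt) == (1472, 0)


class TestCommentExclusion:
    def test_mutect_excludable_comment_removed(self):
        cs = CallSet("mutect2", [_mk_call(comments=["clustered_events"])])
        out = exclude_commented_calls(cs)
        assert len(out) == 0
        assert out.provenance["comment_excluded"] == 1

    def test_rule_scoped_to_mutect_callers(self):
        cs = CallSet("varscan2", [_mk_call(comments=["strand artifact"])])
        assert len(exclude_commented_calls(cs)) == 1

    def test_benign_comments_retained(self):
        cs = CallSet(
            "mutect1",
            [_mk_call(caller="mutect1", comments=["PASS"]),
             _mk_call(pos=101, caller="mutect1", comments=["t_lod_fstar"])],
        )
        assert len(exclude_commented_calls(cs)) == 2

    def test_space_underscore_and_case_equivalence(self):
        assert comment_matches("Clustered_Events", ["clustered events"])
        assert comment_matches("strand artifact", ["Strand_Artifact"])
        assert not comment_matches("germline_risk", ["clustered events"])


class TestMask:
    def test_boundary_half_open(self):
        mask = GenomicMask({"chr1": [(99, 100)]})
        cs = CallSet("varscan2", [_mk_call(pos=100)])
        assert len(apply_mask(cs, mask)) == 0  # pos-1 = 99 in [99,100)
        mask2 = GenomicMask({"chr1": [(100, 200)]})
        assert len(apply_mask(cs, mask2)) == 1  # pos-1 = 99 not in [100,200)

    def test_empty_mask_is_identity(self):
        cs = CallSet("varscan2", [_mk_call()])
        assert len(apply_mask(cs, GenomicMask())) == 1

    def test_chromosome_mismatch_warns_and_skips(self, caplog):
        mask = GenomicMask({"1": [(0, 10_000)]})  # no "chr" prefix
        cs = CallSet("varscan2", [_mk_call(pos=100)])
        with caplog.at_level("WARNING"):
            out = apply_mask(cs, mask)
        assert len(out) == 1
        assert "chr1" in caplog.text

    def test_mask_and_comment_exclusion_commute(self):
        calls = [
            _mk_call(pos=50, caller="mutect2", comments=["clustered events"]),
            _mk_call(pos=150, caller="mutect2", comments=["PASS"]),
            _mk_call(pos=250, caller="mutect2", comments=["nearby_gap"]),
        ]
        cs = CallSet("mutect2", calls)
        mask = GenomicMask({"chr1": [(100, 200)]})
        a = apply_mask(exclude_commented_calls(cs), mask)
        b = exclude_commented_calls(apply_mask(cs, mask))
        assert [c.key for c in a.calls] == [c.key for c in b.calls]

    def test_read_bed_mask_merges_overlaps(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        mask = read_bed_mask(bed)
        assert mask.intervals("chr1") == [(10, 30)]
        assert mask.total_length() == 20

    def test_read_bed_mask_empty_file(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("")
        assert len(read_bed_mask(bed)) == 0

    def test_read_bed_mask_invalid_interval_names_line(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t20\t10\n")
        with pytest.raises(BedFormatError, match=":1"):
            read_bed_mask(bed)


class TestCandidateTable:
    def _results(self):
        call = _mk_call(pos=207461994, caller="varscan2")
        counts = PairedSiteCounts.from_site_call(call)
        v = evaluate_criteria(counts)
        v.c6_recurrent = True
        return [consensus({"varscan2": v})]

    def test_aaf_formatted_as_percent_one_decimal(self, tmp_path):
        res = self._results()
        # brain 400/6 -> 1.5%; check a 997/10 -> 1.0% example too
        call = SiteCall(
            key=SiteKey("chr1", 1, "C", "T"), individual="i1", caller="varscan2",
            brain_ref=997, brain_alt=10, blood_ref=1472, blood_alt=0,
        )
        v = evaluate_criteria(PairedSiteCounts.from_site_call(call))
        v.c6_recurrent = True
        res.append(consensus({"varscan2": v}))
        out = tmp_path / "cand.tsv"
        write_candidates_tsv(res, out)
        text = out.read_text()
        assert "\t1.5" in text and "\t1.0" in text

    def test_round_trip_preserves_keys_and_counts(self, tmp_path):
        res = self._results()
        out = tmp_path / "cand.tsv"
        write_candidates_tsv(res, out)
        df = read_candidates_tsv(out)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row.chrom, row.pos, row.ref, row.alt) == ("chr1", 207461994, "C", "T")
        assert (row.varscan2_brain_ref, row.varscan2_brain_alt) == (400, 6)
        assert (row.varscan2_blood_ref, row.varscan2_blood_alt) == (400, 0)

    def test_empty_results_write_header_only(self, tmp_path):
        out = tmp_path / "cand.tsv"
        write_candidates_tsv([], out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("chrom\tpos")


def test_genome_order_is_natural():
    keys = [
        SiteKey("chr11", 5, "C", "T"),
        SiteKey("chr2", 9, "C", "T"),
        SiteKey("chr1", 7, "C", "T"),
        SiteKey("chr21", 1, "C", "T"),
    ]
    ordered = sorted(keys, key=genome_order_key)
    assert [k.chrom for k in ordered] == ["chr1", "chr2", "chr11", "chr21"]


def test_site_key_validation():
    with pytest.raises(ValueError):
        SiteKey("chr1", 0, "C", "T")
    with pytest.raises(ValueError):
        SiteKey("chr1", 10, "C", "C")
    with pytest.raises(ValueError):
        SiteKey("chr1", 10, "CA", "T")
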