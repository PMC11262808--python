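"""Cohort loading, rarity and segregation filters, cross-family recurrence."""

import pytest
from hypothesis import given, strategies as hst

from famvar.cohort import (filter_by_frequency, filter_by_shared_affected,
                           read_family_table, read_variant_table,
                           recurrence_across_families, write_variant_table)
from famvar.errors import ConfigError, DataError

from conftest import make_variant

HEADER = ("variant_id\tgene\tprotein_accession\twt_aa\tposition\tmut_aa"
          "\tchrom\tgpos\tref\talt\tpop_af\tcarriers\n")


def write_tsv(path, rows):
    path.write_text(HEADER + "".join(rows))
    return path


class TestReadVariantTable:
    def test_identity_load(self, tmp_path, members):
        p = write_tsv(tmp_path / "v.tsv", [
            "v1\tG1\tP1\tT\t305\tM\t9\t1000\tC\tT\t0.001\tfamA:A1;famA:A2\n",
            "v2\tG2\tP2\tA\t10\tV\t\t\t\t\t\tfamB:B1;famB:B2\n",
            "v3\tG3\tP3\tR\t50\tQ\t\t\t\t\t0.005\tfamC:C1\n",
        ])
        vs = read_variant_table(p, members)
        assert len(vs.variants) == 3 and vs.load_errors == []
        v2 = next(v for v in vs.variants if v.variant_id == "v2")
        assert v2.pop_af is None
        assert {c for c in v2.carriers} == {("famB", "B1"), ("famB", "B2")}

    def test_invariant_violations_collected_not_dropped_silently(self, tmp_path, members):
        p = write_tsv(tmp_path / "v.tsv", [
            "bad1\tG1\tP1\tT\t305\tT\t\t\t\t\t0.001\tfamA:A1\n",   # wt == mut
            "bad2\tG2\tP2\tA\t0\tV\t\t\t\t\t0.001\tfamA:A1\n",     # position < 1
            "bad3\tG3\tP3\tA\t10\tV\t\t\t\t\t1.5\tfamA:A1\n",      # af > 1
            "ok\tG4\tP4\tA\t10\tV\t\t\t\t\t0.001\tfamA:A1\n",
        ])
        vs = read_variant_table(p, members)
        assert [v.variant_id for v in vs.variants] == ["ok"]
        assert sorted(e.variant_id for e in vs.load_errors) == ["bad1", "bad2", "bad3"]

    def test_duplicate_rows_merge_carrier_union(self, tmp_path, members):
        p = write_tsv(tmp_path / "v.tsv", [
            "v1\tG1\tP1\tT\t305\tM\t\t\t\t\t0.001\tfamA:A1;famA:A2\n",
            "v1\tG1\tP1\tT\t305\tM\t\t\t\t\t0.001\tfamB:B1;famB:B2\n",
        ])
        vs = read_variant_table(p, members)
        assert len(vs.variants) == 1
        assert vs.variants[0].carriers == {("famA", "A1"), ("famA", "A2"),
                                           ("famB", "B1"), ("famB", "B2")}

    def test_conflicting_duplicate_is_data_error(self, tmp_path, members):
        p = write_tsv(tmp_path / "v.tsv", [
            "v1\tG1\tP1\tT\t305\tM\t\t\t\t\t0.001\tfamA:A1;famA:A2\n",
            "v1\tG1\tP1\tT\t306\tM\t\t\t\t\t0.001\tfamB:B1\n",
        ])
        with pytest.raises(DataError, match="conflicting"):
            read_variant_table(p, members)

    def test_missing_required_column_is_config_error(self, tmp_path, members):
        p = tmp_path / "v.tsv"
        p.write_text("variant_id\tgene\n" "v1\tG1\n")
        with pytest.raises(ConfigError, match="missing required columns"):
            read_variant_table(p, members)

    def test_unknown_carrier_member_is_data_error(self, tmp_path, members):
        p = write_tsv(tmp_path / "v.tsv", [
            "v1\tG1\tP1\tT\t305\tM\t\t\t\t\t0.001\tfamA:NOPE\n"])
        with pytest.raises(DataError, match="unknown members"):
            read_variant_table(p, members)

    def test_roundtrip(self, tmp_path, members, cohort_factory):
        vs = cohort_factory([
            make_variant("v1", [("famA", "A1"), ("famA", "A2")], pop_af=0.004),
            make_variant("v2", [("famB", "B1"), ("famB", "B2")], pop_af=None),
        ])
        out = tmp_path / "out.tsv"
        write_variant_table(vs, out)
        back = read_variant_table(out, members)
        assert {v.variant_id: v.carriers for v in back.variants} == \
               {v.variant_id: v.carriers for v in vs.variants}


class TestVcfDialect:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
        '##INFO=<ID=PACC,Number=1,Type=String,Description="Protein accession">\n'
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">\n'
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=9>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "9\t1000\tv1\tC\tT\t.\t.\tGENE=CRAT;PACC=P43155;PCHANGE=p.T305M;AF=0.002"
        "\tGT\t0/1\t0/1\t0/0\n"
        "9\t2000\tv2\tG\tA\t.\t.\tGENE=XYZ;PACC=P2;PCHANGE=A10V"
        "\tGT\t0/0\t0/0\t1/1\n"
        "9\t3000\tv3\tG\tC\t.\t.\tGENE=NOPE;PACC=P3"  # missing PCHANGE
        "\tGT\t0/1\t0/0\t0/0\n")

    def test_vcf_with_sample_map(self, tmp_path, members):
        vcf_path = tmp_path / "v.vcf"
        vcf_path.write_text(self.VCF)
        smap = tmp_path / "samples.tsv"
        smap.write_text("sample\tfamily_id\tmember_id\n"
                        "S1\tfamA\tA1\nS2\tfamA\tA2\nS3\tfamB\tB1\n")
        vs = read_variant_table(vcf_path, members, dialect="vcf-annotated",
                                sample_map=smap)
        by_id = {v.variant_id: v for v in vs.variants}
        assert set(by_id) == {"v1", "v2"}
        v1 = by_id["v1"]
        assert (v1.gene, v1.wt_aa, v1.position, v1.mut_aa) == ("CRAT", "T", 305, "M")
        assert v1.pop_af == pytest.approx(0.002)
        assert v1.carriers == {("famA", "A1"), ("famA", "A2")}
        assert by_id["v2"].carriers == {("famB", "B1")}  # hom-alt counts
        assert any(e.message.startswith("missing GENE/PCHANGE")
                   for e in vs.load_errors)

    def test_vcf_requires_sample_map(self, tmp_path, members):
        vcf_path = tmp_path / "v.vcf"
        vcf_path.write_text(self.VCF)
        with pytest.raises(ConfigError, match="sample_map"):
            read_variant_table(vcf_path, members, dialect="vcf-annotated")


class TestFamilyTable:
    def test_read(self, tmp_path):
        p = tmp_path / "fam.tsv"
        p.write_text("family_id\tmember_id\taffected\n"
                     "famA\tA1\t1\nfamA\tU1\t0\n")
        ms = read_family_table(p)
        assert [(m.member_id, m.affected) for m in ms] == [("A1", True), ("U1", False)]

    def test_duplicate_member_rejected(self, tmp_path):
        p = tmp_path / "fam.tsv"
        p.write_text("family_id\tmember_id\taffected\nfamA\tA1\t1\nfamA\tA1\t1\n")
        with pytest.raises(DataError, match="duplicate member"):
            read_family_table(p)


class TestFrequencyFilter:
    @pytest.mark.parametrize("af,kept", [
        (0.02, False),   # strictly above 1% -> excluded
        (0.01, True),    # boundary: exactly 1% retained
        (None, True),    # missing frequency retained by default
        (0.0005, True),
    ])
    def test_threshold_rule(self, cohort_factory, af, kept):
        vs = cohort_factory([make_variant("v", [("famA", "A1")], pop_af=af)])
        out = filter_by_frequency(vs)
        assert (len(out.variants) == 1) is kept

    def test_missing_af_drop_policy(self, cohort_factory):
        vs = cohort_factory([make_variant("v", [("famA", "A1")], pop_af=None)])
        assert filter_by_frequency(vs, missing_af="drop").variants == []

    def test_provenance_conserves_counts(self, cohort_factory):
        vs = cohort_factory([
            make_variant("a", [("famA", "A1")], pop_af=0.5),
            make_variant("b", [("famA", "A1")], pop_af=0.001),
            make_variant("c", [("famA", "A1")], pop_af=None),
        ])
        out = filter_by_frequency(vs)
        assert len(out.provenance) == 3
        assert sum(1 for e in out.provenance if e["action"] == "removed") == 1


class TestSharedAffectedFilter:
    def test_two_affected_carriers_retained(self, cohort_factory):
        vs = cohort_factory([make_variant("v", [("famA", "A1"), ("famA", "A2")])])
        assert len(filter_by_shared_affected(vs).variants) == 1

    def test_one_affected_plus_unaffected_removed(self, cohort_factory):
        vs = cohort_factory([make_variant("v", [("famA", "A1"), ("famA", "U1")])])
        assert filter_by_shared_affected(vs).variants == []

    def test_threshold_is_per_family_not_pooled(self, cohort_factory):
        # one affected carrier in each of two multi-patient families
        vs = cohort_factory([make_variant("v", [("famA", "A1"), ("famB", "B1")])])
        assert filter_by_shared_affected(vs).variants == []

    def test_single_patient_family_default_keeps_sole_carrier(self, cohort_factory):
        # famC has one sequenced patient; its variants are carried by all
        # affected members and kept under the default small-family rule
        vs = cohort_factory([make_variant("v", [("famC", "C1")])])
        assert len(filter_by_shared_affected(vs).variants) == 1
        assert filter_by_shared_affected(vs, small_family_rule="strict").variants == []

    def test_requires_members(self, cohort_factory):
        from famvar.cohort import CohortVariantSet
        vs = CohortVariantSet(variants=[make_variant("v", [])], members=[])
        with pytest.raises(ConfigError):
            filter_by_shared_affected(vs)


class TestFilterProperties:
    @given(afs=hst.lists(
        hst.one_of(hst.none(), hst.floats(min_value=0, max_value=1)),
        min_size=1, max_size=20))
    def test_idempotence_and_order_invariance(self, afs):
        from famvar.cohort import CohortVariantSet, Member
        members = [Member("A1", "famA", True), Member("A2", "famA", True)]
        variants = [make_variant(f"v{i}", [("famA", "A1"), ("famA", "A2")], pop_af=af)
                    for i, af in enumerate(afs)]
        vs = CohortVariantSet(variants=variants, members=members)
        once = filter_by_frequency(vs)
        twice = filter_by_frequency(once)
        assert [v.variant_id for v in once.variants] == \
               [v.variant_id for v in twice.variants]
        fa = filter_by_shared_affected(filter_by_frequency(vs))
        af_ = filter_by_frequency(filter_by_shared_affected(vs))
        assert [v.variant_id for v in fa.variants] == \
               [v.variant_id for v in af_.variants]
        # filters only remove
        assert set(v.variant_id for v in fa.variants) <= \
               set(v.variant_id for v in vs.variants)


class TestRecurrence:
    def test_recurrent_in_two_families(self, cohort_factory):
        v = make_variant("v", [("famA", "A1"), ("famA", "A2"),
                               ("famB", "B1"), ("famB", "B2"), ("famB", "B3")])
        rec = recurrence_across_families(cohort_factory([v]))
        assert rec["v"] == ["famA", "famB"]

    def test_partial_family_not_listed(self, cohort_factory):
        v = make_variant("v", [("famB", "B1"), ("famB", "B2")])  # 2 of 3 affected
        rec = recurrence_across_families(cohort_factory([v]))
        assert rec["v"] == []

    def test_single_patient_family_ineligible(self, cohort_factory):
        v = make_variant("v", [("famC", "C1"), ("famA", "A1"), ("famA", "A2")])
        rec = recurrence_across_families(cohort_factory([v]))
        assert rec["v"] == ["famA"]  # famC excluded despite full carriage
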