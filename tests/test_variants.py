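from fractions import Fraction

import numpy as np
import pytest

from radsnp import variants
from radsnp.assembly import RadContig, ReadPair
from radsnp.enzymes import reverse_complement
from tests_support import random_dna

Q40 = chr(33 + 40)


def make_contig(seq, cid="c1_NODE1"):
    return RadContig(cid, "c1", 1, seq, 10.0)


def make_pair(se, pe, sample="s1"):
    return ReadPair("r", se, pe, Q40 * len(se), Q40 * len(pe), sample)


@pytest.fixture
def contig400(rng):
    return make_contig(random_dna(rng, 400))


class TestAlignment:
    def test_exact_pair_accepted(self, contig400):
        seq = contig400.sequence
        pair = make_pair(seq[:54], reverse_complement(seq[146:200]))
        pa = variants.align_read_pair(pair, contig400)
        assert pa is not None
        assert pa.se.mismatches == 0 and pa.se.gap_length == 0
        assert pa.pe.mismatches == 0 and pa.pe.offset == 146

    def test_four_mismatches_rejected(self, contig400):
        seq = contig400.sequence
        pe = list(seq[146:200])
        for i in range(4):
            pe[i * 10] = "A" if pe[i * 10] != "A" else "C"
        pair = make_pair(seq[:54], reverse_complement("".join(pe)))
        assert variants.align_read_pair(pair, contig400) is None

    def test_three_mismatches_accepted(self, contig400):
        seq = contig400.sequence
        pe = list(seq[146:200])
        for i in range(3):
            pe[i * 10] = "A" if pe[i * 10] != "A" else "C"
        pair = make_pair(seq[:54], reverse_complement("".join(pe)))
        pa = variants.align_read_pair(pair, contig400)
        assert pa is not None and pa.pe.mismatches == 3

    def test_three_nt_gap_rejected(self, contig400):
        seq = contig400.sequence
        pe_target = seq[140:167] + seq[170:197]  # 3 nt deletion
        pair = make_pair(seq[:54], reverse_complement(pe_target))
        assert variants.align_read_pair(pair, contig400) is None

    def test_two_nt_gap_accepted(self, contig400):
        seq = contig400.sequence
        pe_target = seq[140:167] + seq[169:196]  # 2 nt deletion
        pair = make_pair(seq[:54], reverse_complement(pe_target))
        pa = variants.align_read_pair(pair, contig400)
        assert pa is not None and pa.pe.gap_length == 2

    def test_contig_shorter_than_read_rejected(self):
        short = make_contig("ACGTACGT")
        pair = make_pair("A" * 54, "C" * 54)
        assert variants.align_read_pair(pair, short) is None


class TestPileup:
    def test_exact_reads_counted(self, contig400):
        seq = contig400.sequence
        pileup = variants.Pileup({"c1_NODE1": seq}, ["s1"])
        for _ in range(10):
            pileup.add_alignment(
                "c1_NODE1", "s1", variants.ReadAlignment(100, 0, 0, seq[100:154]))
        counts = pileup.sample_counts("c1_NODE1", 120)
        assert counts["s1"] == {seq[120]: 10}

    def test_deletion_allele_counts(self, contig400):
        seq = contig400.sequence
        pileup = variants.Pileup({"c1_NODE1": seq}, ["s1"])
        for _ in range(6):
            pileup.add_alignment(
                "c1_NODE1", "s1", variants.ReadAlignment(100, 0, 0, seq[100:154]))
        del_allele = f"{seq[119]}-1"
        for _ in range(4):
            events = [(p, seq[p]) for p in range(100, 119)] + [(119, del_allele)]
            events += [(p, seq[p]) for p in range(121, 154)]
            pileup.add_alignment(
                "c1_NODE1", "s1",
                variants.ReadAlignment(100, 0, 1, "", events=events))
        counts = pileup.sample_counts("c1_NODE1", 119)["s1"]
        assert counts == {seq[119]: 6, del_allele: 4}

    def test_depth_equals_sum_of_counts(self, contig400, rng):
        seq = contig400.sequence
        pileup = variants.Pileup({"c1_NODE1": seq}, ["s1", "s2"])
        for i in range(50):
            off = int(rng.integers(0, 300))
            sample = "s1" if i % 2 else "s2"
            pileup.add_alignment(
                "c1_NODE1", sample, variants.ReadAlignment(off, 0, 0, seq[off:off + 54]))
        for pos in range(0, 350, 7):
            per = pileup.sample_counts("c1_NODE1", pos)
            for s, counts in per.items():
                dense = pileup._dense["c1_NODE1"][s][:, pos].sum()
                assert sum(counts.values()) == dense


def pileup_from_counts(seq, per_sample_counts, pos=10):
    """per_sample_counts: {sample: {allele: n}} at one column."""
    samples = sorted(per_sample_counts)
    pileup = variants.Pileup({"c1_NODE1": seq}, samples)
    for s, counts in per_sample_counts.items():
        for allele, n in counts.items():
            for _ in range(n):
                if len(allele) == 1:
                    pileup.add_alignment(
                        "c1_NODE1", s,
                        variants.ReadAlignment(pos, 0, 0, allele))
                else:
                    pileup.add_alignment(
                        "c1_NODE1", s,
                        variants.ReadAlignment(pos, 0, 1, "", events=[(pos, allele)]))
    return pileup


class TestCcrad1:
    def test_depth_threshold(self):
        seq = "ACGT" * 30
        low = pileup_from_counts(seq, {"s1": {"A": 3, "C": 2}})
        assert variants.call_ccrad1(low) == []
        ok = pileup_from_counts(seq, {"s1": {"A": 3, "C": 3}})
        sites = variants.call_ccrad1(ok)
        assert len(sites) == 1 and sites[0].position == 10

    def test_monomorphic_high_depth_excluded(self):
        seq = "ACGT" * 30
        pileup = pileup_from_counts(seq, {"s1": {"A": 100}})
        assert variants.call_ccrad1(pileup) == []

    def test_three_nt_indel_not_emitted(self):
        assert not variants.allele_is_valid("A+CGT")
        assert variants.allele_is_valid("A+CG")
        assert variants.allele_is_valid("A-2")
        assert not variants.allele_is_valid("A-3")

    def test_monotone_in_min_coverage(self, small_pipeline):
        pileup = small_pipeline.calling.pileup
        counts = [
            len(variants.call_ccrad1(pileup, min_coverage=c)) for c in (2, 6, 10, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_pooled_across_samples(self):
        seq = "ACGT" * 30
        pileup = pileup_from_counts(
            seq, {"s1": {"A": 2}, "s2": {"C": 2}, "s3": {"A": 2}})
        assert len(variants.call_ccrad1(pileup)) == 1


def rule_oracle(n_a: int, n_c: int) -> str:
    """Independent statement of the imputation rule over two alleles,
    evaluated with exact rational arithmetic."""
    depth = n_a + n_c
    if depth == 0:
        return "no_call"
    if Fraction(min(n_a, n_c), depth) < Fraction(1, 10):
        return "hom"
    freqs = [Fraction(n_a, depth), Fraction(n_c, depth)]
    if (depth >= 4 and n_a >= 2 and n_c >= 2
            and all(Fraction(1, 4) <= f <= Fraction(3, 4) for f in freqs)):
        return "het"
    return "ambiguous"


class TestImputeGenotype:
    @pytest.mark.parametrize("counts,expected", [
        ({"A": 10, "C": 10}, "het"),
        ({"A": 2, "C": 2}, "het"),
        ({"A": 19, "C": 1}, "hom"),
        ({"A": 8, "C": 2}, "ambiguous"),
        ({}, "no_call"),
    ])
    def test_spec_examples(self, counts, expected):
        call = variants.impute_genotype(counts, "s1")
        assert call.zygosity == expected

    def test_hom_keeps_major_allele(self):
        call = variants.impute_genotype({"A": 19, "C": 1}, "s1")
        assert call.alleles == ("A",)
        assert call.frequency == pytest.approx(0.05)

    def test_enumeration_oracle_all_pairs_to_20(self):
        for n_a in range(21):
            for n_c in range(21 - n_a):
                got = variants.impute_genotype({"A": n_a, "C": n_c}, "s").zygosity
                assert got == rule_oracle(n_a, n_c), (n_a, n_c)

    def test_three_supported_alleles_ambiguous(self):
        call = variants.impute_genotype({"A": 5, "C": 5, "G": 5}, "s1")
        assert call.zygosity == "ambiguous"

    def test_exact_tenth_boundary_not_hom(self):
        # 1 of 10 reads: minor frequency exactly 0.10, not strictly below
        call = variants.impute_genotype({"A": 9, "C": 1}, "s1")
        assert call.zygosity != "hom"


class TestCcrad2:
    def test_depth_one_everywhere_retained(self):
        seq = "ACGT" * 30
        pileup = pileup_from_counts(
            seq, {"s1": {"A": 8, "C": 4}, "s2": {"A": 6}, "s3": {"C": 1}})
        sites = variants.call_ccrad1(pileup)
        assert variants.select_ccrad2(sites, pileup) == sites
        assert sites[0].in_ccrad2

    def test_missing_sample_excluded(self):
        seq = "ACGT" * 30
        pileup = pileup_from_counts(
            seq, {"s1": {"A": 8, "C": 4}, "s2": {"A": 6}, "s3": {}})
        sites = variants.call_ccrad1(pileup)
        assert variants.select_ccrad2(sites, pileup) == []

    def test_subset_property(self, small_pipeline):
        calling = small_pipeline.calling
        ids1 = {s.site_id for s in calling.ccrad1}
        ids2 = {s.site_id for s in calling.ccrad2}
        assert ids2 <= ids1


def classification_oracle(zygs):
    labels = []
    if all(z == "het" for z in zygs):
        labels.append(("common_intercross",))
        return labels
    for i, zi in enumerate(zygs):
        if zi != "het":
            continue
        for j, zj in enumerate(zygs):
            if i != j and zj == "hom":
                labels.append(("testcross", f"p{i}", f"p{j}"))
    return labels


class TestClassification:
    @staticmethod
    def records_for(zygs):
        site = variants.VariantSite("c1_NODE1", 5, "A", ["C"], "SNP", True, True)
        calls = {}
        for i, z in enumerate(zygs):
            alleles = {"het": ("A", "C"), "hom": ("A",)}.get(z, ())
            calls[f"p{i}"] = variants.GenotypeCall(f"p{i}", z, alleles, {"A": 5}, 0.0)
        genotypes = {site.site_id: calls}
        return variants.classify_markers([site], genotypes, ["p0", "p1", "p2"])

    def test_enumeration_oracle(self):
        import itertools

        for zygs in itertools.product(["het", "hom", "ambiguous", "no_call"], repeat=3):
            [record] = self.records_for(zygs)
            assert sorted(record.labels) == sorted(classification_oracle(zygs)), zygs

    def test_single_het_yields_two_testcross_labels(self):
        [record] = self.records_for(("hom", "het", "hom"))
        assert ("testcross", "p1", "p0") in record.labels
        assert ("testcross", "p1", "p2") in record.labels
        assert record.marker_class == "testcross"

    def test_all_het_is_common_intercross(self):
        [record] = self.records_for(("het", "het", "het"))
        assert record.labels == [("common_intercross",)]

    def test_all_hom_uninformative(self):
        [record] = self.records_for(("hom", "hom", "hom"))
        assert record.labels == []
        assert record.marker_class == "uninformative"

    def test_summary_totals(self, small_pipeline):
        calling = small_pipeline.calling
        df = variants.marker_summary(calling.markers)
        by = dict(zip(df["category"], df["sites"]))
        n_test = sum(1 for r in calling.markers if r.marker_class == "testcross")
        assert by["testcross"] == n_test
        assert (by["all_sites"]
                == by["testcross"] + by["common_intercross"] + by["uninformative"])


class TestVcf:
    def test_empty_site_list_valid_header(self, tmp_path):
        path = tmp_path / "empty.vcf"
        variants.write_vcf([], {}, {"c1_NODE1": "ACGT" * 20}, ["s1", "s2", "s3"], path)
        import pysam

        vcf = pysam.VariantFile(str(path))
        assert list(vcf.fetch()) == []
        assert list(vcf.header.samples) == ["s1", "s2", "s3"]

    def test_round_trip_counts_and_gt(self, tmp_path):
        seq = "ACGT" * 30
        pileup = pileup_from_counts(
            seq, {"s1": {"A": 10, "C": 10}, "s2": {"A": 9}, "s3": {"C": 7}}, pos=8)
        sites = variants.call_ccrad1(pileup)
        genotypes = variants.genotype_sites(sites, pileup)
        variants.select_ccrad2(sites, pileup)
        path = tmp_path / "out.vcf"
        variants.write_vcf(sites, genotypes, {"c1_NODE1": seq}, ["s1", "s2", "s3"], path)
        import pysam

        [rec] = list(pysam.VariantFile(str(path)).fetch())
        assert rec.pos == 9  # 1-based
        assert rec.ref == "A" and rec.alts == ("C",)
        assert rec.samples["s1"]["GT"] == (0, 1)
        assert tuple(rec.samples["s1"]["AD"]) == (10, 10)
        assert rec.samples["s2"]["GT"] == (0, 0)
        assert rec.samples["s3"]["GT"] == (1, 1)

    def test_inconsistent_reference_allele_hard_error(self, tmp_path):
        seq = "ACGT" * 30
        site = variants.VariantSite("c1_NODE1", 10, "T", ["C"], "SNP", True)
        call = variants.GenotypeCall("s1", "hom", ("T",), {"T": 5}, 0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            variants.write_vcf([site], {site.site_id: {"s1": call}},
                               {"c1_NODE1": seq}, ["s1"], tmp_path / "x.vcf")

    def test_indel_alleles_expanded(self, tmp_path):
        seq = "ACGT" * 30
        pos = 10  # base 'G'
        pileup = pileup_from_counts(
            seq, {"s1": {"G": 6, "G-2": 6}, "s2": {"G": 3}, "s3": {"G": 2}}, pos=pos)
        sites = variants.call_ccrad1(pileup)
        assert sites and sites[0].var_class == "indel"
        genotypes = variants.genotype_sites(sites, pileup)
        path = tmp_path / "indel.vcf"
        variants.write_vcf(sites, genotypes, {"c1_NODE1": seq}, ["s1", "s2", "s3"], path)
        import pysam

        [rec] = list(pysam.VariantFile(str(path)).fetch())
        assert rec.ref == seq[pos:pos + 3]
        assert rec.alts == (seq[pos],)
        assert rec.samples["s1"]["GT"] == (0, 1)
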