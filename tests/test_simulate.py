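import itertools
import math

import numpy as np
import pytest

from radsnp import simulate as sim
from radsnp.enzymes import reverse_complement
from radsnp.linkage import kosambi_inverse


class TestSimParams:
    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            sim.SimParams(genome_length=0)

    def test_spacing_below_twice_insert_max_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            sim.SimParams(pstI_site_spacing=900, insert_range=(56, 500))

    def test_het_rate_length(self):
        with pytest.raises(ValueError):
            sim.SimParams(het_rate_per_accession=(0.1, 0.1))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            sim.SimParams(depth_weights=(1.0, -1.0, 2.0))


class TestReference:
    def test_planted_site_count_and_exactness(self):
        p = sim.SimParams(genome_length=100_000, pstI_site_spacing=5_000, seed=1)
        ref = sim.simulate_reference(p)
        seq = ref.chromosomes["chr1"]
        n = len(ref.planted_sites)
        assert 14 <= n <= 24  # ~20 sites, margins trimmed
        for chrom, start in ref.planted_sites:
            assert ref.chromosomes[chrom][start:start + 6] == "CTGCAG"

    def test_no_spurious_recognition_sites(self):
        p = sim.SimParams(genome_length=100_000, pstI_site_spacing=5_000, seed=1)
        ref = sim.simulate_reference(p)
        seq = ref.chromosomes["chr1"]
        assert seq.count("CTGCAG") == len(ref.planted_sites)

    def test_determinism(self):
        make = lambda: sim.simulate_reference(
            sim.SimParams(genome_length=50_000, pstI_site_spacing=2_500, seed=9))
        assert make().chromosomes == make().chromosomes

    def test_gc_content_matches_parameter(self):
        p = sim.SimParams(genome_length=200_000, pstI_site_spacing=5_000,
                          seed=2, gc_content=0.374)
        seq = sim.simulate_reference(p).chromosomes["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.374) < 0.01


class TestAccessions:
    def test_divergence_binomial_oracle(self):
        # independent oracle: count truth sites where the pair's diploid
        # genotypes differ; expectation divergence_rate * L, binomial noise
        p = sim.SimParams(genome_length=1_000_000, pstI_site_spacing=5_000,
                          seed=5, divergence_rate=0.0056,
                          het_rate_per_accession=(0.0, 0.0, 0.0),
                          indel_fraction=0.0)
        ref = sim.simulate_reference(p)
        _, truth = sim.derive_accessions(ref, p)
        expected = 0.0056 * 1_000_000
        tol = 3 * math.sqrt(expected)
        for a, b in itertools.combinations(range(3), 2):
            n = sum(1 for v in truth.variants if v.genotypes[a] != v.genotypes[b])
            assert abs(n - expected) < tol

    def test_zero_het_rate_gives_identical_haplotypes(self, small_reference, small_params):
        import dataclasses

        p = dataclasses.replace(small_params, het_rate_per_accession=(0.0, 0.0, 0.0))
        accessions, _ = sim.derive_accessions(small_reference, p)
        for acc in accessions:
            for h0, h1 in acc.haplotypes.values():
                assert h0 == h1

    def test_site_loss_marks_locus_absent(self):
        p = sim.SimParams(genome_length=60_000, pstI_site_spacing=3_000, seed=4,
                          site_loss_fraction=0.5, indel_fraction=0.0)
        ref = sim.simulate_reference(p)
        accessions, truth = sim.derive_accessions(ref, p)
        absent = [l for l in truth.loci if not all(l.present)]
        assert absent
        for locus in absent:
            ai = locus.present.index(False)
            acc = accessions[ai]
            # neither haplotype of the knocked-out accession has the site
            for hap in acc.haplotypes[locus.chrom]:
                window_count = hap.count("CTGCAG")
                intact = sum(
                    1 for l2 in truth.loci
                    if l2.chrom == locus.chrom and l2.side == "right"
                    and l2.present[ai])
                assert window_count == intact

    def test_truth_table_completeness_brute_force(self, small_world):
        # every difference between an accession haplotype and the reference
        # appears in the truth table (SNP-only simulation, <=200 kb)
        params, reference, accessions, truth = small_world
        ref_seq = reference.chromosomes["chr1"]
        ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        for ai, acc in enumerate(accessions):
            for hi, hap in enumerate(acc.haplotypes["chr1"]):
                arr = np.frombuffer(hap.encode(), dtype=np.uint8)
                observed = set(np.flatnonzero(arr != ref_arr).tolist())
                expected = {
                    v.pos for v in truth.variants
                    if v.chrom == "chr1" and v.genotypes[ai][hi]
                }
                assert observed == expected


class TestLibrary:
    def test_error_free_se_reads_start_at_cut_sites(self, small_world):
        params, reference, accessions, _ = small_world
        acc = accessions[0]
        pairs = sim.simulate_rad_library(acc, params, 300, params.rng(77))
        haps = acc.haplotypes["chr1"]
        strands = [haps[0], haps[1],
                   reverse_complement(haps[0]), reverse_complement(haps[1])]
        cut_starts = set()
        for strand in strands:
            idx = strand.find("CTGCAG")
            while idx >= 0:
                cut_starts.add(strand[idx + 5:idx + 5 + params.read_length])
                cut_starts.add(strand[idx + 1:idx + 1 + params.read_length])
                idx = strand.find("CTGCAG", idx + 1)
        for pair in pairs:
            assert pair.se_seq in cut_starts

    def test_insert_sizes_within_hard_bounds(self, small_world):
        import dataclasses

        params, reference, accessions, _ = small_world
        p = dataclasses.replace(params, insert_range=(300, 800))
        pairs = sim.simulate_rad_library(accessions[0], p, 500, p.rng(78))
        # mate must land 300..800 nt from the cut: its sequence re-occurs
        # in the template at exactly that offset
        templates = sim.enumerate_locus_templates(accessions[0], 300)
        by_se = {}
        for t in templates:
            by_se.setdefault(t.template[:54], []).append(t.template)
        for pair in pairs[:100]:
            target = reverse_complement(pair.pe_seq)
            offsets = [
                tmpl.find(target) + 54
                for tmpl in by_se.get(pair.se_seq, [])
                if tmpl.find(target) >= 0
            ]
            assert offsets and any(300 <= s <= 800 for s in offsets)

    def test_depth_allocation_multinomial(self):
        rng = np.random.default_rng(1)
        counts = sim.allocate_depth(100_000, (1.2, 2.6, 5.9), rng)
        assert counts.sum() == 100_000
        for c, frac in zip(counts, (0.124, 0.268, 0.608)):
            assert abs(c / 100_000 - frac) < 0.02

    def test_fastq_determinism(self, tmp_path, small_world):
        params, reference, accessions, _ = small_world
        out = []
        for run in range(2):
            pairs = sim.simulate_rad_library(accessions[1], params, 50, params.rng(99))
            prefix = tmp_path / f"run{run}"
            sim.write_fastq_pairs(pairs, prefix)
            out.append((prefix.with_name(f"run{run}_1.fastq").read_bytes(),
                        prefix.with_name(f"run{run}_2.fastq").read_bytes()))
        assert out[0] == out[1]

    def test_no_loci_rejected(self):
        acc = sim.DiploidAccession("x", {"chr1": ("ACGT" * 100, "ACGT" * 100)})
        p = sim.SimParams(genome_length=10_000, pstI_site_spacing=2_000, seed=0)
        with pytest.raises(ValueError, match="no surviving RAD loci"):
            sim.simulate_rad_library(acc, p, 10)

    def test_low_quality_plants_trigger_filter(self, small_world):
        import dataclasses

        from radsnp.assembly import quality_filter

        params, _, accessions, _ = small_world
        p = dataclasses.replace(params, low_quality_read_fraction=0.5)
        pairs = sim.simulate_rad_library(accessions[0], p, 400, p.rng(13))
        kept, discarded = quality_filter(pairs)
        assert 0.4 < len(discarded) / 400 < 0.6


class TestProgeny:
    @staticmethod
    def markers(n, group="g1", spacing_cm=0.0, parent_a=(0, 1), parent_b=(0, 0)):
        return [
            sim.ProgenyMarker(f"m{i}", parent_a, parent_b, group, i * spacing_cm)
            for i in range(n)
        ]

    def test_testcross_mean_split(self):
        totals = []
        for seed in range(30):
            g = sim.simulate_progeny(self.markers(1), 94, seed)
            codes = sim.genotype_codes(g)[0]
            totals.append((codes == "h").sum())
        assert abs(np.mean(totals) - 47) < 2.0

    def test_intercross_1_2_1(self):
        m = [sim.ProgenyMarker("m0", (0, 1), (0, 1))]
        g = sim.simulate_progeny(m, 20_000, 1)
        codes = sim.genotype_codes(g)[0]
        counts = {c: (codes == c).sum() / 20_000 for c in "ahb"}
        assert abs(counts["a"] - 0.25) < 0.02
        assert abs(counts["h"] - 0.50) < 0.02
        assert abs(counts["b"] - 0.25) < 0.02

    def test_zero_cm_cosegregation(self):
        m = self.markers(2, spacing_cm=0.0)
        g = sim.simulate_progeny(m, 94, 2)
        codes = sim.genotype_codes(g)
        assert (codes[0] == codes[1]).all()

    def test_linked_recombination_matches_kosambi_inverse(self):
        m = self.markers(2, spacing_cm=20.0)
        g = sim.simulate_progeny(m, 50_000, 3)
        codes = sim.genotype_codes(g)
        r_obs = float((codes[0] != codes[1]).mean())
        assert abs(r_obs - kosambi_inverse(20.0)) < 0.01

    def test_invalid_progeny_count(self):
        with pytest.raises(ValueError):
            sim.simulate_progeny(self.markers(1), 0, 1)


def test_run_simulation_writes_outputs(tmp_path):
    p = sim.SimParams(genome_length=30_000, pstI_site_spacing=2_000, seed=6)
    sim.run_simulation(p, tmp_path, total_pairs=300)
    assert (tmp_path / "reference.fasta").exists()
    assert (tmp_path / "truth_variants.tsv").exists()
    assert (tmp_path / "truth_loci.tsv").exists()
    for name in p.sample_ids:
        assert (tmp_path / f"{name}_1.fastq").exists()
        assert (tmp_path / f"{name}_2.fastq").exists()
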