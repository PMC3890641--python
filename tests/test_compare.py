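import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from genofinish import compare as cp
from genofinish import synthdata as sd
from genofinish._seq import revcomp
from genofinish.genome import GeneModel, ReferenceGenome


class TestAlignCollinear:
    def test_identical_genomes(self, ref_genome):
        aln = cp.align_collinear(ref_genome.seq, ref_genome.seq)
        assert aln.aligned_a == aln.aligned_b == ref_genome.seq

    def test_planted_snps_recovered(self, ref_genome):
        strain, truth = sd.mutate_strain(ref_genome, 10, 0.5, 0, seed=3)
        aln = cp.align_collinear(ref_genome.seq, strain.seq)
        vs = cp.call_variants(aln)
        assert sorted(s.a_pos for s in vs.snps) == [s.position for s in truth.snps]
        assert vs.n_indel_events == 0

    def test_5bp_deletion_one_gap_run(self, ref_genome):
        b = ref_genome.seq[:4000] + ref_genome.seq[4005:]
        aln = cp.align_collinear(ref_genome.seq, b)
        vs = cp.call_variants(aln)
        assert vs.n_snps == 0
        assert vs.n_indel_events == 1
        assert vs.indels[0].length == 5 and not vs.indels[0].is_insertion

    def test_too_few_anchors_raises(self):
        with pytest.raises(cp.CollinearityError):
            cp.align_collinear("A" * 200, "T" * 200)

    def test_rearrangement_degrades_to_error_or_partial_chain(self, ref_genome):
        seq = ref_genome.seq
        swapped = seq[5000:] + seq[:5000]
        # a hard rearrangement must never be silently called collinear with
        # full coverage of matched anchors from both halves
        aln = cp.align_collinear(seq, swapped)
        vs = cp.call_variants(aln)
        assert vs.n_indel_events >= 1   # the unchained half shows up as indels


class TestCallVariants:
    def test_symmetry_of_counts(self, ref_genome):
        strain, _ = sd.mutate_strain(ref_genome, 20, 0.5, 3, seed=8)
        ab = cp.call_variants(cp.align_collinear(ref_genome.seq, strain.seq))
        ba = cp.call_variants(cp.align_collinear(strain.seq, ref_genome.seq))
        assert ab.n_snps == ba.n_snps
        assert ab.n_indel_events == ba.n_indel_events

    def test_pairwise_table_shape(self, ref_genome):
        strain, _ = sd.mutate_strain(ref_genome, 5, 0.5, 1, seed=9)
        vs = cp.call_variants(
            cp.align_collinear(ref_genome.seq, strain.seq), ("A", "B"))
        df = cp.pairwise_tables(["A", "B"], {("A", "B"): vs})
        assert df.loc["A", "B"] == vs.n_snps
        assert df.loc["B", "A"] == vs.n_indel_events


def _one_gene_genome(cds: str) -> ReferenceGenome:
    pad = "TTATTAGTTATCGTACGATTATTGCATTAA"
    seq = pad + cds + pad
    m = GeneModel(id="g1", segments=[(len(pad), len(pad) + len(cds))], strand="+")
    return ReferenceGenome(id="t", seq=seq, models=[m])


def _variant(genome: ReferenceGenome, pos: int, alt: str) -> cp.VariantSet:
    return cp.VariantSet(pair=("a", "b"),
                         snps=[cp.SNP(pos, genome.seq[pos], alt)])


class TestClassifyCodingEffects:
    def test_gct_to_gcc_synonymous(self):
        g = _one_gene_genome("ATG" + "GCT" + "TAA")
        vs = _variant(g, g.models[0].start + 5, "C")   # GCT -> GCC (Ala)
        tbl = cp.classify_coding_effects(vs, g)
        assert (tbl.n_synonymous, tbl.n_nonsynonymous) == (1, 0)

    def test_atg_to_ata_nonsynonymous_internally(self):
        g = _one_gene_genome("ATG" + "ATG" + "TAA")    # internal Met codon
        vs = _variant(g, g.models[0].start + 5, "A")   # ATG -> ATA (Ile)
        tbl = cp.classify_coding_effects(vs, g)
        assert (tbl.n_synonymous, tbl.n_nonsynonymous) == (0, 1)

    def test_start_codon_toggle_synonymous(self):
        g = _one_gene_genome("ATG" + "GCT" + "TAA")
        vs = _variant(g, g.models[0].start, "G")       # ATG -> GTG start
        tbl = cp.classify_coding_effects(vs, g)
        assert (tbl.n_synonymous, tbl.n_nonsynonymous) == (1, 0)

    def test_intergenic_counted_separately(self):
        g = _one_gene_genome("ATG" + "GCT" + "TAA")
        vs = _variant(g, 2, "C")
        tbl = cp.classify_coding_effects(vs, g)
        assert tbl.n_intergenic == 1
        assert tbl.n_synonymous == tbl.n_nonsynonymous == 0

    def test_minus_strand_classification(self):
        cds = "ATGGCTAAATTATGTTAA"
        pad = "TTATTAGTTATCGTACGATTATTGCATTAA"
        seq = pad + revcomp(cds) + pad
        m = GeneModel(id="g1", segments=[(len(pad), len(pad) + len(cds))], strand="-")
        g = ReferenceGenome(id="t", seq=seq, models=[m])
        # mutate coding GCT -> GCC: coding offset 5 -> genome pos end-1-5
        gpos = m.end - 1 - 5
        vs = cp.VariantSet(pair=("a", "b"), snps=[cp.SNP(gpos, seq[gpos], "G")])
        tbl = cp.classify_coding_effects(vs, g)
        assert (tbl.n_synonymous, tbl.n_nonsynonymous) == (1, 0)

    def test_truth_mix_recovered_and_matches_oracle(self, ref_genome):
        strain, truth = sd.mutate_strain(ref_genome, 30, 0.5, 0, seed=13)
        aln = cp.align_collinear(ref_genome.seq, strain.seq)
        tbl = cp.classify_coding_effects(cp.call_variants(aln), ref_genome)
        assert tbl.n_synonymous == 15
        assert tbl.n_nonsynonymous == 15
        # independent oracle: full-gene translate-and-diff
        n_nonsyn_oracle = 0
        for m in ref_genome.models:
            before = oracles.bio_translate(m.extract(ref_genome.seq))
            after = oracles.bio_translate(
                GeneModel(id=m.id, segments=list(m.segments), strand=m.strand)
                .extract(oracles.apply_events(ref_genome.seq, truth)))
            n_nonsyn_oracle += sum(a != b for a, b in zip(before, after))
        assert tbl.n_nonsynonymous == n_nonsyn_oracle

    def test_gene_with_indel_unclassified(self, ref_genome):
        m = ref_genome.models[3]
        pos = m.start + 10
        vs = cp.VariantSet(
            pair=("a", "b"),
            snps=[cp.SNP(m.start + 31, ref_genome.seq[m.start + 31], "A")],
            indels=[cp.IndelRecord(pos, "A", False, 1)],
        )
        if vs.snps[0].b_base == vs.snps[0].a_base:
            vs.snps[0] = cp.SNP(m.start + 31, ref_genome.seq[m.start + 31], "C")
        tbl = cp.classify_coding_effects(vs, ref_genome)
        assert tbl.n_unclassified == 1


class TestRunsTest:
    def test_block_sequence_matches_enumeration(self):
        res = cp.runs_test([1] * 5 + [0] * 5)
        dist = oracles.enumerate_runs_distribution(5, 5)
        mu = 2 * 5 * 5 / 10 + 1
        expected_p = sum(p for r, p in dist.items()
                         if abs(r - mu) >= abs(2 - mu) - 1e-12)
        assert res.runs_observed == 2
        assert res.method == "exact_enumeration"
        assert res.p_value == pytest.approx(expected_p)

    def test_alternating_sequence_symmetry(self):
        r2 = cp.runs_test([1] * 5 + [0] * 5)
        r10 = cp.runs_test([1, 0] * 5)
        assert abs(r10.z_statistic) == pytest.approx(abs(r2.z_statistic))
        assert r10.p_value == pytest.approx(r2.p_value)

    def test_degenerate_all_ones_raises(self):
        with pytest.raises(ValueError):
            cp.runs_test([1, 1, 1, 1])

    def test_normal_statistics_formulas(self):
        xs = [1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        res = cp.runs_test(xs)          # n = 22 > 20 -> normal approximation
        n1, n2 = sum(xs), len(xs) - sum(xs)
        n = n1 + n2
        mu = 2 * n1 * n2 / n + 1
        var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n * n * (n - 1))
        assert res.method == "normal_approx"
        assert res.z_statistic == pytest.approx(
            (oracles.count_runs(xs) - mu) / math.sqrt(var))

    @given(st.integers(2, 8), st.integers(2, 8), st.randoms())
    @settings(max_examples=25, deadline=None)
    def test_exact_method_matches_bruteforce_enumeration(self, n1, n2, rnd):
        bits = [1] * n1 + [0] * n2
        rnd.shuffle(bits)
        res = cp.runs_test(bits)
        dist = oracles.enumerate_runs_distribution(n1, n2)
        mu = 2 * n1 * n2 / (n1 + n2) + 1
        dev = abs(res.runs_observed - mu)
        expected = min(1.0, sum(p for r, p in dist.items()
                                if abs(r - mu) >= dev - 1e-12))
        assert res.p_value == pytest.approx(expected)


class TestGenomeStats:
    def test_no_features(self):
        g = ReferenceGenome(id="t", seq="ATAT", models=[])
        st_ = cp.genome_stats(g)
        assert st_.genic_size == 0
        assert st_.intergenic_gc_percent == 0.0
        assert st_.genome_size == 4

    def test_fully_covered_gc(self):
        g = ReferenceGenome(
            id="t", seq="GGCCCA",
            models=[GeneModel(id="g", segments=[(0, 6)], strand="+")])
        st_ = cp.genome_stats(g)
        assert st_.genic_size == 6 and st_.intergenic_size == 0
        assert st_.genic_gc_percent == pytest.approx(83.33)

    def test_overlapping_features_not_double_counted(self):
        g = ReferenceGenome(
            id="t", seq="A" * 99,
            models=[GeneModel(id="a", segments=[(0, 60)], strand="+"),
                    GeneModel(id="b", segments=[(30, 90)], strand="+")])
        st_ = cp.genome_stats(g)
        assert st_.genic_size == 90
        assert st_.genic_size + st_.intergenic_size == 99

    def test_synthetic_roundtrip_gc(self, spec_factory):
        spec = spec_factory(length=33_000, genes=30, genic_gc=0.2634)
        g = sd.simulate_reference(spec, seed=17)
        st_ = cp.genome_stats(g)
        assert abs(st_.genic_gc_percent - 26.34) < 2.0

    def test_partition_conservation_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = oracles.random_annotated_genome(rng)
            st_ = cp.genome_stats(g)
            assert st_.genic_size + st_.intergenic_size == len(g.seq)


class TestAtTrack:
    def test_window_values(self):
        track = cp.at_frequency_track("ATGC" * 50, window=100, step=10)
        assert all(v == 0.5 for _, _, v in track)

    def test_complement_invariance(self, ref_genome):
        comp = ref_genome.seq.translate(str.maketrans("ACGT", "TGCA"))
        t1 = cp.at_frequency_track(ref_genome.seq[:2000])
        t2 = cp.at_frequency_track(comp[:2000])
        assert t1 == t2
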