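import numpy as np
import pytest
from scipy.stats import binom

import oracles
from genofinish import _seq
from genofinish import synthdata as sd


class TestSimulateReference:
    def test_genic_gc_matches_spec(self, spec_factory):
        spec = spec_factory(length=55_000, genes=50, gene_len=900, genic_gc=0.2634)
        g = sd.simulate_reference(spec, seed=1)
        genic = "".join(g.seq[s:e] for m in g.models for s, e in m.segments)
        assert abs(oracles.gc_fraction(genic) - 0.2634) < 0.02

    def test_compositional_fidelity_over_seeds(self, spec_factory):
        spec = spec_factory(length=22_000, genes=20, genic_gc=0.2634, intergenic_gc=0.1572)
        for seed in range(10):
            g = sd.simulate_reference(spec, seed)
            genic = "".join(g.seq[s:e] for m in g.models for s, e in m.segments)
            ivs = _seq.merge_intervals([s for m in g.models for s in m.segments])
            inter = []
            prev = 0
            for s, e in ivs:
                inter.append(g.seq[prev:s])
                prev = e
            inter.append(g.seq[prev:])
            assert abs(oracles.gc_fraction(genic) - 0.2634) < 0.02
            assert abs(oracles.gc_fraction("".join(inter)) - 0.1572) < 0.02

    def test_orfs_are_clean(self, ref_genome):
        for m in ref_genome.models:
            prot = oracles.bio_translate(m.extract(ref_genome.seq))
            assert prot.endswith("*")
            assert "*" not in prot[:-1]
            assert m.extract(ref_genome.seq)[:3] == "ATG"

    def test_polya_rate_zero_plants_nothing(self, spec_factory):
        g = sd.simulate_reference(spec_factory(polyA_tract_rate=0.0), seed=3)
        assert g.polyA_tracts == []

    def test_deterministic(self, spec_factory):
        spec = spec_factory()
        a = sd.simulate_reference(spec, seed=5)
        b = sd.simulate_reference(spec, seed=5)
        assert a.seq == b.seq
        assert [m.segments for m in a.models] == [m.segments for m in b.models]

    def test_infeasible_spec_raises(self):
        with pytest.raises(sd.SizingError):
            sd.GenomeSpec(chromosome_length=1000, n_genes=50,
                          mean_gene_length=900).validate()

    def test_planted_tracts_are_homopolymers(self, ref_genome):
        for s, e in ref_genome.polyA_tracts:
            run = ref_genome.seq[s:e]
            assert len(set(run)) == 1 and run[0] in "AT" and len(run) >= 6


class TestMutateStrain:
    def test_zero_events_is_identity(self, ref_genome):
        strain, truth = sd.mutate_strain(ref_genome, 0, 0.5, 0, seed=1)
        assert strain.seq == ref_genome.seq
        assert truth.snps == [] and truth.indels == []

    def test_syn_nonsyn_mix_verified_by_translation_oracle(self, ref_genome):
        strain, truth = sd.mutate_strain(ref_genome, 50, 0.5, 0, seed=7)
        assert sum(s.synonymous for s in truth.snps) == 25
        assert sum(not s.synonymous for s in truth.snps) == 25
        by_model = {m.id: m for m in ref_genome.models}
        for snp in truth.snps:
            owner = next(m for m in ref_genome.models
                         if m.start <= snp.position < m.end)
            before = oracles.bio_translate(owner.extract(ref_genome.seq))
            mutated_seq = (ref_genome.seq[:snp.position] + snp.alt_base
                           + ref_genome.seq[snp.position + 1:])
            after = oracles.bio_translate(by_model[owner.id].extract(mutated_seq))
            assert (before == after) == snp.synonymous

    def test_indels_prefer_polya(self, ref_genome):
        _, truth = sd.mutate_strain(ref_genome, 0, 0.5, 5, seed=3)
        assert sum(i.in_polyA for i in truth.indels) >= 4

    def test_truth_roundtrip(self, ref_genome, strain_with_truth):
        strain, truth = strain_with_truth
        assert oracles.apply_events(ref_genome.seq, truth) == strain.seq

    def test_positions_strictly_increasing(self, strain_with_truth):
        _, truth = strain_with_truth
        truth.validate()

    def test_too_many_snps_raises(self, spec_factory):
        tiny = sd.simulate_reference(
            spec_factory(length=1100, genes=1, gene_len=900, spacer=200), seed=1)
        with pytest.raises(ValueError, match="eligible codon"):
            sd.mutate_strain(tiny, 5000, 0.5, 0, seed=1)


class TestShredContigs:
    def test_zero_gaps_single_contig(self, ref_genome):
        cs = sd.shred_contigs(ref_genome, 0, seed=1)
        assert len(cs.contigs) == 1
        assert cs.contigs[0][1] == ref_genome.seq

    def test_reassembly_identity(self, ref_genome):
        cs = sd.shred_contigs(ref_genome, 15, seed=2)
        assert len(cs.gaps) == 15
        parts = []
        for (s, e), (_, cseq) in zip(cs.gaps, cs.contigs):
            parts.append(cseq)
            parts.append(ref_genome.seq[s:e])
        parts.append(cs.contigs[-1][1])
        assert "".join(parts) == ref_genome.seq

    def test_gap_polya_bias(self, spec_factory):
        g = sd.simulate_reference(
            spec_factory(length=22_000, genes=20, polyA_tract_rate=2.0), seed=8)
        cs = sd.shred_contigs(g, 4, seed=4, polyA_gap_bias=1.0)
        tracts = g.polyA_tracts
        n_on_tract = sum(
            any(gs < te and ts < ge for ts, te in tracts)
            for gs, ge in cs.gaps
        )
        assert n_on_tract == 4

    def test_homopolymer_error_count_within_binomial_bounds(self, spec_factory):
        g = sd.simulate_reference(spec_factory(length=33_000, genes=30,
                                               polyA_tract_rate=1.0), seed=9)
        cs = sd.shred_contigs(g, 0, seed=5, homopolymer_error_rate=0.5)
        n_runs = sum(
            len(_seq.homopolymer_runs(seq, 6)) for _, seq in
            [("c", g.seq)]
        )
        lo, hi = binom.ppf([0.005, 0.995], n_runs, 0.5)
        assert lo <= len(cs.hp_errors) <= hi

    def test_insufficient_tracts_warns_and_falls_back(self, spec_factory):
        # balanced GC leaves (almost) no natural A/T runs to fall back on
        g = sd.simulate_reference(
            spec_factory(length=5_500, genes=5, polyA_tract_rate=0.0,
                         genic_gc=0.5, intergenic_gc=0.5), seed=2)
        with pytest.warns(UserWarning, match="poly-A"):
            cs = sd.shred_contigs(g, 8, seed=3, polyA_gap_bias=1.0)
        assert len(cs.gaps) == 8


class TestSimulateReads:
    def test_read_count_matches_coverage(self, ref_genome):
        rs = sd.simulate_reads(ref_genome, 200, seed=1)
        expected = len(ref_genome.seq) * 200 / 36
        assert abs(len(rs.reads) - expected) / expected < 0.05
        assert all(len(s) == 36 for s in rs.sequences())

    def test_error_free_reads_are_substrings(self, ref_genome):
        rs = sd.simulate_reads(ref_genome, 2, seed=6, error_rate=0.0)
        doubled = ref_genome.seq + ref_genome.seq[:36]
        for s in rs.sequences():
            assert s in doubled or oracles.bio_revcomp(s) in doubled

    def test_deterministic(self, ref_genome):
        a = sd.simulate_reads(ref_genome, 5, seed=9)
        b = sd.simulate_reads(ref_genome, 5, seed=9)
        assert a.reads == b.reads

    def test_error_rate_injects_mismatches(self, ref_genome):
        rs = sd.simulate_reads(ref_genome, 5, seed=3, error_rate=0.05)
        doubled = ref_genome.seq + ref_genome.seq[:36]
        n_exact = sum(
            s in doubled or oracles.bio_revcomp(s) in doubled
            for s in rs.sequences()
        )
        # P(read error-free) = 0.95^36 ~ 0.158
        assert n_exact / len(rs.reads) < 0.35

    def test_zero_coverage_raises(self, ref_genome):
        with pytest.raises(ValueError):
            sd.simulate_reads(ref_genome, 0, seed=1)
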