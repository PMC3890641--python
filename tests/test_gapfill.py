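import numpy as np
import pytest

import oracles
from genofinish import gapfill as gf
from genofinish import scaffold as sc
from genofinish import synthdata as sd
from genofinish._seq import revcomp


def _mini_repo(seqs, seed_length=30, max_mismatches=2):
    repo = gf.ReadRepository(seed_length=seed_length, max_mismatches=max_mismatches)
    for s in seqs:
        repo.add_read(s)
    return repo


class TestRepository:
    def test_three_reads_six_oriented(self):
        rng = np.random.default_rng(4)
        reads = ["".join(rng.choice(list("ACGT"), size=36)) for _ in range(3)]
        assert all(revcomp(r) != r for r in reads)
        repo = _mini_repo(reads)
        assert repo.n_reads == 3
        assert len(repo.seqs) == 6

    def test_palindrome_self_paired(self):
        pal = "ACGT" * 9
        assert revcomp(pal) == pal
        repo = _mini_repo([pal])
        assert len(repo.seqs) == 1
        assert repo.partner[0] == 0

    def test_short_reads_excluded_with_count(self):
        repo = _mini_repo(["ACGT" * 9, "ACGTACGT"])
        assert repo.n_reads == 1
        assert repo.n_too_short == 1

    def test_index_agrees_with_bruteforce_scan(self, ref_genome):
        reads = sd.simulate_reads(ref_genome, 8, seed=2, error_rate=0.01)
        repo = gf.build_repository(reads)
        rng = np.random.default_rng(0)
        L = len(ref_genome.seq)
        for _ in range(50):
            p = int(rng.integers(0, L - 30))
            seed = ref_genome.seq[p : p + 30]
            got = {i for i, w, mm in repo.query(seed)}
            expected = oracles.scan_reads_for_seed(seed, repo.seqs, 2)
            assert got == expected

    def test_consume_removes_pair(self):
        repo = _mini_repo(["A" * 20 + "CGTACGTACGTACGTA"])
        assert repo.n_active == 2
        repo.consume({0})
        assert repo.n_active == 0

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError):
            gf.build_repository([])


def _make_gap_scenario(rng_seed, gap_len=50, coverage=60.0, error_rate=0.0,
                       genome_len=4000):
    spec = sd.GenomeSpec(chromosome_length=genome_len,
                         n_genes=max(2, genome_len // 1000),
                         mean_gene_length=800, mean_intergenic_length=200)
    g = sd.simulate_reference(spec, rng_seed)
    mid = len(g.seq) // 2
    upstream = g.seq[:mid]
    truth_gap = g.seq[mid : mid + gap_len]
    downstream = g.seq[mid + gap_len:]
    reads = sd.simulate_reads(g, coverage, seed=rng_seed + 1, error_rate=error_rate)
    repo = gf.build_repository(reads)
    return g, upstream, truth_gap, downstream, repo


class TestExtendConsensus:
    def test_closes_50bp_gap_exactly(self):
        g, up, gap, down, repo = _make_gap_scenario(1)
        res = gf.extend_consensus(up, down, repo, gap_estimate=50)
        assert res.status == gf.CLOSED
        assert res.joined == g.seq

    def test_strict_majority_of_recorded_bases(self):
        # 3 reads share the seed; following bases A, A, G -> consensus A
        seed = "ATCGGATTACAGATCGGATTACAGATCGGA"
        assert len(seed) == 30
        reads = [seed + "A" + "TTTGG", seed + "A" + "CCAGG", seed + "G" + "ACAGG"]
        repo = _mini_repo(reads)
        res = gf.extend_consensus("TTACTT" + seed, "X" * 0 + "GGGGGG" * 10, repo,
                                  gap_estimate=3)
        assert res.filled_sequence.startswith("A")
        assert res.per_base_support[0] == 3

    def test_tie_aborts_with_partial_result(self):
        seed = "ATCGGATTACAGATCGGATTACAGATCGGA"
        reads = [seed + "ATTTGG", seed + "GCCAGG"]
        repo = _mini_repo(reads)
        res = gf.extend_consensus("TTACTT" + seed, "GGGGGG" * 10, repo,
                                  gap_estimate=3)
        assert res.status == gf.AMBIGUOUS_TIE
        assert res.filled_sequence == ""
        assert res.per_base_support == []

    def test_empty_repository_no_reads(self):
        repo = _mini_repo(["A" * 36])
        repo.consume({0})
        res = gf.extend_consensus("ACGT" * 10, "TTGCA" * 8, repo)
        assert res.status == gf.NO_READS

    def test_non_acgt_contig_rejected(self):
        repo = _mini_repo(["A" * 36])
        with pytest.raises(ValueError, match="non-ACGT"):
            gf.extend_consensus("ACGTN" * 8, "ACGT" * 10, repo)

    def test_cap_exceeded_on_unterminated_extension(self):
        g, up, gap, down, repo = _make_gap_scenario(3, gap_len=80)
        params = gf.GapFillParams(cap_slack=10)
        res = gf.extend_consensus(up, "G" * 40, repo, params, gap_estimate=5)
        assert res.status in (gf.CAP_EXCEEDED, gf.NO_READS, gf.AMBIGUOUS_TIE)

    def test_short_upstream_rejected(self):
        repo = _mini_repo(["A" * 36])
        with pytest.raises(ValueError, match="seed_length"):
            gf.extend_consensus("ACGT", "ACGT" * 10, repo)

    def test_small_overlap_extends_then_merges(self):
        g, up, gap, down, repo = _make_gap_scenario(4, gap_len=0)
        # downstream starts 10 bp before upstream's end: negative gap
        res = gf.extend_consensus(up, g.seq[len(up) - 10:], repo, gap_estimate=0)
        assert res.status == gf.CLOSED
        assert res.joined == g.seq

    def test_large_overlap_merges_without_extension(self):
        g, up, gap, down, repo = _make_gap_scenario(6, gap_len=0)
        res = gf.extend_consensus(up, g.seq[len(up) - 60:], repo, gap_estimate=0)
        assert res.status == gf.CLOSED
        assert res.joined == g.seq
        assert res.filled_sequence == ""


class TestReadConservation:
    def test_consumed_reads_never_vote_twice_and_repo_shrinks(self):
        g, up, gap, down, repo = _make_gap_scenario(5, gap_len=120)
        before = repo.n_active
        res = gf.extend_consensus(up, down, repo, gap_estimate=120)
        assert res.status == gf.CLOSED
        assert repo.n_active <= before
        assert res.reads_consumed <= before // 2 + 1
        assert len(res.per_base_support) == len(res.filled_sequence)
        assert all(s >= 1 for s in res.per_base_support)


class TestFillAllGaps:
    def test_zero_gap_scaffold_identity(self, ref_genome):
        placements, _ = sc.anchor_contigs({"c": ref_genome.seq}, ref_genome.seq)
        scaf = sc.build_scaffold(placements, len(ref_genome.seq))
        reads = sd.simulate_reads(ref_genome, 5, seed=1)
        repo = gf.build_repository(reads)
        out = gf.fill_all_gaps(scaf, {"c": ref_genome.seq}, repo)
        assert out.sequence == ref_genome.seq
        assert out.gap_results == []

    def test_multi_gap_end_to_end(self, ref_genome):
        strain, _ = sd.mutate_strain(ref_genome, 15, 0.5, 2, seed=9)
        cs = sd.shred_contigs(strain, 7, seed=10)
        placements, _ = sc.anchor_contigs(cs.sequences(), ref_genome.seq)
        scaf = sc.build_scaffold(placements, len(ref_genome.seq))
        reads = sd.simulate_reads(strain, 60, seed=11)
        repo = gf.build_repository(reads)
        out = gf.fill_all_gaps(scaf, cs.sequences(), repo)
        assert out.n_closed == 7
        assert out.sequence == strain.seq

    def test_unclosed_gap_becomes_n_run(self, ref_genome):
        cs = sd.shred_contigs(ref_genome, 3, seed=12)
        placements, _ = sc.anchor_contigs(cs.sequences(), ref_genome.seq)
        scaf = sc.build_scaffold(placements, len(ref_genome.seq))
        empty = _mini_repo(["A" * 36])
        empty.consume({0})
        out = gf.fill_all_gaps(scaf, cs.sequences(), empty)
        assert out.n_closed == 0
        assert "N" in out.sequence
        assert all(r.status == gf.NO_READS for r in out.gap_results)

    def test_exact_repeat_spanning_gap_misleads_filler(self):
        # a 200 bp exact repeat, one copy hidden in the gap: the filler either
        # cannot resolve it or mis-joins; the truth check must flag it
        rng = np.random.default_rng(0)
        unique = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        repeat = unique(200)
        genome = unique(900) + repeat + unique(500) + repeat + unique(900)
        gap_start, gap_end = 1500, 1900   # second repeat copy sits inside the gap
        contigs = {"a": genome[:gap_start], "b": genome[gap_end:]}
        reads = sd.simulate_reads(genome, 80, seed=3)
        repo = gf.build_repository(reads)
        res = gf.extend_consensus(contigs["a"], contigs["b"], repo,
                                  gap_estimate=gap_end - gap_start)
        flagged = res.status != gf.CLOSED or res.joined != genome
        assert flagged
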