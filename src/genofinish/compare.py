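"""Pairwise comparison of finished collinear genomes.

Whole-genome alignment by unique shared k-mer anchoring with global
alignment of the interstitial segments, SNP/indel-event calling,
per-gene synonymous/nonsynonymous classification under translation
table 11, a Wald-Wolfowitz runs test of nonsynonymous randomness, and
genome composition statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import norm

from . import _seq
from .genome import GeneModel, ReferenceGenome


class CollinearityError(ValueError):
    """Raised when the two genomes do not share a collinear anchor chain."""


# ---------------------------------------------------------------------------
# whole-genome alignment

@dataclass
class WholeGenomeAlignment:
    aligned_a: str
    aligned_b: str
    anchors_used: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def a_seq(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def b_seq(self) -> str:
        return self.aligned_b.replace("-", "")

    def a_to_b_map(self) -> np.ndarray:
        """Monotone coordinate map: for every a position (plus one-past-end),
        the corresponding b position (gaps project to the next b coordinate)."""
        la = len(self.a_seq)
        out = np.zeros(la + 1, dtype=np.int64)
        ai = bi = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                out[ai] = bi
                ai += 1
            if cb != "-":
                bi += 1
        out[la] = bi
        return out


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -3
    al.extend_gap_score = -1
    return al


def _align_segment(a: str, b: str, aligner: Align.PairwiseAligner) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    if a == b:
        return a, b
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def align_collinear(
    genome_a: str | ReferenceGenome,
    genome_b: str | ReferenceGenome,
    k: int = 17,
) -> WholeGenomeAlignment:
    """Full-coverage collinear alignment of two genomes.

    Anchors are k-mers unique in both genomes; the longest chain monotone in
    both coordinates is kept and the segments between consecutive anchors
    are globally aligned.  Fewer than 2 shared unique anchors raises
    :class:`CollinearityError` (use a direct global aligner for such inputs).
    """
    a = genome_a.seq if isinstance(genome_a, ReferenceGenome) else genome_a
    b = genome_b.seq if isinstance(genome_b, ReferenceGenome) else genome_b
    if a == b:
        return WholeGenomeAlignment(a, b, anchors_used=0)

    idx_a = _unique_kmers(a, k)
    idx_b = _unique_kmers(b, k)
    shared = sorted(
        (pa, idx_b[kmer]) for kmer, pa in idx_a.items() if kmer in idx_b
    )
    chain = _lis_by_second(shared)
    # enforce non-overlapping consecutive anchors
    filtered: list[tuple[int, int]] = []
    for pa, pb in chain:
        if not filtered or (pa >= filtered[-1][0] + k and pb >= filtered[-1][1] + k):
            filtered.append((pa, pb))
    if len(filtered) < 2:
        raise CollinearityError(
            "fewer than 2 collinear unique shared k-mers; "
            "genomes may be rearranged or too diverged for anchored alignment"
        )

    aligner = _aligner()
    parts_a: list[str] = []
    parts_b: list[str] = []
    prev_a = prev_b = 0
    for pa, pb in filtered:
        sa, sb = _align_segment(a[prev_a:pa], b[prev_b:pb], aligner)
        parts_a.append(sa)
        parts_b.append(sb)
        parts_a.append(a[pa : pa + k])
        parts_b.append(b[pb : pb + k])
        prev_a, prev_b = pa + k, pb + k
    sa, sb = _align_segment(a[prev_a:], b[prev_b:], aligner)
    parts_a.append(sa)
    parts_b.append(sb)

    aln = WholeGenomeAlignment("".join(parts_a), "".join(parts_b), anchors_used=len(filtered))
    if aln.a_seq != a or aln.b_seq != b:
        raise AssertionError("alignment does not reproduce its inputs")
    return aln


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        pos[kmer] = -1 if kmer in pos else i
    return {kmer: p for kmer, p in pos.items() if p >= 0}


def _lis_by_second(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest subsequence strictly increasing in the second coordinate
    (input sorted by the first)."""
    from bisect import bisect_left

    if not pairs:
        return []
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, pb) in enumerate(pairs):
        j = bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tails_idx.append(i)
        else:
            tails[j] = pb
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j else -1
    out = []
    i = tails_idx[-1]
    while i >= 0:
        out.append(pairs[i])
        i = prev[i]
    return out[::-1]


# ---------------------------------------------------------------------------
# variant calling

class SNP(NamedTuple):
    a_pos: int
    a_base: str
    b_base: str


class IndelRecord(NamedTuple):
    a_pos: int           # position on a where the event begins
    sequence: str        # inserted (into b) or deleted (from a) bases
    is_insertion: bool   # True: present in b, absent in a
    length: int


@dataclass
class VariantSet:
    pair: tuple[str, str]
    snps: list[SNP] = field(default_factory=list)
    indels: list[IndelRecord] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_indel_events(self) -> int:
        return len(self.indels)


def call_variants(
    alignment: WholeGenomeAlignment,
    pair: tuple[str, str] = ("a", "b"),
) -> VariantSet:
    """Mismatch columns become SNPs; each maximal gap run becomes one indel
    event (event-counted, not base-counted)."""
    vs = VariantSet(pair=pair)
    a_pos = 0
    gap_seq: list[str] = []
    gap_kind: str | None = None
    gap_start = 0

    def flush() -> None:
        nonlocal gap_seq, gap_kind
        if gap_kind is not None:
            vs.indels.append(IndelRecord(
                gap_start, "".join(gap_seq), gap_kind == "ins", len(gap_seq)
            ))
        gap_seq, gap_kind = [], None

    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            if gap_kind != "ins":
                flush()
                gap_kind, gap_start = "ins", a_pos
            gap_seq.append(cb)
        elif cb == "-":
            if gap_kind != "del":
                flush()
                gap_kind, gap_start = "del", a_pos
            gap_seq.append(ca)
            a_pos += 1
        else:
            flush()
            if ca != cb and ca in "ACGT" and cb in "ACGT":
                vs.snps.append(SNP(a_pos, ca, cb))
            a_pos += 1
    flush()
    return vs


def pairwise_tables(
    names: list[str],
    variant_sets: dict[tuple[str, str], VariantSet],
) -> pd.DataFrame:
    """SNP counts in the upper triangle, indel-event counts in the lower."""
    df = pd.DataFrame("", index=names, columns=names, dtype=object)
    for (na, nb), vs in variant_sets.items():
        ia, ib = names.index(na), names.index(nb)
        if ia < ib:
            df.iloc[ia, ib] = vs.n_snps
            df.iloc[ib, ia] = vs.n_indel_events
        else:
            df.iloc[ib, ia] = vs.n_snps
            df.iloc[ia, ib] = vs.n_indel_events
    return df


# ---------------------------------------------------------------------------
# coding-effect classification

@dataclass
class GeneEffectTable:
    per_gene: pd.DataFrame     # gene_id, order_index, n_synonymous, n_nonsynonymous
    n_synonymous: int
    n_nonsynonymous: int
    n_unclassified: int
    n_intergenic: int
    pair: tuple[str, str] = ("a", "b")

    def nonsyn_indicator(self) -> np.ndarray:
        """Per gene (genome order): 1 iff the gene has >=1 nonsynonymous SNP."""
        return (self.per_gene["n_nonsynonymous"].to_numpy() > 0).astype(int)


def classify_coding_effects(
    variants: VariantSet,
    genome_a: ReferenceGenome,
) -> GeneEffectTable:
    """Classify each coding SNP as synonymous/nonsynonymous by substituting
    the base in its genome-a codon and translating both codons (table 11).

    SNPs in dual-frame (polyA-merged) models and in genes overlapping indel
    events are tallied as unclassified.  A SNP toggling one accepted start
    codon into another at codon 1 counts as synonymous (both initiate Met).
    Each SNP is classified independently against the reference codon.
    """
    models = [m for m in genome_a.models if m.feature_type == "CDS"]
    indel_positions = [iv.a_pos for iv in variants.indels]

    rows = []
    seq = genome_a.seq
    n_syn = n_nonsyn = n_uncl = n_inter = 0
    per_gene_counts: dict[str, list[int]] = {m.id: [0, 0] for m in models}

    def owning_models(pos: int) -> list[GeneModel]:
        return [m for m in models if m.start <= pos < m.end
                and any(s <= pos < e for s, e in m.segments)]

    genes_with_indels = {
        m.id for m in models
        for p in indel_positions
        if m.start <= p <= m.end
    }

    for snp in variants.snps:
        owners = owning_models(snp.a_pos)
        if not owners:
            n_inter += 1
            continue
        for m in owners:
            if not m.is_single_frame or m.id in genes_with_indels:
                n_uncl += 1
                continue
            s, e = m.segments[0]
            if m.strand == "+":
                cds_off = snp.a_pos - s
                ref_b, alt_b = snp.a_base, snp.b_base
            else:
                cds_off = e - 1 - snp.a_pos
                ref_b, alt_b = _seq.revcomp(snp.a_base), _seq.revcomp(snp.b_base)
            ci, off = divmod(cds_off, 3)
            if m.strand == "+":
                codon = seq[s + 3 * ci : s + 3 * ci + 3]
            else:
                codon = _seq.revcomp(seq[e - 3 * ci - 3 : e - 3 * ci])
            alt_codon = codon[:off] + alt_b + codon[off + 1:]
            if ci == 0:
                syn = (codon in _seq.START_CODONS) and (alt_codon in _seq.START_CODONS)
            else:
                syn = _seq.CODON_TO_AA.get(codon, "X") == _seq.CODON_TO_AA.get(alt_codon, "X")
            if syn:
                n_syn += 1
                per_gene_counts[m.id][0] += 1
            else:
                n_nonsyn += 1
                per_gene_counts[m.id][1] += 1

    for i, m in enumerate(models):
        c = per_gene_counts[m.id]
        rows.append({
            "gene_id": m.id,
            "order_index": i,
            "n_synonymous": c[0],
            "n_nonsynonymous": c[1],
        })
    return GeneEffectTable(
        per_gene=pd.DataFrame(rows),
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
        n_unclassified=n_uncl,
        n_intergenic=n_inter,
        pair=variants.pair,
    )


# ---------------------------------------------------------------------------
# runs test

@dataclass
class RunsTestResult:
    n1: int
    n2: int
    runs_observed: int
    z_statistic: float
    p_value: float
    method: str                 # normal_approx | exact_enumeration


def _runs_exact_distribution(n1: int, n2: int) -> dict[int, float]:
    """Permutation distribution of the number of runs for n1 ones and n2
    zeros (closed-form combinatorial identities; equals full enumeration)."""
    n = n1 + n2
    total = comb(n, n1)
    dist: dict[int, float] = {}
    for kk in range(1, min(n1, n2) + 1):
        dist[2 * kk] = 2 * comb(n1 - 1, kk - 1) * comb(n2 - 1, kk - 1) / total
        p_odd = (comb(n1 - 1, kk - 1) * comb(n2 - 1, kk)
                 + comb(n1 - 1, kk) * comb(n2 - 1, kk - 1)) / total
        if p_odd:
            dist[2 * kk + 1] = dist.get(2 * kk + 1, 0.0) + p_odd
    return dist


def count_runs(x: Iterable[int]) -> int:
    xs = list(x)
    return 1 + sum(a != b for a, b in zip(xs, xs[1:])) if xs else 0


def runs_test(
    x: Iterable[int] | GeneEffectTable,
    exact_limit: int = 20,
) -> RunsTestResult:
    """Wald-Wolfowitz runs test on a binary sequence (or on the per-gene
    nonsynonymous indicator of a :class:`GeneEffectTable`).

    Normal approximation without continuity correction; for
    ``n1 + n2 <= exact_limit`` the two-sided p comes from the exact
    permutation distribution (symmetric-deviation convention,
    ``P(|R - mu| >= |r_obs - mu|)``).
    """
    xs = [int(v) for v in (x.nonsyn_indicator() if isinstance(x, GeneEffectTable) else x)]
    if any(v not in (0, 1) for v in xs):
        raise ValueError("runs test input must be binary")
    n1 = sum(xs)
    n2 = len(xs) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("runs test undefined: need at least one of each symbol")
    r = count_runs(xs)
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    z = (r - mu) / sqrt(var) if var > 0 else 0.0
    p_norm = min(1.0, 2.0 * (1.0 - norm.cdf(abs(z))))
    if n <= exact_limit:
        dist = _runs_exact_distribution(n1, n2)
        dev = abs(r - mu)
        p = min(1.0, sum(pr for rr, pr in dist.items() if abs(rr - mu) >= dev - 1e-12))
        method = "exact_enumeration"
    else:
        p = p_norm
        method = "normal_approx"
    return RunsTestResult(n1, n2, r, z, p, method)


# ---------------------------------------------------------------------------
# genome statistics

@dataclass
class GenomeStats:
    genome_size: int
    genic_size: int
    intergenic_size: int
    genic_gc_percent: float
    intergenic_gc_percent: float
    n_cds: int
    n_pseudogenes: int
    n_trna: int
    n_rrna: int
    avg_gene_length: float
    avg_intergenic_length: float


def genome_stats(genome: ReferenceGenome) -> GenomeStats:
    """Composition statistics over the genic/intergenic partition.

    Genic size is the number of bases covered by the union of all annotated
    features (overlaps never double-counted); intergenic is the exact
    complement, so genic + intergenic = genome size always.  GC percentages
    are rounded to 2 dp; mean gene length is over CDS features.
    """
    seq = genome.seq
    L = len(seq)
    ivs = _seq.merge_intervals([seg for m in genome.models for seg in m.segments])
    genic_size = sum(e - s for s, e in ivs)
    genic_seq = "".join(seq[s:e] for s, e in ivs)
    inter_parts = []
    prev = 0
    for s, e in ivs:
        inter_parts.append(seq[prev:s])
        prev = e
    inter_parts.append(seq[prev:])
    inter_seq = "".join(inter_parts)
    inter_lengths = [len(p) for p in inter_parts if p]

    cds = [m for m in genome.models if m.feature_type == "CDS"]
    return GenomeStats(
        genome_size=L,
        genic_size=genic_size,
        intergenic_size=L - genic_size,
        genic_gc_percent=round(100.0 * _seq.gc_fraction(genic_seq), 2),
        intergenic_gc_percent=round(100.0 * _seq.gc_fraction(inter_seq), 2),
        n_cds=len(cds),
        n_pseudogenes=sum(m.feature_type == "pseudogene" for m in genome.models),
        n_trna=sum(m.feature_type == "tRNA" for m in genome.models),
        n_rrna=sum(m.feature_type == "rRNA" for m in genome.models),
        avg_gene_length=round(float(np.mean([m.length for m in cds])), 2) if cds else 0.0,
        avg_intergenic_length=round(float(np.mean(inter_lengths)), 2) if inter_lengths else 0.0,
    )


def at_frequency_track(
    seq: str, window: int = 100, step: int = 10
) -> list[tuple[int, int, float]]:
    """Sliding-window AT fraction: (start, end, at_fraction) per window."""
    enc = _seq.encode(seq)
    is_at = ((enc == 0) | (enc == 3)).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_at)))
    out = []
    for start in range(0, max(1, len(seq) - window + 1), step):
        end = min(len(seq), start + window)
        out.append((start, end, float((cum[end] - cum[start]) / (end - start))))
    return out
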