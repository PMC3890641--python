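"""Synthetic endosymbiont-genome generator.

Produces AT-rich circular chromosomes with dense single-exon gene models,
diverged strains with a known event truth set, 454-style contigs whose gaps
and homopolymer-length errors are biased to poly-A tracts, and 36 bp
single-end reads — everything downstream is exercised against these known
truths, no downloads required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _seq
from .genome import GeneModel, ReferenceGenome

_BASES = "ACGT"
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class SizingError(ValueError):
    """The requested gene census cannot fit in the requested genome length."""


@dataclass
class GenomeSpec:
    """Parameters of a simulated chromosome.

    Defaults follow the compositional regime of a reduced, AT-rich
    endosymbiont chromosome: genic GC ~26.3%, intergenic GC ~15.7%, mean
    gene length ~989 bp with ~118 bp spacers.
    """

    chromosome_length: int = 100_000
    n_genes: int = 90
    mean_gene_length: int = 989
    mean_intergenic_length: int = 118
    genic_gc: float = 0.2634
    intergenic_gc: float = 0.1572
    polyA_tract_rate: float = 0.5  # tracts per kb
    polyA_length_range: tuple[int, int] = (8, 12)
    plasmid_specs: list[tuple[str, int, int]] = field(default_factory=list)
    circular: bool = True

    def validate(self) -> None:
        if not (0.0 < self.genic_gc < 1.0 and 0.0 < self.intergenic_gc < 1.0):
            raise ValueError("GC fractions must lie strictly between 0 and 1")
        if self.n_genes < 1 or self.mean_gene_length < 60:
            raise SizingError("need >=1 gene of >=60 bp")
        expected = self.n_genes * (self.mean_gene_length + self.mean_intergenic_length)
        if abs(expected - self.chromosome_length) > 0.10 * self.chromosome_length:
            raise SizingError(
                f"n_genes*(gene+spacer) = {expected} not within 10% of "
                f"chromosome_length = {self.chromosome_length}"
            )


class SNPEvent(NamedTuple):
    position: int        # reference coordinate of the substituted base
    ref_base: str
    alt_base: str
    coding: bool
    synonymous: bool


class IndelEvent(NamedTuple):
    position: int        # reference coordinate (insertion: base inserted *after* position-1)
    sequence: str        # inserted or deleted bases
    is_insertion: bool
    in_polyA: bool


@dataclass
class StrainTruth:
    """Known divergence events of a simulated strain, in reference coordinates."""

    strain_id: str
    snps: list[SNPEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)

    def validate(self) -> None:
        positions = [s.position for s in self.snps] + [i.position for i in self.indels]
        if len(positions) != len(set(positions)):
            raise ValueError("truth events overlap")
        for events in (self.snps, self.indels):
            if any(b.position <= a.position for a, b in zip(events, events[1:])):
                raise ValueError("truth positions not strictly increasing")


@dataclass
class SimulatedGenome(ReferenceGenome):
    """A reference genome plus generator-side truth annotations."""

    polyA_tracts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ContigSet:
    """Shredded contigs with the true gap coordinates they were cut around."""

    contigs: list[tuple[str, str]]
    gaps: list[tuple[int, int]] = field(default_factory=list)   # genome coords, half-open
    hp_errors: list[tuple[str, int, int]] = field(default_factory=list)  # (contig_id, contig_pos, delta)

    def sequences(self) -> dict[str, str]:
        return dict(self.contigs)


@dataclass
class SimulatedReadSet:
    reads: list[tuple[str, str, str]]   # (id, sequence, quality)
    read_length: int = 36
    mean_coverage: float = 0.0
    error_rate: float = 0.0
    rng_seed: int = 0

    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.reads]


# ---------------------------------------------------------------------------
# reference simulation

def _sampling_gc_for(target: float) -> float:
    """Per-base GC to sample at so the stop-codon-rejected output hits ``target``.

    Rejecting stop codons (TAA/TAG/TGA) enriches GC; invert that bias by
    bisection on the closed-form post-rejection mean.
    """
    def out_gc(x: float) -> float:
        a = (1 - x) / 2
        p_stop = a * a * (a + x)          # TAA + TAG + TGA
        gc_in_stops = a * a * x           # TAG, TGA carry one G each
        return (3 * x - gc_in_stops) / (3 * (1 - p_stop))

    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(50):
        mid = (lo + hi) / 2
        if out_gc(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _gene_body(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Random internal codons with no stop codons, approximately at ``gc``."""
    gc = _sampling_gc_for(gc)
    codons: list[str] = []
    while len(codons) < n_codons:
        chunk = _seq.random_dna(rng, 3 * (n_codons - len(codons)), gc)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon not in _seq.STOP_CODONS:
                codons.append(codon)
    return "".join(codons[:n_codons])


def simulate_reference(spec: GenomeSpec, seed: int) -> SimulatedGenome:
    """Generate a chromosome satisfying ``spec``; deterministic in ``seed``.

    Every CDS starts with ATG, ends with a stop codon, and contains no
    internal stop under table 11.  Poly-A tracts are planted at
    ``polyA_tract_rate`` per kb, preferentially (80%) in intergenic spacers;
    genic tracts are in-frame runs of AAA (Lys) codons so ORFs stay open.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    gene_lengths = []
    for _ in range(spec.n_genes):
        ln = int(rng.normal(spec.mean_gene_length, 0.15 * spec.mean_gene_length))
        ln = max(90, ln - ln % 3)
        gene_lengths.append(ln)
    spacer_lengths = [
        max(20, int(rng.normal(spec.mean_intergenic_length, 0.3 * spec.mean_intergenic_length)))
        for _ in range(spec.n_genes + 1)
    ]

    total = sum(gene_lengths) + sum(spacer_lengths)
    n_tracts = int(round(spec.polyA_tract_rate * total / 1000.0))

    genes: list[str] = []
    strands: list[str] = []
    for ln in gene_lengths:
        body = _gene_body(rng, ln // 3 - 2, spec.genic_gc)
        stop = str(rng.choice(["TAA", "TAG", "TGA"], p=[0.6, 0.2, 0.2]))
        genes.append("ATG" + body + stop)
        strands.append("+" if rng.random() < 0.5 else "-")
    spacers = [_seq.random_dna(rng, ln, spec.intergenic_gc) for ln in spacer_lengths]

    # plant poly-A tracts; record (container_kind, index, offset, tract)
    planted: list[tuple[str, int, int, str]] = []
    for _ in range(n_tracts):
        lo, hi = spec.polyA_length_range
        tlen = int(rng.integers(lo, hi + 1))
        base = "A" if rng.random() < 0.5 else "T"
        if rng.random() < 0.8:  # intergenic
            idx = int(rng.integers(0, len(spacers)))
            sp = spacers[idx]
            if len(sp) < tlen + 4:
                continue
            off = int(rng.integers(2, len(sp) - tlen - 1))
            spacers[idx] = sp[:off] + base * tlen + sp[off + tlen:]
            planted.append(("spacer", idx, off, base * tlen))
        else:  # genic: in-frame AAA (or TTT on the template strand) codons
            glen = max(6, tlen - tlen % 3)
            idx = int(rng.integers(0, len(genes)))
            g = genes[idx]
            n_codons = glen // 3
            max_codon = len(g) // 3 - 1 - n_codons
            if max_codon <= 2:
                continue
            ci = int(rng.integers(2, max_codon))
            genes[idx] = g[: 3 * ci] + "A" * glen + g[3 * ci + glen:]
            planted.append(("gene", idx, 3 * ci, "A" * glen))

    parts: list[str] = []
    models: list[GeneModel] = []
    tracts: list[tuple[int, int]] = []
    pos = 0

    def _note_spacer_tracts(idx: int, at: int) -> None:
        for kind, i, off, tract in planted:
            if kind == "spacer" and i == idx:
                tracts.append((at + off, at + off + len(tract)))

    _note_spacer_tracts(0, 0)
    parts.append(spacers[0])
    pos += len(spacers[0])
    for gi, (gene, strand) in enumerate(zip(genes, strands)):
        placed = gene if strand == "+" else _seq.revcomp(gene)
        for kind, i, off, tract in planted:
            if kind == "gene" and i == gi:
                if strand == "+":
                    tracts.append((pos + off, pos + off + len(tract)))
                else:
                    tracts.append((pos + len(gene) - off - len(tract), pos + len(gene) - off))
        models.append(GeneModel(
            id=f"G{gi + 1:04d}",
            segments=[(pos, pos + len(gene))],
            strand=strand,
            feature_type="CDS",
            product="hypothetical protein",
        ))
        parts.append(placed)
        pos += len(gene)
        _note_spacer_tracts(gi + 1, pos)
        parts.append(spacers[gi + 1])
        pos += len(spacers[gi + 1])

    genome = SimulatedGenome(
        id=f"sim_{seed}",
        seq="".join(parts),
        models=models,
        circular=spec.circular,
        polyA_tracts=sorted(tracts),
    )
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# strain divergence

def _codon_site_alternatives(codon: str, offset: int) -> tuple[list[str], list[str]]:
    """Alternative bases at ``offset`` of ``codon`` split into (syn, nonsyn).

    Nonsynonymous alternatives that create a stop codon are excluded.
    """
    aa = _seq.CODON_TO_AA[codon]
    syn, nonsyn = [], []
    for b in _BASES:
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1:]
        alt_aa = _seq.CODON_TO_AA[alt]
        if alt_aa == aa:
            syn.append(b)
        elif alt_aa != "*":
            nonsyn.append(b)
    return syn, nonsyn


def mutate_strain(
    ref: ReferenceGenome,
    n_snps: int,
    syn_fraction: float,
    n_indels: int,
    seed: int,
    strain_id: str = "strain",
    polyA_indel_prob: float = 0.8,
    intergenic_indels_only: bool = False,
) -> tuple[SimulatedGenome, StrainTruth]:
    """Plant coding SNPs with an exact syn/nonsyn mix plus 1 bp indels.

    ``round(n_snps * syn_fraction)`` SNPs are synonymous, the rest
    nonsynonymous (never creating a stop); synonymy is established by codon
    substitution under table 11.  ``round(n_indels * polyA_indel_prob)``
    indels fall inside poly-A tracts, the remainder at uniform intergenic
    positions.  Returns the mutated genome (with coordinate-shifted models)
    and the truth set in reference coordinates.
    """
    if not 0.0 <= syn_fraction <= 1.0:
        raise ValueError("syn_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_syn = int(round(n_snps * syn_fraction))
    n_nonsyn = n_snps - n_syn

    tracts = list(getattr(ref, "polyA_tracts", [])) or \
        [(s, e) for s, e, _ in _seq.homopolymer_runs(ref.seq, 6)]
    tract_positions = set()
    for s, e in tracts:
        tract_positions.update(range(s - 1, e + 1))

    # candidate codon sites: (genome positions of codon, offset, strand)
    sites = []
    for m in ref.cds_models():
        if not m.is_single_frame:
            continue
        s, e = m.segments[0]
        n_codons = (e - s) // 3
        for ci in range(1, n_codons - 1):      # skip start and stop codons
            sites.append((m, ci))
    rng.shuffle(sites)

    used: set[int] = set()
    snps: list[SNPEvent] = []
    want = {"syn": n_syn, "nonsyn": n_nonsyn}
    for m, ci in sites:
        if want["syn"] == 0 and want["nonsyn"] == 0:
            break
        s, e = m.segments[0]
        if m.strand == "+":
            codon = ref.seq[s + 3 * ci : s + 3 * ci + 3]
        else:
            codon = _seq.revcomp(ref.seq[e - 3 * ci - 3 : e - 3 * ci])
        syn_alts, nonsyn_alts = _codon_site_alternatives_all(codon)
        for kind, per_offset in (("syn", syn_alts), ("nonsyn", nonsyn_alts)):
            if want[kind] == 0:
                continue
            offsets = [o for o in range(3) if per_offset[o]]
            if not offsets:
                continue
            off = offsets[int(rng.integers(0, len(offsets)))]
            if m.strand == "+":
                gpos = s + 3 * ci + off
            else:
                gpos = e - 3 * ci - 1 - off
            if gpos in used or gpos in tract_positions:
                continue
            alt_coding = per_offset[off][int(rng.integers(0, len(per_offset[off])))]
            alt_genome = alt_coding if m.strand == "+" else _seq.revcomp(alt_coding)
            snps.append(SNPEvent(gpos, ref.seq[gpos], alt_genome, True, kind == "syn"))
            used.add(gpos)
            want[kind] -= 1
            break
    if want["syn"] or want["nonsyn"]:
        raise ValueError(
            f"not enough eligible codon positions (short {want['syn']} syn / {want['nonsyn']} nonsyn)"
        )

    # indels
    genic_iv = _seq.merge_intervals([seg for m in ref.models for seg in m.segments])

    def _is_genic(p: int) -> bool:
        from bisect import bisect_right
        i = bisect_right(genic_iv, (p, len(ref.seq) + 1)) - 1
        return i >= 0 and genic_iv[i][0] <= p < genic_iv[i][1]

    n_in_tract = min(int(round(n_indels * polyA_indel_prob)), n_indels)
    # canonicalise to maximal homopolymer runs and dedupe: two planted tracts
    # can merge into one run, and opposite indels in one run would cancel
    seen_runs: set[int] = set()
    avail = []
    for s, e in tracts:
        base = ref.seq[s]
        rs, re_ = s, e
        while rs > 0 and ref.seq[rs - 1] == base:
            rs -= 1
        while re_ < len(ref.seq) and ref.seq[re_] == base:
            re_ += 1
        if rs not in seen_runs:
            seen_runs.add(rs)
            avail.append((rs, re_))
    if intergenic_indels_only:
        avail = [t for t in avail if not (_is_genic(t[0]) or _is_genic(t[1] - 1))]
    rng.shuffle(avail)
    if len(avail) < n_in_tract:
        warnings.warn("fewer poly-A tracts than requested tract indels; using what exists")
        n_in_tract = len(avail)
    indels: list[IndelEvent] = []
    for s, e in avail[:n_in_tract]:
        base = ref.seq[s]
        if rng.random() < 0.5:
            indels.append(IndelEvent(s + 1, base, True, True))
        else:
            indels.append(IndelEvent(s + 1, base, False, True))
        used.update(range(s, e))
    genic = set()
    for m in ref.models:
        genic.update(range(m.start, m.end))
    attempts = 0
    while len(indels) < n_indels and attempts < 10_000:
        attempts += 1
        p = int(rng.integers(50, len(ref.seq) - 50))
        if p in used or p in genic or p in tract_positions:
            continue
        if rng.random() < 0.5:
            indels.append(IndelEvent(p, str(rng.choice(list(_BASES))), True, False))
        else:
            indels.append(IndelEvent(p, ref.seq[p], False, False))
        used.add(p)
    if len(indels) < n_indels:
        raise ValueError("could not place all requested indels")

    truth = StrainTruth(
        strain_id=strain_id,
        snps=sorted(snps, key=lambda x: x.position),
        indels=sorted(indels, key=lambda x: x.position),
    )
    truth.validate()

    strain_seq = apply_truth(ref.seq, truth)

    # shift model/tract coordinates through the planted indels
    events = sorted(
        [(i.position, (1 if i.is_insertion else -1) * len(i.sequence)) for i in truth.indels]
    )
    def shift(p: int) -> int:
        d = 0
        for pos, delta in events:
            if pos < p:
                d += delta
        return p + d

    new_models = []
    for m in ref.models:
        nm = m.copy()
        nm.segments = [(shift(s), shift(e)) for s, e in m.segments]
        new_models.append(nm)
    strain = SimulatedGenome(
        id=strain_id,
        seq=strain_seq,
        models=new_models,
        circular=ref.circular,
        polyA_tracts=[(shift(s), shift(e)) for s, e in getattr(ref, "polyA_tracts", [])],
    )
    return strain, truth


def _codon_site_alternatives_all(codon: str):
    """Per-offset alternative bases: ([syn@0, syn@1, syn@2], [nonsyn@...])."""
    syn = [[], [], []]
    nonsyn = [[], [], []]
    for off in range(3):
        s, n = _codon_site_alternatives(codon, off)
        syn[off] = s
        nonsyn[off] = n
    return syn, nonsyn


def apply_truth(ref_seq: str, truth: StrainTruth) -> str:
    """Reconstruct the strain sequence from the reference and the truth set."""
    edits: list[tuple[int, int, str]] = []   # (pos, ref_len, replacement)
    for s in truth.snps:
        if ref_seq[s.position] != s.ref_base:
            raise ValueError(f"SNP ref base mismatch at {s.position}")
        edits.append((s.position, 1, s.alt_base))
    for i in truth.indels:
        if i.is_insertion:
            edits.append((i.position, 0, i.sequence))
        else:
            if ref_seq[i.position : i.position + len(i.sequence)] != i.sequence:
                raise ValueError(f"indel ref sequence mismatch at {i.position}")
            edits.append((i.position, len(i.sequence), ""))
    seq = ref_seq
    for pos, ref_len, repl in sorted(edits, reverse=True):
        seq = seq[:pos] + repl + seq[pos + ref_len:]
    return seq


# ---------------------------------------------------------------------------
# contig shredding

def shred_contigs(
    genome: ReferenceGenome,
    n_gaps: int,
    seed: int,
    gap_length_range: tuple[int, int] = (50, 300),
    polyA_gap_bias: float = 0.8,
    homopolymer_error_rate: float = 0.0,
    min_contig: int = 120,
) -> ContigSet:
    """Cut the (linearised) genome into contigs separated by gaps.

    A fraction ``polyA_gap_bias`` of gaps are centred on poly-A tracts
    (falling back to uniform placement with a warning when tracts run out);
    the rest are uniform.  With ``homopolymer_error_rate`` > 0, each A/T
    homopolymer run >= 6 bp inside a contig independently suffers a +-1 bp
    length error with that probability — the 454 error mode.
    """
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    if n_gaps == 0:
        contigs = ContigSet(contigs=[("contig_0001", genome.seq)])
        return _apply_hp_errors(contigs, homopolymer_error_rate, rng)

    tracts = list(getattr(genome, "polyA_tracts", [])) or \
        [(s, e) for s, e, _ in _seq.homopolymer_runs(genome.seq, 6)]
    tracts = [t for t in tracts if min_contig < t[0] and t[1] < L - min_contig]
    rng.shuffle(tracts)

    n_bias = int(round(n_gaps * polyA_gap_bias))
    gaps: list[tuple[int, int]] = []

    def _fits(s: int, e: int) -> bool:
        if s < min_contig or e > L - min_contig:
            return False
        return all(e + min_contig <= gs or ge + min_contig <= s for gs, ge in gaps)

    placed_bias = 0
    for ts, te in tracts:
        if placed_bias >= n_bias:
            break
        glen = int(rng.integers(gap_length_range[0], gap_length_range[1] + 1))
        centre = (ts + te) // 2
        s = max(0, centre - glen // 2)
        e = s + glen
        if _fits(s, e):
            gaps.append((s, e))
            placed_bias += 1
    if placed_bias < n_bias:
        warnings.warn("not enough usable poly-A tracts for the requested gap bias; "
                      "placing remaining gaps uniformly")

    attempts = 0
    while len(gaps) < n_gaps and attempts < 100_000:
        attempts += 1
        glen = int(rng.integers(gap_length_range[0], gap_length_range[1] + 1))
        s = int(rng.integers(min_contig, L - min_contig - glen))
        if _fits(s, s + glen):
            gaps.append((s, s + glen))
    if len(gaps) < n_gaps:
        raise ValueError("could not place the requested number of gaps")

    gaps.sort()
    contigs: list[tuple[str, str]] = []
    prev = 0
    for i, (s, e) in enumerate(gaps):
        contigs.append((f"contig_{i + 1:04d}", genome.seq[prev:s]))
        prev = e
    contigs.append((f"contig_{len(gaps) + 1:04d}", genome.seq[prev:]))
    cs = ContigSet(contigs=contigs, gaps=gaps)
    return _apply_hp_errors(cs, homopolymer_error_rate, rng)


def _apply_hp_errors(cs: ContigSet, rate: float, rng: np.random.Generator) -> ContigSet:
    if rate <= 0:
        return cs
    new_contigs = []
    for cid, seq in cs.contigs:
        runs = _seq.homopolymer_runs(seq, 6)
        out = []
        prev = 0
        for s, e, base in runs:
            out.append(seq[prev:s])
            run = seq[s:e]
            if rng.random() < rate:
                delta = 1 if rng.random() < 0.5 else -1
                run = base * (e - s + delta)
                cs.hp_errors.append((cid, s, delta))
            out.append(run)
            prev = e
        out.append(seq[prev:])
        new_contigs.append((cid, "".join(out)))
    cs.contigs = new_contigs
    return cs


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(
    genome: ReferenceGenome | str,
    mean_coverage: float,
    seed: int,
    read_length: int = 36,
    error_rate: float = 0.0,
) -> SimulatedReadSet:
    """Uniform single-end reads over the circular sequence (wrapping starts),
    both strands equiprobable, i.i.d. substitution errors at ``error_rate``."""
    seq = genome.seq if isinstance(genome, ReferenceGenome) else genome
    circular = genome.circular if isinstance(genome, ReferenceGenome) else True
    L = len(seq)
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if read_length > L:
        raise ValueError("read_length exceeds genome length")

    rng = np.random.default_rng(seed)
    n_reads = int(round(L * mean_coverage / read_length))
    enc = _seq.encode(seq)
    if circular:
        starts = rng.integers(0, L, size=n_reads)
    else:
        starts = rng.integers(0, L - read_length + 1, size=n_reads)
    idx = (starts[:, None] + np.arange(read_length)[None, :]) % L
    mat = enc[idx]

    rc = rng.random(n_reads) < 0.5
    mat[rc] = 3 - mat[rc][:, ::-1]  # codes 0..3 only: A<->T, C<->G

    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        mat[mask] = (mat[mask] + shift) % 4

    qual = "I" * read_length
    raw = _CODE_TO_BASE[mat]
    reads = [
        (f"read_{i + 1:07d}", raw[i].tobytes().decode("ascii"), qual)
        for i in range(n_reads)
    ]
    return SimulatedReadSet(
        reads=reads,
        read_length=read_length,
        mean_coverage=mean_coverage,
        error_rate=error_rate,
        rng_seed=seed,
    )
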