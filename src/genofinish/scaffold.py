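"""Reference-synteny scaffolding: order/orient contigs on a collinear
reference with unique k-mer anchors and infer gap sizes from reference
distance."""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

from . import _seq
from .genome import ReferenceGenome

log = logging.getLogger(__name__)


@dataclass
class ContigPlacement:
    contig_id: str
    reference_start: int
    reference_end: int
    strand: str
    identity: float
    anchor_count: int
    trim_left: int = 0    # bases trimmed from the oriented contig's start
    trim_right: int = 0   # bases trimmed from the oriented contig's end

    def validate(self) -> None:
        if self.reference_start >= self.reference_end:
            raise ValueError(f"{self.contig_id}: start >= end")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.contig_id}: identity outside [0, 1]")


@dataclass
class ScaffoldGap:
    upstream_contig: str
    downstream_contig: str
    estimated_length: int


@dataclass
class Scaffold:
    placements: list[ContigPlacement]
    gaps: list[ScaffoldGap]
    dropped: list[str] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    def oriented_contigs(self, contigs: dict[str, str]) -> list[tuple[str, str]]:
        """Contig sequences in scaffold order, oriented to the reference
        strand and trimmed as recorded during overlap resolution."""
        out = []
        for p in self.placements:
            seq = contigs[p.contig_id]
            if p.strand == "-":
                seq = _seq.revcomp(seq)
            if p.trim_left or p.trim_right:
                seq = seq[p.trim_left : len(seq) - p.trim_right or None]
            out.append((p.contig_id, seq))
        return out


def _unique_kmer_index(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = -1 if kmer in counts else i   # -1 marks repeats
    return {kmer: pos for kmer, pos in counts.items() if pos >= 0}


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchors increasing in both coordinates
    (anchors pre-sorted by contig position)."""
    if not anchors:
        return []
    tails: list[int] = []          # ref positions of chain tails
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for i, (_, rpos) in enumerate(anchors):
        j = bisect_left(tails, rpos)
        if j == len(tails):
            tails.append(rpos)
            tails_idx.append(i)
        else:
            tails[j] = rpos
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(anchors[i])
        i = prev[i]
    return chain[::-1]


def _chain_identity(contig: str, reference: str, chain: list[tuple[int, int]]) -> float:
    """Identity estimate from direct comparison at anchor-implied offsets."""
    matches = 0
    compared = 0
    for i, (cpos, rpos) in enumerate(chain):
        nxt_c = chain[i + 1][0] if i + 1 < len(chain) else len(contig)
        span = nxt_c - cpos
        off = rpos - cpos
        for j in range(cpos, min(nxt_c, cpos + span)):
            r = j + off
            if 0 <= r < len(reference):
                compared += 1
                if contig[j] == reference[r]:
                    matches += 1
    return matches / compared if compared else 0.0


def anchor_contigs(
    contigs: dict[str, str],
    reference: ReferenceGenome | str,
    k: int = 17,
) -> tuple[list[ContigPlacement], list[str]]:
    """Place each contig on the reference via unique k-mer anchors and
    collinear chaining; returns (placements, unplaced contig ids)."""
    ref_seq = reference.seq if isinstance(reference, ReferenceGenome) else reference
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(ref_seq) < k:
        raise ValueError("reference shorter than k")
    if not contigs:
        raise ValueError("no contigs supplied")
    ref_index = _unique_kmer_index(ref_seq, k)

    placements: list[ContigPlacement] = []
    unplaced: list[str] = []
    for cid, seq in contigs.items():
        best = None
        for strand, oriented in (("+", seq), ("-", _seq.revcomp(seq))):
            anchors = []
            for i in range(len(oriented) - k + 1):
                pos = ref_index.get(oriented[i : i + k])
                if pos is not None:
                    anchors.append((i, pos))
            chain = _lis_chain(anchors)
            if chain and (best is None or len(chain) > best[2]):
                best = (strand, oriented, len(chain), chain)
        if best is None:
            unplaced.append(cid)
            continue
        strand, oriented, n_anchors, chain = best
        first_c, first_r = chain[0]
        last_c, last_r = chain[-1]
        start = max(0, first_r - first_c)
        end = min(len(ref_seq), last_r + (len(oriented) - last_c))
        p = ContigPlacement(
            contig_id=cid,
            reference_start=start,
            reference_end=end,
            strand=strand,
            identity=_chain_identity(oriented, ref_seq, chain),
            anchor_count=n_anchors,
        )
        p.validate()
        placements.append(p)
    return placements, unplaced


def build_scaffold(
    placements: list[ContigPlacement],
    reference_length: int,
    contig_lengths: dict[str, int] | None = None,
) -> Scaffold:
    """Order placements, drop contained contigs, trim overlaps at the
    midpoint, and infer gap sizes from reference distance."""
    if not placements:
        raise ValueError("no placements to scaffold")
    ordered = sorted(placements, key=lambda p: (p.reference_start, p.reference_end))

    kept: list[ContigPlacement] = []
    dropped: list[str] = []
    for p in ordered:
        if kept and p.reference_end <= kept[-1].reference_end:
            log.warning("contig %s fully contained in %s; dropped",
                        p.contig_id, kept[-1].contig_id)
            dropped.append(p.contig_id)
            continue
        kept.append(p)

    # trim overlapping neighbours at the midpoint of the overlap
    for a, b in zip(kept, kept[1:]):
        overlap = a.reference_end - b.reference_start
        if overlap > 0:
            left = overlap // 2
            right = overlap - left
            a.reference_end -= right
            a.trim_right += right
            b.reference_start += left
            b.trim_left += left

    gaps = [
        ScaffoldGap(a.contig_id, b.contig_id, max(0, b.reference_start - a.reference_end))
        for a, b in zip(kept, kept[1:])
    ]
    return Scaffold(placements=kept, gaps=gaps, dropped=dropped)
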