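"""Independent oracles used by the test suite.

Everything here is deliberately written against *other* primitives than the
package uses (Biopython translation, brute-force scanning, itertools
enumeration) so each check is a genuine dual route.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def bio_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def bio_translate(seq: str) -> str:
    """Translation table 11 via Biopython, trailing partial codon dropped."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate(table=11))


def apply_events(ref_seq: str, truth) -> str:
    """Left-to-right reconstruction of a strain sequence from a truth set
    (independent of synthdata.apply_truth, which edits right-to-left)."""
    events = {}
    for s in truth.snps:
        events[s.position] = ("snp", s)
    for i in truth.indels:
        events[i.position] = ("ins" if i.is_insertion else "del", i)
    out = []
    pos = 0
    while pos < len(ref_seq):
        if pos in events:
            kind, ev = events[pos]
            if kind == "snp":
                assert ref_seq[pos] == ev.ref_base
                out.append(ev.alt_base)
                pos += 1
            elif kind == "ins":
                out.append(ev.sequence)
                out.append(ref_seq[pos])
                pos += 1
            else:
                assert ref_seq[pos : pos + len(ev.sequence)] == ev.sequence
                pos += len(ev.sequence)
        else:
            out.append(ref_seq[pos])
            pos += 1
    return "".join(out)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_reads_for_seed(seed: str, oriented_seqs: list[str], max_mm: int) -> set[int]:
    """Brute-force: indices of oriented sequences containing a window matching
    ``seed`` with <= max_mm mismatches and >= 1 base after the window."""
    hits = set()
    L = len(seed)
    for i, s in enumerate(oriented_seqs):
        for w in range(0, len(s) - L):
            if hamming(s[w : w + L], seed) <= max_mm:
                hits.add(i)
                break
    return hits


def brute_force_best_mapping(genome: str, read: str, max_mm: int):
    """All-positions scan on both strands.

    Returns (best_mismatches, [(pos, strand), ...]) or (None, []) if no
    placement has <= max_mm mismatches.
    """
    L = len(read)
    best = max_mm + 1
    hits = []
    for strand, oriented in (("+", read), ("-", bio_revcomp(read))):
        for p in range(len(genome) - L + 1):
            mm = hamming(genome[p : p + L], oriented)
            if mm < best:
                best = mm
                hits = [(p, strand)]
            elif mm == best:
                hits.append((p, strand))
    if best > max_mm:
        return None, []
    return best, hits


def count_runs(bits) -> int:
    bits = list(bits)
    return 1 + sum(a != b for a, b in zip(bits, bits[1:])) if bits else 0


def enumerate_runs_distribution(n1: int, n2: int) -> dict[int, float]:
    """Exhaustive enumeration of the runs distribution over all C(n, n1)
    arrangements of n1 ones among n1 + n2 positions."""
    n = n1 + n2
    counts: dict[int, int] = {}
    total = 0
    for ones in combinations(range(n), n1):
        bits = [0] * n
        for i in ones:
            bits[i] = 1
        r = count_runs(bits)
        counts[r] = counts.get(r, 0) + 1
        total += 1
    return {r: c / total for r, c in counts.items()}


def gc_fraction(seq: str) -> float:
    acgt = [c for c in seq if c in BASES]
    if not acgt:
        return 0.0
    return sum(c in "GC" for c in acgt) / len(acgt)


def random_annotated_genome(rng: np.random.Generator):
    """A random sequence plus random (possibly overlapping) feature intervals;
    for the exact genic/intergenic conservation check."""
    from genofinish.genome import GeneModel, ReferenceGenome

    L = int(rng.integers(50, 2000))
    seq = "".join(rng.choice(list(BASES), size=L))
    n = int(rng.integers(0, 8))
    models = []
    for i in range(n):
        s = int(rng.integers(0, L - 3))
        e = int(rng.integers(s + 3, min(L, s + 300) + 1))
        e = s + ((e - s) // 3) * 3
        if e <= s:
            continue
        models.append(GeneModel(
            id=f"r{i}", segments=[(s, e)],
            strand="+" if rng.random() < 0.5 else "-",
            feature_type="CDS",
        ))
    return ReferenceGenome(id="rand", seq=seq, models=models)
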