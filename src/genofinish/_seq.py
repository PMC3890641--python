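"""Low-level sequence helpers shared across the pipeline.

Everything here operates on plain upper-case ACGT(N) strings; translation
uses NCBI table 11 via Biopython so codon semantics are never hand-rolled.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid (``*`` for stop) under bacterial translation table 11
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: start codons accepted by table 11, plus the rare ATT initiator
START_CODONS: tuple[str, ...] = ("ATG", "GTG", "TTG", "ATT")

STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str, *, as_start: bool = True) -> str:
    """Translate ``seq`` (whole codons only) under table 11.

    Initiator codons translate as Met when ``as_start`` is true, matching
    prokaryotic initiation with fMet regardless of the codon identity.
    Codons containing N translate as ``X``.
    """
    n = len(seq) - len(seq) % 3
    aas = []
    for i in range(0, n, 3):
        codon = seq[i : i + 3]
        aa = CODON_TO_AA.get(codon, "X")
        if i == 0 and as_start and codon in START_CODONS:
            aa = "M"
        aas.append(aa)
    return "".join(aas)


def gc_fraction(seq: str) -> float:
    """Fraction of G+C over A+C+G+T bases (N excluded); 0.0 for empty input."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to uint8 codes 0..4 for vectorised comparison."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def check_acgt(seq: str, *, what: str = "sequence") -> None:
    """Raise ``ValueError`` if ``seq`` contains anything but ACGT."""
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT symbols: {sorted(bad)!r}")


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random DNA with the given expected GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def homopolymer_runs(seq: str, min_len: int, bases: str = "AT") -> list[tuple[int, int, str]]:
    """Maximal runs of a single base from ``bases`` with length >= min_len.

    Returns ``(start, end, base)`` half-open intervals.
    """
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] in bases and j - i >= min_len:
            runs.append((i, j, seq[i]))
        i = j
    return runs


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and coalesced."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
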