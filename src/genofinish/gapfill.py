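"""Overlap-consensus gap filling.

The growing sequence is extended one base at a time: the terminal 30-mer
seed recruits every active repository read containing a window that matches
it with at most 2 mismatches and has at least one base after the window;
the recorded following bases are put to a strict majority vote; any voting
read whose recorded base was its final base is exhausted and removed from
the repository together with its complement; the winning base is appended
and the seed shifts by one.  Extension terminates when the tail of the
growing sequence overlaps the head of the downstream contig.

A read keeps voting at successive steps until its last base has been
recorded; only then is it consumed.  Removing every voter immediately would
leave roughly ``coverage / read_length`` fresh reads per step (only reads
starting exactly at the new seed position), which stalls extension even at
high coverage; consuming on exhaustion sustains ``~coverage / 6`` voters
per step and is what makes closure at modest coverage possible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import _seq
from .scaffold import Scaffold

CLOSED = "closed"
NO_READS = "no_reads"
AMBIGUOUS_TIE = "ambiguous_tie"
CAP_EXCEEDED = "cap_exceeded"


@dataclass
class GapFillParams:
    seed_length: int = 30
    max_seed_mismatches: int = 2
    min_depth: int = 1
    termination_overlap: int = 30
    cap_slack: int = 500          # extension cap = 2 * gap_estimate + cap_slack
    min_seed_quality: int = 20    # Q threshold for seed selection
    seed_slide: int = 20          # how far to slide inward looking for a clean seed

    def cap(self, gap_estimate: int) -> int:
        return 2 * max(gap_estimate, 0) + self.cap_slack


@dataclass
class GapFillResult:
    status: str
    filled_sequence: str = ""
    per_base_support: list[int] = field(default_factory=list)
    reads_consumed: int = 0
    joined: str | None = None     # full upstream+gap+downstream sequence when closed
    gap_id: str = ""

    @property
    def min_support(self) -> int:
        return min(self.per_base_support) if self.per_base_support else 0


class ReadRepository:
    """Consumable pool of oriented read sequences with a mismatch-tolerant index.

    Each read enters as a linked (forward, reverse-complement) pair; a
    palindromic read is stored once, self-paired.  Matching a seed of length
    ``L`` with at most ``m`` mismatches is done by pigeonhole: the seed is
    split into ``m + 1`` disjoint chunks, at least one of which must occur
    exactly; an index of every chunk-length substring of every oriented read
    yields the candidates, verified by Hamming distance.
    """

    def __init__(self, seed_length: int = 30, max_mismatches: int = 2):
        self.seed_length = seed_length
        self.max_mismatches = max_mismatches
        self.chunk = seed_length // (max_mismatches + 1)
        self.seqs: list[str] = []
        self.partner: list[int] = []
        self.active: list[bool] = []
        self.n_reads = 0
        self.n_too_short = 0
        self._index: dict[str, list[tuple[int, int]]] = {}

    @property
    def n_active(self) -> int:
        return sum(self.active)

    def _add_oriented(self, seq: str) -> int:
        idx = len(self.seqs)
        self.seqs.append(seq)
        self.partner.append(idx)  # provisional; fixed by caller
        self.active.append(True)
        index = self._index
        c = self.chunk
        for off in range(len(seq) - c + 1):
            index.setdefault(seq[off : off + c], []).append((idx, off))
        return idx

    def add_read(self, seq: str) -> None:
        seq = seq.upper()
        if len(seq) < self.seed_length or set(seq) - set("ACGT"):
            self.n_too_short += 1
            return
        rc = _seq.revcomp(seq)
        i = self._add_oriented(seq)
        if rc == seq:
            self.partner[i] = i      # palindrome: self-paired single entry
        else:
            j = self._add_oriented(rc)
            self.partner[i] = j
            self.partner[j] = i
        self.n_reads += 1

    def query(self, seed: str) -> list[tuple[int, int, int]]:
        """All active oriented sequences with a window matching ``seed``.

        Returns ``(seq_index, window_start, mismatches)``, at most one window
        per oriented sequence (fewest mismatches, then leftmost), windows
        guaranteed to leave >= 1 following base.
        """
        L = self.seed_length
        if len(seed) != L:
            raise ValueError(f"seed must be {L} bp")
        c = self.chunk
        m = self.max_mismatches
        candidates: set[tuple[int, int]] = set()
        for ci in range(m + 1):
            part = seed[ci * c : (ci + 1) * c]
            for idx, off in self._index.get(part, ()):
                if self.active[idx]:
                    w = off - ci * c
                    if 0 <= w and w + L < len(self.seqs[idx]):
                        candidates.add((idx, w))
        best: dict[int, tuple[int, int]] = {}
        for idx, w in sorted(candidates):
            seq = self.seqs[idx]
            window = seq[w : w + L]
            mm = 0
            for a, b in zip(window, seed):
                if a != b:
                    mm += 1
                    if mm > m:
                        break
            if mm <= m:
                cur = best.get(idx)
                if cur is None or mm < cur[1]:
                    best[idx] = (w, mm)
        return [(idx, w, mm) for idx, (w, mm) in best.items()]

    def consume(self, indices: set[int]) -> int:
        """Deactivate the given oriented sequences and their partners.

        Returns the number of *molecules* removed.
        """
        removed = 0
        for idx in indices:
            if self.active[idx]:
                self.active[idx] = False
                removed += 1
                p = self.partner[idx]
                if p != idx and self.active[p]:
                    self.active[p] = False
        return removed


def build_repository(reads, seed_length: int = 30, max_mismatches: int = 2) -> ReadRepository:
    """Build a repository from a ``SimulatedReadSet``, FASTQ records, or
    an iterable of sequences."""
    repo = ReadRepository(seed_length=seed_length, max_mismatches=max_mismatches)
    if hasattr(reads, "sequences"):
        seqs = reads.sequences()
    else:
        seqs = [r[1] if isinstance(r, tuple) else str(r) for r in reads]
    if not seqs:
        raise ValueError("read set is empty")
    for s in seqs:
        repo.add_read(s)
    return repo


def _pick_seed(growing: str, quality: str | None, params: GapFillParams) -> int:
    """Offset (from the 3' end) of the seed window.

    Mirrors "a 30 bp fragment with a high sequencing quality score": take the
    terminal window unless it contains a sub-Q20 base, in which case slide
    inward up to ``seed_slide`` bases to the nearest clean window.  With no
    quality track (the usual case here) the terminal window is used.
    """
    L = params.seed_length
    if quality is None or len(quality) < len(growing):
        return 0
    for back in range(0, params.seed_slide + 1):
        lo = len(growing) - L - back
        if lo < 0:
            break
        window_q = quality[lo : lo + L]
        if all(ord(q) - 33 >= params.min_seed_quality for q in window_q):
            return back
    return 0


def _overlap_match(tail: str, head: str, max_mm: int) -> bool:
    if len(tail) != len(head):
        return False
    mm = 0
    for a, b in zip(tail, head):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def extend_consensus(
    upstream: str,
    downstream: str,
    repo: ReadRepository,
    params: GapFillParams | None = None,
    gap_estimate: int = 0,
    upstream_quality: str | None = None,
) -> GapFillResult:
    """Extend from the 3' end of ``upstream`` across the gap to ``downstream``.

    Implements the seed/match/record/majority/consume/shift loop described in
    the module docstring.  Termination: the last ``termination_overlap`` bases
    of the growing sequence match the first ``termination_overlap`` bases of
    ``downstream`` with at most ``max_seed_mismatches`` mismatches; the
    downstream contig's bases win inside the merged overlap.
    """
    params = params or GapFillParams()
    L = params.seed_length
    # only the anchoring tail of the upstream sequence feeds the seed; an
    # earlier unfilled gap may legitimately have left Ns far upstream
    tail_n = max(L, params.termination_overlap) + params.seed_slide
    _seq.check_acgt(upstream[-tail_n:], what="upstream contig (anchoring tail)")
    _seq.check_acgt(downstream[: max(L, params.termination_overlap)],
                    what="downstream contig (anchoring head)")
    t = params.termination_overlap
    if len(upstream) < L:
        raise ValueError(f"upstream contig shorter than seed_length ({len(upstream)} < {L})")
    if repo.seed_length != L or repo.max_mismatches != params.max_seed_mismatches:
        raise ValueError("repository was built for different seed parameters")

    back = _pick_seed(upstream, upstream_quality, params)
    growing = upstream[: len(upstream) - back] if back else upstream
    anchor_len = len(growing)
    extension: list[str] = []
    support: list[int] = []
    consumed = 0
    cap = params.cap(gap_estimate)

    def result(status: str) -> GapFillResult:
        return GapFillResult(
            status=status,
            filled_sequence="".join(extension),
            per_base_support=support,
            reads_consumed=consumed,
        )

    # contigs may already overlap by more than the termination window (gap
    # estimates can be off); scan the upstream tail for the downstream head
    # before extending at all
    if len(downstream) >= t:
        head = downstream[:t]
        lo = max(0, len(growing) - t - 300)   # overlaps beyond ~300 bp not expected
        for q in range(len(growing) - t, lo - 1, -1):
            if _overlap_match(growing[q : q + t], head, params.max_seed_mismatches):
                res = result(CLOSED)
                res.joined = growing[:q] + downstream
                return res

    while True:
        if len(growing) >= t and len(downstream) >= t:
            if _overlap_match(growing[-t:], downstream[:t], params.max_seed_mismatches):
                joined = growing[:-t] + downstream
                res = result(CLOSED)
                res.joined = joined
                res.filled_sequence = "".join(extension)
                return res
        if len(extension) > cap:
            return result(CAP_EXCEEDED)

        seed = growing[-L:]
        hits = repo.query(seed)
        # one vote per molecule: a read and its complement never vote twice
        by_molecule: dict[int, tuple[int, int, int]] = {}
        for idx, w, mm in hits:
            key = min(idx, repo.partner[idx])
            cur = by_molecule.get(key)
            if cur is None or mm < cur[2]:
                by_molecule[key] = (idx, w, mm)
        votes = [(idx, repo.seqs[idx][w + L]) for idx, w, _ in by_molecule.values()]
        if len(votes) < max(params.min_depth, 1):
            return result(NO_READS)
        counts = Counter(b for _, b in votes)
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return result(AMBIGUOUS_TIE)
        base = ranked[0][0]
        exhausted = {
            idx for idx, w, _ in by_molecule.values()
            if w + L + 1 == len(repo.seqs[idx])
        }
        consumed += repo.consume(exhausted)
        growing += base
        extension.append(base)
        support.append(len(votes))


@dataclass
class AssemblyResult:
    sequence: str
    gap_results: list[GapFillResult]

    @property
    def n_closed(self) -> int:
        return sum(r.status == CLOSED for r in self.gap_results)


def fill_all_gaps(
    scaffold: Scaffold,
    contigs: dict[str, str],
    repo: ReadRepository,
    params: GapFillParams | None = None,
) -> AssemblyResult:
    """Fill every scaffold gap in order; unclosed gaps become runs of N of the
    estimated length."""
    params = params or GapFillParams()
    ordered = scaffold.oriented_contigs(contigs)
    if not ordered:
        raise ValueError("scaffold has no placed contigs")
    assembly = ordered[0][1]
    results: list[GapFillResult] = []
    for i, gap in enumerate(scaffold.gaps):
        downstream = ordered[i + 1][1]
        res = extend_consensus(
            assembly, downstream, repo, params, gap_estimate=gap.estimated_length
        )
        res.gap_id = f"gap_{i + 1:04d}"
        if res.status == CLOSED:
            assembly = res.joined
        else:
            assembly = assembly + "N" * max(gap.estimated_length, 0) + downstream
        results.append(res)
    return AssemblyResult(sequence=assembly, gap_results=results)
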