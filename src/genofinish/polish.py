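"""Read-back mapping, per-site coverage, and excise-and-refill correction.

Mapping is ungapped with at most 3 mismatches, indexed with exact seed
chunks (pigeonhole over ``max_mismatches + 1`` chunks, so the index is
guaranteed to recover every position a brute-force scan would).  Each read
is assigned to its unique best position; equal-best ties are broken by a
seeded RNG so the coverage sum rule stays exact.  Regions below the
coverage threshold are excised and re-derived with the overlap-consensus
extender anchored on their flanks, which fixes both substitutions and the
+-1 homopolymer indels characteristic of 454 data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .gapfill import CLOSED, GapFillParams, ReadRepository, build_repository, extend_consensus


@dataclass
class Mapping:
    read_index: int
    position: int
    strand: str
    mismatches: int


@dataclass
class MappingSet:
    mappings: list[Mapping]
    n_reads: int
    n_unmapped: int
    read_length: int


@dataclass
class CoverageProfile:
    depth: np.ndarray
    mean_depth: float

    @classmethod
    def from_mappings(
        cls, mapset: MappingSet, assembly_length: int, circular: bool = False
    ) -> "CoverageProfile":
        L = assembly_length
        diff = np.zeros(L + 1, dtype=np.int64)
        for m in mapset.mappings:
            end = m.position + mapset.read_length
            if end <= L:
                diff[m.position] += 1
                diff[end] -= 1
            elif circular:
                diff[m.position] += 1
                diff[L] -= 1
                diff[0] += 1
                diff[end - L] -= 1
            else:
                diff[m.position] += 1
                diff[L] -= 1
        depth = np.cumsum(diff)[:L]
        return cls(depth=depth, mean_depth=float(depth.mean()) if L else 0.0)


@dataclass
class CorrectionRecord:
    region: tuple[int, int]
    action: str                      # refilled | substituted | unresolved
    before: str = ""
    after: str = ""
    depth_before: float = 0.0
    depth_after: float = 0.0


def map_reads(
    assembly: str,
    reads,
    max_mismatches: int = 3,
    rng_seed: int = 0,
    circular: bool = False,
) -> tuple[MappingSet, CoverageProfile]:
    """Map each read to its best ungapped position on either strand.

    Guaranteed-complete candidate generation: the read is split into
    ``max_mismatches + 1`` equal chunks, one of which must match exactly at
    any position with <= ``max_mismatches`` mismatches; candidates come from
    an exact-chunk index of the assembly and are verified vectorised.

    With ``circular=True`` reads may span the origin; reported positions are
    mod the assembly length and coverage wraps.
    """
    if not assembly:
        raise ValueError("assembly is empty")
    seqs = reads.sequences() if hasattr(reads, "sequences") else list(reads)
    rng = np.random.default_rng(rng_seed)
    mappings: list[Mapping] = []
    if not seqs:
        prof = CoverageProfile(np.zeros(len(assembly), dtype=np.int64), 0.0)
        return MappingSet([], 0, 0, 0), prof

    L = len(assembly)
    read_len = len(seqs[0])
    search_seq = assembly + assembly[: read_len - 1] if circular else assembly
    chunk = max(1, read_len // (max_mismatches + 1))
    enc = _seq.encode(search_seq)
    # exact-chunk index of the (possibly wrapped) assembly
    index: dict[str, list[int]] = {}
    for i in range(len(search_seq) - chunk + 1):
        index.setdefault(search_seq[i : i + chunk], []).append(i)
    index_arr = {k: np.array(v, dtype=np.int64) for k, v in index.items()}

    windows = np.lib.stride_tricks.sliding_window_view(enc, read_len) \
        if len(search_seq) >= read_len else None

    uniform = [s for s in seqs if len(s) == read_len]
    fwd_mat = rc_mat = None
    rc_strings: list[str] = []
    if uniform and windows is not None:
        flat = np.frombuffer("".join(uniform).encode("ascii"), dtype=np.uint8)
        lut = np.full(256, 4, dtype=np.uint8)
        for b, c in zip(b"ACGT", range(4)):
            lut[b] = c
        fwd_mat = lut[flat].reshape(len(uniform), read_len)
        comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
        rc_mat = comp[fwd_mat][:, ::-1]
        rc_strings = [_seq.revcomp(s) for s in uniform]

    n_unmapped = 0
    n_chunks = max_mismatches + 1
    max_pos = L - 1 if circular else L - read_len
    ui = -1
    for ri, seq in enumerate(seqs):
        if len(seq) != read_len or windows is None:
            n_unmapped += 1
            continue
        ui += 1
        best_mm = max_mismatches + 1
        best: list[tuple[int, str]] = []
        for strand, oriented, enc_read in (
            ("+", seq, fwd_mat[ui]),
            ("-", rc_strings[ui], rc_mat[ui]),
        ):
            cand: list[np.ndarray] = []
            for ci in range(n_chunks):
                off = ci * chunk
                if off + chunk > read_len:
                    break
                hits = index_arr.get(oriented[off : off + chunk])
                if hits is not None:
                    cand.append(hits - off)
            if not cand:
                continue
            pos = np.concatenate(cand)
            if circular:
                pos = pos % L
            pos = np.unique(pos)
            pos = pos[(pos >= 0) & (pos <= max_pos)]
            if pos.size == 0:
                continue
            mm = (windows[pos] != enc_read).sum(axis=1)
            lo = int(mm.min())
            if lo < best_mm:
                best_mm = lo
                best = [(int(p), strand) for p in pos[mm == lo]]
            elif lo == best_mm:
                best.extend((int(p), strand) for p in pos[mm == lo])
        if best_mm > max_mismatches:
            n_unmapped += 1
            continue
        p, strand = best[int(rng.integers(0, len(best)))] if len(best) > 1 else best[0]
        mappings.append(Mapping(ri, p, strand, best_mm))

    mapset = MappingSet(mappings, len(seqs), n_unmapped, read_len)
    return mapset, CoverageProfile.from_mappings(mapset, L, circular=circular)


def find_low_coverage(
    profile: CoverageProfile,
    threshold: int = 21,
    pad: int = 0,
) -> list[tuple[int, int]]:
    """Maximal half-open intervals where depth < threshold, each padded by
    ``pad`` and merged if padding makes them touch."""
    low = profile.depth < threshold
    if not low.any():
        return []
    d = np.diff(np.concatenate(([0], low.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    n = len(profile.depth)
    ivs = [(max(0, int(s) - pad), min(n, int(e) + pad)) for s, e in zip(starts, ends)]
    return _seq.merge_intervals(ivs)


def correct_errors(
    assembly: str,
    regions: list[tuple[int, int]],
    repo: ReadRepository,
    params: GapFillParams | None = None,
) -> tuple[str, list[CorrectionRecord]]:
    """Excise each region and re-derive it with the consensus extender
    anchored on the flanks.  Regions are processed right to left so earlier
    corrections cannot shift later coordinates.

    ``repo`` must be a fresh repository (correction never reuses a pool
    already consumed by gap filling).
    """
    params = params or GapFillParams()
    records: list[CorrectionRecord] = []
    seq = assembly
    for start, end in sorted(regions, reverse=True):
        start = max(0, start)
        end = min(len(assembly), end)
        upstream = seq[:start]
        downstream = seq[end:]
        before = seq[start:end]
        if len(upstream) < params.seed_length or len(downstream) < params.termination_overlap:
            records.append(CorrectionRecord((start, end), "unresolved", before=before))
            continue
        res = extend_consensus(
            upstream, downstream, repo, params, gap_estimate=end - start
        )
        if res.status == CLOSED:
            seq = res.joined
            action = "refilled" if res.filled_sequence != before else "substituted"
            records.append(CorrectionRecord(
                (start, end), action, before=before, after=res.filled_sequence,
            ))
        else:
            records.append(CorrectionRecord((start, end), "unresolved", before=before))
    return seq, list(reversed(records))


@dataclass
class PolishResult:
    assembly: str
    rounds: int
    records: list[CorrectionRecord] = field(default_factory=list)
    final_profile: CoverageProfile | None = None
    converged: bool = False


def polish_assembly(
    assembly: str,
    reads,
    threshold: int = 21,
    max_mismatches: int = 3,
    params: GapFillParams | None = None,
    max_rounds: int = 3,
    rng_seed: int = 0,
    circular: bool = False,
) -> PolishResult:
    """Iterate map -> find-low-coverage -> excise-and-refill until no
    interval remains below threshold or ``max_rounds`` is reached."""
    params = params or GapFillParams()
    records: list[CorrectionRecord] = []
    current = assembly
    profile = None
    for rnd in range(1, max_rounds + 1):
        mapset, profile = map_reads(current, reads, max_mismatches, rng_seed + rnd,
                                    circular=circular)
        regions = find_low_coverage(profile, threshold, pad=params.seed_length)
        if not regions:
            return PolishResult(current, rnd - 1, records, profile, converged=True)
        repo = build_repository(
            reads, seed_length=params.seed_length,
            max_mismatches=params.max_seed_mismatches,
        )
        depth_by_region = {r: float(profile.depth[r[0]:r[1]].mean()) for r in regions}
        current, new_records = correct_errors(current, regions, repo, params)
        for rec in new_records:
            rec.depth_before = depth_by_region.get(rec.region, 0.0)
        records.extend(new_records)
        if all(r.action == "unresolved" for r in new_records):
            break
    mapset, profile = map_reads(current, reads, max_mismatches, rng_seed + max_rounds + 1,
                                circular=circular)
    leftover = find_low_coverage(profile, threshold)
    # re-mapped depth decides whether a refill really resolved its region
    for rec in records:
        if rec.action in ("refilled", "substituted"):
            s = min(rec.region[0], len(current) - 1)
            e = min(max(s + 1, s + len(rec.after)), len(current))
            rec.depth_after = float(profile.depth[s:e].mean())
            if rec.depth_after < threshold:
                rec.action = "unresolved"
    return PolishResult(current, max_rounds, records, profile, converged=not leftover)


def flag_for_validation(
    records: list[CorrectionRecord],
    assembly_length: int,
    flank: int = 500,
) -> list[dict]:
    """Machine-readable validation candidates (stand-in for Sanger checks):
    one row per correction with primer-window flanks."""
    rows = []
    for rec in records:
        s, e = rec.region
        rows.append({
            "start": s,
            "end": e,
            "action": rec.action,
            "left_flank_start": max(0, s - flank),
            "left_flank_end": s,
            "right_flank_start": e,
            "right_flank_end": min(assembly_length, e + flank),
        })
    return rows
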