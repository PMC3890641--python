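"""Annotation projection and automated curation.

Reference gene models are carried onto each finished genome through the
collinear whole-genome alignment (projection replaces ab-initio
prediction, which is exact for genomes that conserve gene order).  The
curation cascade then handles, per CDS: length deviation >10% from the
reference model, premature stops adjacent to poly-A tracts (merged into a
dual-frame model with the tract length unchanged), missing starts
(extension to an upstream ATG/GTG/TTG/ATT), and finally pseudogene calls
for models that stay interrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from . import _seq
from .compare import WholeGenomeAlignment
from .genome import GeneModel, ReferenceGenome

LENGTH_DEVIATION = "length_deviation"
PREMATURE_STOP = "premature_stop"
START_EXTENSION = "start_extension"
POLYA_MERGE = "polyA_merge"
PSEUDOGENE_CALL = "pseudogene_call"


@dataclass
class CurationEvent:
    gene_id: str
    rule: str
    detail: str = ""


@dataclass
class ProjectionResult:
    models: list[GeneModel]
    flagged: list[str] = field(default_factory=list)   # ids not projected


def project_annotation(
    reference: ReferenceGenome,
    alignment: WholeGenomeAlignment,
) -> ProjectionResult:
    """Map every reference feature through the alignment onto the target.

    Features falling in unaligned segments or overlapping an N run in the
    target are flagged and omitted from the projected model list.
    """
    if alignment.a_seq != reference.seq:
        raise ValueError("alignment 'a' side does not match the reference sequence")
    a2b = alignment.a_to_b_map()
    b_seq = alignment.b_seq
    out: list[GeneModel] = []
    flagged: list[str] = []
    for m in reference.models:
        segs = [(int(a2b[s]), int(a2b[e])) for s, e in m.segments]
        if any(s >= e for s, e in segs):
            flagged.append(m.id)
            continue
        if any("N" in b_seq[s:e] for s, e in segs):
            flagged.append(m.id)
            continue
        nm = m.copy()
        nm.segments = segs
        out.append(nm)
    return ProjectionResult(models=out, flagged=flagged)


# ---------------------------------------------------------------------------
# curation

_PROT_ALIGNER = Align.PairwiseAligner()
_PROT_ALIGNER.mode = "global"
_PROT_ALIGNER.match_score = 1
_PROT_ALIGNER.mismatch_score = -1
_PROT_ALIGNER.open_gap_score = -1
_PROT_ALIGNER.extend_gap_score = -1


def protein_identity(p1: str, p2: str) -> float:
    """Identity of a unit-cost global alignment, over the longer length."""
    if not p1 or not p2:
        return 0.0
    aln = _PROT_ALIGNER.align(p1, p2)[0]
    identities = aln.counts().identities
    return identities / max(len(p1), len(p2))


def _local_to_genome(m: GeneModel, x1: int, x2: int) -> tuple[int, int]:
    """Coding-orientation local half-open interval -> genome interval."""
    if m.strand == "+":
        return (m.start + x1, m.start + x2)
    return (m.end - x2, m.end - x1)


def _extended_local_seq(m: GeneModel, genome_seq: str, extra: int) -> str:
    """Model sequence in coding orientation plus ``extra`` downstream bases."""
    if m.strand == "+":
        return genome_seq[m.start : min(len(genome_seq), m.end + extra)]
    return _seq.revcomp(genome_seq[max(0, m.start - extra) : m.end])


def _upstream_local_seq(m: GeneModel, genome_seq: str, extra: int) -> str:
    """``extra`` bases upstream of the model start, coding orientation."""
    if m.strand == "+":
        return genome_seq[max(0, m.start - extra) : m.start]
    return _seq.revcomp(genome_seq[m.end : min(len(genome_seq), m.end + extra)])


def _first_internal_stop(protein: str) -> int:
    """Index of the first internal stop in a conceptual translation; -1 if none
    (a trailing stop is terminal, not internal)."""
    i = protein.find("*")
    if i < 0 or i == len(protein) - 1:
        return -1
    return i


def _try_polya_merge(
    m: GeneModel,
    genome_seq: str,
    ref_protein: str,
    stop_aa: int,
    min_identity: float,
    tract_min: int = 5,   # a 6 bp tract that lost one base shows 5 here
) -> GeneModel | None:
    """Attempt a dual-frame merge across a poly-A tract near a premature stop.

    Tries every A/T homopolymer >= ``tract_min`` upstream of the
    interruption (after a frameshift inside a tract, the first off-frame
    stop can land many codons downstream, so no distance cutoff is safe)
    with both frame shifts for the downstream segment; accepts the variant
    whose combined translation is most similar to the reference protein
    (>= ``min_identity``) — the identity floor is what prevents merging
    across an unrelated tract.
    """
    local = _extended_local_seq(m, genome_seq, extra=90)
    model_len = m.length
    stop_pos = 3 * stop_aa if stop_aa >= 0 else model_len
    runs = [r for r in _seq.homopolymer_runs(local[:model_len], tract_min)
            if r[0] <= stop_pos + 3]
    best: tuple[float, GeneModel] | None = None
    for ts, te, _base in runs:
        c1 = (ts // 3) * 3
        if c1 < 3:
            continue
        p1 = _seq.translate_cds(local[:c1])
        if "*" in p1:
            continue
        for shift in (1, 2):   # downstream frame relative to segment-1 frame
            o2 = te + ((c1 + shift - te) % 3)
            # translate from o2 to the first in-frame stop
            prot2 = _seq.translate_cds(local[o2:], as_start=False)
            end_aa = prot2.find("*")
            if end_aa < 0:
                continue
            seg2_len = 3 * (end_aa + 1)
            if o2 + seg2_len > len(local):
                continue
            combined = p1 + prot2[:end_aa]
            ident = protein_identity(combined, ref_protein)
            if ident >= min_identity and (best is None or ident > best[0]):
                g1 = _local_to_genome(m, 0, c1)
                g2 = _local_to_genome(m, o2, o2 + seg2_len)
                nm = m.copy()
                nm.segments = sorted([g1, g2])
                nm.attributes = dict(m.attributes, polyA_merge="true")
                best = (ident, nm)
    return best[1] if best else None


def curate_models(
    models: list[GeneModel],
    genome_seq: str,
    reference: ReferenceGenome,
    reference_seq: str | None = None,
    min_merge_identity: float = 0.90,
    length_ratio: float = 0.10,
) -> tuple[list[GeneModel], list[CurationEvent]]:
    """Apply the curation cascade to projected models.

    The genome sequence is never modified; only models change.  Pseudogene
    and dual-frame models pass through untouched, which makes the cascade
    idempotent.
    """
    ref_seq = reference_seq if reference_seq is not None else reference.seq
    ref_by_id = {m.id: m for m in reference.models}
    events: list[CurationEvent] = []
    curated: list[GeneModel] = []

    for m in models:
        if m.feature_type != "CDS" or not m.is_single_frame:
            curated.append(m.copy())
            continue
        ref_m = ref_by_id.get(m.id)
        cur = m.copy()

        # (1) length deviation
        if ref_m is not None and ref_m.length > 0:
            dev = abs(cur.length - ref_m.length) / ref_m.length
            if dev > length_ratio:
                events.append(CurationEvent(
                    cur.id, LENGTH_DEVIATION,
                    f"length {cur.length} vs reference {ref_m.length} ({dev:.2f})",
                ))

        # (2) interruption (internal stop, or a frameshift that erased the
        #     terminal stop) -> polyA dual-frame merge
        prot = _seq.translate_cds(cur.extract(genome_seq))
        stop_aa = _first_internal_stop(prot)
        interrupted = stop_aa >= 0 or not prot.endswith("*")
        if interrupted:
            detail = (f"internal stop at codon {stop_aa}" if stop_aa >= 0
                      else "missing terminal stop")
            events.append(CurationEvent(cur.id, PREMATURE_STOP, detail))
            ref_protein = ref_m.protein(ref_seq) if ref_m is not None else ""
            merged = _try_polya_merge(
                cur, genome_seq, ref_protein, stop_aa, min_merge_identity,
            ) if ref_protein else None
            if merged is not None:
                events.append(CurationEvent(
                    cur.id, POLYA_MERGE,
                    "dual-frame merge across poly-A tract",
                ))
                curated.append(merged)
                continue

        # (3) start extension to an upstream alternate start codon
        first_codon = cur.extract(genome_seq)[:3]
        if not interrupted and first_codon not in _seq.START_CODONS and ref_m is not None:
            upstream = _upstream_local_seq(cur, genome_seq, extra=max(30, ref_m.length))
            found = None
            for d in range(3, len(upstream) + 1, 3):
                codon = upstream[len(upstream) - d : len(upstream) - d + 3]
                if codon in _seq.STOP_CODONS:
                    break
                if codon in _seq.START_CODONS:
                    found = d
                    break
            if found is not None:
                if cur.strand == "+":
                    cur.segments = [(cur.start - found, cur.end)]
                else:
                    cur.segments = [(cur.start, cur.end + found)]
                events.append(CurationEvent(
                    cur.id, START_EXTENSION,
                    f"extended {found} bp upstream to {upstream[len(upstream) - found:len(upstream) - found + 3]}",
                ))
                curated.append(cur)
                continue

        # (4) still interrupted -> pseudogene
        if interrupted:
            cur.feature_type = "pseudogene"
            events.append(CurationEvent(cur.id, PSEUDOGENE_CALL, "unresolved interruption"))
        curated.append(cur)

    return curated, events


# ---------------------------------------------------------------------------
# gene content comparison

@dataclass
class GeneContentDiff:
    shared: list[tuple[str, str, float]]   # (id_a, id_b, identity)
    unique_to_a: list[str]
    unique_to_b: list[str]


def translate_all(genome: ReferenceGenome) -> dict[str, str]:
    return {m.id: m.protein(genome.seq) for m in genome.cds_models()}


def gene_content_diff(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    identity_floor: float = 0.4,
) -> GeneContentDiff:
    """Reciprocal best protein match with a minimum-identity floor.

    Pairs are formed when each protein is the other's highest-identity
    match and the identity is >= ``identity_floor``; everything unpaired
    lands in the unique lists.  Deterministic: ties resolve to the
    lexicographically smallest partner id.
    """
    ids_a = sorted(proteins_a)
    ids_b = sorted(proteins_b)

    def best_match(p: str, pool: dict[str, str]) -> tuple[str | None, float]:
        best_id, best_ident = None, 0.0
        lp = len(p)
        for oid in sorted(pool):
            q = pool[oid]
            if not q or not p:
                continue
            if min(lp, len(q)) / max(lp, len(q)) < identity_floor:
                continue  # identity can never reach the floor
            ident = protein_identity(p, q)
            if ident > best_ident:
                best_id, best_ident = oid, ident
        return best_id, best_ident

    fwd = {ia: best_match(proteins_a[ia], proteins_b) for ia in ids_a}
    rev = {ib: best_match(proteins_b[ib], proteins_a) for ib in ids_b}

    shared: list[tuple[str, str, float]] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for ia in ids_a:
        ib, ident = fwd[ia]
        if ib is None or ident < identity_floor:
            continue
        back, _ = rev[ib]
        if back == ia:
            shared.append((ia, ib, round(ident, 4)))
            matched_a.add(ia)
            matched_b.add(ib)
    return GeneContentDiff(
        shared=shared,
        unique_to_a=[i for i in ids_a if i not in matched_a],
        unique_to_b=[i for i in ids_b if i not in matched_b],
    )
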