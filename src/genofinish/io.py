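"""Standard-format I/O.

FASTA/FASTQ/GenBank parsing is delegated to Biopython; GFF3 and the
tabular interchange formats (scaffold TSV, coverage, variant and report
tables) are written/read here.  All conversions between the package's
0-based half-open coordinates and the 1-based closed conventions of
GFF3/GenBank happen in this module and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, ReferenceGenome
from .scaffold import ContigPlacement, Scaffold, ScaffoldGap
from .synthdata import SimulatedReadSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> upper-case sequence, in file order."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, seqs: dict[str, str] | list[tuple[str, str]], width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path, expected_length: int | None = None) -> SimulatedReadSet:
    """Read FASTQ; off-length reads are kept with a logged warning."""
    reads: list[tuple[str, str, str]] = []
    n_odd = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        if expected_length is not None and len(seq) != expected_length:
            n_odd += 1
        reads.append((rec.id, seq, qual))
    if not reads:
        raise ValueError(f"no FASTQ records in {path}")
    if n_odd:
        log.warning("%d reads in %s deviate from the expected length %s",
                    n_odd, path, expected_length)
    lengths = {len(s) for _, s, _ in reads}
    return SimulatedReadSet(
        reads=reads,
        read_length=max(lengths),
    )


def write_fastq(path: str | Path, readset: SimulatedReadSet) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPE_OUT = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "pseudogene"}


def write_gff3(path: str | Path, genome: ReferenceGenome) -> None:
    """One ``gene`` row per model plus one row per segment (two rows and a
    ``polyA_merge=true`` attribute for dual-frame models)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.seq)}\n")
        for m in genome.models:
            attrs = [f"ID={m.id}"]
            if m.product:
                attrs.append(f"product={m.product}")
            if not m.is_single_frame:
                attrs.append("polyA_merge=true")
            fh.write("\t".join([
                genome.id, "genofinish", "gene",
                str(m.start + 1), str(m.end), ".", m.strand, ".",
                ";".join(attrs),
            ]) + "\n")
            for i, (s, e) in enumerate(m.segments):
                fh.write("\t".join([
                    genome.id, "genofinish", _GFF_TYPE_OUT[m.feature_type],
                    str(s + 1), str(e), ".", m.strand, ".",
                    f"ID={m.id}.seg{i};Parent={m.id}",
                ]) + "\n")


def read_gff3(path: str | Path, seq: str = "", genome_id: str | None = None) -> ReferenceGenome:
    """Inverse of :func:`write_gff3` (coordinates back to 0-based half-open)."""
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    gid = genome_id
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _frame, attr_s = fields
            gid = gid or seqid
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: bad coordinates") from exc
            if ftype == "gene":
                mid = attrs.get("ID", f"gene_{ln}")
                genes[mid] = GeneModel(
                    id=mid, segments=[], strand=strand,
                    product=attrs.get("product", ""),
                    attributes={k: v for k, v in attrs.items()
                                if k not in ("ID", "product")},
                )
                order.append(mid)
            else:
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    raise ValueError(f"{path}:{ln}: segment row without known Parent")
                genes[parent].segments.append((s, e))
                genes[parent].feature_type = {v: k for k, v in _GFF_TYPE_OUT.items()}.get(
                    ftype, "CDS")
    models = []
    for mid in order:
        m = genes[mid]
        m.segments.sort()
        models.append(m)
    return ReferenceGenome(id=gid or "genome", seq=seq, models=models)


# ---------------------------------------------------------------------------
# GenBank flat files

_GB_FEATURE_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "pseudogene"}


def read_genbank_flat(path: str | Path) -> list[ReferenceGenome]:
    """Parse GenBank records into genomes with gene models.

    join-style multi-segment CDS locations become multi-segment models;
    CDS features carrying a ``/pseudo`` qualifier become pseudogenes.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        models = []
        counter = 0
        for feat in rec.features:
            if feat.type not in _GB_FEATURE_TYPES:
                continue
            counter += 1
            segments = sorted(
                (int(part.start), int(part.end)) for part in feat.location.parts
            )
            ftype = feat.type
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                ftype = "pseudogene"
            locus = feat.qualifiers.get("locus_tag", [f"{rec.id}_{feat.type}_{counter:05d}"])[0]
            models.append(GeneModel(
                id=locus,
                segments=segments,
                strand="+" if feat.location.strand in (1, None) else "-",
                feature_type=ftype,
                product=feat.qualifiers.get("product", [""])[0],
            ))
        genomes.append(ReferenceGenome(
            id=rec.id,
            seq=str(rec.seq).upper(),
            models=models,
            circular=rec.annotations.get("topology") == "circular",
        ))
    if not genomes:
        raise ValueError(f"no GenBank records in {path}")
    return genomes


# ---------------------------------------------------------------------------
# scaffold TSV (AGP-like)

def write_scaffold_tsv(path: str | Path, scaffold: Scaffold) -> None:
    with open(path, "w") as fh:
        fh.write("row_type\tcontig_id\tref_start\tref_end\tstrand\tidentity\t"
                 "anchors\ttrim_left\ttrim_right\tgap_length\n")
        gaps = {g.upstream_contig: g for g in scaffold.gaps}
        for p in scaffold.placements:
            fh.write(f"contig\t{p.contig_id}\t{p.reference_start}\t{p.reference_end}\t"
                     f"{p.strand}\t{p.identity:.4f}\t{p.anchor_count}\t"
                     f"{p.trim_left}\t{p.trim_right}\t\n")
            g = gaps.get(p.contig_id)
            if g is not None:
                fh.write(f"gap\t{g.upstream_contig}..{g.downstream_contig}\t\t\t\t\t\t\t\t"
                         f"{g.estimated_length}\n")


def read_scaffold_tsv(path: str | Path) -> Scaffold:
    placements: list[ContigPlacement] = []
    gaps: list[ScaffoldGap] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("row_type"):
            raise ValueError(f"{path}: missing scaffold TSV header")
        for ln, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if f[0] == "contig":
                placements.append(ContigPlacement(
                    contig_id=f[1], reference_start=int(f[2]), reference_end=int(f[3]),
                    strand=f[4], identity=float(f[5]), anchor_count=int(f[6]),
                    trim_left=int(f[7]), trim_right=int(f[8]),
                ))
            elif f[0] == "gap":
                up, down = f[1].split("..")
                gaps.append(ScaffoldGap(up, down, int(f[9])))
            else:
                raise ValueError(f"{path}:{ln}: unknown row type {f[0]!r}")
    return Scaffold(placements=placements, gaps=gaps)


# ---------------------------------------------------------------------------
# small tabular writers

def write_tsv(path: str | Path, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            missing = set(columns) - set(row)
            if missing:
                raise ValueError(f"row missing columns: {sorted(missing)}")
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def write_bedgraph(path: str | Path, name: str, values) -> None:
    """Collapse a per-base vector into bedGraph runs."""
    with open(path, "w") as fh:
        start = 0
        prev = None
        for i, v in enumerate(values):
            if prev is None:
                prev, start = v, i
            elif v != prev:
                fh.write(f"{name}\t{start}\t{i}\t{prev}\n")
                prev, start = v, i
        if prev is not None:
            fh.write(f"{name}\t{start}\t{len(values)}\t{prev}\n")
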