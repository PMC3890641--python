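"""Core genome/annotation data model.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based closed happens only at the GFF3/GenBank boundary (see
:mod:`genofinish.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import _seq

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "pseudogene")


@dataclass
class GeneModel:
    """One annotated feature.

    ``segments`` is a list of half-open ``(start, end)`` intervals in genome
    coordinates, ordered 5'->3' on the *genome* (ascending).  Single-frame
    CDS have one segment; polyA-merged dual-frame models have two.
    """

    id: str
    segments: list[tuple[int, int]]
    strand: str  # '+' or '-'
    feature_type: str = "CDS"
    product: str = ""
    attributes: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def is_single_frame(self) -> bool:
        return len(self.segments) == 1

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"{self.id}: bad feature type {self.feature_type!r}")
        prev_end = -1
        for s, e in self.segments:
            if not (0 <= s < e):
                raise ValueError(f"{self.id}: bad segment ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.id}: segments overlap or are unordered")
            prev_end = e
        if self.feature_type == "CDS" and self.is_single_frame and self.length % 3:
            raise ValueError(f"{self.id}: single-frame CDS length {self.length} not divisible by 3")

    def extract(self, genome_seq: str) -> str:
        """Coding-orientation nucleotide sequence of the model."""
        parts = [genome_seq[s:e] for s, e in self.segments]
        seq = "".join(parts)
        if self.strand == "-":
            seq = _seq.revcomp(seq)
        return seq

    def protein(self, genome_seq: str) -> str:
        """Conceptual translation (dual-frame models: translate each segment's
        in-frame portion and concatenate, trailing stop stripped)."""
        if self.is_single_frame:
            aa = _seq.translate_cds(self.extract(genome_seq))
        else:
            segs = self.segments if self.strand == "+" else list(reversed(self.segments))
            aas = []
            for i, (s, e) in enumerate(segs):
                sub = genome_seq[s:e]
                if self.strand == "-":
                    sub = _seq.revcomp(sub)
                aas.append(_seq.translate_cds(sub, as_start=(i == 0)))
            aa = "".join(a.rstrip("*").replace("*", "X") if i < len(segs) - 1 else a
                         for i, a in enumerate(aas))
        return aa.rstrip("*") if aa.endswith("*") else aa

    def copy(self) -> "GeneModel":
        return replace(self, segments=list(self.segments), attributes=dict(self.attributes))


@dataclass
class ReferenceGenome:
    """A sequence with its ordered gene models (chromosome or plasmid)."""

    id: str
    seq: str
    models: list[GeneModel] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.models.sort(key=lambda m: (m.start, m.end))

    def __len__(self) -> int:
        return len(self.seq)

    def cds_models(self) -> list[GeneModel]:
        return [m for m in self.models if m.feature_type == "CDS"]

    def validate(self) -> None:
        for m in self.models:
            m.validate()
            if m.end > len(self.seq):
                raise ValueError(f"{m.id}: extends past genome end ({m.end} > {len(self.seq)})")
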