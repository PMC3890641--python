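"""Pipeline orchestration: configuration, stage sequencing, manifest.

The pipeline runs scaffold -> gapfill -> polish -> annotate -> compare on
either user-supplied inputs or the built-in synthetic multi-strain demo,
writing every stage artifact plus a digest manifest that makes reruns
byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate, compare, gapfill, io, polish, scaffold, synthdata

log = logging.getLogger("genofinish.pipeline")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published operating point."""

    # gap filling
    seed_length: int = 30
    max_seed_mismatches: int = 2
    min_depth: int = 1
    # polishing
    mapping_mismatches: int = 3
    coverage_threshold: int = 21
    polish_rounds: int = 3
    # curation
    curation_length_ratio: float = 0.10
    min_merge_identity: float = 0.90
    # scaffolding / comparison
    anchor_k: int = 17
    # randomness
    rng_seed: int = 0
    # inputs (empty => synthetic demo)
    reference_path: str = ""
    contig_paths: dict = field(default_factory=dict)     # strain -> fasta
    read_paths: dict = field(default_factory=dict)       # strain -> fastq
    # synthetic demo shape
    synthetic: dict = field(default_factory=lambda: {
        "chromosome_length": 20_000,
        "n_genes": 18,
        "mean_gene_length": 900,
        "mean_intergenic_length": 200,
        "strains": ["strain_a", "strain_b", "strain_c", "strain_d"],
        "n_snps": 40,
        "syn_fraction": 0.5,
        "n_indels": 4,
        "n_gaps": 6,
        "coverage": 60.0,
        "error_rate": 0.0,
    })
    output_dir: str = "genofinish_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def gapfill_params(self) -> gapfill.GapFillParams:
        return gapfill.GapFillParams(
            seed_length=self.seed_length,
            max_seed_mismatches=self.max_seed_mismatches,
            min_depth=self.min_depth,
        )


@dataclass
class RunManifest:
    stages: list[str] = field(default_factory=list)
    digests: dict = field(default_factory=dict)    # filename -> sha256
    wall_time_s: float = 0.0

    def record(self, path: Path) -> None:
        self.digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"stages": self.stages, "digests": self.digests,
             "wall_time_s": round(self.wall_time_s, 2)},
            indent=2, sort_keys=True,
        ))


def _seed_for(config: PipelineConfig, stage: str, index: int = 0) -> int:
    """Derive a per-stage seed from the root seed, stably."""
    h = hashlib.sha256(f"{config.rng_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def assemble_strain(
    strain_id: str,
    contigs: dict[str, str],
    reads: synthdata.SimulatedReadSet,
    reference_seq: str,
    config: PipelineConfig,
    circular: bool = True,
) -> tuple[str, dict]:
    """scaffold -> gapfill -> polish for one strain; returns (sequence, report)."""
    placements, unplaced = scaffold.anchor_contigs(contigs, reference_seq, k=config.anchor_k)
    scaf = scaffold.build_scaffold(placements, len(reference_seq))
    params = config.gapfill_params()
    repo = gapfill.build_repository(
        reads, seed_length=params.seed_length, max_mismatches=params.max_seed_mismatches
    )
    asm = gapfill.fill_all_gaps(scaf, contigs, repo, params)
    pol = polish.polish_assembly(
        asm.sequence, reads,
        threshold=config.coverage_threshold,
        max_mismatches=config.mapping_mismatches,
        params=params,
        max_rounds=config.polish_rounds,
        rng_seed=_seed_for(config, "polish-" + strain_id),
        circular=circular,
    )
    report = {
        "strain": strain_id,
        "n_contigs": len(contigs),
        "n_unplaced": len(unplaced),
        "n_gaps": len(scaf.gaps),
        "n_gaps_closed": asm.n_closed,
        "gap_status": [r.status for r in asm.gap_results],
        "polish_rounds": pol.rounds,
        "polish_converged": pol.converged,
        "n_corrections": len(pol.records),
    }
    return pol.assembly, report


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline and write all artifacts under ``output_dir``."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    config.to_yaml(outdir / "config.yaml")

    if config.reference_path:
        genomes = io.read_genbank_flat(config.reference_path) \
            if config.reference_path.endswith((".gb", ".gbk", ".genbank")) else None
        if genomes is None:
            raise ValueError("non-synthetic runs require a GenBank reference")
        reference = genomes[0]
        strain_inputs = {
            s: (io.read_fasta(config.contig_paths[s]), io.read_fastq(config.read_paths[s]))
            for s in config.contig_paths
        }
        truths = {}
        strain_order = list(strain_inputs)
    else:
        syn = config.synthetic
        spec = synthdata.GenomeSpec(
            chromosome_length=syn["chromosome_length"],
            n_genes=syn["n_genes"],
            mean_gene_length=syn["mean_gene_length"],
            mean_intergenic_length=syn["mean_intergenic_length"],
        )
        reference = synthdata.simulate_reference(spec, _seed_for(config, "reference"))
        strain_order = list(syn["strains"])
        strain_inputs = {}
        truths = {}
        for i, s in enumerate(strain_order):
            strain, truth = synthdata.mutate_strain(
                reference, syn["n_snps"], syn["syn_fraction"], syn["n_indels"],
                _seed_for(config, "mutate", i), strain_id=s,
            )
            cs = synthdata.shred_contigs(strain, syn["n_gaps"], _seed_for(config, "shred", i))
            reads = synthdata.simulate_reads(
                strain, syn["coverage"], _seed_for(config, "reads", i),
                error_rate=syn["error_rate"],
            )
            strain_inputs[s] = (cs.sequences(), reads)
            truths[s] = truth
            io.write_fasta(outdir / f"{s}.contigs.fasta", cs.sequences())
            io.write_fastq(outdir / f"{s}.reads.fastq", reads)
        io.write_fasta(outdir / "reference.fasta", {"reference": reference.seq})
        io.write_gff3(outdir / "reference.gff3", reference)
    manifest.stages.append("inputs")

    # assembly per strain
    assemblies: dict[str, str] = {}
    reports = []
    for s in strain_order:
        contigs, reads = strain_inputs[s]
        seq, report = assemble_strain(s, contigs, reads, reference.seq, config)
        assemblies[s] = seq
        reports.append(report)
        io.write_fasta(outdir / f"{s}.assembly.fasta", {s: seq})
    io.write_tsv(outdir / "assembly_report.tsv",
                 [{k: r[k] for k in ("strain", "n_contigs", "n_unplaced", "n_gaps",
                                     "n_gaps_closed", "polish_rounds",
                                     "polish_converged", "n_corrections")}
                  for r in reports],
                 ["strain", "n_contigs", "n_unplaced", "n_gaps", "n_gaps_closed",
                  "polish_rounds", "polish_converged", "n_corrections"])
    manifest.stages.append("assemble")

    # annotation per strain (projected from the reference, curated)
    annotated: dict[str, "object"] = {}
    for s in strain_order:
        aln = compare.align_collinear(reference.seq, assemblies[s], k=config.anchor_k)
        proj = annotate.project_annotation(reference, aln)
        curated, events = annotate.curate_models(
            proj.models, assemblies[s], reference,
            min_merge_identity=config.min_merge_identity,
            length_ratio=config.curation_length_ratio,
        )
        from .genome import ReferenceGenome
        genome = ReferenceGenome(id=s, seq=assemblies[s], models=curated, circular=True)
        annotated[s] = genome
        io.write_gff3(outdir / f"{s}.gff3", genome)
        io.write_tsv(outdir / f"{s}.curation.tsv",
                     [{"gene_id": e.gene_id, "rule": e.rule, "detail": e.detail}
                      for e in events],
                     ["gene_id", "rule", "detail"])
    manifest.stages.append("annotate")

    # comparison: pairwise variants in the frame of the first strain ordering
    variant_sets = {}
    effect_tables = {}
    runs_results = {}
    frame = strain_order[0]
    for i, a in enumerate(strain_order):
        for b in strain_order[i + 1:]:
            aln = compare.align_collinear(assemblies[a], assemblies[b], k=config.anchor_k)
            vs = compare.call_variants(aln, (a, b))
            variant_sets[(a, b)] = vs
            if a == frame:
                tbl = compare.classify_coding_effects(vs, annotated[a])
                effect_tables[b] = tbl
                try:
                    runs_results[b] = compare.runs_test(tbl)
                except ValueError as exc:
                    runs_results[b] = str(exc)
    pair_df = compare.pairwise_tables(strain_order, variant_sets)
    pair_df.to_csv(outdir / "pairwise_variants.tsv", sep="\t")
    eff_rows = []
    for b, tbl in effect_tables.items():
        eff_rows.append({
            "strain": b, "n_synonymous": tbl.n_synonymous,
            "n_nonsynonymous": tbl.n_nonsynonymous,
            "n_unclassified": tbl.n_unclassified,
            "genes_with_nonsyn": int(tbl.nonsyn_indicator().sum()),
        })
    io.write_tsv(outdir / "effects.tsv", eff_rows,
                 ["strain", "n_synonymous", "n_nonsynonymous", "n_unclassified",
                  "genes_with_nonsyn"])
    runs_out = {
        b: (asdict(r) if not isinstance(r, str) else {"error": r})
        for b, r in runs_results.items()
    }
    (outdir / "runs_test.json").write_text(json.dumps(runs_out, indent=2, sort_keys=True))

    stats_rows = []
    for s in strain_order:
        st = compare.genome_stats(annotated[s])
        stats_rows.append({"strain": s, **asdict(st)})
    io.write_tsv(outdir / "genome_stats.tsv", stats_rows,
                 ["strain"] + list(asdict(compare.genome_stats(annotated[frame])).keys()))
    # gene presence/absence of the frame strain against the reference
    # annotation (reciprocal best protein match)
    diff = annotate.gene_content_diff(
        annotate.translate_all(annotated[frame]),
        annotate.translate_all(reference),
    )
    io.write_tsv(outdir / "gene_content.tsv",
                 [{"category": "shared", "id_a": a, "id_b": b, "identity": i}
                  for a, b, i in diff.shared]
                 + [{"category": "unique_to_assembly", "id_a": a, "id_b": "",
                     "identity": ""} for a in diff.unique_to_a]
                 + [{"category": "unique_to_reference", "id_a": "", "id_b": b,
                     "identity": ""} for b in diff.unique_to_b],
                 ["category", "id_a", "id_b", "identity"])

    track = compare.at_frequency_track(assemblies[frame])
    io.write_tsv(outdir / "at_track.tsv",
                 [{"start": s, "end": e, "at_fraction": f"{v:.4f}"} for s, e, v in track],
                 ["start", "end", "at_fraction"])
    manifest.stages.append("compare")

    # config.yaml embeds the output path, so it is provenance, not output
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name not in ("manifest.json", "config.yaml"):
            manifest.record(p)
    manifest.wall_time_s = time.time() - t0
    manifest.write(outdir / "manifest.json")
    return manifest
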