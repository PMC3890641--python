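# genofinish

Reference-guided finishing and comparative analysis of small, collinear
bacterial genomes (endosymbiont-scale), built around an overlap-consensus
gap filler driven by short single-end reads.

The pipeline covers:

1. **Synthetic data** (`genofinish.synthdata`) — AT-rich circular
   chromosomes with dense gene models and poly-A tracts, diverged strains
   with a known SNP/indel truth set, 454-style contigs whose gaps are
   biased to poly-A regions, and 36 bp single-end reads at configurable
   coverage and error rate. Every downstream stage is testable against
   these truths without downloads.
2. **Scaffolding** (`genofinish.scaffold`) — contigs are ordered and
   oriented against a collinear reference via unique k-mer anchors and
   monotone chaining; gap sizes are inferred from reference distance.
3. **Gap filling** (`genofinish.gapfill`) — the overlap-consensus
   extender: a 30 bp terminal seed recruits repository reads containing a
   matching window (≤2 mismatches), the base following each match is put
   to a strict majority vote, exhausted reads are consumed together with
   their reverse complements, and extension terminates when the growing
   sequence overlaps the downstream contig.
4. **Polishing** (`genofinish.polish`) — reads are mapped back with a
   guaranteed-complete ≤3-mismatch indexed mapper (MAQ-like random tie
   breaking), per-site coverage is computed, and regions below the
   coverage threshold (default 21×) are excised and re-derived with the
   consensus extender anchored on their flanks.
5. **Annotation** (`genofinish.annotate`) — reference gene models are
   projected through the whole-genome alignment and curated automatically:
   >10% length deviations flagged, frameshifts across poly-A tracts merged
   into dual-frame models (tract length unchanged), missing starts extended
   to upstream ATG/GTG/TTG/ATT, unresolved interruptions called pseudogenes.
   Gene content comparison is by reciprocal best protein match.
6. **Comparison** (`genofinish.compare`) — collinear whole-genome
   alignment, SNP and indel-event calling, per-gene synonymous /
   nonsynonymous classification under translation table 11, a
   Wald–Wolfowitz runs test of nonsynonymous randomness (exact permutation
   distribution for n ≤ 20, normal approximation beyond), genome
   composition statistics and a sliding-window AT-frequency track.

## CLI

Each stage is independently scriptable; `run` chains them:

```sh
genofinish simulate --length 50000 --genes 45 --strains 2 --gaps 8 \
    --coverage 60 --seed 1 -o work/
genofinish scaffold --contigs work/strain1.contigs.fasta \
    --reference work/reference.fasta -o work/scaf.tsv
genofinish gapfill --scaffold work/scaf.tsv --contigs work/strain1.contigs.fasta \
    --reads work/strain1.reads.fastq -o work/assembly.fasta --report work/gaps.tsv
genofinish polish --assembly work/assembly.fasta --reads work/strain1.reads.fastq \
    --circular -o work/polish
genofinish annotate --genome work/polish/polished.fasta \
    --reference work/reference.fasta --reference-gff work/reference.gff3 -o work/annot
genofinish compare --genome-a work/reference.fasta \
    --genome-b work/polish/polished.fasta --gff-a work/reference.gff3 -o work/cmp

# full synthetic multi-strain demo (writes variant/effect/stats tables,
# runs-test JSON, AT track, and a digest manifest):
genofinish run --seed 1 -o work/demo
```

All randomness flows from one root seed; reruns with the same seed produce
byte-identical outputs (checked via the manifest digests).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (gap-filler
completeness and robustness, mapper-vs-brute-force agreement,
excise-and-refill correction, exact variant recovery, runs-test checks,
partition conservation). Two tests are expected to fail by design:

* `test_runs_normal_vs_exact_agreement` — the stated 0.02 agreement bound
  between the normal approximation and the exact runs distribution cannot
  hold for small n (discrete distribution); the companion test verifies
  the exact method against brute-force enumeration instead.
* `test_accession_deposited_record_values` — needs the deposited GenBank records,
  which are not distributable with this repository; place them under
  `data/accessions/<ACC>.gb` to enable it.

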