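# hybasm

Hybrid overlap-layout-consensus assembly of long, erroneous reads (PacBio /
Nanopore-like, 15-40% error) anchored on accurate pre-assembled contigs.

Instead of correcting long reads base by base, each read is lossily
**compressed** into the ordered, oriented list of accurate contigs it
confidently touches (via unique k-mer anchors). All expensive work then
happens in this compressed domain:

1. **compress** — index contigs by their globally unique k-mers; convert each
   read into a compressed read; collapse strand-canonical duplicates.
2. **clean** — pile each compressed read against its candidate neighbors
   (inverted index + identifier-level Smith-Waterman); drop anchors nobody
   confirms and split chimeric reads at junctions no neighbor alignment
   crosses.
3. **graph** — remove contained reads, keep each read's best suffix-prefix
   overlap per end, clip tips, pop bubbles.
4. **layout** — uncompress maximal unbranched paths into draft backbones,
   patching long-read coverage gaps (and backbone ends) with contig sequence.
5. **consensus** — align the related raw reads and contigs back to each
   backbone with a built-in seed-chain-extend aligner and polish via a sparse
   k-mer graph: thread every sequence through position-anchored k-mer nodes,
   reweight edge support against local coverage, and read out the heaviest
   source-to-sink path.

A fully truth-tracked simulator (genomes with optional repeats, fragmented
contigs, lognormal erroneous reads, injectable chimeras) makes the whole
pipeline testable offline.

## CLI

```sh
# simulate a dataset with truth maps
hybasm simulate -o sim --genome-length 100000 --coverage 20 --seed 1

# assemble: contigs FASTA + long reads FASTA/FASTQ
hybasm assemble sim/contigs.fasta sim/reads.fastq -o out

# draft only (skip polishing); stage-wise artifacts
hybasm assemble ... -o out --no-consensus
hybasm compress|clean|graph|layout|consensus CONTIGS READS -o out
```

Key knobs (flags or `--config cfg.yaml`): `-k` (anchor k-mer, default 17),
`--adaptive-frac` (anchor threshold as a fraction of contig length,
0.001-0.02, default 0.008), `--min-overlap-score` (default 150),
`--remove-chimera/--no-remove-chimera`, `--consensus-rounds`.

Every run writes stage artifacts (`compressed_reads.tsv`,
`cleaning_report.tsv`, `graph.gfa`, `backbones.tsv`, `draft.fasta`,
`assembly.fasta`) plus a `manifest.json` with the config, input hashes and
stage statistics (reads, anchors/read, chimeras split, graph size, N50/NG50).
Runs are deterministic: identical inputs and config give byte-identical
output.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance properties
(oracle equivalences for the identifier-domain DP, containment and heaviest
path; structural recovery, low-coverage operation, chimera handling, hybrid
gap patching, strand symmetry and compression sanity on seed-fixed
simulations). The full suite takes a few minutes on one CPU.

## Library use

```python
from hybasm import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(), "contigs.fasta", "reads.fastq", "out")
for name, seq in result.assembly:
    ...
```

Individual stages are importable from `hybasm.anchor_index`,
`hybasm.compressed_align`, `hybasm.read_cleaning`, `hybasm.overlap_graph`,
`hybasm.layout_consensus`, and `hybasm.synthetic_data`.
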