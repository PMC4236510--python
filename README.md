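# mipscan

Characterization and subfamily classification of Major Intrinsic Protein
(MIP / aquaporin-superfamily) channel sequences.

Given protein sequences in FASTA, the pipeline

- validates the MIP architecture (two NPA(-like) boxes, six transmembrane
  segments by Kyte–Doolittle hydropathy, group conservation of small residues
  at 17 helix–helix interface positions),
- extracts the aromatic/arginine (Ar/R) selectivity filter (TM2, TM5, LE1,
  LE2) and the two NPA boxes by global alignment onto annotated anchor
  sequences,
- profiles each sequence (isoelectric point, molecular weight, loop-D length
  and charge, loop-E motif class and intra-helical salt bridge),
- builds a neighbor-joining tree with bootstrap support and 50% majority-rule
  collapse, and
- combines rule-based filter matching (per-subfamily residue sets stored as
  data) with tree clade assignment into a final subfamily call:
  AQP, the aquaglyceroporin subgroups (Fps1-like, Yfl054-like, α, β, γ1, γ2,
  δ), XIP, or SIP-like.

A first-class synthetic-data module generates labeled MIP-like sequences with
planted features (filter residues, NPA substitutions, loop-E motifs, loop-D
charge, topology), so the whole pipeline is testable without any downloads.

## CLI

```bash
# generate a labeled synthetic dataset (ground truth in the headers)
mipscan simulate --labels all --n-per-label 10 --seed 7 \
    --out-fasta demo.fasta --out-truth truth.tsv

# per-sequence features + MIP validation verdicts
mipscan scan demo.fasta --out features.tsv

# bootstrapped, majority-rule-collapsed NJ tree
mipscan tree demo.fasta --out tree.nwk --bootstrap 100 --seed 7

# full pipeline: features, tree, subfamily calls, per-group summary, manifest
mipscan classify demo.fasta --outdir results/ --seed 7 --bootstrap 100

# rebuild the per-group summary from saved tables
mipscan summarize --calls results/calls.tsv --features results/features.tsv \
    --out summary.tsv
```

All outputs are TSV/Newick/JSON and byte-reproducible for a fixed seed.
`mipscan classify --labeled-refs refs.fasta` accepts user-supplied labeled
reference sequences (description field `subfamily=<label>`); by default the
built-in per-subfamily exemplars are used for clade labeling.

## Package layout

- `mipscan.io_core` — FASTA I/O, sequence records, greedy redundancy removal
- `mipscan.topology` — hydropathy profiles, TM-span prediction, imported spans
- `mipscan.anchor_align` — global alignment, anchor choice, position mapping
- `mipscan.features` — NPA boxes, Ar/R filter, pI/MW, loop metrics, motifs,
  MIP validation
- `mipscan.phylo` — p-distances, neighbor joining, bootstrap, majority-rule
  collapse, clade labeling
- `mipscan.classify` — rule table, call combination, group summaries
- `mipscan.synthetic` — synthetic sequence generator, anchors, exemplars
- `mipscan.pipeline` / `mipscan.cli` — orchestration and the `mipscan` CLI
- `mipscan/data/rules.json` — per-subfamily Ar/R filter residue sets
- `mipscan/data/references.json` — annotated anchor sequences (regenerate via
  `python scripts/build_reference_data.py`)
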