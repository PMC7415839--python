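# issalign

Remote protein homology detection by **intermediate sequence search (ISS)**
and query–template **alignment generation through intermediates**, for use in
template-based modeling pipelines.

Direct sequence search misses homologs whose pairwise identity is too low.
`issalign` chains searches through intermediate sequences: hits of one round
become (extended sub-region) queries of the next, the last round targets a
structural database, and each query→…→template chain is scored by the sum of
its E-values (smallest sum ranks first). For alignment generation, a
Smith-Waterman alignment is computed per chain edge, lifted to full-sequence
coordinates, and the alignments are merged by **residue-map composition** —
residue positions of every per-edge alignment are preserved exactly; no
multiple-alignment DP is involved. The query–template alignment is split out
of the merged stack, and whichever of that alignment and the direct
Smith-Waterman alignment covers the longer aligned region is kept.

## Layout

| module | contents |
| --- | --- |
| `issalign.seqcore` | domain types: sequences, regions, hits, search paths, pairwise alignments, monotone residue maps; BLOSUM62 scoring scheme |
| `issalign.localalign` | affine-gap Smith-Waterman (numba-accelerated DP, deterministic traceback) |
| `issalign.search_engines` | search-backend contract; built-in Smith-Waterman scan engine with Karlin-Altschul E-values; BLAST-style 8-column tabular adapter |
| `issalign.iss_search` | layered search orchestration, hit-region extension, cycle-free path construction, sum-of-E-value ranking |
| `issalign.align_merge` | residue-map composition, merged multi-row alignment, query–template split-out, longer-aligned-region selection |
| `issalign.eval_bench` | superfamily truth labels (SCOP sccs), ROC_n/AUC_n evaluation |
| `issalign.synthfam` | synthetic remote-homolog families with exact ground-truth residue correspondences; multi-domain decoys; desk-scale detection benchmark |
| `issalign.io_cli` | FASTA / aligned-FASTA / PIR / ranked-TSV readers and writers, `issalign` CLI |

## CLI

Generate a seeded synthetic family (query, per-layer intermediate databases,
final database, true residue pairs):

```sh
issalign simulate --seed 7 --length 150 --intermediates 2 \
    --identity 0.55 --indel-rate 0.02 --decoys 10 --out-dir fixtures/
```

Layered search (ranked TSV is the interchange format between stages):

```sh
issalign search --query fixtures/query.fasta \
    --intermediate-db fixtures/intermediate_db1.fasta \
    --intermediate-db fixtures/intermediate_db2.fasta \
    --final-db fixtures/final_db.fasta \
    --ext 5,5,20 --cutoffs 0.001,0.001,10 --out ranked.tsv
```

Alignment generation for one ranked template (PIR or aligned FASTA; add
`--emit-merged` for the full query/intermediates/template stack):

```sh
issalign align --query fixtures/query.fasta --template-id T \
    --paths ranked.tsv \
    --intermediate-db fixtures/intermediate_db1.fasta \
    --intermediate-db fixtures/intermediate_db2.fasta \
    --final-db fixtures/final_db.fasta \
    --out aln.pir --format pir --emit-merged
```

Detection-accuracy evaluation (AUC_n under same-superfamily truth, sccs codes
taken from FASTA headers such as `>d1tp6a_ a.118.1.1`):

```sh
issalign eval --queries queries.fasta --db scop.fasta \
    --intermediate-db uniref.fasta --layers 1 \
    --n 10,50,100,250,500 --out auc.tsv
```

External search tools are supported via their tabular output
(`--engine tabular --hits-file hits.tsv`, columns
`qseqid sseqid evalue bitscore qstart qend sstart send`).

## Conventions

All internal coordinates are 0-based half-open; 1-based inclusive dialects
are converted at the I/O boundary. The gap symbol is `-`. Non-standard
residues are mapped to `X` at ingest. Defaults: BLOSUM62, gap open 11 /
extend 1; hit-region extension 5 per intermediate layer and 20 at the final
layer; E-value cutoffs 1e-3 (intermediate) and 10 (final). All outputs are
byte-deterministic given identical inputs and seeds.
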