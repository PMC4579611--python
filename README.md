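# dechip

Reference-free ("de novo") ChIP-seq analysis. Instead of aligning reads to
a genome, `dechip` assembles the ChIP (case) reads into **ChIPtigs** —
putative bound regions — ranks them by case-vs-control enrichment with a
binomial tail test, and discovers transcription-factor binding motifs in
the top-ranked ChIPtigs. A built-in simulator generates complete synthetic
experiments with known ground truth, so the whole pipeline is testable
without any external data.

## Components

| Module | What it does |
| --- | --- |
| `dechip.io_formats` | FASTA/FASTQ reading (plain/gzip), FASTA writing, MEME minimal motif files, ranking TSV |
| `dechip.simulate` | Random genome, planted PWM sites, fragment-model case/control reads with anti-correlated strand geometry |
| `dechip.assemble_dbg` | Velvet-style de Bruijn assembler: reverse-complement node pairing, linear merging, tip clipping (<2k bp), Tour-Bus-like bubble collapse, low-coverage pruning |
| `dechip.assemble_profile` | SEECER-style consensus profile assembler: seed k-mer clusters, per-column emission model, discounted online count updates, entropy-based extension stop (0.6 nats) |
| `dechip.quantify` | Seed-and-extend read mapping, 50–500 bp length filter, binomial enrichment P-value with the global library ratio, ranking, top-M selection |
| `dechip.motifs` | DREME-style discriminative IUPAC-word discovery (Fisher exact test against a dinucleotide-shuffled background), greedy degenerate-symbol generalization, simplified PWM-vs-database matcher |
| `dechip.pipeline` | End-to-end orchestration with per-stage RNG streams and a run manifest |

## Quick start

```bash
# 1. generate a synthetic experiment (100 kb genome, 200 planted sites,
#    10x enrichment, 50k+50k 36-bp reads, 0.5% error)
dechip simulate --outdir sim --seed 7

# 2. run the full pipeline with the de Bruijn assembler
dechip run --case sim/case.fastq --control sim/control.fastq \
    --assembler dbg --outdir out --seed 7

# outputs: out/chiptigs.fasta, out/ranking.tsv, out/top_chiptigs.fasta,
#          out/motifs.meme, out/manifest.json, out/run.log

# or stage by stage
dechip assemble --reads sim/case.fastq --assembler profile --out tigs.fasta
dechip rank --chiptigs tigs.fasta --case sim/case.fastq \
    --control sim/control.fastq --out ranking.tsv
dechip motifs --chiptigs out/top_chiptigs.fasta --out motifs.meme \
    [--motif-db jaspar.meme]
```

The ranking TSV columns are `chiptig_id  length  x1  x0  p_value  rank`,
where `x1`/`x0` are case/control reads mapped to the ChIPtig and the
P-value is the binomial tail for observing `x1` or more case reads among
`x1 + x0` at success probability `r/(r+1)` (`r` = mapped case / mapped
control totals). Discovered motifs are written in MEME minimal format and
can be fed to MEME-suite tools or matched against a database with
`--motif-db`.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(assembler exactness over seeds, error robustness, entropy-stop behavior,
null calibration, planted-motif recovery, ranking truthfulness); the other
files are per-module unit and property tests backed by independent oracles
(log-space binomial summation, exhaustive hypergeometric enumeration,
brute-force IUPAC matching, dinucleotide count verification).

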