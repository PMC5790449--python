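# rnacensus

A two-phase small-RNA census pipeline over synthetic cohorts with planted,
exactly recoverable ground truth.

**Phase 1** cleans raw FASTQ reads (adapter clipping, mean-quality filter,
minimum-length filter), aligns them ungapped to precursor miRNA sequences with
up to 3 mismatches, assigns them to mature arms, builds the miRNA counting
matrix and calls isomiRs (5′/3′ shifts and internal mismatches with strictly
more than 20 supporting reads in at least one specimen group).

**Phase 2** takes the miRNA-unmapped pool, aligns it to a toy genome on both
strands (≤2 mismatches, provably complete via pigeonhole seed-and-extend),
applies the size-selection rule to annotations (GENCODE ≤70 bp; DASHR piRNA
and tRNA exempt), and assigns reads to same-strand annotations with homolog
sharing, so identical-sequence piRNA loci carry exactly equal counts.

Downstream: median-of-ratios size factors, per-batch median centering on the
log scale (a testable surrogate for latent-factor correction of the plasma
studies), a detection census (group median strictly above 20 normalized
reads), Venn decomposition into common/specimen-specific sets, MAD/median
stability ranking of candidate reference RNAs, and random-forest specimen
classification with chi-square attribute (merit) ranking.

The `simulate` module generates everything the pipeline consumes: a toy
genome and miRNA/sncRNA annotations, plus a multi-specimen multi-batch read
cohort with planted common/specific/stable/correlated features, adapter
contamination, sequencing errors, low-quality reads, study batch offsets and
unmappable noise. Every read id encodes its true source feature, so
assignment accuracy is computable exactly.

## CLI

```sh
rnacensus simulate --seed 1 --depth 50000 --out cohort/
rnacensus run-all --seed 1 --out results_run/        # full pipeline
rnacensus preprocess cohort/reads/plasma01.fastq --out clean.fastq
rnacensus normalize counts.tsv sample_sheet.tsv --out normalized.tsv
rnacensus census normalized.tsv sample_sheet.tsv --out census/
```

`run-all` writes per-stage TSV/JSON artifacts plus `manifest.json` with the
seed, parameters and per-stage read accounting. A YAML config can replace the
flags (`rnacensus run-all --config pipeline.yaml`).

## Layout

```
src/rnacensus/
  simulate.py    reference + cohort generator with planted truth
  preprocess.py  adapter trimming, quality and length filters
  mirna.py       phase-1 aligner, mature assignment, isomiR calling
  sncrna.py      phase-2 genome aligner, size selection, assignment
  normalize.py   median-of-ratios size factors, batch median-centering
  census.py      detection, Venn partition, top-expressed, PCA, pairing
  stability.py   MAD/median reference ranking
  classify.py    random-forest CV + chi-square merit
  matrix.py      CountMatrix / NormalizedMatrix containers
  io.py          FASTA/FASTQ/GTF/BED6/TSV/JSON adapters
  pipeline.py    orchestration + manifest
  cli.py         click entry points
```
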