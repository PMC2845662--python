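# nadscan

Dual-platform discovery of nucleolus-associated chromatin domains (NADs)
from population-average data, as a tested, reproducible pipeline:

* **aCGH caller** — probe-anchored 0.1 Mb running-window means, a
  genome-wide 85th-percentile cut per replicate, and base-pair intersection
  of the replicate region sets.
* **Read-coverage caller** — presence/absence binarization of mapped reads
  on 100 bp segments spaced every 1 kb, a 100-point running mean, and a
  per-chromosome 98th-percentile cut.
* **Catalog assembly** — single-linkage fusion of overlapping
  cross-platform candidates (borders follow the aCGH extremes where array
  probes exist near the merged border, otherwise the sequencing limits),
  joining of neighbours separated by less than 0.1 Mb, detection-source
  labels (`both` / `acgh_only` / `seq_only`), and size statistics.
* **Empirical significance** — each domain's read count ranked (mid-rank)
  against 1,000 random same-chromosome regions of the same size, reported
  as a quantile and quartile label.
* **Feature enrichment** — per-class Fisher exact tests (one- or
  two-sided), fold densities versus the genome, one-sample density t-tests
  with Benjamini–Hochberg adjustment.
* **Synthetic data** — generators for genomes with planted domains,
  replicate aCGH noise tracks, two-level read coverage and clustered
  feature annotations, so the whole pipeline is testable offline.

Coordinates are 0-based half-open throughout; BED is the on-disk interval
dialect. Chromosome names are matched exactly (no `chr` normalization).

## CLI

Every stage is a subcommand writing plain BED/TSV/JSON, so stages can be
rerun in isolation:

```bash
nadscan simulate --config sim.yaml --outdir fixtures/
nadscan acgh --signal fixtures/probes.tsv --chrom-sizes fixtures/chrom_sizes.tsv --out acgh.bed
nadscan seq --reads fixtures/reads.bed --chrom-sizes fixtures/chrom_sizes.tsv --out seq.bed
nadscan assemble --acgh acgh.bed --seq seq.bed --probes fixtures/probes.tsv --out nads.bed
nadscan significance --nads nads.bed --reads fixtures/reads.bed \
    --chrom-sizes fixtures/chrom_sizes.tsv --seed 17 --out nads_scored.tsv
nadscan enrich --nads nads.bed --features fixtures/features.bed \
    --chrom-sizes fixtures/chrom_sizes.tsv --out enrichment.tsv
nadscan compare --a nads.bed --b fixtures/truth.bed
```

or run everything at once from a YAML config:

```bash
nadscan run --config pipeline.yaml --outdir out/
```

with a config like

```yaml
run: {seed: 1}
simulation:
  chrom_lengths: [60000000, 60000000]
  n_planted: 8
acgh: {percentile: 85, window_bp: 100000}
seq: {percentile: 98, window_points: 100}
significance: {n_random: 1000}
```

`out/manifest.json` records the config hash, seeds, package version,
per-stage record counts and (for simulated runs) planted-domain recovery
metrics. Identical config + seed produces byte-identical outputs.

Exit codes: 0 success, 2 validation/config error, 3 runtime error.

## Layout

```
src/nadscan/
  genome_model.py       interval types, interval algebra, tabular I/O
  acgh_caller.py        running-window percentile caller + replicate intersection
  seq_caller.py         binarized-coverage running-mean caller
  nad_assembly.py       cross-platform fusion, gap joining, catalog stats
  read_significance.py  random-region empirical significance
  feature_enrichment.py Fisher / fold-density / t-test statistics
  synthetic_data.py     planted-domain simulators
  pipeline.py           orchestration, config validation, manifest
  cli.py                click command group
tests/                  unit + property + acceptance suites (_oracles.py holds
                        the independent brute-force oracles)
scripts/acceptance.py   acceptance report
```
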