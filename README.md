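# m6a-landscape

Site-level differential m6A epitranscriptome analysis from nanopore
modification pileups: per-site stoichiometry aggregation and filtering,
DRACH/region/metagene annotation against a transcript model, differential-site
threshold counting, isoform modification classes, per-gene ranking with
preranked enrichment, treatment-restoration and net-change statistics, and
integration with differential-expression tables and reader-binding intervals.
A deterministic synthetic-data generator emulates every input at desk scale so
the whole pipeline is testable offline.

## Layout

| module | role |
|---|---|
| `m6a_landscape.data_model_io` | bedMethyl pileup / BED / DE-table / read-level / GMT readers and writers, core record types |
| `m6a_landscape.transcript_annotation` | GTF/FASTA transcript models, genome↔transcript coordinates, region and DRACH-motif assignment, metagene positions |
| `m6a_landscape.site_stats` | replicate aggregation, site filters and calls, differential sites with ±10%/±20% threshold counts, isoform classes, restoration analysis |
| `m6a_landscape.gene_level` | per-gene average-Δ ranking, net methylation change, native preranked enrichment (weighted running sum + permutation null), hypergeometric overlap, top-net-gain DE composition |
| `m6a_landscape.integration` | DE up/down set intersection across cell lines, reader-binding interval overlap |
| `m6a_landscape.synthetic_data` | pure-function synthetic corpus generator (annotation, pileups, reads, DE, binding, ground truth) |
| `m6a_landscape.pipeline_cli` | orchestration, manifests, `m6a-landscape` CLI |

## CLI

Every subcommand takes `--config FILE --out DIR --seed INT`; the site-filter
commands also take `--filter-preset {methods,figure}` (aggregated coverage
>20 vs >10 per condition, both with >10% mean level in at least one
condition). Exit codes: 0 success, 2 validation error, 3 data error.

```sh
# 1. simulate a corpus (config = SyntheticConfig fields as YAML)
m6a-landscape simulate --config sim.yaml --out corpus/ --seed 1

# 2. two-condition landscape comparison
m6a-landscape landscape --config landscape.yaml --out results/landscape --seed 1

# 3. treated-vs-untreated analysis (restoration, net change, composition)
m6a-landscape treatment --config treatment.yaml --out results/treatment --seed 1

# 4. intersect DE gene sets across cell lines
m6a-landscape de-intersect --config de.yaml --out results/de --seed 1

# 5. overlap called m6A sites with reader-binding intervals
m6a-landscape binding-overlap --config overlap.yaml --out results/overlap --seed 1
```

A minimal landscape config:

```yaml
condition_a: tumor
condition_b: normal
pileups:
  tumor: [corpus/pileup_tumor_rep1.tsv, corpus/pileup_tumor_rep2.tsv]
  normal: [corpus/pileup_normal_rep1.tsv, corpus/pileup_normal_rep2.tsv]
annotation_gtf: corpus/annotation.gtf
genome_fasta: corpus/genome.fa
read_level_tsv: corpus/read_level.tsv   # optional: isoform classes
gene_sets_gmt: sets.gmt                 # optional: preranked enrichment
n_perm: 1000
```

The treatment config points `hypo_sites_tsv` at a prior landscape run's
`differential_sites.tsv`; sites with delta < −0.10 form the hypo set whose
restoration (treated − untreated > +0.10) is quantified.

Every output directory contains a `manifest.json` (config hash, input
checksums, preset, thresholds, seeds, timings, version); all analytic outputs
are TSVs with `#key=value` metadata headers and are byte-identical on re-runs
with the same inputs and seed.

## Conventions

All internal coordinates are 0-based half-open. All printed thresholds
(>10 reads, >20 coverage, >10%, >20%, >50%, <30%, >70%) are strict
inequalities; the medium isoform bin is the closed interval [30%, 70%].
Deltas are differences of unweighted replicate-mean stoichiometries; the
coverage-weighted aggregate level is reported alongside. Sites are annotated
against one representative transcript per gene (longest CDS, deterministic
tie-breaks).
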