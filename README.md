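# votax

Consensus-vote taxonomic classification of eukaryotic amplicon sequences
(18S rRNA / ITS1), fully offline. `votax` takes tabular BLAST-style hits, a
local NCBI-taxdump-dialect taxonomy and an accession→taxid map, filters hits
on query coverage and percent identity, and votes bottom-up through the
eight standardized ranks (domain … species) with rank-specific identity and
majority thresholds. Generic or partial database annotations ("uncultured
…", kingdom-only records) are ignored at ranks where they are uninformative
and counted where they are, and hit sets dominated by them are left
unassigned. Results are written as QIIME-style taxonomy tables plus a full
voting log.

The package also ships:

- a deterministic **community read simulator** (per-base substitution
  errors, exponential 3'-end truncation, truth tables) plus toy-taxonomy and
  hit-table emulation so the whole pipeline is testable with no network or
  external databases;
- a **degenerate-primer profiler** computing IUPAC-aware best edit distances
  of a primer against clade-grouped target sequences.

## Layout

| module            | what it does                                             |
|-------------------|----------------------------------------------------------|
| `votax.taxonomy`  | taxdump loading, lineages, standardized ranks, generic names |
| `votax.blast`     | 13-column tabular parsing, query coverage, HSP dedup/cap |
| `votax.classify`  | quality filters + bottom-up per-rank consensus voting    |
| `votax.report`    | standardized / full taxonomy TSVs and the voting log     |
| `votax.simulate`  | toy taxonomies, read simulation, emulated hit tables     |
| `votax.primers`   | semi-global IUPAC edit distance, per-clade histograms    |
| `votax.cli`       | `votax classify / simulate / primer-scan`                |

## CLI

Hit tables are the standard 12 tabular columns **extended with the query
length as column 13** (emit with `blastn -outfmt '6 std qlen'`); coverage is
the aligned query span over query length.

```sh
# classify with the ITS identity preset (species 95.2 / genus 83.05 / other 80)
votax classify --hits hits.tsv --taxdump taxdump_dir --acc-map acc2taxid.tsv \
    --preset its --out results/

# 18S preset: 99 / 96 / 80. All thresholds can be overridden:
votax classify ... --preset 18s --min-coverage 0.7 --majority-low 0.6 \
    --majority-high 0.9 --generic-max 0.7 --generics keywords.txt --max-hits 100

# simulate an in-silico community (32 reads/organism, 1% substitutions,
# exponential truncation with mean 5 by default)
votax simulate --spec community.json --seed 42 --out sim/

# profile a degenerate primer against clade-grouped targets
votax primer-scan --primer GGTTGATYYTGCCAG --fasta targets.fasta \
    --clades clades.tsv --out profile.tsv [--hamming] [--revcomp]
```

`classify` writes `standard_taxonomy.tsv` (8-rank lineage, blanks kept as
empty components), `full_taxonomy.tsv` (complete lineage incl. unranked
nodes) and `voting_log.tsv` (votes cast, winner tally and fraction, generic
exclusions per rank, final status) into `--out`. Exit status is 0 even when
queries are unclassified; only I/O or format errors are fatal.

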