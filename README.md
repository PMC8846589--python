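# regulonkit

Terminal-selector regulon analysis as a reusable pipeline. Starting from
per-replicate ChIP peaks (narrowPeak), gene models (GFF3), a genome (FASTA),
a differential-expression table (TSV) and a cell-type (metacell) footprint
matrix (TSV), it derives:

- **consensus peaks** across replicates (transitive-overlap grouping with a
  weak/strong p-value rule and Fisher combination);
- **degenerate-motif occurrences** (IUPAC or `(A/T)`-style parenthetical
  consensus, both strands) and their **central enrichment** within peaks
  (one-sided binomial test against a uniform-placement null);
- **direct target genes** — any gene whose territory (promoter window,
  default −350/+100 bp around the TSS strand-aware, united with the gene
  body) overlaps a consensus peak by ≥ 1 bp;
- **directly activated vs directly repressed** splits by intersecting
  targets with the DE table (log2 fold change is mutant-vs-sibling, so down
  in the mutant = activated by the factor; strict `padj < alpha`), plus
  autoregulation detection;
- **per-metacell regulon summaries**: activated/repressed counts, repression
  proportion (percent, half-up rounding), and exclusive markers
  (represented in exactly one metacell);
- **set overrepresentation** (hypergeometric upper tail + Benjamini–Hochberg).

A fully seeded synthetic-study generator (`regulonkit.synthetic_data`)
emulates all inputs with planted ground truth (motif-centered peaks, signed
DE effects, skewed metacells, exclusive markers) and writes a machine-readable
`truth.json`, so the entire pipeline is testable offline.

Coordinates are 1-based inclusive internally; BED-family files are converted
on read/write.

## CLI

```sh
# generate a synthetic study with planted truth
regulonkit simulate --seed 1 --out-dir sim/

# run the whole pipeline
regulonkit run-all \
  --peaks sim/rep1.narrowPeak --peaks sim/rep2.narrowPeak --peaks sim/rep3.narrowPeak \
  --gff sim/genes.gff3 --fasta sim/genome.fa \
  --de sim/de.tsv --metacells sim/metacells.tsv \
  --motif "GCAT(A/T)ATT(A/T)AT" --tf-gene g0042 \
  --out-dir out/
```

`run-all` writes per-stage TSVs, `manifest.json` (inputs, parameters,
row counts) and a human-readable `report.txt`. Each stage is also available
as its own subcommand (`consensus`, `scan`, `targets`, `classify`,
`celltype`, `enrich`), so real data in the same formats can replace any
synthetic file. Outputs are byte-stable across reruns with identical inputs.

## Layout

```
src/regulonkit/
  genome_intervals.py     intervals, gene models, promoter/territory rules, GFF3/FASTA readers
  peak_consensus.py       narrowPeak IO, Fisher combination, consensus builder
  motif_scan.py           IUPAC motif parsing/expansion, scanning, central enrichment
  target_assignment.py    peak -> gene territory assignment
  regulon_classify.py     DE intersection, activated/repressed labels, autoregulation
  celltype_integration.py metacell representation, repression proportion, exclusivity
  enrichment.py           hypergeometric overrepresentation + BH adjustment
  synthetic_data.py       seeded study generator with truth record
  cli.py                  click CLI and run-all orchestration
```
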