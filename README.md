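# genefam

Gene-family census and expression analysis as a tested, reusable pipeline:

- **census** — locate domain instances in proteins with a sliding-window
  consensus scanner (or consume a precomputed hit table), build ordered
  domain-architecture strings (tandem MD pairs collapse to MLD), classify
  them into five superclades (`LRR-MD-PK`, `MLD-LRR-PK`, `MLD-PK`,
  `MLD-LRR`, `MD-Kin`), and compute molecular weight / isoelectric point.
- **phylogeny** — p/Poisson distances from an aligned FASTA,
  neighbor-joining with deterministic tie-breaking, column-resampling
  bootstrap support, extraction of maximal supported clades plus orphans,
  and a chi-square clade-expansion test between two species.
- **genome_map** — GFF3 gene models, tandem-duplication cluster detection
  (configurable intervening-gene and bp-gap rule), intron counts,
  chromosome-vs-scaffold localization summaries.
- **expression** — median-of-ratios size factors, a `log2(count/factor + 1)`
  variance-stabilizing surrogate, per-sample median centering,
  multi-experiment merging, tau tissue-specificity, peak-tissue assignment
  and peak-grouped heatmap ordering.
- **coexpression** — mutual information on equal-frequency bins, CLR
  background correction, guide-gene first-neighbor networks signed by
  Pearson correlation, GraphML export.
- **simulate** — synthetic proteomes, chromosome layouts and
  negative-binomial count matrices with planted truth (domain positions,
  tandem clusters, peak tissues, co-expressed modules), so the whole
  pipeline is testable without any external data.
- **pipeline / cli** — one config, one master seed, byte-reproducible
  report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(NJ exactness on additive matrices, bootstrap calibration, planted-truth
recovery, CLR null calibration, chi-square type-I error, tau invariants).

## CLI

```bash
# full synthetic pipeline: simulate -> census -> phylo -> map -> express -> coexpress
genefam all --seed 1 --outdir out/

# individual stages on files
genefam census --fasta proteome.fasta --out architectures.tsv
genefam phylo --alignment aligned.fasta --n-bootstrap 1000 --outdir out/
genefam map --gff genes.gff3 --family family_ids.txt --outdir out/
genefam express --counts exp1.tsv --counts exp2.tsv --meta samples.tsv --outdir out/
genefam coexpress --expr expression.tsv --guides guides.txt --outdir out/
```

`genefam all` writes the standard-format artifacts (FASTA, GFF3, Newick,
TSV tables, GraphML) together with the planted-truth tables and a
machine-readable `report.json`; two runs with the same seed produce
byte-identical output.

A YAML config covering every stage parameter can be passed with
`--config`; defaults are produced by `genefam.pipeline.PipelineConfig()`.

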