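# prstress

Reusable pipeline for genome-wide stress-response analysis of plant defense
gene families: time-course differential-expression calling with fixed
thresholds (|log2FC| > 1, FDR ≤ 5%, low-count filter at a mean of 20 reads),
classification of genes into temporal (early / late / sustained) and hormone
(SA/JA) expression programs, cross-genotype trend clustering, phylogeny-based
nomenclature and same-species expansion detection, tandem physical-cluster
detection, and cross-stress profile consolidation with outlier-robust Pearson
correlation — exercised end-to-end on synthetic data with planted structure.

## Layout

- `prstress.io` — readers/writers: counts + sample metadata, DEG tables,
  BED/GFF3 gene coordinates (stored 1-based inclusive), species-tagged
  Newick trees.
- `prstress.simulate` — negative-binomial count simulation with planted
  temporal programs, paired SA/JA responses with tunable co-regulation,
  and family structure (trees with planted expansions, chromosomes with
  planted tandem arrays); fully deterministic under a seed.
- `prstress.deg` — low-count filter, median-of-ratios normalization,
  NB Wald contrast with trend-shrunk moments dispersion, Benjamini–Hochberg
  adjustment, status thresholding, FPKM-ratio log2FC.
- `prstress.programs` — temporal programs, 16-class cross-genotype trend
  clusters, hormone programs (sa_only / ja_only / co_regulated / reciprocal),
  SA-vs-JA correlation, summary tables.
- `prstress.family` — expansion detection (maximal monophyletic same-species
  clades of ≥ 3 tips), clade-letter nomenclature with the `L` infix for
  never-DEG genes, tandem cluster detection (≤ 100 kb gap, ≤ 5 intervening
  genes by default).
- `prstress.cross` — per-stress mean-log2FC consolidation over DEG time
  points, boxplot-rule outlier removal (k = 2.0, single pass), Pearson
  correlation with Evans strength labels, minimum-10-shared-DEGs skip gate,
  per-family attribution tables.
- `prstress.qpcr` — comparative-Ct (2^-ddCt) fold changes and
  qPCR-vs-sequencing concordance.
- `prstress.pipeline` / `prstress.cli` — orchestration with a reproducible
  run manifest.

## CLI

```sh
prstress simulate   --seed 3 --out-dir sim/
prstress call-degs  --counts sim/counts.tsv --meta sim/samples.tsv --out degs.tsv
prstress classify   --degs degs.tsv --out programs.tsv
prstress structure  --tree sim/tree.nwk --catalog sim/catalog.gff3 --out-prefix fam
prstress cross-stress --degs degsA.tsv --degs degsB.tsv --out corr.tsv
prstress qpcr       --ct ct.tsv --ref-gene UBQ --treated trt --control ctl --out qpcr.tsv
prstress run        --seed 3 --out-dir run/      # end-to-end with manifest
```

`prstress run` accepts a YAML config (`--config`) whose keys mirror
`prstress.pipeline.default_config()`; all analysis thresholds are exposed
there. Outputs are tab-separated tables stamped with the run-manifest hash,
plus `manifest.json`.

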