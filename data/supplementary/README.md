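# Supplementary drop-in tables

The source publication distributes its per-gene expression tables as Excel
attachments that are not redistributable with this repository and cannot be
downloaded in the offline test environment.  Three acceptance tests and five
acceptance-report targets consume them.  To enable those checks, convert the
attachments to tab-separated files in this directory:

- `additional_file_3.tsv` — per-gene, per-time-point DEG statistics for the
  four whitefly-infested genotypes.
  Columns: `gene`, `condition` (genotype label: COL2246, COL1468, 60444,
  TME3), `timepoint` (dpi), `log2fc`, `fdr`.
- `additional_file_7.tsv` — consolidated hormone responses.
  Columns: `gene`, `program` (sa_only / ja_only / co_regulated / reciprocal),
  `sa_mean_log2fc`, `ja_mean_log2fc`.
- `additional_file_9.tsv` — consolidated per-stress profiles.
  Columns: `gene`, `stress` (whitefly, mealybug, bacteria, fungi, cmv, cbsv),
  `mean_log2fc`.

With these files present, `tests/test_acceptance.py::TestSupplementarySurface`
turns green and `scripts/acceptance.py` reports targets t5, t6, t7, t9 and
t10 in addition to the desk-scale targets.
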