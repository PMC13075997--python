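# splicechrom

Quantification of splicing-factor chromatin occupancy and classification of
knockdown-induced splicing errors, for CUT&RUN/CUT&Tag-style mapped
fragment data.

Splicing factors such as U2AF2 are classically pictured binding nascent
pre-mRNA, but chromatin profiling shows some of them sitting directly on
gene-body DNA, preferentially on exons of highly expressed, exon-dense
genes. The question this toolkit serves: does that chromatin-bound pool
matter for splicing fidelity — do the genes carrying the most
chromatin-bound factor make the most exon-inclusion errors when the factor
is knocked down?

`splicechrom` implements the full analysis chain as a tested, reusable
library plus CLI:

1. **Coverage tracks** from fragment BEDs — raw per-base counts; the
   fraction-of-counts normalization `value_b = (count_b / T) · G` (uniform
   coverage ⇒ exactly 1 at every base); and spike-in calibration
   (`10,000 / mapped spike-genome fragments`).
2. **Occupancy metrics** — per-gene RPK (fragments over gene ± 1 kb per
   kilobase of gene length) and density `log2(1 + RPK)`; per-exon/intron
   RPK, %GC, and nucleosome-sized (≥ 150 bp) fragment occupancy per kb and
   per 1,000 GC bases; deepTools-style metagene matrices (reference-point
   and scale-regions) with mean-per-base bins and strand flipping.
3. **Gene classes** — active/inactive at RNAPIIS2P density ≥ 4;
   high/low factor occupancy by seeded k-means (k = 3, Lloyd + k-means++)
   on the gene-body metagene matrix; RNase-sensitivity by a defined
   differential-enrichment test (median-of-ratios size factors, Welch t on
   log2 normalized counts, Benjamini-Hochberg, flagged iff log2FC ≤ −1 and
   adjusted p < 0.05); quantile/decile groupings.
4. **Splicing errors** — rMATS-style PSI tables (ΔPSI oriented WT − KD)
   classified per event (SE/MXE → exon inclusion, RI → intron removal,
   A5SS/A3SS → splice site) and per gene (skipped / included / MXE /
   unchanged / untested), with summary percentages, cross-cell-line
   concordance, and FPKM-decile reports; Mann-Whitney comparisons with
   exact small-sample enumeration and Bonferroni correction.
5. **Synthetic data** — a first-class generator that plants gene classes,
   fragment rates, RNase-sensitive genes, and splice-error classes with
   calibrated p-values, so the whole pipeline is testable offline.

See `docs/methods.md` for the formal conventions, defaults, and known
limitations (including the power characteristics of the simplified
differential test).

## Worked example

Run the six pipeline stages on the default synthetic bundle (400 genes,
5 Mb, one chromosome):

```sh
splicechrom all --outdir run --seed 1
```

or from Python:

```python
from splicechrom.pipeline import RunConfig, run_all
report = run_all(RunConfig(outdir="run", seed=1))
```

The consolidated `run/report/report.json` from that seed contains, among
other things:

```
"errors_by_class": {
  "U2AF2_high_active": {"tested": 59, "error_genes": 31,
                        "error_percent": 53, "skipped_percent": 31},
  "U2AF2_low_active":  {"tested": 131, "error_genes": 44,
                        "error_percent": 34, "skipped_percent": 24}},
"concordance": {
  "error_to_error":       {"count": 49, "of": 75,  "percent": 65},
  "no_error_to_no_error": {"count": 67, "of": 115, "percent": 58}},
"planted_recovery": {
  "max_class_proportion_error": 0.0,
  "percent_skipped_by_occupancy": {"U2AF2_high": 30.51, "U2AF2_low": 23.66},
  ...}
```

Reading: among recovered factor-high active genes, 53% show exon-inclusion
errors after knockdown versus 34% of factor-low active genes, and skipped
genes dominate the errors — the planted signature of chromatin-bound-factor
-dependent exon selection. Error status agrees across the two simulated
cell lines for 65% of error genes (the generator's configured concordance),
and the recovered high/low/inactive gene-class proportions match the
planted ones exactly at this seed. The exon-versus-intron occupancy
comparison in the same report rejects equality at p ≈ 10⁻¹⁸ (rank-sum),
reflecting the planted 3-fold exon enrichment.

## Layout

```
src/splicechrom/
  annotation.py   gene models, BED12/GTF, FASTA, structural features
  coverage.py     fragments, coverage, normalization, calibration, bedGraph
  occupancy.py    counting, RPK/density, metagenes, nucleosome/GC metrics
  classify.py     activity, k-means occupancy split, differential test
  splicing.py     PSI tables, gene splice classes, summaries, concordance
  stats.py        Mann-Whitney (exact + corrected normal), BH, Bonferroni
  simulate.py     synthetic genomes/fragments/PSI with planted truth
  pipeline.py     stage orchestration, run manifest
  cli.py          `splicechrom` subcommands
```
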