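# spermhist

Downstream analysis of histone H3 retention in sperm chromatin, comparing a
purified histone-replacement-completed fraction ("hrcs") against total
sperm. The package implements the complete desk-side analysis stack and a
planted-truth synthetic data generator so every estimator can be scored
against known ground truth:

- **intervals_io** — 0-based half-open interval model; BED / bedGraph /
  gene-table / FASTA I/O; any-overlap counting with a sorted index; a
  simple fold-change + Poisson enrichment screen with Benjamini–Hochberg
  correction (a documented stand-in for a full peak caller).
- **compartments** — paint-by-precedence genomic compartment annotation
  (promoter > exon > intron > upstream > downstream > intergenic
  repeat/unique) that partitions every base exactly, plus per-compartment
  peak distribution and enrichment tables.
- **cgi_analysis** — CpG-island observed/expected ratios
  (`oe = N_CpG·L / (N_C·N_G)`, Gardiner-Garden & Frommer convention),
  box-plot summaries, exact/asymptotic Wilcoxon rank-sum tests, and
  per-chromosome peak/CGI densities.
- **target_categories** — promoter-overlap peak-to-gene mapping, pairwise
  sample overlap summaries with integer-rounded percentages, and the
  three-way H / PH / TS target-gene categorization driven by purified-
  fraction signal over total-sperm promoter peaks.
- **signal_profiles** — TSS-anchored RPM matrices (default 3 kb window, 50
  bp bins, strand-flipped so column 0 is always 5′-most), profile curves,
  and deterministic heatmap-matrix export.
- **integrative_epigenomics** — region-level methylation averaging over CG
  sites, Pearson cross-sample correlation, and stage-wise
  fraction-highly-expressed dynamics per gene category (strict FPKM
  threshold, condition stage configurable).
- **mixture_model** — the two-population contamination model
  `R = (1−f) + f·(h_un/h_c)`: forward evaluation, inversion with
  contamination share, bootstrap recovery from noisy replicates, and
  sensitivity to the assumed cell fraction.
- **synthetic_data** — constructive (not rejection-sampled) generator for
  genome, genes, repeats, CGIs with prescribed o/e, peaks with an exact
  planted promoter fraction, coverage tracks, methylation and expression
  tables, plus `mix_total_sperm` to synthesize a contaminated bulk sample.
- **pipeline** / **cli** — end-to-end orchestration from one YAML config
  with a hash-stable JSON run report.

## CLI

```sh
spermhist simulate --outdir data --seed 1            # synthetic dataset + truth.json
spermhist screen --chip chip.bedGraph --input input.bedGraph \
    --chip-total 1e6 --input-total 1e6 --fdr 0.01 --fc 5 -o peaks.bed
spermhist annotate --peaks peaks.bed --genes genes.tsv \
    --repeats repeats.bed --chrom-sizes sizes.tsv -o dist.tsv
spermhist cgi --cgis cgis.bed --fasta genome.fa \
    --peaks-total total.bed --peaks-hrcs hrcs.bed -o oe.json
spermhist categorize --genes genes.tsv --peaks-total total.bed \
    --peaks-hrcs hrcs.bed --cov hrcs.bedGraph --cov-total-reads 1e6 -o catalog.tsv
spermhist matrix --cov cov.bedGraph --cov-total-reads 1e6 \
    --anchors tss.tsv --window 3000 --bin 50 -o matrix.tsv
spermhist methyl --table meth.tsv --regions peaks.bed -o region_meth.tsv
spermhist dynamics --expression expr.tsv --catalog catalog.tsv -o dynamics.tsv
spermhist mixture --f 0.10 --ratio-total-vs-hrcs 5.0
spermhist run --config cfg.yaml                      # full pipeline
```

A minimal pipeline config:

```yaml
outdir: out
seed: 1
simulate: true
generator: {n_genes: 60, hrcs_peak_count: 40, total_peak_count: 60}
categorize: {k_background: 2.0}
```

## Conventions and notable defaults

- All coordinates 0-based half-open; overlap means ≥1 shared bp,
  strand-blind.
- Promoter = TSS ± 1 kb (configurable); upstream/downstream flanks extend
  5 kb beyond the promoter/TES and exclude higher-precedence classes.
- Peak-to-compartment assignment uses the peak midpoint by default
  (`any_overlap` mode available).
- Reported overlap percentages are rounded half-up to integers; raw
  fractions are always retained alongside.
- The PH/TS cutoff is `mean signal ≥ k × genome background` with k = 2 by
  default; a quantile rule is available.
- Methylation region values are unweighted means over CG sites with
  coverage ≥ `min_coverage` (default 1); all inputs must share one genome
  assembly — no liftover is performed.
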