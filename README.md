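# neutroflux

A tested, reusable implementation of a two-colour common-reference microarray
analysis of LPS-induced lung inflammation with and without neutrophil
depletion: four-step normalization, median fold-change differential
expression over three contrasts with Venn partitioning, hypergeometric
gene-set enrichment, and a per-sample expression-response score correlated
with genotoxicity/neutrophil phenotypes. Because no raw-data accession
exists for the original study, the package ships a first-class synthetic
data generator that emulates the study design (3 groups x 5 mice, pooled
sham Cy3 reference, large inter-animal heterogeneity, phenotypes coupled to
response magnitude) and is used to drive and validate every downstream
stage.

## Layout

- `src/neutroflux/io_formats.py` — TSV/GMT readers and writers with strict
  validation (spot tables, study design, gene sets, phenotypes, matrices).
- `src/neutroflux/synthetic.py` — simulation config, generative model, and
  phenotype simulator; ground truth returned alongside the data.
- `src/neutroflux/normalization.py` — ln transform, quantile normalization
  of all scans, reference-channel correction, gene-symbol collapse, PCA QC.
- `src/neutroflux/de.py` — group medians, fold changes for the three
  contrasts, threshold DE calling, 7-region Venn partition, overlap
  percentages, extreme genes, cross-contrast regression.
- `src/neutroflux/enrichment.py` — hypergeometric / EASE over-representation
  with Benjamini-Hochberg adjustment.
- `src/neutroflux/response.py` — RMS response scores, Spearman (exact
  permutation p for n <= 9) and Pearson correlations with phenotypes.
- `src/neutroflux/pipeline.py`, `cli.py` — end-to-end orchestration with a
  manifest (checksums, row counts) guaranteeing byte-identical reruns.

## CLI

```sh
neutroflux simulate --seed 0 --out-dir run/inputs
neutroflux normalize --spots run/inputs/spot_tables.tsv \
    --annotation run/inputs/annotation.tsv --design run/inputs/design.tsv \
    --out run/matrix.tsv --qc-report run/qc.tsv
neutroflux de --matrix run/matrix.tsv --design run/inputs/design.tsv \
    --out run/contrasts.tsv --venn run/venn.tsv
neutroflux enrich --list genes.txt --universe universe.txt --gmt sets.gmt \
    --method fisher --out run/enrichment.tsv
neutroflux score --matrix run/matrix.tsv --design run/inputs/design.tsv \
    --genes genes.txt --phenotypes run/inputs/phenotypes.tsv \
    --marker m1dg --out run/scores.tsv
neutroflux all --out-dir run --seed 0        # everything in one call
neutroflux report --run-dir run              # regenerate report.md
```

`neutroflux all` also accepts `--config run.yaml` with any
`PipelineConfig` field (threshold, strict, pool_channels, reference_mode,
enrichment_method, min_set, score_gene_list, marker, ...).

## Notes on interpretation

- Quantile normalization assumes all channels share one intensity
  distribution. The simulator optionally (default: on) emits unannotated
  "balancer" spots that make this hold exactly in the noise-free limit, so
  injected fold changes pass through the pipeline unchanged; they are
  dropped at the gene-collapse step and never reach DE calling.
- DE threshold is strict (> 1.5-fold) by default; `--no-strict` switches
  to >=.
- Step 3 of normalization subtracts each array's reference deviation from
  the across-array spot mean (`--reference-mode deviation`); the plain
  log-ratio is available via `--reference-mode ratio`.
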