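# oncochrom

Analysis pipeline for studying how an oncohistone (H3.3K27M-style) reshapes
the H3K27me3 landscape in a worm-like genome:

- **`track_io`** — bedGraph I/O and binned-signal processing: max-depth
  binning of fragment placements, equal-total scaling, input normalization
  (subtraction or log2 ratio), replicate merging, centered-mean smoothing,
  re-binning, and whole-genome coverage-uniformity reports.
- **`domain_calling`** — classification of every bin into four H3K27me3 fate
  categories (autosomal maintained / lost / never present, X maintained),
  with per-chromosome and per-category occupancy summaries.
- **`dependency_model`** — the concentration-dependency polynomial
  `Z = A0 + A1 * sum_{n=1..7} A_{n+1} (x - y)^n` linking pre-existing
  H3K27me3 (x) and oncohistone occupancy (y) to mutant H3K27me3 (z);
  evaluation with the packaged published coefficients, identifiable
  reduced-form least-squares fitting, and goodness-of-fit reporting.
- **`clustering`** — hierarchical clustering of 10 kb bins on the
  (wt K27me3, oncohistone, mut K27me3) triplet, autosomes and X separately
  (1 − Pearson distance, average linkage by default).
- **`expression`** — differential-expression filtering (FDR < 0.05,
  fold change > 2), expression quintiles, metagene profiles, per-gene
  ΔH3K27me3, change anti-correlation with permutation tests, quintile
  fractions of misregulated genes, and gene-set overlaps.
- **`ploidy`** — DNA-content estimation from DAPI integrated intensities via
  a linear calibration anchored at 4n oocytes and 32n intestine nuclei.
- **`synthetic_data`** — a fully seeded generator for every pipeline input
  (assembly, ChIP-like tracks, gene tables, DAPI intensities) with the
  statistical structure the analysis assumes.
- **`pipeline`** — end-to-end orchestration with a schema-validated JSON
  report.

## CLI

```sh
# generate a synthetic fixture set (bedGraphs + TSVs + manifest)
oncochrom synth --config cfg.yaml --out fixtures/ --seed 1

# full pipeline run -> JSON report
oncochrom run --config run.yaml --out report.json

# individual stages
oncochrom bin --fragments frags.tsv --assembly assembly.tsv --bin-size 1000 --out raw.bedgraph
oncochrom normalize --ip ip.bedgraph --input input.bedgraph --method logratio --assembly assembly.tsv --out norm.bedgraph
oncochrom smooth --track norm.bedgraph --assembly assembly.tsv --window 5 --out smoothed.bedgraph
oncochrom rebin --track t.bedgraph --assembly assembly.tsv --bin-size 1000 --new-bin-size 10000 --out coarse.bedgraph
oncochrom call-domains --wt wt.bedgraph --mut mut.bedgraph --assembly assembly.tsv --out domains.bed
oncochrom fit-model --x wt.bedgraph --y onco.bedgraph --z mut.bedgraph --assembly assembly.tsv --bin-size 1000
oncochrom eval-model --x wt.bedgraph --y onco.bedgraph --assembly assembly.tsv --out predicted.bedgraph
oncochrom cluster --wt wt.bedgraph --onco onco.bedgraph --mut mut.bedgraph --assembly assembly.tsv --k 6 --partition autosomes
oncochrom integrate --genes genes.tsv --wt wt.bedgraph --mut mut.bedgraph --assembly assembly.tsv
oncochrom ploidy --measurements dapi.tsv
oncochrom uniformity --sample s.bedgraph --reference r.bedgraph --assembly assembly.tsv
```

A run config is a YAML mapping with `synthetic` (generator parameters,
including `seed`), optional `stages` (subset of
`domains, clustering, fit, integration, ploidy`) and `params`
(thresholds, window sizes, cluster k, permutation count, ...). Identical
config + seed reproduces the report byte-for-byte. Exit codes: 0 ok,
2 configuration error, 3 stage error.

## Coordinates and formats

All coordinates are 0-based half-open (bedGraph convention); a chromosome of
length L at bin size b has `ceil(L / b)` bins and the trailing partial bin is
real. bedGraph files written by the package carry a `#state=` comment so the
normalization-state tag survives round trips, merge equal-value runs and omit
zero bins.
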