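# evoreserve

Lineage-aware systematic conservation planning on gridded landscapes, end
to end: intraspecific lineage delimitation on ultrametric trees,
presence–background distribution modelling, geostatistical interpolation
of lineage ranges from genetic distances, richness mapping, gap analysis
against a zoned protection plan, and target-based greedy reserve
prioritization.  Every stage can be exercised on synthetic data with
known ground truth — no downloads required.

## Modules

| module | what it does |
|---|---|
| `evoreserve.synth` | seeded generators: random-field landscapes, virtual species with Voronoi lineage domains, occurrence samples, mixed Yule/coalescent trees, genetic-distance matrices, zoning plans |
| `evoreserve.gmyc` | single-threshold mixed Yule/coalescent delimitation: exact log-likelihood, ML fit over candidate thresholds, likelihood-ratio test, Metropolis–Hastings sampler with tip-pair conspecificity, consensus clustering |
| `evoreserve.sdm` | regularized maximum-entropy models (linear+quadratic features), variable decorrelation (\|r\| ≤ 0.75), PCA-space thinning, replicate AUC evaluation, minimum-training-presence binarization, TSS, permutation variable contributions |
| `evoreserve.kriging` | empirical variograms of genetic vs geographic distance, WLS/manual model fitting, ordinary indicator kriging, 0.5-threshold lineage ranges intersected with species ranges |
| `evoreserve.richness` | species/lineage richness stacks (all / wide / restricted at the 30% rule), difference maps, 75th-percentile hotspots, Pearson correlations against landscape variables |
| `evoreserve.gap` | per-category representation accounting, log-linear representation targets (CR → 100%, DD → +30%), target achievement, Poisson-GLM inside/outside-PA comparison |
| `evoreserve.prioritize` | cost rasters (road/urban buffers, category costs 100/50/25/1), greedy edge-only cell removal with boundary-length penalty, minimal-set extraction, chi-square solution comparison |
| `evoreserve.pipeline` / `evoreserve.cli` | single-config orchestration of all stages with a YAML manifest |

## CLI

```bash
evoreserve run-all --out demo_run --seed 1      # full synthetic pipeline
evoreserve simulate --out demo_run --seed 1     # inputs only
evoreserve delimit trees.nwk --out lineages.csv # GMYC on your own trees
evoreserve table3-check                         # packaged worked-example arithmetic
```

A YAML config (`evoreserve run-all --config cfg.yaml`) exposes every
tunable (grid size, species/lineage counts, correlation/threshold
cutoffs, boundary-length penalty, warp, seeds); unknown keys are
rejected.  Outputs are plain text: ESRI ASCII grids, CSV, newick, and a
`manifest.yaml` recording the full configuration.

## Notes

- Rasters use a shared `Grid` (row 0 at the top, cell-centre
  coordinates, abstract map units); persistence is the text ESRI ASCII
  grid format.
- The maximum-entropy fit is a convex regularized log-linear density over
  background cells with linear+quadratic features only; suitability maps
  are the fitted density rescaled by its maximum.
- Kriging weights are shared across a species' lineage indicators, so
  per-cell lineage probabilities sum to 1 wherever the system solves.
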