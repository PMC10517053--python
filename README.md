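# planknet

Delineate plankton community types from an OTU co-occurrence network and
predict their distribution from satellite-derived features.

The pipeline:

1. **Preprocess** — rarefy read counts, average samples into 5′ monthly
   bins, keep open-ocean samples (seafloor ≥ 200 m), drop samples with
   missing satellite features, thin to ≥ 200 km spacing, filter OTUs by
   occurrence, centered log-ratio transform.
2. **Network** — infer a sparse network of direct positive associations
   between OTUs (partial-correlation conditional-independence screening),
   detect modules maximizing weighted modularity Q (Leiden, Louvain, greedy,
   label propagation), and select the best partition.
3. **Community typing** — compute the edge-satisfaction index per
   (sample, module) — the edge-weight-weighted mean of `min(p(u), p(v))`
   over a module's internal edges, with `p` the logistic transform of clr
   abundance — and label each sample with its top module.
4. **Classify** — train a multiclass classifier (linear SVM with Platt
   probability calibration, KNN, or Gaussian naive Bayes) on 17 satellite
   parameters, validated by leave-one-out and spatially buffered (2000 km)
   cross-validation with nested grid search, micro-average ROC-AUC,
   F1-optimal probability thresholding, and permutation importance.
5. **Spacetime** — apply the model to monthly feature grids (12×12
   center-cell downsampling), derive per-region community-type area series,
   and test long-term trends with the seasonal Mann-Kendall test and
   seasonal Theil-Sen slope.

A fully seeded synthetic-data module generates worlds with planted OTU
modules, a latitude-driven latent gradient, correlated satellite features
and spatially clustered sampling, plus gridded monthly series with known
injected trends — so every stage is testable end to end offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the oracle-based acceptance suite
(brute-force modularity agreement, worked edge-satisfaction examples,
planted-structure recovery, CV contracts, trend-statistic calibration).

## CLI

```sh
planknet run-all --out runs/demo --seed 7        # synthetic end-to-end demo
planknet simulate --out runs/sim --seed 3        # generate inputs only
planknet network --out runs/net --seed 7         # run up to module detection
planknet cv --out runs/cv --feature-set sst_chl  # CV on a feature subset
planknet validate --features-csv features.csv    # schema checks (exit 2 on error)
```

All stage parameters live in a flat YAML config (`--config run.yaml`;
unknown keys are rejected); CLI flags override config values. Every run
writes `config_resolved.yaml` and a `manifest.json` with input hashes and
the seed; reruns with the same config are byte-identical. Exit codes:
0 success, 2 validation failure, 3 stage failure.

To run on real data instead of the synthetic world, set `simulate: false`
and provide `otu_tsv` (OTUs × samples, tab-separated integer counts),
`meta_csv` (`sample_id, latitude, longitude, date, sampling_depth_m,
seafloor_depth_m, size_fraction`) and `features_csv` (`sample_id` plus the
17 parameter columns `rrs_412 … rrs_678, chl_a, kd_490, poc, pic, par,
nflh, sst`); gridded inputs are NetCDF with `time/lat/lon` dimensions and
the same variable names.

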