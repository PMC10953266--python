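# sgm — spectral graph model of regional neural oscillations

A linear, closed-form frequency-domain model of regional brain activity:
local excitatory–inhibitory circuits drive each region, and long-range
excitatory populations couple through a structural connectome via a
frequency-dependent complex Laplacian. The package covers the full
analysis loop on synthetic data with known ground truth:

- **`sgm.connectome`** — connectome validation/normalization, complex
  Laplacian `L(ω) = I − α·C*(ω)` and its eigendecomposition.
- **`sgm.model`** — Gamma ensemble response, local E–I transfer
  function, eigenmode-expansion network spectrum (with an equivalent
  batched direct solver), and a degree-6 pole stability test.
- **`sgm.fitting`** — per-subject inference by dual annealing over the
  sum of spectral (per-region Pearson r of dB spectra) and spatial
  (connectome-smoothed alpha-power map) correlations, with staged gain
  bounds for stability, plus a progressive parameter-importance refit.
- **`sgm.features`** — Welch PSD in dB, intrinsic timescale (lag where
  the region-mean autocorrelation decays to 1/e), and an
  aperiodic+Gaussian-peaks spectral parameterization with a two-peak
  summary.
- **`sgm.stats`** — age-adjusted group comparisons (LS-means,
  Bonferroni, Cohen's D) and cognition regressions.
- **`sgm.classify`** — random-forest group discrimination with repeated
  nested stratified cross-validation and averaged feature importances.
- **`sgm.synth`** — synthetic connectomes, per-group parameter draws,
  model-consistent spectra/time series, covariates and cognition scores.
- **`sgm.pipeline` / `sgm.cli`** — staged orchestration with checksum
  caching and run manifests.

## CLI

```bash
sgm run --out scratch/demo --seed 1           # simulate → fit → features → stats → classify
sgm simulate --config cfg.yaml --seed 1       # single stages also available
sgm report --out scratch/demo                 # print the run manifest
```

Configuration is YAML (see `sgm.pipeline.RunConfig`); re-running with an
unchanged config reuses cached stage outputs after verifying checksums.

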