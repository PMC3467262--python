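# retinaresp

Analysis toolkit for retinal response data: extracellular spike detection,
PSTH-based response parameterization and ganglion-cell classification,
stimulus-series analysis (spot size / intensity / flicker), flash-ERG
a-/b-wave metrics with flicker-fusion estimation, and optomotor contrast
sensitivity. A first-class synthetic-data module generates spike trains,
raw traces, and ERG waveforms with known ground truth so every stage is
validated by parameter recovery.

## What it computes

- **Spike detection** (`retinaresp.detect`): zero-phase 300–5,000 Hz
  band-pass, threshold crossing at 2.8 robust standard deviations of the
  broadband input, refractory merging, extremum alignment.
- **PSTH metrics** (`retinaresp.psth`): 1 ms trial-averaged histograms,
  25 ms Gaussian smoothing, baseline from the 100 ms pre-onset window, and
  the six response parameters — peak amplitude, latency, and decay-to-A/e
  duration for the windows after stimulus onset (A1, L1, A1τ2) and offset
  (A2, L2, A2τ2).
- **Classification** (`retinaresp.classify`): bias index
  `(A1−A2)/(A1+A2)` → ON / OFF / ON-OFF polarity, and the 200 ms duration
  boundary → transient / sustained kinetics for ON cells.
- **Series analysis** (`retinaresp.series`): per-level metrics, per-cell
  normalization, preferred stimulus, cycle-folded flicker amplitudes, and
  two-group repeated-measures (split-plot) ANOVA.
- **ERG metrics** (`retinaresp.erg`): a-wave trough and b-wave
  trough-to-peak amplitude/latency from flash-aligned traces;
  flicker-series amplitudes and fusion frequency against a 3σ noise
  criterion.
- **Optomotor** (`retinaresp.optomotor`): Michelson contrast, contrast
  sensitivity (reciprocal threshold), and contrast-sensitivity-function
  summaries with per-frequency group comparisons.
- **Synthetic data** (`retinaresp.synth`): inhomogeneous Poisson spike
  trains (thinning), biphasic-template raw traces, two-lobe ERG waveforms,
  and low-pass-attenuated flicker generators — all seeded and storing
  their ground truth.

## Command-line pipeline

```sh
retinaresp simulate --seed 1 --out results    # synthetic fixture
retinaresp psth     --seed 1 --out results    # PSTH response metrics
retinaresp classify --seed 1 --out results    # bias-index classification
retinaresp all      --seed 1 --out results    # every stage in order
```

Stages: `simulate | detect | psth | classify | series | erg | optomotor |
all`. Options come from a YAML config (`--config`); `--seed`/`--out`
override it. All outputs are tab-separated text or JSON, plus a per-stage
`report_<stage>.json` with the package version, config hash, and row
counts.

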