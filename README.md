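# eegbattery

A tested, reusable pipeline for resting-state EEG group-difference analysis
on synthetic cohorts:

1. **Synthetic cohort generation** — demographics tables (age in months,
   sex, IQ, diagnosis ∈ {AD, ASD, CON}) and epoched multichannel EEG with a
   1/f background, band-limited oscillations whose amplitudes depend on
   covariates with configurable effect sizes, optional phase-amplitude
   coupling and inter-channel phase coupling. A fast feature-level
   simulator injects standardized effects directly into the 726-variable
   battery for cohort-scale statistical experiments.
2. **Signal features** — six per-channel metric families: narrowband power
   spectra (Gaussian frequency-domain convolution, 100 log-spaced
   frequencies 2–80 Hz), aperiodic 1/f exponent/offset, peak alpha
   frequency (6–14 Hz), Tort modulation index PAC, multiscale sample
   entropy, and inter-site phase clustering on spherical-spline
   surface-Laplacian data.
3. **Variable registry** — the canonical 726-variable battery
   (324 power + 36 slope + 36 peak-alpha + 216 PAC + 72 MSE + 42 ISPC)
   over 18 channel groupings (13 regional means + 5 asymmetry contrasts;
   ISPC uses 7 channel-pair contrasts), with per-channel metrics averaged
   into one feature row per participant.
4. **Group statistics** — per variable and age tertile: robust-z outlier
   removal, a likelihood-ratio test for a quadratic age term, four OLS
   models (main effects; +diagnosis×sex; +diagnosis×age; full
   age×sex×diagnosis factorial + IQ) with sum-to-zero contrasts, and
   type-III partial η² for the designated terms — 8712 model fits over the
   full registry. GVIF multicollinearity diagnostics included.
5. **Replication** — stratified split-half replication rates (150 seeded
   splits by default; an effect replicates when η² > 0.035 in both
   halves), with selection at a replication rate ≥ 0.64 (the square of the
   0.80 power convention).
6. **Sample-size analysis** — repeated stratified subsampling at several
   fractions, per-term supra-threshold proportions, pairwise NMI of
   supra-threshold patterns, and a greedy demographically matched
   case-control subset (same sex, |Δage| ≤ 5 months, |ΔIQ| ≤ 10 points).

## CLI

All stages run through one entry point with a YAML config (every field has
a default; see `eegbattery.pipeline.DEFAULT_CONFIG`):

```sh
eegbattery simulate   --out runs/demo --seed 1 --subset 60
eegbattery stats      --out runs/demo --seed 1 --subset 60
eegbattery replicate  --out runs/demo --seed 1 --subset 60 --splits 150
eegbattery samplesize --out runs/demo --seed 1 --subset 60 --fractions 0.3,0.5,0.7 --reps 10
eegbattery matchsample --demographics runs/demo/demographics.csv --out pairs.csv
eegbattery report     --out runs/demo
eegbattery run-all    --config config.yaml --out runs/full --seed 1
```

Outputs are CSV tables plus PNG report figures under the run directory;
a `manifest.json` records config hash and per-stage row counts, and
re-running an unchanged config skips completed stages. Exit codes:
0 ok, 1 config error, 2 stage failure.

Example config:

```yaml
seed: 1
cohort:
  n_per_stratum: {AD: [50, 50, 50], ASD: [50, 50, 50], CON: [200, 200, 200]}
  female_fraction: 0.4
effects:
  - {family: power, qualifier: delta, age_beta: -0.5}
registry_subset: 60        # null = full 726-variable battery
stages: {simulate: true, stats: true, replicate: true, samplesize: true}
replication: {n_splits: 150, max_effects: 50}
samplesize: {fractions: [0.2, 0.45, 0.7], reps: 10}
```

## Layout

```
src/eegbattery/
  layout.py       channel montage, regional groups, asymmetry/ISPC contrasts
  cohort.py       demographics + EEG + feature-level simulation
  features.py     power / 1-f fit / PAF / PAC / MSE / Laplacian / ISPC
  registry.py     726-variable registry and per-participant aggregation
  stats.py        outliers, age-tertiles, LRT, M1-M4, type-III partial η², GVIF
  replication.py  stratified split-halves and replication rates
  samplesize.py   subsampling curves, NMI, matched sampling
  pipeline.py     staged, resumable orchestration + report
  cli.py          click entry points
tests/            pytest suite (unit, property, acceptance); oracles.py holds
                  independent brute-force reference implementations
scripts/acceptance.py
```
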