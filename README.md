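# circalipid

Circadian light-exposure rhythmometry and blood-lipid association analysis
for wearable light-logger cohorts — built for the question of whether the
*timing* and *dynamic range* of light exposure, rather than photoperiod
duration, predict fasting lipid profiles in people living through extreme
seasonal light regimes (Arctic winter/summer solstices and the equinox).

The package is aimed at chronobiologists and biostatisticians working with
per-minute light/actigraphy recordings, salivary melatonin profiles and
clinical lipid panels. Because such field data are rarely public, it ships
a first-class seeded synthetic-cohort generator with the statistical
structure the analysis assumes, so the whole pipeline is testable and
reproducible end to end.

## What it computes

* **Cosinor rhythmometry** — for a light series Y(t) the single-component
  model Y(t) = M + A·cos(2π(t − φ)/24) fitted by least squares: MESOR *M*,
  amplitude *A*, acrophase φ (clock time of the peak) and the
  zero-amplitude F test on (2, n − 3) df.
* **Non-parametric actigraphy endpoints** — M10 and L5 (means of the
  most-exposed 10 h and least-exposed 5 h cyclic windows of the composite
  day) with their onsets, RA = (M10 − L5)/(M10 + L5), and the circadian
  light hygiene index NA = A/M (normalized amplitude of blue-light
  exposure).
* **Melatonin profiling** — 2-SD consecutive-difference QC of 21-sample
  salivary profiles and acrophase estimation from irregular 24 h sampling.
* **Association battery** — Pearson correlations, photoperiod-adjusted
  regressions (photoperiod coded 1/12/23 h for the three seasons), and
  fully adjusted ANCOVA (photoperiod + age + sex + indigeneity) reporting
  standardized β and Type III partial η², with Benjamini–Hochberg FDR
  control at q = 0.1 and VIF screening.
* **Correlation rhythmometry** — Pearson r between a morning lipid and
  blue-light exposure in each of 48 consecutive 30-min clock epochs, a BH
  significance mask, and a 24 h cosinor fitted to the r(t) curve whose
  acrophase localizes *when* in the day the lipid–light association peaks.

See `docs/methods.md` for the models, generator design and limitations.

## Worked example

```python
from circalipid import (default_profiles, generate_light_series, fit_cosinor,
                        nonparametric_metrics, generate_cohort, cohort_frame,
                        fully_adjusted_model)

profile = default_profiles()["SE"]          # spring equinox
series = generate_light_series(profile, subject_draw_seed=42)
est = fit_cosinor(series)
npar = nonparametric_metrics(series, est)
print(f"MESOR     {est.mesor:7.2f} uW/cm2")
print(f"amplitude {est.amplitude:7.2f} uW/cm2")
print(f"acrophase {est.acrophase_h:7.2f} h")
print(f"M10 {npar.m10:7.2f} at {npar.m10_onset_h:.2f} h, "
      f"L5 {npar.l5:7.3f} at {npar.l5_onset_h:.2f} h")
print(f"RA  {npar.ra:.3f}   NA {npar.na:.3f}")

cohort = cohort_frame(generate_cohort(27, seed=1))
row = fully_adjusted_model(cohort, "tg_hdl", "ble_na")
print(f"NA BLE -> TG/HDL (n={row.n}): beta = {row.estimate:+.3f}, "
      f"partial eta2 = {row.variance_explained:.3f}, p = {row.p:.4f}")
```

prints

```
MESOR       11.02 uW/cm2
amplitude   14.03 uW/cm2
acrophase   13.60 h
M10   22.28 at 8.83 h, L5   0.094 at 22.40 h
RA  0.992   NA 1.273
NA BLE -> TG/HDL (n=81): beta = -0.244, partial eta2 = 0.071, p = 0.0192
```

The first block is one simulated spring-equinox subject: blue-light MESOR
≈ 11 μW/cm², a 14 μW/cm² 24 h amplitude peaking at 13:36, bright daytime
exposure (M10) starting 08:50, very low light at night (L5), and a healthy
dynamic range (NA ≈ 1.27). The last line is the headline association on a
27-subject × 3-season synthetic cohort: a larger normalized amplitude of
blue-light exposure predicts a lower TG/HDL ratio (negative standardized
β), the structure the generator plants by default.

## Command-line interface

```sh
circalipid run --out-dir out --seed 1            # full pipeline
circalipid simulate --n-subjects 27 --seed 1 --out-dir out
circalipid metrics --light-dir out/light --out out/metrics.tsv
circalipid melatonin --melatonin-tsv out/melatonin.tsv --out-dir out
circalipid associate --dir out
circalipid rhythm --dir out --outcomes hdl,tg
```

`run` chains simulate → metrics → melatonin → associate → rhythm through
the on-disk text formats (per-minute light CSVs, TSV tables) and writes a
`manifest.json` with the config hash and SHA-256 of every table; re-running
with the same config and seed reproduces all tables byte-identically.
Configuration (season profiles, planted effects, FDR level, BH family,
metric options) can be supplied as YAML or TOML via `--config`.

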