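# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `circalipid`.

## Cosinor rhythmometry

Light series and melatonin profiles are modelled with the single-component
cosinor

Y(t) = M + A·cos(2π(t − φ)/τ) + e(t),  τ = 24 h,

fitted by linear least squares on cosine/sine regressors: MESOR *M* (the
rhythm-adjusted mean), amplitude *A* ≥ 0 (half the peak-to-trough range) and
acrophase φ (local clock time of the fitted peak, reported in hours rather
than negative degrees). The zero-amplitude test is the standard F statistic
of the two harmonic coefficients on (2, n − 3) degrees of freedom. The
acrophase is flagged undefined when A < 10⁻⁹·max(|M|, 1); a series whose
total sum of squares is at rounding level is treated as constant (F = 0,
p = 1). The cosinor is fitted on the full per-minute record, not the
composite day, following standard single-cosinor practice. Light is fitted
in raw units by default (the calibration targets are raw-unit means);
log10(x+1) preprocessing is available behind the `log_light` config flag.

## Non-parametric metrics

M10 and L5 are the means of the most-exposed 600-minute and least-exposed
300-minute windows; RA = (M10 − L5)/(M10 + L5) and NA = A/M (the
normalized amplitude of blue-light exposure, the circadian light hygiene
index). Windows are scanned at 1-minute resolution over all 1440 cyclic
starts of the *composite day* (per-clock-minute mean across days), with
ties broken toward the earliest clock onset. The composite basis was chosen
for robustness on 7-day records; a `per_day` option computes windows per
retained day and averages levels (arithmetically) and onsets (circularly).
Missingness policy: minutes missing in ≤ 20 % of a day are ignored in the
averaging, days with more are dropped, and fewer than 3 valid days is an
error (the threshold is a parameter; the epoch-matrix builder for
correlation rhythmometry accepts single-day records).

## Melatonin quality control and acrophase

QC removes non-finite and negative concentrations, then applies the 2-SD
jump rule: the SD of all consecutive differences is computed once from the
raw profile, and each sample is flagged when its step from the previously
*accepted* sample exceeds twice that SD. The pass is single and
deterministic — the SD is not re-estimated after removals — and QC is
defined on raw profiles, so re-filtering an audited profile is a no-op
(this is what makes the operation idempotent). A profile with fewer than 4
surviving samples, or a surviving time span of ≤ 12 h, is unusable (a 24 h
cosinor on a shorter span is aliased). Acrophase estimation reuses the
cosinor solver on the irregular sample times; concentrations are fitted
untransformed.

A caveat worth knowing: for a smooth high-SNR sinusoid sampled with
heterogeneous gaps, the largest legitimate between-sample step sits at
roughly 1.8–2.0 SD of the steps, so the 2-SD gate is knife-edged and a
single flag can cascade along a monotone rise (each subsequent sample is
compared against an increasingly stale accepted predecessor). The
generator's default schedule keeps daytime gaps ≤ 1.5 h partly for this
reason.

## Association models

All subject-season rows are pooled and treated as independent — a
deliberate simplification matching "overall data" regression reporting; no
subject random effect is fitted. Three tiers:

* **simple** — Pearson r per (predictor, outcome) pair;
* **photoperiod-adjusted** — OLS of the z-scored outcome on the z-scored
  predictor plus photoperiod duration, coded 1/12/23 h for winter solstice,
  spring equinox and summer solstice;
* **fully adjusted** — ANCOVA-style OLS adding age, sex (female = 0,
  male = 1) and indigeneity (N = 0, NN = 1); binaries are z-scored too so
  standardized betas are comparable across predictors. The predictor's
  partial η² uses Type III (marginal) sums of squares,
  η² = SS_pred/(SS_pred + SS_res), computed via the t-statistic identity
  t²/(t² + df_res) — identical to the reduced-vs-full RSS difference since
  each predictor enters once (verified to 10⁻¹⁰ against that oracle).

Circular predictors (acrophases, window onsets, melatonin acrophase) are
linearized before any linear model by unwrapping onto a ±12 h band around
their circular mean, so onsets straddling midnight stay adjacent. TG/HDL is
always recomputed from the TG and HDL columns, never stored. Multiplicity
is controlled with the classic Benjamini–Hochberg step-up rule at q = 0.1,
applied across the whole predictor × outcome family by default
(`per_outcome` option available). Variance inflation factors
(1/(1 − R²ⱼ) from auxiliary regressions with intercept) are screened per
model; values above the ceiling (default 10) attach a warning to the row.
Melatonin models run on the complete-case subset; the other models use the
full cohort. Seasonal comparisons route on normality: Shapiro–Wilk
(decisive) and Kolmogorov–Smirnov are reported per group, and the
parametric branch (t test / one-way ANOVA) is taken only when every group
passes Shapiro at α = 0.05, otherwise Mann–Whitney U / Kruskal–Wallis.

## Correlation rhythmometry

For each lipid, Pearson r against mean blue-light exposure in each of 48
consecutive 30-minute clock epochs of the composite day, a BH mask at
q = 0.1 over the 48-epoch family (per lipid, not pooled), and a 24 h
cosinor fitted to the (epoch centre, r) points — epoch centres, not starts,
are the time coordinate. Zero-variance epochs are dropped from both the BH
family and the fit. The cosinor is fitted to raw r values (a Fisher-z
option exists but is off by default).

**Limitation (measured, not hypothetical).** The zero-amplitude F statistic
on the r(t) curve is correctly size-calibrated when the 48 r-values carry
independent noise (rejection rate 0.04–0.05 at α = 0.05 in simulation).
With realistic exposure matrices it is strongly anticonservative: epoch
columns share subject-level brightness and light-at-night factors, so under
lipid–light independence the r(t) curve is a smooth day/night-structured
random function rather than white noise, and the F test rejects at ≈ 0.85
instead of 0.05 — whether seasons are pooled or analysed separately. The F
statistic should therefore be read as a descriptive measure of
rhythmicity of the correlation curve, not as a calibrated test against
chance.

## Synthetic cohort generator

The generator exists so every stage is testable without the (non-public)
field data. It emulates a high-latitude design: the same subjects recorded
7 days per season (winter solstice WS, spring equinox SE, summer solstice
SS), 75 % women, 19/27 non-native, 13/27 with melatonin profiles; ages are
drawn N(38, 11) clipped to 18–59 and MEQ scores N(51.6, 5.1) (stored,
never modelled).

**Light.** A subject-season day is a trapezoidal daytime plateau
(half-cosine ramps, default 1 h; per-day centre jitter, SD 0.25 h) on a
shallow nocturnal baseline, with multiplicative log-normal per-minute noise
(σ = 0.5 on the log scale, mean-one). Subject-season targets are drawn from
season profiles calibrated to published seasonal means: MESOR and LAN level
as moment-matched log-normals (light is positive and right-skewed, with
between-subject SDs of the order of the means), NA as a truncated normal,
amplitude as NA × MESOR (amplitude and MESOR are strongly coupled within
subjects), acrophase and L5 onset as wrapped normals. The plateau height
and width are then solved in closed form from the first Fourier harmonic of
the trapezoid so that the *fitted* cosinor of the generated series matches
the drawn targets; the day-jitter attenuation of the fitted amplitude,
exp(−(ωσ)²/2), is compensated. The effective daytime window solves to
10–13 h in every season — deliberately decoupled from the astronomical
photoperiod, which indoor lighting overrides; photoperiod enters the
analysis only as the 1/12/23 h covariate. The nocturnal baseline carries a
shallow cosine trough (depth 0.1, normalized so the least-5-h-window mean
equals the drawn LAN level) centred 2.5 h after the drawn L5 onset, so L5
onsets are meaningful rather than tie-broken. White lux is a fixed multiple
(6.5) of blue irradiance; only the blue channel carries headline metrics,
and in synthetic data the two channels' metrics are therefore perfectly
correlated. Activity counts are Poisson, day-modulated, and purely
decorative. Subjects carry persistent latent offsets for acrophase
(SD 0.3 h) and NA (SD 0.05) across seasons, absorbed into the season SDs in
quadrature so the between-subject calibration is unchanged.

The generator calibrates {MESOR, amplitude, acrophase, NA, L5 level} per
season; M10, the onsets and RA are *emergent* from the waveform geometry
(the trapezoid has fewer shape parameters than the published table has
rows). Cohort means of the calibrated metrics reproduce their targets
within 3 standard errors at n = 200.

**Melatonin.** 21 samples over 24 h, densest between 21:00 and 08:00
(13/21 ≈ 62 % in that window; daytime gaps ≤ 1.5 h; ±5 min schedule
jitter), concentrations cosine-shaped (default MESOR 10, amplitude
8 pg/mL) plus additive Gaussian assay noise (default 2.0 pg/mL, a typical
ELISA error at these concentrations), floored at 0. About 5 % of noisy
profiles lose their usable span to QC cascades and are treated as
attrition, mirroring the melatonin subsample of the emulated design.

**Lipids.** Latent z-scored outcomes are linear in z-scored predictors
(metrics computed from the subject's own generated series, plus
demographics), with Gaussian residual SD √(1 − Σβ²) so each latent outcome
has unit variance (planted predictors are chosen mutually near-orthogonal);
raw panels rescale to adult reference marginals (TC 5.2 ± 1.0, LDL
3.0 ± 0.9, HDL 1.4 ± 0.35, TG 1.3 ± 0.6 mmol/L, TG/HDL 1.0 ± 0.45 —
invented defaults, as the emulated cohort's lipid summaries are not
published) and are floored at 2 % of the mean. When TG/HDL carries planted
effects the ratio is generated and TG derived as ratio × HDL, so the
recomputed ratio reproduces the planted structure exactly; planting both TG
and the ratio is rejected. Default planted effects are the published
fully-adjusted standardized betas (L5→TC 0.290, acrophase→HDL −0.257,
male→HDL −0.412, NA→TG/HDL −0.390, plus age→TC and the ratio's demographic
terms).

**Time-structured effects.** For correlation-rhythmometry recovery the
planted truth is the population correlation curve itself: a half-rectified
cosine peaking at the nominal clock time, realized by ridge-whitened
loadings on the column-standardized epoch matrix (ridge 0.05) with a
fixed-point shift so the curve's own cosinor acrophase lands exactly on the
nominal peak. A naive cosine-weighted exposure sum does *not* work — the
epoch correlation matrix smears its correlation peak toward midday by more
than an hour. Default planted strength gives maximum |r| ≈ 0.45.

## Problem sizes used in tests

Parameter recovery uses 100 replicate cohorts of 501 subject-season rows
(167 subjects × 3 seasons); rhythm recovery uses 5 replicates of 201 rows
with the acrophase compared as a circular mean over replicates (the
single-replicate acrophase SD is ≈ 25–30 min); calibration uses 200 series
per season; BH null control uses 500 replicate 14-test families. The
acceptance script reruns the same computations at 30 replicates for the
betas.

## Numerical choices

TSV outputs carry floats at 6 significant digits in fixed column order;
timestamps are naive local ISO-8601 (the emulated site observes no daylight
saving time). All randomness flows from `numpy.random.default_rng` seeded
through `SeedSequence`, and identical configurations reproduce every output
table byte-identically. Window ties break to the earliest onset; circular
means with vanishing resultant (< 10⁻⁹) are reported undefined; BH accepts
p = 0 as underflow of a tiny p-value.

## Known limitations

* Pooled rows ignore within-subject correlation across seasons; standard
  errors of the association models are accordingly optimistic.
* The zero-amplitude F test on correlation curves is anticonservative under
  realistic exposure correlation (see above).
* The generator's light waveform is a single daily trapezoid: no weekend
  effects, weather, naps or discrete light-at-night episodes (the nocturnal
  baseline is continuous), and the white channel is exactly proportional to
  blue. Passing tests therefore demonstrate correctness of the estimators
  and the statistical machinery under the stated generative model, not
  robustness to every feature of field actigraphy.
* Lipid marginals are generic adult values; only the *standardized*
  structure is calibrated to published effects.
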