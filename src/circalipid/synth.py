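"""Seeded synthetic cohorts: light recordings, melatonin profiles, lipids.

The generator emulates a high-latitude field design: the same subjects
recorded for seven days around the winter solstice (WS), spring equinox (SE)
and summer solstice (SS), with a morning fasting lipid panel per season.

**Light model.**  Each subject-season blue-irradiance day is a trapezoidal
daytime plateau (half-cosine ramp edges, per-day center jitter) on top of a
shallow nocturnal baseline (light at night, LAN), with per-minute
multiplicative log-normal noise.  The plateau height and width are solved in
closed form from the subject's drawn target MESOR and amplitude via the
trapezoid's first Fourier harmonic, so the *fitted* cosinor of the generated
series matches the drawn targets; season-level target distributions are
calibrated to published seasonal actigraphy means (e.g. WS blue MESOR
2.64 +/- 1.61 uW/cm2, SE normalized amplitude 1.43 +/- 0.16).  The daytime
window width is deliberately *not* the astronomical photoperiod: indoor
lighting keeps the effective exposure window at 10-13 h in all seasons, and
photoperiod enters the analysis only as the 1/12/23 h covariate code.

**Lipid model.**  Standardized outcomes are linear in z-scored predictors
(light metrics computed from the subject's own generated series, plus
age/sex/indigeneity), with Gaussian residuals scaled so each outcome has
unit latent variance; raw panels are rescaled to configurable adult
reference means/SDs (invented defaults - the source cohort's lipid
marginals are not published).  When the TG/HDL ratio carries planted
effects, the ratio is generated and TG is derived as ratio x HDL so the
downstream recomputed ratio reproduces the planted structure exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from . import melatonin as mel
from .assoc import (CIRCULAR_COLUMNS, ParticipantSeason, linearize_circular,
                    zscore)
from .errors import (CircalipidError, InsufficientDataError, ValidationError)
from .metrics import (EpochSeries, MINUTES_PER_DAY, composite_day,
                      fit_cosinor, nonparametric_metrics)

#: nominal recording start dates (no-DST site; naive local clock)
SEASON_DATES = {
    "WS": datetime(2023, 12, 18),
    "SE": datetime(2024, 3, 18),
    "SS": datetime(2024, 6, 17),
}


# ---------------------------------------------------------------------------
# season profiles
# ---------------------------------------------------------------------------

@dataclass
class SeasonProfile:
    """Target distributions for one season's blue-light exposure metrics.

    Means/SDs describe the between-subject distribution of *fitted* metrics
    the generated cohort should reproduce.  ``lan_level`` is the nocturnal
    baseline (operationalized as L5 of blue irradiance), ``lan_onset`` the
    clock time at which the least-exposed window should start.
    """

    season_label: str
    photoperiod_h: int
    mesor_mean: float
    mesor_sd: float
    amplitude_mean: float
    amplitude_sd: float
    acrophase_mean_h: float
    acrophase_sd_h: float
    lan_level_mean: float
    lan_level_sd: float
    lan_onset_mean_h: float
    lan_onset_sd_h: float
    na_mean: Optional[float] = None     # default amplitude_mean / mesor_mean
    na_sd: float = 0.0
    noise_sigma: float = 0.5            # log-scale SD of per-minute noise
    edge_ramp_h: float = 1.0
    day_jitter_sd_h: float = 0.25
    night_dip: float = 0.1              # fractional depth of the LAN trough
    lux_factor: float = 6.5             # white lux per unit blue irradiance

    def __post_init__(self) -> None:
        if self.season_label not in SEASON_DATES:
            raise ValidationError(f"invalid season label {self.season_label!r}")
        if self.photoperiod_h not in (1, 12, 23):
            raise ValidationError(
                "photoperiod incompatible with the 1/12/23 h coding of a 24 h day")
        for name in ("mesor_sd", "amplitude_sd", "acrophase_sd_h",
                     "lan_level_sd", "lan_onset_sd_h", "na_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.acrophase_mean_h < 24:
            raise ValidationError("acrophase mean must lie in [0, 24)")
        if self.na_mean is None:
            self.na_mean = (self.amplitude_mean / self.mesor_mean
                            if self.mesor_mean > 0 else 0.0)


def default_profiles() -> dict[str, SeasonProfile]:
    """Season profiles calibrated to published seasonal blue-light means."""
    return {
        "WS": SeasonProfile(
            "WS", 1, mesor_mean=2.64, mesor_sd=1.61,
            amplitude_mean=2.93, amplitude_sd=1.74,
            acrophase_mean_h=14.2, acrophase_sd_h=1.2,
            lan_level_mean=0.128, lan_level_sd=0.213,
            lan_onset_mean_h=2.067, lan_onset_sd_h=1.517,
            na_mean=1.12, na_sd=0.20),
        "SE": SeasonProfile(
            "SE", 12, mesor_mean=11.11, mesor_sd=7.55,
            amplitude_mean=16.12, amplitude_sd=11.19,
            acrophase_mean_h=12.867, acrophase_sd_h=0.95,
            lan_level_mean=0.077, lan_level_sd=0.019,
            lan_onset_mean_h=1.333, lan_onset_sd_h=1.817,
            na_mean=1.43, na_sd=0.16),
        "SS": SeasonProfile(
            "SS", 23, mesor_mean=36.66, mesor_sd=43.81,
            amplitude_mean=49.91, amplitude_sd=65.04,
            acrophase_mean_h=14.1, acrophase_sd_h=1.55,
            lan_level_mean=0.816, lan_level_sd=2.871,
            lan_onset_mean_h=1.7, lan_onset_sd_h=1.317,
            na_mean=1.25, na_sd=0.29),
    }


# ---------------------------------------------------------------------------
# light series generation
# ---------------------------------------------------------------------------

@dataclass
class LightRecording:
    blue: EpochSeries
    white: EpochSeries
    activity: np.ndarray
    truth: dict                       # drawn subject-season parameters


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched log-normal draw (exact mean/SD); degenerate when sd=0."""
    if mean <= 0:
        return 0.0
    if sd == 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _solve_plateau(mesor: float, amplitude: float, baseline_mean: float,
                   ramp_h: float, jitter_sd_h: float) -> tuple[float, float]:
    """Height H and effective width W of the daytime trapezoid.

    First harmonic of a trapezoid of plateau width w = W - r with half-cosine
    ramps of length r: A = (2 H / pi) * sin(pi W / 24) * K(r) with the Hann
    smoothing factor K(r) = sinc(pi r / 24) / (1 - (r/24)^2); the mean is
    b + H W / 24.  Day-to-day Gaussian center jitter attenuates the fitted
    amplitude by exp(-(omega * sd)^2 / 2), compensated here.
    """
    omega = 2.0 * np.pi / 24.0
    level = mesor - baseline_mean
    if level <= 0:
        return 0.0, 24.0
    x_r = np.pi * ramp_h / 24.0
    k_ramp = (np.sinc(x_r / np.pi)) / (1.0 - (ramp_h / 24.0) ** 2)
    a_target = amplitude / math.exp(-((omega * jitter_sd_h) ** 2) / 2.0)
    ratio = a_target / level
    w_min = max(ramp_h, 0.25)
    if ratio <= 1e-12:
        return level, 24.0                      # flat day at the MESOR
    g = lambda x: 2.0 * k_ramp * np.sin(x) / x - ratio
    x_lo, x_hi = np.pi * w_min / 24.0, np.pi * 23.99 / 24.0
    if g(x_lo) <= 0:                            # ratio unattainable: narrow
        width = w_min                           # window, amplitude shortfall
    elif g(x_hi) >= 0:
        width = 23.99
    else:
        width = brentq(g, x_lo, x_hi) * 24.0 / np.pi
    return level * 24.0 / width, width


def _draw_subject_season(profile: SeasonProfile, rng: np.random.Generator,
                         offsets: Optional[dict] = None) -> dict:
    """Subject-season target metrics from the season's distributions."""
    offsets = offsets or {}
    acro_off = offsets.get("acrophase_h", 0.0)
    na_off = offsets.get("na", 0.0)
    subj_acro_sd = offsets.get("acro_sd", 0.0)
    subj_na_sd = offsets.get("na_sd", 0.0)
    # persistent subject offsets absorb part of the between-subject SD
    acro_sd = math.sqrt(max(profile.acrophase_sd_h ** 2 - subj_acro_sd ** 2, 0.0))
    na_sd = math.sqrt(max(profile.na_sd ** 2 - subj_na_sd ** 2, 0.0))

    mesor = _lognormal(rng, profile.mesor_mean, profile.mesor_sd)
    na = max(float(rng.normal(profile.na_mean + na_off, na_sd))
             if na_sd > 0 else profile.na_mean + na_off, 0.0)
    acrophase = float(rng.normal(profile.acrophase_mean_h + acro_off,
                                 acro_sd)) % 24.0 if acro_sd > 0 else \
        (profile.acrophase_mean_h + acro_off) % 24.0
    lan = _lognormal(rng, profile.lan_level_mean, profile.lan_level_sd)
    lan_onset = (float(rng.normal(profile.lan_onset_mean_h,
                                  profile.lan_onset_sd_h)) % 24.0
                 if profile.lan_onset_sd_h > 0 else profile.lan_onset_mean_h)
    return {"mesor": mesor, "na": na, "amplitude": na * mesor,
            "acrophase_h": acrophase, "lan_level": lan,
            "lan_onset_h": lan_onset}


def _night_shape(lan_onset_h: float, dip: float) -> np.ndarray:
    """Normalized nocturnal baseline with its least-5h-window mean = 1.

    A shallow cosine trough centered 2.5 h after ``lan_onset_h`` makes the
    L5 window start near the configured onset instead of being tie-broken.
    """
    t = np.arange(MINUTES_PER_DAY) / 60.0
    trough = lan_onset_h + 2.5
    shape = 1.0 - dip * np.cos(2.0 * np.pi * (t - trough) / 24.0)
    # closed-form mean of the cosine over the centered 5 h window
    x5 = np.pi * 5.0 / 24.0
    l5_mean = 1.0 - dip * np.sin(x5) / x5
    return shape / l5_mean


def _plateau_day(acro_h: float, height: float, width: float,
                 ramp_h: float) -> np.ndarray:
    t = np.arange(MINUTES_PER_DAY) / 60.0
    delta = np.abs(((t - acro_h + 12.0) % 24.0) - 12.0)
    w = max(width - ramp_h, 0.0)
    day = np.zeros(MINUTES_PER_DAY)
    core = delta <= w / 2.0
    day[core] = height
    if ramp_h > 0:
        edge = (~core) & (delta <= w / 2.0 + ramp_h)
        day[edge] = height * 0.5 * (
            1.0 + np.cos(np.pi * (delta[edge] - w / 2.0) / ramp_h))
    return day


def generate_light_recording(
    profile: SeasonProfile,
    subject_draw_seed: int,
    n_days: int = 7,
    offsets: Optional[dict] = None,
) -> LightRecording:
    """One subject-season recording: blue + white series and activity counts.

    Deterministic for a fixed (profile, seed); the ``truth`` dict carries the
    drawn target metrics for diagnostics and tests.
    """
    if subject_draw_seed < 0:
        raise ValidationError("seed must be non-negative")
    rng = np.random.default_rng(subject_draw_seed)
    draw = _draw_subject_season(profile, rng, offsets)

    night = _night_shape(draw["lan_onset_h"], profile.night_dip) * draw["lan_level"]
    height, width = _solve_plateau(
        draw["mesor"], draw["amplitude"], float(night.mean()),
        profile.edge_ramp_h, profile.day_jitter_sd_h)

    days = []
    for _ in range(n_days):
        jitter = (rng.normal(0.0, profile.day_jitter_sd_h)
                  if profile.day_jitter_sd_h > 0 else 0.0)
        if width >= 23.98:      # flat day: plateau covers the full circle
            day = np.full(MINUTES_PER_DAY, height)
        else:
            day = _plateau_day(draw["acrophase_h"] + jitter, height, width,
                               profile.edge_ramp_h)
        days.append(day + night)
    blue = np.concatenate(days)
    if profile.noise_sigma > 0:
        s = profile.noise_sigma
        blue = blue * np.exp(rng.normal(-s * s / 2.0, s, blue.size))

    start = SEASON_DATES[profile.season_label]
    blue_series = EpochSeries(start, blue, channel="blue_irradiance")
    white_series = EpochSeries(start, blue * profile.lux_factor,
                               channel="white_lux")
    day_frac = np.tile(
        _plateau_day(draw["acrophase_h"], 1.0, min(width, 23.98),
                     profile.edge_ramp_h) if width < 23.98
        else np.ones(MINUTES_PER_DAY), n_days)
    activity = rng.poisson(5.0 + 45.0 * day_frac).astype(float)
    truth = dict(draw, plateau_height=height, plateau_width_h=width)
    return LightRecording(blue_series, white_series, activity, truth)


def generate_light_series(
    profile: SeasonProfile, subject_draw_seed: int, n_days: int = 7,
) -> EpochSeries:
    """Blue-channel per-minute series for one subject-season."""
    return generate_light_recording(profile, subject_draw_seed, n_days).blue


# ---------------------------------------------------------------------------
# melatonin profile generation
# ---------------------------------------------------------------------------

def melatonin_schedule(n_samples: int = 21,
                       rng: Optional[np.random.Generator] = None,
                       jitter_min: float = 5.0) -> np.ndarray:
    """Sampling clock times (hours, monotonically increasing past 24).

    Densest in the 21:00-08:00 window (~70% of samples, half-hourly to
    hourly at night), sparser 2 h spacing through the daytime.
    """
    if n_samples < 4:
        raise ValidationError("need >= 4 samples for a downstream cosinor")
    if n_samples == 21:
        # day steps kept <= 1.5 h so that smooth circadian changes between
        # consecutive samples stay well below the downstream 2-SD QC gate
        day = [9.0, 10.5, 12.0, 13.5, 15.0, 16.5, 18.0, 19.5]
        nightt = [21.0, 21.75, 22.5, 23.25, 24.0, 25.0, 26.0, 27.0,
                  28.0, 29.0, 30.0, 31.0, 31.75]
        times = np.array(day + nightt)
    else:
        n_night = max(int(round(0.62 * n_samples)), 2)
        n_day = n_samples - n_night
        day = np.linspace(9.0, 19.5, n_day) if n_day else np.empty(0)
        nightt = np.linspace(21.0, 31.75, n_night)
        times = np.concatenate([day, nightt])
    if rng is not None and jitter_min > 0:
        times = times + rng.uniform(-jitter_min, jitter_min, times.size) / 60.0
        times = np.sort(times)
    return times


def generate_melatonin_profile(
    acrophase_h: float,
    mesor: float = 10.0,
    amplitude: float = 8.0,
    n_samples: int = 21,
    noise_sd: float = 2.0,
    seed: int = 0,
    subject: str = "sim",
    season: str = "SE",
) -> mel.MelatoninProfile:
    """Cosine melatonin profile on the night-dense schedule, floored at 0."""
    if amplitude > mesor:
        raise ValidationError(
            "amplitude must not exceed MESOR (negative expected concentration)")
    if n_samples < 4:
        raise ValidationError("n_samples < 4: cosinor unidentifiable downstream")
    rng = np.random.default_rng(seed)
    times = melatonin_schedule(n_samples, rng)
    conc = mesor + amplitude * np.cos(2.0 * np.pi * (times - acrophase_h) / 24.0)
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, conc.size)
    conc = np.maximum(conc, 0.0)
    base = SEASON_DATES.get(season, datetime(2024, 3, 18))
    samples = [
        mel.MelatoninSample(
            time=base.replace(hour=0) + _hours_delta(t), concentration=float(c))
        for t, c in zip(times, conc)
    ]
    return mel.MelatoninProfile(subject=subject, season=season, samples=samples)


def _hours_delta(hours: float):
    from datetime import timedelta
    return timedelta(seconds=round(hours * 3600.0))


# ---------------------------------------------------------------------------
# effect specification and cohort generation
# ---------------------------------------------------------------------------

#: invented adult reference marginals, mmol/L (ratio dimensionless):
#: the source cohort's lipid summary statistics are not published.
DEFAULT_LIPID_SCALES = {
    "tc": (5.2, 1.0),
    "ldl": (3.0, 0.9),
    "hdl": (1.4, 0.35),
    "tg": (1.3, 0.6),
    "tg_hdl": (1.0, 0.45),
}

#: published fully-adjusted standardized effects used as planted truth
DEFAULT_EFFECTS = {
    "tc": {"ble_l5": 0.290, "age": 0.261},
    "ldl": {"ble_l5": 0.253},
    "hdl": {"ble_acrophase_h": -0.257, "male": -0.412},
    "tg_hdl": {"ble_na": -0.390, "nn": 0.288, "male": 0.238},
}

_ALLOWED_PREDICTORS = {
    "ble_mesor", "ble_amplitude", "ble_acrophase_h", "ble_m10",
    "ble_m10_onset_h", "ble_l5", "ble_l5_onset_h", "ble_ra", "ble_na",
    "le_mesor", "le_amplitude", "le_acrophase_h",
    "age", "male", "nn", "photoperiod_h", "melatonin_acrophase_h",
}


@dataclass
class EffectSpec:
    """Planted standardized linear effects per lipid outcome.

    ``effects[outcome][predictor] = beta`` on the z-scored scale.  The
    residual SD defaults to sqrt(1 - sum(beta^2)) so each latent outcome has
    unit variance (planted predictors are mutually near-orthogonal in the
    generator).  TG and TG/HDL cannot both carry planted effects: whichever
    is planted is generated, the other derived.
    """

    effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_EFFECTS.items()})
    residual_sd: Optional[dict] = None
    lipid_scales: dict = field(default_factory=lambda: dict(DEFAULT_LIPID_SCALES))

    def __post_init__(self) -> None:
        for outcome, betas in self.effects.items():
            if outcome not in DEFAULT_LIPID_SCALES:
                raise ValidationError(f"unknown outcome {outcome!r}")
            for pred in betas:
                if pred not in _ALLOWED_PREDICTORS:
                    raise ValidationError(f"unknown predictor {pred!r}")
            r2 = sum(b * b for b in betas.values())
            if r2 >= 1.0:
                raise ValidationError(
                    f"planted R^2 = {r2:.3f} >= 1 for outcome {outcome!r}")
        if self.effects.get("tg") and self.effects.get("tg_hdl"):
            raise ValidationError(
                "plant effects on TG or TG/HDL, not both (ratio is derived)")

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(effects={})

    def sd_for(self, outcome: str) -> float:
        if self.residual_sd and outcome in self.residual_sd:
            return self.residual_sd[outcome]
        r2 = sum(b * b for b in self.effects.get(outcome, {}).values())
        return math.sqrt(max(1.0 - r2, 1e-12))


def generate_cohort(
    n_subjects: int,
    profiles: Optional[dict[str, SeasonProfile]] = None,
    effects: Optional[EffectSpec] = None,
    seed: int = 0,
    seasons: Sequence[str] = ("WS", "SE", "SS"),
    n_days: int = 7,
    melatonin_fraction: float = 13.0 / 27.0,
    keep_series: bool = False,
    subject_acro_sd: float = 0.3,
    subject_na_sd: float = 0.05,
    epoch_min: int = 30,
    include_white: bool = True,
) -> list[ParticipantSeason]:
    """Full synthetic cohort: every subject once per listed season.

    Demographics mirror the source design (75% women, 19/27 non-native,
    13/27 with melatonin profiles); each subject carries persistent latent
    offsets for acrophase and NA across seasons.  Lipids are built from the
    planted ``EffectSpec`` on metrics *computed from the generated series*,
    so parameter-recovery tests close the full loop.
    """
    if n_subjects < 2:
        raise ValidationError("need >= 2 subjects")
    profiles = profiles or default_profiles()
    effects = effects if effects is not None else EffectSpec()
    for s in seasons:
        if s not in profiles:
            raise ValidationError(f"no profile for season {s!r}")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    series_seeds = rng.integers(0, 2**31 - 1,
                                size=(n_subjects, len(seasons)))

    needs_mel = any("melatonin_acrophase_h" in b
                    for b in effects.effects.values())
    mel_frac = 1.0 if needs_mel else melatonin_fraction
    n_mel = int(round(mel_frac * n_subjects))
    mel_subjects = set(rng.choice(n_subjects, size=n_mel, replace=False))

    subjects = []
    for i in range(n_subjects):
        subjects.append({
            "id": f"S{i + 1:03d}",
            "age": float(np.clip(rng.normal(38.0, 11.0), 18.0, 59.0)),
            "sex": "female" if rng.random() < 0.75 else "male",
            "indigeneity": "NN" if rng.random() < 19.0 / 27.0 else "N",
            "meq": float(np.clip(rng.normal(51.6, 5.1), 16, 86)),
            "acro_off": float(rng.normal(0.0, subject_acro_sd)),
            "na_off": float(rng.normal(0.0, subject_na_sd)),
            "mel_acro": float(rng.normal(3.5, 0.8)) % 24.0,
        })

    records = []   # (subject dict, season, recording, metrics row pieces)
    for i, subj in enumerate(subjects):
        offsets = {"acrophase_h": subj["acro_off"], "na": subj["na_off"],
                   "acro_sd": subject_acro_sd, "na_sd": subject_na_sd}
        for j, season in enumerate(seasons):
            rec = generate_light_recording(
                profiles[season], int(series_seeds[i, j]), n_days, offsets)
            cos_b = fit_cosinor(rec.blue)
            np_b = nonparametric_metrics(rec.blue, cos_b)
            channel_metrics = {"blue_irradiance": (cos_b, np_b)}
            if include_white:
                cos_w = fit_cosinor(rec.white)
                np_w = nonparametric_metrics(rec.white, cos_w)
                channel_metrics["white_lux"] = (cos_w, np_w)
            comp = composite_day(rec.blue)
            epochs = comp.reshape(MINUTES_PER_DAY // epoch_min, epoch_min).mean(axis=1)

            mel_acro = None
            mel_profile = None
            if i in mel_subjects:
                mel_profile = generate_melatonin_profile(
                    acrophase_h=(subj["mel_acro"]
                                 + float(rng.normal(0.0, 0.5))) % 24.0,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject=subj["id"], season=season)
                filtered = mel.qc_filter(mel_profile)
                if filtered.usable:
                    try:
                        mel_acro = mel.melatonin_acrophase(
                            filtered).acrophase_h
                    except CircalipidError:
                        mel_acro = None     # QC left an unusable time span
            records.append({
                "subject": subj, "season": season, "recording": rec,
                "metrics": channel_metrics,
                "epochs": epochs, "melatonin_acrophase_h": mel_acro,
                "melatonin_profile": mel_profile,
            })

    lipids = _build_lipids(records, effects, rng)

    participants = []
    for rec, lip in zip(records, lipids):
        subj = rec["subject"]
        participants.append(ParticipantSeason(
            subject=subj["id"], age=subj["age"], sex=subj["sex"],
            indigeneity=subj["indigeneity"], season=rec["season"],
            tc=lip["tc"], ldl=lip["ldl"], hdl=lip["hdl"], tg=lip["tg"],
            meq=subj["meq"], metrics=rec["metrics"],
            melatonin_acrophase_h=rec["melatonin_acrophase_h"],
            melatonin_profile=rec["melatonin_profile"],
            ble_epochs=rec["epochs"],
            series={"blue_irradiance": rec["recording"].blue,
                    "white_lux": rec["recording"].white,
                    "activity": rec["recording"].activity}
            if keep_series else None,
        ))
    return participants


def _predictor_values(records: list[dict], name: str) -> np.ndarray:
    vals = []
    for r in records:
        if name == "age":
            vals.append(r["subject"]["age"])
        elif name == "male":
            vals.append(1.0 if r["subject"]["sex"] == "male" else 0.0)
        elif name == "nn":
            vals.append(1.0 if r["subject"]["indigeneity"] == "NN" else 0.0)
        elif name == "photoperiod_h":
            from .assoc import SEASON_PHOTOPERIOD_H
            vals.append(float(SEASON_PHOTOPERIOD_H[r["season"]]))
        elif name == "melatonin_acrophase_h":
            v = r["melatonin_acrophase_h"]
            vals.append(np.nan if v is None else v)
        else:
            prefix, attr = name.split("_", 1)
            channel = {"ble": "blue_irradiance", "le": "white_lux"}[prefix]
            cos, nonpar = r["metrics"][channel]
            vals.append({
                "mesor": cos.mesor, "amplitude": cos.amplitude,
                "acrophase_h": cos.acrophase_h, "m10": nonpar.m10,
                "m10_onset_h": nonpar.m10_onset_h, "l5": nonpar.l5,
                "l5_onset_h": nonpar.l5_onset_h, "ra": nonpar.ra,
                "na": nonpar.na,
            }[attr])
    return np.asarray(vals, dtype=float)


def _build_lipids(records: list[dict], effects: EffectSpec,
                  rng: np.random.Generator) -> list[dict]:
    n = len(records)
    zcache: dict[str, np.ndarray] = {}

    def z_of(name: str) -> np.ndarray:
        if name not in zcache:
            v = _predictor_values(records, name)
            if name in CIRCULAR_COLUMNS:
                v = linearize_circular(v)
            finite = np.isfinite(v)
            if finite.all() and np.std(v, ddof=1) == 0:
                # constant column (e.g. one-sex mini cohort): the planted
                # term is absorbed by the outcome mean and contributes 0
                z = np.zeros(n)
            else:
                z = np.full(n, np.nan)
                if finite.sum() >= 2 and np.std(v[finite], ddof=1) > 0:
                    z[finite] = zscore(v[finite])
            zcache[name] = z
        return zcache[name]

    ratio_planted = "tg_hdl" in effects.effects
    outcomes = ["tc", "ldl", "hdl"] + (["tg_hdl"] if ratio_planted else ["tg"])
    latent = {}
    for outcome in outcomes:
        y = rng.normal(0.0, effects.sd_for(outcome), n)
        for pred, beta in effects.effects.get(outcome, {}).items():
            zp = z_of(pred)
            if np.isnan(zp).any():
                raise ValidationError(
                    f"predictor {pred!r} has missing values; cannot plant "
                    f"effects on an incomplete column")
            y = y + beta * zp
        mean, sd = effects.lipid_scales[outcome]
        latent[outcome] = np.maximum(mean + sd * y, 0.02 * mean)

    out = []
    for i in range(n):
        tc, ldl, hdl = latent["tc"][i], latent["ldl"][i], latent["hdl"][i]
        tg = (latent["tg_hdl"][i] * hdl) if ratio_planted else latent["tg"][i]
        out.append({"tc": tc, "ldl": ldl, "hdl": hdl, "tg": max(tg, 0.01)})
    return out


# ---------------------------------------------------------------------------
# time-resolved (epoch-weighted) effect cohorts
# ---------------------------------------------------------------------------

def generate_timed_effect_cohort(
    n_subjects: int,
    peaks: dict[str, float],
    beta: float = 0.8,
    profiles: Optional[dict[str, SeasonProfile]] = None,
    seed: int = 0,
    seasons: Sequence[str] = ("WS", "SE", "SS"),
    epoch_min: int = 30,
    n_days: int = 7,
) -> tuple[list[ParticipantSeason], np.ndarray, np.ndarray]:
    """Cohort whose lipids carry a *time-of-day-structured* light association.

    The planted truth is the epoch-wise correlation curve itself: a
    half-rectified cosine peaking at the stated clock time,

        r(t) proportional to max(cos(2 pi (t - peak) / 24), 0),

    scaled so its maximum is ``beta``.  The latent lipid is built from the
    whitened epoch matrix (coefficients ``C^{-1} w`` for epoch correlation
    ``C`` and target curve ``w``) so the population correlation with each
    raw epoch column equals the planted curve exactly; the fitted r-rhythm
    acrophase is then an unbiased estimate of ``peak`` and BH-flagged epochs
    form a contiguous block around it.  ``beta = 0`` gives the global null.
    Returns (participants, epoch matrix, epoch centers).
    """
    if not 0.0 <= abs(beta) < 1.0:
        raise ValidationError("|beta| must lie in [0, 1)")
    for outcome in peaks:
        if outcome not in ("tc", "ldl", "hdl", "tg"):
            raise ValidationError(
                f"timed effects plant stored lipids only, not {outcome!r}")
    base = generate_cohort(
        n_subjects, profiles=profiles, effects=EffectSpec.null(),
        seed=seed, seasons=seasons, n_days=n_days,
        melatonin_fraction=0.0, epoch_min=epoch_min, include_white=False)
    matrix = np.vstack([p.ble_epochs for p in base])
    centers = (np.arange(matrix.shape[1]) + 0.5) * epoch_min / 60.0
    col_sd = matrix.std(axis=0, ddof=1)
    zcols = (matrix - matrix.mean(axis=0)) / np.where(col_sd > 0, col_sd, 1.0)
    n_rows = matrix.shape[0]
    corr = (zcols.T @ zcols) / (n_rows - 1)
    ridge = corr + 0.05 * np.eye(corr.shape[0])

    from .metrics import fit_cosinor_times

    def curve_for(peak: float) -> tuple[np.ndarray, np.ndarray]:
        w = np.maximum(np.cos(2.0 * np.pi * (centers - peak) / 24.0), 0.0)
        a = np.linalg.solve(ridge, w)
        return a, corr @ a                    # loading, population r-shape

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    scales = DEFAULT_LIPID_SCALES
    for outcome, peak_h in peaks.items():
        # fixed-point shift of the target so the population correlation
        # curve's own cosinor acrophase lands exactly on the nominal peak
        target = peak_h
        for _ in range(6):
            a, shape = curve_for(target)
            fitted = fit_cosinor_times(centers, shape).acrophase_h
            delta = ((fitted - peak_h + 12.0) % 24.0) - 12.0
            if abs(delta) < 1e-3:
                break
            target = (target - delta) % 24.0
        signal = zcols @ a
        var = float(a @ corr @ a)
        if var > 0:
            signal = signal / math.sqrt(var)
        signal = zscore(signal)
        y = beta * signal + math.sqrt(1.0 - beta * beta) * rng.normal(
            0.0, 1.0, n_rows)
        mean, sd = scales[outcome]
        raw = np.maximum(mean + sd * y, 0.02 * mean)
        for p, v in zip(base, raw):
            setattr(p, outcome, float(v))
    return base, matrix, centers
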