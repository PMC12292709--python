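"""Parametric (cosinor) and non-parametric endpoints of a per-minute light series.

The single-component cosinor model is

    Y(t) = M + A * cos(2*pi*(t - phi)/tau) + e(t)

with MESOR ``M`` (rhythm-adjusted mean), amplitude ``A`` (half the
peak-to-trough range) and acrophase ``phi`` (clock time of the fitted peak),
fitted by linear least squares on cosine/sine regressors for a fixed period
``tau`` (24 h throughout).  The zero-amplitude test is the classic F test of
the two harmonic coefficients on (2, n - 3) degrees of freedom.

Non-parametric endpoints are computed on the composite day (per-clock-minute
mean across recording days): M10 and L5 are the means of the most-exposed
600-minute and least-exposed 300-minute cyclic windows, RA is their
normalized difference, and NA (normalized amplitude) is the cosinor
amplitude-to-MESOR ratio - the circadian light hygiene index for the blue
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError

MINUTES_PER_DAY = 1440
#: amplitudes below ``tol * max(|M|, 1)`` leave the acrophase undefined
AMPLITUDE_TOL = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EpochSeries:
    """One participant-season per-minute light (or activity) recording.

    ``values`` is a float array on a uniform 1-minute grid starting at
    ``start_time``; missing epochs are NaN.  ``channel`` names the physical
    quantity (``"blue_irradiance"`` in uW/cm2 or ``"white_lux"``).
    """

    start_time: datetime
    values: np.ndarray
    channel: str = "blue_irradiance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("EpochSeries values must be 1-D")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=np.inf) < 0:
                raise ValidationError("light values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def start_clock_h(self) -> float:
        t = self.start_time
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    def clock_hours(self) -> np.ndarray:
        """Continuous clock time (hours since midnight of day 0) per epoch."""
        return self.start_clock_h + np.arange(self.values.size) / 60.0


@dataclass
class CosinorEstimate:
    mesor: float
    amplitude: float
    acrophase_h: float          # NaN when undefined
    rss: float
    f_zero_amp: float
    p_zero_amp: float
    n_used: int

    @property
    def acrophase_defined(self) -> bool:
        return np.isfinite(self.acrophase_h)


@dataclass
class NonparametricMetrics:
    m10: float
    m10_onset_h: float
    l5: float
    l5_onset_h: float
    ra: float
    na: float


@dataclass
class CircularMean:
    """Angular mean of clock times with the resultant length as dispersion."""
    mean_h: float               # NaN when the resultant vanishes
    resultant: float


# ---------------------------------------------------------------------------
# cosinor fitting
# ---------------------------------------------------------------------------

def fit_cosinor_times(
    t_hours: np.ndarray,
    y: np.ndarray,
    period_h: float = 24.0,
) -> CosinorEstimate:
    """Least-squares single cosinor on arbitrary (possibly irregular) times.

    ``t_hours`` are clock hours (values beyond 24 wrap naturally through the
    cosine).  NaNs in ``y`` are dropped.  Raises when fewer than 3 distinct
    time points remain or the time support spans no more than half a period
    (the fit would be aliased).
    """
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("times and values must have equal length")
    keep = np.isfinite(y) & np.isfinite(t)
    t, y = t[keep], y[keep]
    if t.size == 0:
        raise DegenerateInputError("all values missing")
    if np.unique(t).size < 3:
        raise InsufficientDataError(
            "cosinor needs >= 3 distinct time points (insufficient df)")
    if t.max() - t.min() <= period_h / 2:
        raise DegenerateInputError(
            f"time span {t.max() - t.min():.2f} h <= half period; aliased fit")

    omega = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    # normal equations on a 3-column design; well conditioned for any
    # non-degenerate time support
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta_c, beta_s = coef
    resid = y - X @ coef
    rss = float(resid @ resid)
    amplitude = float(np.hypot(beta_c, beta_s))

    n = t.size
    tss = float(np.sum((y - y.mean()) ** 2))
    ss_rhythm = max(tss - rss, 0.0)
    scale = float(np.sum(y * y)) + 1.0
    if tss <= 1e-15 * scale:            # constant series (within rounding)
        f_stat, p = 0.0, 1.0
    elif rss <= 1e-12 * tss:            # numerically perfect fit
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_rhythm / 2.0) / (rss / (n - 3))
        p = float(stats.f.sf(f_stat, 2, n - 3))

    if amplitude < AMPLITUDE_TOL * max(abs(mesor), 1.0):
        acrophase = np.nan
    else:
        acrophase = (np.arctan2(beta_s, beta_c) / omega) % period_h
    return CosinorEstimate(
        mesor=float(mesor), amplitude=amplitude, acrophase_h=float(acrophase),
        rss=rss, f_zero_amp=float(f_stat), p_zero_amp=float(p), n_used=int(n),
    )


def fit_cosinor(series: EpochSeries, period_h: float = 24.0) -> CosinorEstimate:
    """Cosinor fit on the full per-minute record (not the composite day)."""
    return fit_cosinor_times(series.clock_hours(), series.values, period_h)


# ---------------------------------------------------------------------------
# composite day and non-parametric window metrics
# ---------------------------------------------------------------------------

def composite_day(
    series: EpochSeries,
    max_missing_frac: float = 0.2,
    min_days: int = 3,
) -> np.ndarray:
    """Per-clock-minute mean across recording days (length 1440, minute 0 =
    midnight).

    Days (midnight-to-midnight segments, including partial first/last
    segments) with more than ``max_missing_frac`` missing minutes are dropped;
    within retained days missing minutes are ignored in the averaging.
    """
    if len(series) < MINUTES_PER_DAY:
        raise DegenerateInputError("series must cover at least one full day")
    start_min = int(round(series.start_clock_h * 60))
    n = len(series)
    grid = np.full(((start_min + n + MINUTES_PER_DAY - 1) // MINUTES_PER_DAY,
                    MINUTES_PER_DAY), np.nan)
    idx = start_min + np.arange(n)
    grid[idx // MINUTES_PER_DAY, idx % MINUTES_PER_DAY] = series.values

    missing_frac = np.mean(np.isnan(grid), axis=1)
    kept = grid[missing_frac <= max_missing_frac]
    if kept.shape[0] < min_days:
        raise InsufficientDataError(
            f"only {kept.shape[0]} valid day(s); need >= {min_days}")
    with np.errstate(invalid="ignore"):
        comp = np.nanmean(kept, axis=0)
    if np.isnan(comp).any():
        raise DegenerateInputError(
            "composite day has undefined minutes after missingness policy")
    return comp


def _best_cyclic_window(profile: np.ndarray, width: int, mode: str):
    """(mean, onset_minute) of the extreme cyclic window; earliest-start ties."""
    ext = np.concatenate([profile, profile[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means = (csum[width:] - csum[:-width]) / width   # one start per minute
    i = int(np.argmax(means) if mode == "max" else np.argmin(means))
    return float(means[i]), i


def nonparametric_metrics(
    series: EpochSeries,
    cosinor: CosinorEstimate,
    max_missing_frac: float = 0.2,
    min_days: int = 3,
    basis: str = "composite",
) -> NonparametricMetrics:
    """M10/L5 (with onsets), RA and NA for one series.

    ``basis="composite"`` (default) scans all 1440 cyclic window starts on the
    composite day; ``basis="per_day"`` computes windows per retained day and
    averages levels and (circularly) onsets.
    """
    if basis not in ("composite", "per_day"):
        raise ValidationError(f"unknown basis {basis!r}")
    if basis == "composite":
        profiles = [composite_day(series, max_missing_frac, min_days)]
    else:
        start_min = int(round(series.start_clock_h * 60))
        n = len(series)
        grid = np.full(((start_min + n + MINUTES_PER_DAY - 1) // MINUTES_PER_DAY,
                        MINUTES_PER_DAY), np.nan)
        idx = start_min + np.arange(n)
        grid[idx // MINUTES_PER_DAY, idx % MINUTES_PER_DAY] = series.values
        rows = [r for r in grid if np.isnan(r).mean() <= max_missing_frac
                and not np.isnan(r).any()]
        if len(rows) < min_days:
            raise InsufficientDataError(
                f"only {len(rows)} complete day(s); need >= {min_days}")
        profiles = rows

    m10s, m10_on, l5s, l5_on = [], [], [], []
    for prof in profiles:
        m, i = _best_cyclic_window(prof, 600, "max")
        m10s.append(m)
        m10_on.append(i / 60.0)
        l, j = _best_cyclic_window(prof, 300, "min")
        l5s.append(l)
        l5_on.append(j / 60.0)
    m10, l5 = float(np.mean(m10s)), float(np.mean(l5s))
    if len(profiles) == 1:
        m10_onset, l5_onset = m10_on[0], l5_on[0]
    else:
        m10_onset = circular_mean_clock(m10_on).mean_h
        l5_onset = circular_mean_clock(l5_on).mean_h

    denom = m10 + l5
    ra = (m10 - l5) / denom if denom > 0 else 0.0
    na = cosinor.amplitude / cosinor.mesor if cosinor.mesor > 0 else np.nan
    return NonparametricMetrics(
        m10=m10, m10_onset_h=float(m10_onset),
        l5=l5, l5_onset_h=float(l5_onset),
        ra=float(ra), na=float(na),
    )


def normalized_amplitude(cosinor: CosinorEstimate) -> float:
    """NA = cosinor amplitude / MESOR (dimensionless rhythm-strength index)."""
    if cosinor.mesor <= 0:
        raise DegenerateInputError("NA undefined for MESOR <= 0")
    return cosinor.amplitude / cosinor.mesor


def circular_mean_clock(times_h: Sequence[float]) -> CircularMean:
    """Angular mean of clock hours on the 24 h circle.

    Returns the mean in [0, 24) and the resultant length in [0, 1]; the mean
    is NaN (undefined) when the resultant vanishes, e.g. for perfectly
    symmetric inputs such as [0, 8, 16].
    """
    t = np.asarray(list(times_h), dtype=float)
    if t.size == 0:
        raise ValidationError("empty list of clock times")
    ang = 2.0 * np.pi * t / 24.0
    z = np.mean(np.exp(1j * ang))
    r = float(np.abs(z))
    if r < 1e-9:
        return CircularMean(mean_h=np.nan, resultant=r)
    mean_h = (np.angle(z) * 24.0 / (2.0 * np.pi)) % 24.0
    # snap values that round to 24.000... back to 0
    if mean_h >= 24.0 - 1e-12:
        mean_h = 0.0
    return CircularMean(mean_h=float(mean_h), resultant=r)
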