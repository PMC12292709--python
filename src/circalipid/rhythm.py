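"""Correlation rhythmometry: time-resolved lipid-light association.

The workflow correlates a single morning lipid value with blue-light
exposure within each consecutive 30-minute clock epoch of the composite
day (48 epochs), masks epochs surviving Benjamini-Hochberg correction at
q = 0.1, and fits a 24 h cosinor to the correlation curve r(t).  The
acrophase of that fitted r-rhythm is the clock time at which the
lipid-light association peaks; its zero-amplitude F statistic tests whether
the association is time-structured at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .assoc import bh_adjust
from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .metrics import (CosinorEstimate, EpochSeries, MINUTES_PER_DAY,
                      composite_day, fit_cosinor_times)


@dataclass
class CorrelationRhythm:
    outcome: str
    epoch_centers_h: np.ndarray
    r_values: np.ndarray               # NaN at zero-variance epochs
    p_values: np.ndarray
    significant_mask: np.ndarray
    r_cosinor: CosinorEstimate
    n: int


def epoch_exposure_matrix(
    series_list: Sequence[EpochSeries],
    epoch_min: int = 30,
    min_days: int = 1,
) -> np.ndarray:
    """rows x (1440/epoch_min) matrix of composite-day epoch means.

    Each cell is the mean blue irradiance of that clock epoch averaged
    across the recording's days.
    """
    if MINUTES_PER_DAY % epoch_min != 0:
        raise ValidationError(
            f"epoch length {epoch_min} min does not divide the 1440-min day")
    n_epochs = MINUTES_PER_DAY // epoch_min
    rows = []
    for series in series_list:
        comp = composite_day(series, min_days=min_days)
        rows.append(comp.reshape(n_epochs, epoch_min).mean(axis=1))
    if not rows:
        raise InsufficientDataError("no series supplied")
    return np.vstack(rows)


def epoch_centers(epoch_min: int = 30) -> np.ndarray:
    """Clock hours of epoch midpoints (cosinor time coordinate)."""
    if MINUTES_PER_DAY % epoch_min != 0:
        raise ValidationError(
            f"epoch length {epoch_min} min does not divide the 1440-min day")
    n_epochs = MINUTES_PER_DAY // epoch_min
    return (np.arange(n_epochs) + 0.5) * epoch_min / 60.0


def epochwise_correlation(
    matrix: np.ndarray, lipid_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch Pearson r and two-sided p of lipid vs epoch exposure.

    Zero-variance epoch columns yield NaN (excluded from the BH family and
    the cosinor fit downstream).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(lipid_values, dtype=float)
    if X.ndim != 2:
        raise ValidationError("matrix must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValidationError("lipid vector not aligned with matrix rows")
    if X.shape[0] < 4:
        raise InsufficientDataError("need >= 4 rows for per-epoch correlation")
    if np.std(y) == 0:
        raise ValidationError("lipid values are constant")
    r = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0:
            continue
        r[j], p[j] = stats.pearsonr(col, y)
    return r, p


def significant_epoch_mask(p_values: np.ndarray, fdr: float = 0.1) -> np.ndarray:
    """BH step-up mask over the defined epochs of one lipid's family."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.size, dtype=bool)
    defined = np.isfinite(p)
    if defined.any():
        mask[defined] = bh_adjust(p[defined], fdr=fdr)
    return mask


def fit_r_rhythm(
    epoch_centers_h: np.ndarray, r_values: np.ndarray,
) -> CosinorEstimate:
    """24 h single cosinor on the (epoch center, r) points.

    Undefined r-values are dropped; needs >= 4 defined epochs.  The
    zero-amplitude F statistic is on (2, n_epochs - 3) df.
    """
    t = np.asarray(epoch_centers_h, dtype=float)
    r = np.asarray(r_values, dtype=float)
    keep = np.isfinite(r)
    if keep.sum() < 4:
        raise InsufficientDataError(
            f"{int(keep.sum())} defined r-values < 4 (insufficient df)")
    return fit_cosinor_times(t[keep], r[keep], period_h=24.0)


def correlation_rhythm(
    matrix: np.ndarray,
    lipid_values: np.ndarray,
    outcome: str = "",
    epoch_min: int = 30,
    fdr: float = 0.1,
) -> CorrelationRhythm:
    """Full Fig-2-style workflow on a precomputed epoch exposure matrix."""
    centers = epoch_centers(epoch_min)
    if matrix.shape[1] != centers.size:
        raise ValidationError("matrix width inconsistent with epoch length")
    r, p = epochwise_correlation(matrix, lipid_values)
    mask = significant_epoch_mask(p, fdr=fdr)
    est = fit_r_rhythm(centers, r)
    return CorrelationRhythm(
        outcome=outcome, epoch_centers_h=centers, r_values=r, p_values=p,
        significant_mask=mask, r_cosinor=est, n=int(np.asarray(matrix).shape[0]))


def plot_rhythms(rhythms: Sequence[CorrelationRhythm], path: str) -> None:
    """Basic inspection plot of r(t) curves, cosinor fits and BH shading."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for k, rhy in enumerate(rhythms):
        c = colors[k % len(colors)]
        ax.plot(rhy.epoch_centers_h, rhy.r_values, ":", color=c,
                label=f"{rhy.outcome} r(t)")
        tt = np.linspace(0, 24, 481)
        est = rhy.r_cosinor
        if est.acrophase_defined:
            fit = est.mesor + est.amplitude * np.cos(
                2 * np.pi * (tt - est.acrophase_h) / 24.0)
            ax.plot(tt, fit, "-", color=c)
        sig = rhy.significant_mask
        if sig.any():
            ax.fill_between(rhy.epoch_centers_h, rhy.r_values, 0,
                            where=sig, alpha=0.2, color=c)
    ax.axhline(0, color="gray", lw=0.8)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("Pearson r")
    ax.set_xlim(0, 24)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
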