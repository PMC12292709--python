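"""Salivary melatonin profiles: quality control and acrophase estimation.

A profile is ~21 samples over one 24 h period, sampled densest before and
during the night sleep window.  QC removes non-finite/negative
concentrations and "jump" outliers - samples whose step from the previously
accepted sample exceeds twice the standard deviation of all consecutive
differences of the raw profile.  The acrophase is then the peak time of a
24 h single cosinor fitted to the surviving irregularly-timed samples.

The 2-SD rule is applied in a single deterministic pass: the SD is computed
once from the raw (finite, non-negative) profile and is not re-estimated
after removals.  QC therefore acts on raw profiles; re-filtering an
already-audited profile is a no-op, making the operation idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .metrics import CosinorEstimate, fit_cosinor_times

MIN_SAMPLES = 4  # fewer leaves the 3-parameter cosinor unidentifiable


@dataclass
class MelatoninSample:
    time: datetime
    concentration: float      # pg/mL
    valid: bool = True

    @property
    def clock_h(self) -> float:
        t = self.time
        return t.hour + t.minute / 60.0 + t.second / 3600.0


@dataclass
class MelatoninProfile:
    subject: str
    season: str
    samples: list[MelatoninSample]
    acrophase_h: Optional[float] = None
    qc_audit: Optional[list[dict]] = None   # None until qc_filter has run
    usable: bool = True

    def __post_init__(self) -> None:
        self.samples = sorted(self.samples, key=lambda s: s.time)

    def valid_samples(self) -> list[MelatoninSample]:
        return [s for s in self.samples if s.valid]

    def hours_since_start(self) -> np.ndarray:
        """Continuous hours from the first sample (handles past-midnight)."""
        t0 = self.samples[0].time
        return np.array(
            [(s.time - t0).total_seconds() / 3600.0 for s in self.samples])


def qc_filter(profile: MelatoninProfile) -> MelatoninProfile:
    """Flag invalid and jump-outlier samples; returns the audited profile.

    Removal reasons recorded in ``qc_audit``: ``non_finite``, ``negative``,
    ``jump_outlier`` (step from the accepted predecessor > 2 SD of the raw
    profile's consecutive differences).  Profiles with < 4 surviving samples
    are marked unusable.
    """
    if len(profile.samples) < 2:
        raise InsufficientDataError("QC needs at least 2 samples")
    if profile.qc_audit is not None:      # QC is defined on raw profiles
        return profile

    audit: list[dict] = []
    samples = [MelatoninSample(s.time, s.concentration, s.valid)
               for s in profile.samples]

    finite = []
    for i, s in enumerate(samples):
        if not np.isfinite(s.concentration):
            s.valid = False
            audit.append({"index": i, "time": s.time, "reason": "non_finite"})
        elif s.concentration < 0:
            s.valid = False
            audit.append({"index": i, "time": s.time, "reason": "negative"})
        else:
            finite.append((i, s))

    conc = np.array([s.concentration for _, s in finite])
    if conc.size >= 3:
        step_sd = float(np.std(np.diff(conc), ddof=1))
    else:
        step_sd = 0.0

    if step_sd > 0:
        last_accepted = conc[0]           # first finite sample is anchored
        for i, s in finite[1:]:
            if abs(s.concentration - last_accepted) > 2.0 * step_sd:
                s.valid = False
                audit.append(
                    {"index": i, "time": s.time, "reason": "jump_outlier"})
            else:
                last_accepted = s.concentration

    out = MelatoninProfile(
        subject=profile.subject, season=profile.season, samples=samples,
        qc_audit=audit,
    )
    out.usable = len(out.valid_samples()) >= MIN_SAMPLES
    return out


def melatonin_acrophase(profile: MelatoninProfile) -> CosinorEstimate:
    """24 h cosinor acrophase of a QC-passed profile (irregular times).

    Requires >= 4 valid samples whose times span more than 12 h (otherwise
    the 24 h fit is aliased).
    """
    valid = profile.valid_samples()
    if len(valid) < MIN_SAMPLES:
        raise InsufficientDataError(
            f"{len(valid)} valid samples; need >= {MIN_SAMPLES} "
            "(insufficient df)")
    t_all = profile.hours_since_start()
    mask = np.array([s.valid for s in profile.samples])
    t = t_all[mask] + profile.samples[0].clock_h   # absolute clock hours
    y = np.array([s.concentration for s in valid])
    if t.max() - t.min() <= 12.0:
        raise DegenerateInputError(
            f"sample span {t.max() - t.min():.1f} h <= 12 h; aliased fit")
    est = fit_cosinor_times(t, y, period_h=24.0)
    profile.acrophase_h = est.acrophase_h
    return est
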