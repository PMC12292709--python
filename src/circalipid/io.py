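"""Readers and writers for the pipeline's text formats.

Per-minute light recordings travel as a delimiter-separated dialect modeled
on wearable light-logger exports: header ``timestamp,lux,blue_uw_cm2,
activity`` with ISO-8601 naive local timestamps (the study region observes
no daylight saving time) on a strict 1-minute grid.  Gaps are re-read as
missing minutes; duplicated timestamps are a hard error.  Tabular outputs
are TSV with floats at 6 significant digits.
"""

from __future__ import annotations

import csv
import logging
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .melatonin import MelatoninProfile, MelatoninSample
from .metrics import EpochSeries

logger = logging.getLogger(__name__)

LIGHT_HEADER = ["timestamp", "lux", "blue_uw_cm2", "activity"]
CHANNEL_COLUMN = {"blue_irradiance": "blue_uw_cm2", "white_lux": "lux"}
FLOAT_FMT = "%.6g"
MALFORMED_TOLERANCE = 0.01


def write_light_csv(
    path: str | Path,
    blue: EpochSeries,
    white: Optional[EpochSeries] = None,
    activity: Optional[np.ndarray] = None,
) -> Path:
    """Write a per-minute recording; missing values become empty fields."""
    path = Path(path)
    n = len(blue)
    t0 = blue.start_time
    lux = white.values if white is not None else np.full(n, np.nan)
    act = activity if activity is not None else np.full(n, np.nan)

    def fmt(x: float) -> str:
        return "" if not np.isfinite(x) else FLOAT_FMT % x

    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LIGHT_HEADER)
        for i in range(n):
            ts = (t0 + timedelta(minutes=i)).isoformat(timespec="seconds")
            w.writerow([ts, fmt(lux[i]), fmt(blue.values[i]), fmt(act[i])])
    return path


def read_epoch_csv(path: str | Path, channel: str = "blue_irradiance") -> EpochSeries:
    """Parse a light CSV into an :class:`EpochSeries` on a strict 1-min grid.

    Interior gaps become missing (NaN) minutes with a logged warning;
    duplicated timestamps raise naming the timestamp; malformed rows are
    logged and skipped up to a 1% tolerance, beyond which the file is
    rejected.
    """
    path = Path(path)
    if channel not in CHANNEL_COLUMN:
        raise ValidationError(f"unknown channel {channel!r}")
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if [h.strip() for h in header] != LIGHT_HEADER:
            raise ValidationError(
                f"{path}: expected header {','.join(LIGHT_HEADER)}")
        col = LIGHT_HEADER.index(CHANNEL_COLUMN[channel])
        rows: dict[datetime, float] = {}
        total = bad = 0
        for lineno, fields in enumerate(reader, start=2):
            if not fields or all(not f.strip() for f in fields):
                continue
            total += 1
            try:
                ts = datetime.fromisoformat(fields[0].strip())
                raw = fields[col].strip()
                val = float(raw) if raw else np.nan
            except (ValueError, IndexError):
                bad += 1
                logger.warning("%s:%d malformed row skipped", path, lineno)
                continue
            if ts.second != 0 or ts.microsecond != 0:
                bad += 1
                logger.warning("%s:%d timestamp off the 1-min grid", path, lineno)
                continue
            if ts in rows:
                raise ValidationError(
                    f"{path}: duplicate timestamp {ts.isoformat()}")
            rows[ts] = val
    if total and bad / total > MALFORMED_TOLERANCE:
        raise ValidationError(
            f"{path}: {bad}/{total} malformed rows exceeds "
            f"{MALFORMED_TOLERANCE:.0%} tolerance")
    if not rows:
        raise ValidationError(f"{path}: no parseable rows")

    times = sorted(rows)
    t0, t_end = times[0], times[-1]
    n = int((t_end - t0).total_seconds() // 60) + 1
    values = np.full(n, np.nan)
    for ts, val in rows.items():
        values[int((ts - t0).total_seconds() // 60)] = val
    n_gap = n - len(rows)
    if n_gap:
        logger.warning("%s: %d missing minute(s) filled as NaN", path, n_gap)
    return EpochSeries(start_time=t0, values=values, channel=channel)


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """TSV with fixed column order and floats at 6 significant digits."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_melatonin_tsv(profiles: list[MelatoninProfile], path: str | Path) -> Path:
    rows = [
        {"subject": p.subject, "season": p.season,
         "time": s.time.isoformat(timespec="seconds"),
         "pg_ml": s.concentration}
        for p in profiles for s in p.samples
    ]
    return write_table(pd.DataFrame(rows), path)


def read_melatonin_tsv(path: str | Path) -> list[MelatoninProfile]:
    df = read_table(path)
    needed = {"subject", "season", "time", "pg_ml"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"{path}: melatonin table needs columns {sorted(needed)}")
    profiles = []
    for (subject, season), grp in df.groupby(["subject", "season"], sort=True):
        samples = [
            MelatoninSample(time=datetime.fromisoformat(str(r.time)),
                            concentration=float(r.pg_ml))
            for r in grp.itertuples()
        ]
        profiles.append(MelatoninProfile(
            subject=str(subject), season=str(season), samples=samples))
    return profiles
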