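from datetime import datetime

import numpy as np
import pytest

from circalipid import EpochSeries

MIDNIGHT = datetime(2024, 3, 18)


@pytest.fixture
def make_cosine_series():
    """7-day per-minute cosine series factory: M + A*cos(w(t-phi)) + noise."""

    def _make(mesor=10.0, amplitude=5.0, acrophase_h=14.0, n_days=7,
              noise_sd=0.0, seed=0, start=MIDNIGHT):
        t = np.arange(n_days * 1440) / 60.0
        clock = start.hour + start.minute / 60.0 + t
        y = mesor + amplitude * np.cos(2 * np.pi * (clock - acrophase_h) / 24.0)
        if noise_sd > 0:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
        return EpochSeries(start, np.maximum(y, 0.0))

    return _make


@pytest.fixture
def square_wave_series():
    """7-day square wave: 100 on [08:00, 20:00), 0 elsewhere."""
    day = np.zeros(1440)
    day[8 * 60: 20 * 60] = 100.0
    return EpochSeries(MIDNIGHT, np.tile(day, 7))


def brute_force_window(profile, width, mode):
    """Independent oracle: scan all 1440 cyclic window starts with plain
    slicing/np.mean (no shared code with the cumsum implementation)."""
    ext = np.concatenate([profile, profile])
    best_val, best_start = None, None
    for start in range(1440):
        m = float(np.mean(ext[start: start + width]))
        if best_val is None or (mode == "max" and m > best_val + 1e-12) \
                or (mode == "min" and m < best_val - 1e-12):
            best_val, best_start = m, start
    return best_val, best_start
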