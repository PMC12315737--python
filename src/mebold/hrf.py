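"""Canonical haemodynamic response function and task-regressor construction.

Shared by the phantom generator (which injects task-evoked R2* changes) and
the design-matrix builder (which models them), so simulation and analysis
agree on the response shape by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = ["HRF_DURATION_S", "canonical_hrf", "simulate_task_timecourse", "make_event_table"]

#: Support of the canonical response (s); the regressor has returned to
#: within ~1% of peak by this lag after stimulus offset.
HRF_DURATION_S = 32.0

# Double-gamma parameterisation: response peak ~5 s, undershoot ~15 s,
# undershoot-to-peak ratio 1/6 (the standard canonical shape).
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_DISPERSION = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def canonical_hrf(time_grid_s) -> np.ndarray:
    """Canonical double-gamma HRF sampled on a uniform time grid, unit peak.

    ``h(t) = g(t; 6, 1) - (1/6) g(t; 16, 1)`` with gamma densities ``g``;
    h(0) = 0, peak near 5 s, undershoot near 15 s.  Scaled so max(h) = 1 on
    the given grid.
    """
    t = np.asarray(time_grid_s, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with >= 2 points")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time grid must be uniform with dt > 0")
    h = gamma_dist.pdf(t, a=_PEAK_DELAY / _DISPERSION, scale=_DISPERSION)
    h = h - _UNDERSHOOT_RATIO * gamma_dist.pdf(
        t, a=_UNDERSHOOT_DELAY / _DISPERSION, scale=_DISPERSION
    )
    peak = h.max()
    if peak <= 0:
        raise ValueError("time grid does not cover the HRF response")
    return h / peak


def simulate_task_timecourse(events: pd.DataFrame, tr_s: float, n_volumes: int,
                             condition: str, dt: float = 0.05) -> np.ndarray:
    """HRF-convolved boxcar regressor for one condition, one value per volume.

    Events is a BIDS-style table with columns ``onset`` (s), ``duration``
    (s), ``trial_type``.  The condition's boxcar is built on a fine grid
    (``dt`` seconds), convolved with the canonical HRF, and sampled at
    volume midpoints ``(i + 1/2) * TR``.  Deterministic; linear in events.
    """
    if tr_s <= 0 or dt <= 0:
        raise ValueError("tr_s and dt must be > 0")
    sel = events[events["trial_type"] == condition]
    if len(sel) == 0:
        warnings.warn(f"no events for condition {condition!r}; returning zeros")
        return np.zeros(n_volumes)
    total_s = n_volumes * tr_s
    t_fine = np.arange(0.0, total_s + HRF_DURATION_S, dt)
    boxcar = np.zeros_like(t_fine)
    for onset, duration in zip(sel["onset"], sel["duration"]):
        if onset < 0 or duration <= 0:
            raise ValueError("event onsets must be >= 0 and durations > 0")
        boxcar[(t_fine >= onset) & (t_fine < onset + duration)] = 1.0
    h = canonical_hrf(np.arange(0.0, HRF_DURATION_S + dt, dt))
    conv = np.convolve(boxcar, h)[: t_fine.size] * dt
    t_mid = (np.arange(n_volumes) + 0.5) * tr_s
    return np.interp(t_mid, t_fine, conv)


def make_event_table(onsets, durations, trial_types) -> pd.DataFrame:
    """Assemble and validate a BIDS-style event table.

    Onsets must be non-negative and non-decreasing; durations positive.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    trial_types = list(trial_types)
    if not (onsets.size == durations.size == len(trial_types)):
        raise ValueError("onsets, durations, trial_types must have equal length")
    if np.any(onsets < 0) or np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be non-negative and non-decreasing")
    if np.any(durations <= 0):
        raise ValueError("durations must be > 0")
    return pd.DataFrame(
        {"onset": onsets, "duration": durations, "trial_type": trial_types}
    )
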