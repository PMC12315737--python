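"""Physiological and motion nuisance signals.

Respiration preprocessing (smooth, high-pass, detrend, standardise,
resample to one value per TR), trial-wise sniff metrics, Power-style
framewise displacement, and the motion-vs-task R^2 diagnostic that checks
whether head motion is time-locked to stimulus onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .hrf import simulate_task_timecourse

__all__ = [
    "RespiratoryTrace",
    "MotionTrace",
    "preprocess_respiration",
    "sniff_metrics",
    "sniff_metrics_per_event",
    "framewise_displacement",
    "fd_task_r2",
]


@dataclass
class RespiratoryTrace:
    """A breathing-belt recording: samples at ``fs_hz`` Hz, arbitrary units."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be > 0")
        if self.samples.size < 2 * self.fs_hz:
            raise ValueError("respiratory trace must span at least 2 s")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume plus FD."""

    params: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad
    fd: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("params must be (n_volumes, 6)")
        if self.fd.shape != (self.params.shape[0],) or np.any(self.fd < 0):
            raise ValueError("fd must be non-negative with one value per volume")

    @classmethod
    def from_params(cls, params, radius_mm: float = 50.0) -> "MotionTrace":
        params = np.asarray(params, dtype=float)
        return cls(params=params, fd=framewise_displacement(params, radius_mm))


def preprocess_respiration(trace: RespiratoryTrace, tr_s: float,
                           n_volumes: int | None = None,
                           smooth_window_s: float = 0.25,
                           highpass_hz: float = 0.05) -> np.ndarray:
    """Respiratory nuisance regressor: one value per fMRI volume.

    Chain: moving average over a 250 ms window -> zero-phase 2nd-order
    Butterworth (IIR) high-pass at 0.05 Hz -> linear detrend -> standardise
    to mean 0 / SD 1 -> resample at volume midpoints (1/TR Hz).

    Raises on a constant trace (no respiratory variance to regress).
    """
    if trace.fs_hz < 2.0:
        raise ValueError("sampling rate must be >= 2 Hz to resolve breathing")
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    x = trace.samples
    if np.ptp(x) == 0:
        raise ValueError("constant respiratory trace has zero variance")

    win = max(int(round(smooth_window_s * trace.fs_hz)), 1)
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")[pad:pad + x.size]

    nyq = trace.fs_hz / 2.0
    sos = sp_signal.butter(2, highpass_hz / nyq, btype="highpass", output="sos")
    hp = sp_signal.sosfiltfilt(sos, sm)

    dt = sp_signal.detrend(hp, type="linear")
    sd = dt.std()
    if sd == 0:
        raise ValueError("respiratory trace has zero variance after filtering")
    z = (dt - dt.mean()) / sd

    if n_volumes is None:
        n_volumes = int(np.floor(x.size / trace.fs_hz / tr_s))
    t_mid = (np.arange(n_volumes) + 0.5) * tr_s
    return np.interp(t_mid, trace.times_s, z)


def sniff_metrics(trace: RespiratoryTrace, cue_window: tuple) -> tuple:
    """Sniff volume and duration within a cue window.

    Volume = amplitude difference between the peak and the trough in the
    window; duration = |t_peak - t_trough| in seconds.
    """
    start_s, end_s = float(cue_window[0]), float(cue_window[1])
    if end_s - start_s < 0.5:
        raise ValueError("cue window must span at least 0.5 s")
    t = trace.times_s
    sel = (t >= start_s) & (t <= end_s)
    if not sel.any():
        raise ValueError("cue window lies outside the trace")
    seg, ts = trace.samples[sel], t[sel]
    i_max, i_min = int(np.argmax(seg)), int(np.argmin(seg))
    volume = float(seg[i_max] - seg[i_min])
    duration = float(abs(ts[i_max] - ts[i_min]))
    return volume, duration


def sniff_metrics_per_event(trace: RespiratoryTrace, events: pd.DataFrame,
                            window_s: float = 4.0):
    """Trial-by-trial sniff volume and duration (one pair per event row)."""
    volumes, durations = [], []
    for onset in events["onset"]:
        v, d = sniff_metrics(trace, (onset, onset + window_s))
        volumes.append(v)
        durations.append(d)
    return np.asarray(volumes), np.asarray(durations)


def framewise_displacement(params, radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement per volume (Power convention).

    ``fd(t) = sum |d translations| + radius * sum |d rotations|`` with
    backward differences; fd(0) = 0.  Translations in mm, rotations in
    radians, converted to arc length on a ``radius_mm`` sphere.
    """
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be (n_volumes, 6)")
    d = np.diff(p, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def fd_task_r2(motion: MotionTrace, events: pd.DataFrame, tr_s: float,
               condition: str) -> float:
    """Squared Pearson correlation between FD and a condition's HRF-convolved
    onset regressor — high values flag stimulus-locked head motion."""
    fd = motion.fd
    reg = simulate_task_timecourse(events, tr_s, fd.size, condition)
    if fd.std() == 0 or reg.std() == 0:
        raise ValueError("zero-variance FD or regressor: correlation undefined")
    r = np.corrcoef(fd, reg)[0, 1]
    return float(r**2)
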