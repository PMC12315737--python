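"""Synthetic multi-echo task-fMRI phantom with known ground truth.

The generator emulates the data regime of olfactory task fMRI at 3 T:

* regions with short T2* (susceptibility dropout near the sinuses) next to
  regions with ordinary cortical T2*, surrounded by air (zero signal);
* task-evoked BOLD injected as a transient *fractional decrease of R2*,
  convolved with the canonical HRF — the physically correct mechanism that
  makes TE-dependent echo weighting meaningful;
* a breathing-locked, TE-independent S0 modulation (the respiratory
  artifact, optionally time-locked to sniff cues at event onsets);
* thermal noise added as two independent Gaussian channels with the
  magnitude taken, so the Rician noise floor of magnitude images is
  physically realised: a zero-signal voxel has mean magnitude
  ``sigma * sqrt(pi/2)``, which is the floor ``x0`` the noise-floor decay
  model estimates.

Everything is reproducible bit-for-bit from ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decay import DEFAULT_TE_MS, validate_echo_times
from .fitting import MultiEchoSeries
from .hrf import canonical_hrf, make_event_table, simulate_task_timecourse

__all__ = [
    "ROIDef",
    "RespirationSpec",
    "MotionSpec",
    "PhantomSpec",
    "GroundTruth",
    "Phantom",
    "default_rois",
    "default_events",
    "generate_phantom",
    "canonical_hrf",
    "simulate_task_timecourse",
]

#: Conditions of the default three-alternative odor paradigm.
DEFAULT_CONDITIONS = ("lemon", "benzaldehyde", "control")

#: Conditions that drive the BOLD response in active regions (odor trials).
ODOR_CONDITIONS = ("lemon", "benzaldehyde")


@dataclass(frozen=True)
class ROIDef:
    """A rectangular tissue region with uniform decay parameters.

    ``box`` is voxel-index bounds (x0, x1, y0, y1, z0, z1), half-open.
    ``bold_effect`` is the peak fractional decrease of R2* during the
    response to the listed conditions (0 = inactive).
    """

    label: str
    box: Tuple[int, int, int, int, int, int]
    s0: float
    t2star_ms: float
    bold_effect: float = 0.0
    conditions: Tuple[str, ...] = ODOR_CONDITIONS

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        x0, x1, y0, y1, z0, z1 = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass(frozen=True)
class RespirationSpec:
    """Breathing trace: sinusoid at ``rate_hz`` plus, when ``sniff_locked``,
    Gaussian sniff bursts at event onsets; unit-normalised to peak 1.
    ``s0_fluctuation_fraction`` scales the multiplicative S0 modulation."""

    rate_hz: float = 0.3
    s0_fluctuation_fraction: float = 0.01
    sniff_locked: bool = True
    fs_hz: float = 50.0
    sniff_amp: float = 1.5
    sniff_width_s: float = 0.4
    sniff_delay_s: float = 0.5


@dataclass(frozen=True)
class MotionSpec:
    """Rigid-body motion trace (random walk).  Feeds the nuisance-regression
    path only; no image-domain resampling is simulated."""

    enabled: bool = False
    step_sigma_mm: float = 0.02
    step_sigma_rad: float = 0.0004
    n_spikes: int = 0
    spike_size_mm: float = 1.0


def default_rois() -> Tuple[ROIDef, ...]:
    """Illustrative regions on the default 24 x 24 x 12 grid.

    Short-T2* active regions stand in for orbitofrontal / entorhinal-like
    dropout zones; values are plausible 3 T magnitudes chosen for the
    phantom, not measured tissue constants.
    """
    return (
        ROIDef("ofc", (3, 9, 3, 9, 3, 9), s0=800.0, t2star_ms=18.0, bold_effect=0.02),
        ROIDef("piriform", (14, 20, 3, 9, 3, 9), s0=900.0, t2star_ms=30.0, bold_effect=0.02),
        ROIDef("cortex", (3, 9, 14, 20, 3, 9), s0=1000.0, t2star_ms=45.0, bold_effect=0.02),
        ROIDef("white", (14, 20, 14, 20, 3, 9), s0=950.0, t2star_ms=40.0, bold_effect=0.0,
               conditions=()),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full configuration of a synthetic multi-echo task-fMRI run.

    Defaults reproduce the acquisition's temporal structure (200 volumes,
    TR 2.041 s, five echoes) on a small grid.  ``seed`` is mandatory: every
    stochastic field derives from it.
    """

    seed: int
    grid_shape: Tuple[int, int, int] = (24, 24, 12)
    tr_s: float = 2.041
    n_volumes: int = 200
    echo_times: Tuple[float, ...] = DEFAULT_TE_MS
    rois: Tuple[ROIDef, ...] = field(default_factory=default_rois)
    events: Optional[pd.DataFrame] = None
    respiration: RespirationSpec = field(default_factory=RespirationSpec)
    motion: MotionSpec = field(default_factory=MotionSpec)
    noise_sigma: float = 5.0
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("PhantomSpec.seed is mandatory")
        validate_echo_times(self.echo_times)
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.respiration.s0_fluctuation_fraction < 0:
            raise ValueError("s0_fluctuation_fraction must be >= 0")
        shape = tuple(self.grid_shape)
        seen = np.zeros(shape, dtype=int)
        for roi in self.rois:
            if roi.s0 <= 0 or roi.t2star_ms <= 0:
                raise ValueError(f"ROI {roi.label!r}: s0 and t2star_ms must be > 0")
            if roi.bold_effect < 0:
                raise ValueError(f"ROI {roi.label!r}: bold_effect must be >= 0")
            m = roi.mask(shape)
            if not m.any():
                raise ValueError(f"ROI {roi.label!r} is empty on grid {shape}")
            seen += m
        if np.any(seen > 1):
            raise ValueError("ROIs must be disjoint")
        if self.events is not None:
            scan_s = self.n_volumes * self.tr_s
            if np.any(self.events["onset"] + self.events["duration"] > scan_s):
                raise ValueError("events extend beyond the scan duration")


@dataclass
class GroundTruth:
    """True parameters behind a generated phantom."""

    s0_map: np.ndarray
    t2star_map: np.ndarray          # ms; NaN outside tissue
    x0: float                       # thermal floor sigma*sqrt(pi/2)
    tissue_mask: np.ndarray
    activation_mask: np.ndarray
    roi_masks: dict
    task_courses: dict              # per-ROI unit-peak effect time course
    breath_volumes: np.ndarray      # S0 modulation sampled per volume
    events: pd.DataFrame
    motion_params: np.ndarray       # (n_volumes, 6)


@dataclass
class Phantom:
    """A generated dataset: the series plus everything used to make it."""

    series: MultiEchoSeries
    truth: GroundTruth
    events: pd.DataFrame
    resp_samples: np.ndarray
    resp_fs_hz: float
    motion_params: np.ndarray
    spec: PhantomSpec


def default_events(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """24-trial, three-condition paradigm filling the scan.

    Eight trials per condition in a shuffled order; 2 s stimulus, mean
    inter-trial interval ~17 s with a small uniform jitter — the temporal
    structure of a slow event-related olfactory design.
    """
    n_per = 8
    conds = list(spec.conditions)
    labels = np.repeat(conds, n_per)
    rng.shuffle(labels)
    n_trials = len(labels)
    scan_s = spec.n_volumes * spec.tr_s
    spacing = (scan_s - 30.0) / n_trials
    onsets = 8.0 + spacing * np.arange(n_trials) + rng.uniform(0.0, 4.0, n_trials)
    onsets = np.sort(onsets)
    durations = np.full(n_trials, 2.0)
    return make_event_table(onsets, durations, labels)


def _breathing_trace(spec: PhantomSpec, events: pd.DataFrame):
    """Fine-grid breathing trace and its per-volume samples (unit peak)."""
    resp = spec.respiration
    total_s = spec.n_volumes * spec.tr_s
    t = np.arange(0.0, total_s, 1.0 / resp.fs_hz)
    b = np.sin(2.0 * np.pi * resp.rate_hz * t)
    if resp.sniff_locked:
        for onset in events["onset"]:
            center = onset + resp.sniff_delay_s
            b += resp.sniff_amp * np.exp(-0.5 * ((t - center) / resp.sniff_width_s) ** 2)
    peak = np.max(np.abs(b))
    if peak > 0:
        b = b / peak
    t_mid = (np.arange(spec.n_volumes) + 0.5) * spec.tr_s
    return b, np.interp(t_mid, t, b)


def _motion_trace(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    mo = spec.motion
    params = np.zeros((spec.n_volumes, 6))
    if not mo.enabled:
        return params
    steps = np.empty((spec.n_volumes, 6))
    steps[:, :3] = rng.normal(0.0, mo.step_sigma_mm, (spec.n_volumes, 3))
    steps[:, 3:] = rng.normal(0.0, mo.step_sigma_rad, (spec.n_volumes, 3))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    if mo.n_spikes > 0:
        # isolated large displacements for spike-regressor tests
        idx = rng.choice(np.arange(5, spec.n_volumes - 5), mo.n_spikes, replace=False)
        for i in idx:
            params[i, 0] += mo.spike_size_mm
    return params


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a multi-echo series, ground truth and nuisance traces.

    Signal model per voxel, volume ``t`` and echo ``e``::

        R2*(x, t) = (1 / t2star(x)) * (1 - bold_effect(x) * task(x, t))
        S0(x, t)  = s0(x) * (1 + resp_fraction * breath(t))
        clean     = S0(x, t) * exp(-TE_e * R2*(x, t))
        observed  = |clean + n1 + i*n2|,  n1, n2 ~ N(0, noise_sigma)

    ``task(x, t)`` is the unit-peak HRF-convolved regressor summed over the
    ROI's driving conditions, so ``bold_effect`` is the peak fractional R2*
    decrease.  The expected magnitude floor in signal-free voxels is
    ``x0 = noise_sigma * sqrt(pi/2)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    te = validate_echo_times(spec.echo_times)

    events = spec.events if spec.events is not None else default_events(spec, rng)
    spec_checked = replace(spec, events=events)
    spec_checked.validate()

    # condition regressors at volume resolution, unit peak per condition set
    cond_reg = {
        c: simulate_task_timecourse(events, spec.tr_s, spec.n_volumes, c)
        for c in spec.conditions
    }

    s0_map = np.zeros(shape)
    t2_map = np.full(shape, np.nan)
    effect_map = np.zeros(shape)
    tissue = np.zeros(shape, dtype=bool)
    activation = np.zeros(shape, dtype=bool)
    roi_masks, task_courses = {}, {}
    course_map = np.zeros(shape + (spec.n_volumes,))
    for roi in spec.rois:
        m = roi.mask(shape)
        roi_masks[roi.label] = m
        tissue |= m
        s0_map[m] = roi.s0
        t2_map[m] = roi.t2star_ms
        course = np.zeros(spec.n_volumes)
        for c in roi.conditions:
            course = course + cond_reg.get(c, 0.0)
        peak = course.max() if course.size else 0.0
        if peak > 0:
            course = course / peak
        task_courses[roi.label] = course
        if roi.bold_effect > 0 and peak > 0:
            effect_map[m] = roi.bold_effect
            activation |= m
            course_map[m] = course

    breath_fine, breath_vol = _breathing_trace(spec_checked, events)
    frac = spec.respiration.s0_fluctuation_fraction

    r2s_base = np.zeros(shape)
    r2s_base[tissue] = 1.0 / t2_map[tissue]           # 1/ms
    r2s = r2s_base[..., None] * (1.0 - effect_map[..., None] * course_map)
    s0_t = s0_map[..., None] * (1.0 + frac * breath_vol)

    clean = s0_t[None] * np.exp(-te[:, None, None, None, None] * r2s[None])
    if spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, clean.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, clean.shape)
        data = np.hypot(clean + n1, n2)
    else:
        data = clean

    motion = _motion_trace(spec_checked, rng)
    x0_true = spec.noise_sigma * np.sqrt(np.pi / 2.0)

    series = MultiEchoSeries(
        data=data, echo_times=te, tr_s=spec.tr_s, mask=tissue.copy(),
        affine=np.diag([2.4, 2.4, 2.4, 1.0]),
    )
    truth = GroundTruth(
        s0_map=s0_map, t2star_map=t2_map, x0=float(x0_true),
        tissue_mask=tissue, activation_mask=activation, roi_masks=roi_masks,
        task_courses=task_courses, breath_volumes=breath_vol, events=events,
        motion_params=motion,
    )
    return Phantom(
        series=series, truth=truth, events=events,
        resp_samples=breath_fine, resp_fs_hz=spec.respiration.fs_hz,
        motion_params=motion, spec=spec_checked,
    )
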