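"""GLM design-matrix construction for task fMRI.

Columns, in order: HRF-convolved condition regressors; HRF-convolved
trial-wise sniff volume/duration modulators; the preprocessed breathing
trace (entered unconvolved — it is already a measured physiological
signal); 24 motion regressors (6 realignment parameters, their squares,
backward first differences, and squared differences); one-hot spike
regressors for volumes where any raw parameter deviates more than a
threshold number of SDs from its mean; a discrete-cosine drift basis
implementing the high-pass filter; and an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hrf import HRF_DURATION_S, canonical_hrf, simulate_task_timecourse

__all__ = ["DesignMatrix", "build_design_matrix", "dct_drift_basis", "motion_24"]


@dataclass
class DesignMatrix:
    """Named regressors, one row per volume.

    ``groups`` maps a group name (task / sniff / physio / motion / spike /
    drift / intercept) to its column names, preserving build order.
    """

    frame: pd.DataFrame
    tr_s: float
    groups: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def names(self) -> list:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def contrast_vector(self, spec) -> np.ndarray:
        """Contrast vector from a string like ``"lemon>control"`` or
        ``"odor>control"`` (odor = mean of non-control task columns), or a
        mapping {column: weight}, or an explicit vector."""
        names = self.names
        c = np.zeros(len(names))
        if isinstance(spec, str):
            pos, _, neg = spec.partition(">")
            pos, neg = pos.strip(), neg.strip()
            task = self.groups.get("task", [])

            def cols_for(token):
                if token == "odor":
                    return [n for n in task if not n.startswith("control")]
                return [n for n in task if n == token or n.startswith(token)]

            pcols = cols_for(pos)
            if not pcols:
                raise ValueError(f"no task columns match {pos!r}")
            for n in pcols:
                c[names.index(n)] = 1.0 / len(pcols)
            if neg:
                ncols = cols_for(neg)
                if not ncols:
                    raise ValueError(f"no task columns match {neg!r}")
                for n in ncols:
                    c[names.index(n)] -= 1.0 / len(ncols)
            return c
        if isinstance(spec, dict):
            for name, w in spec.items():
                c[names.index(name)] = w
            return c
        v = np.asarray(spec, dtype=float)
        if v.size != len(names):
            raise ValueError("contrast vector length must equal #regressors")
        return v


def dct_drift_basis(n_volumes: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (constant term excluded).

    Keeps cosines with period above ``cutoff_s``:
    K = floor(2 * N * TR / cutoff), basis k in 1..K with
    ``cos(pi * k * (2t + 1) / (2N))``, unit-normalised.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be > 0")
    n_basis = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def motion_24(params) -> np.ndarray:
    """Expand 6 realignment parameters into the 24-parameter set:
    the parameters, their squares, backward first differences (zero first
    element), and squared differences."""
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be (n_volumes, 6)")
    d = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    return np.hstack([p, p**2, d, d**2])


def _convolve_amplitudes(events: pd.DataFrame, amplitudes, tr_s: float,
                         n_volumes: int, dt: float = 0.05) -> np.ndarray:
    """HRF-convolved stick regressor with per-event amplitudes
    (mean-centred so the modulator is orthogonal to the main response)."""
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size != len(events):
        raise ValueError("one amplitude per event required")
    amp = amp - amp.mean()
    total_s = n_volumes * tr_s
    t_fine = np.arange(0.0, total_s + HRF_DURATION_S, dt)
    x = np.zeros_like(t_fine)
    for onset, duration, a in zip(events["onset"], events["duration"], amp):
        x[(t_fine >= onset) & (t_fine < onset + duration)] += a
    h = canonical_hrf(np.arange(0.0, HRF_DURATION_S + dt, dt))
    conv = np.convolve(x, h)[: t_fine.size] * dt
    t_mid = (np.arange(n_volumes) + 0.5) * tr_s
    return np.interp(t_mid, t_fine, conv)


def build_design_matrix(
    n_volumes: int,
    tr_s: float,
    events: Optional[pd.DataFrame] = None,
    conditions: Optional[Sequence[str]] = None,
    sniff_volume: Optional[np.ndarray] = None,
    sniff_duration: Optional[np.ndarray] = None,
    breathing: Optional[np.ndarray] = None,
    motion_params: Optional[np.ndarray] = None,
    spike_sd_threshold: float = 6.0,
    hp_cutoff_s: float = 128.0,
    include_drift: bool = True,
) -> DesignMatrix:
    """Assemble the full task + nuisance design matrix.

    Spike regressors follow the raw-parameter rule: a volume is censored
    (given its own one-hot column) when any of the six realignment
    parameters deviates more than ``spike_sd_threshold`` SDs from that
    parameter's run mean.
    """
    cols, groups = {}, {}

    def add(group, name, values):
        if name in cols:
            raise ValueError(f"duplicate design column {name!r}")
        v = np.asarray(values, dtype=float)
        if v.shape != (n_volumes,):
            raise ValueError(f"column {name!r} must have one value per volume")
        cols[name] = v
        groups.setdefault(group, []).append(name)

    if events is not None:
        if conditions is None:
            conditions = list(pd.unique(events["trial_type"]))
        for c in conditions:
            reg = simulate_task_timecourse(events, tr_s, n_volumes, c)
            add("task", str(c), reg)

    if sniff_volume is not None:
        if events is None:
            raise ValueError("sniff modulators require an event table")
        add("sniff", "sniff_volume",
            _convolve_amplitudes(events, sniff_volume, tr_s, n_volumes))
    if sniff_duration is not None:
        if events is None:
            raise ValueError("sniff modulators require an event table")
        add("sniff", "sniff_duration",
            _convolve_amplitudes(events, sniff_duration, tr_s, n_volumes))

    if breathing is not None:
        add("physio", "breathing", breathing)

    if motion_params is not None:
        p = np.asarray(motion_params, dtype=float)
        m24 = motion_24(p)
        base = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        names = base + [f"{b}_sq" for b in base] + [f"{b}_diff" for b in base] \
            + [f"{b}_diff_sq" for b in base]
        for name, col in zip(names, m24.T):
            add("motion", name, col)
        # spike censoring on the 6 raw parameters
        sd = p.std(axis=0, ddof=0)
        sd_safe = np.where(sd > 0, sd, np.inf)
        z = np.abs(p - p.mean(axis=0)) / sd_safe
        spike_vols = np.flatnonzero((z > spike_sd_threshold).any(axis=1))
        for v in spike_vols:
            onehot = np.zeros(n_volumes)
            onehot[v] = 1.0
            add("spike", f"spike_{v:04d}", onehot)

    if include_drift:
        drift = dct_drift_basis(n_volumes, tr_s, hp_cutoff_s)
        for k in range(drift.shape[1]):
            add("drift", f"drift_{k + 1:02d}", drift[:, k])

    add("intercept", "intercept", np.ones(n_volumes))

    # constant nuisance columns carry no information and would be collinear
    # with the intercept (e.g. a motionless run); drop them silently.  Task
    # columns are kept — an all-zero one already warned upstream.
    droppable = {"sniff", "physio", "motion"}
    for group in list(groups):
        if group not in droppable:
            continue
        kept = []
        for name in groups[group]:
            if np.ptp(cols[name]) == 0:
                del cols[name]
            else:
                kept.append(name)
        if kept:
            groups[group] = kept
        else:
            del groups[group]

    frame = pd.DataFrame(cols)
    return DesignMatrix(frame=frame, tr_s=tr_s, groups=groups)
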