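"""Voxel-wise estimation of (S0, T2*) and the thermal noise floor x0.

Three estimators of increasing fidelity:

``loglinear_fit``
    Ordinary least squares of ``ln S`` against TE.  Exact for noiseless
    monoexponential data; used to initialise the nonlinear fits.  Where the
    signal decays into a noise floor the flattened tail biases the slope,
    so T2* is systematically overestimated.

``monoexp_nls_fit``
    Bounded nonlinear least squares of the monoexponential model.  Shares
    the log-linear fit's overestimation bias on noise-floored data.

``noisefloor_fit``
    Bounded nonlinear least squares of the noise-floor model
    ``sqrt((S0 exp(-TE/T2*))**2 + x0**2)`` with signal-weighted residuals

        r_i = (S_i / sum_j S_j) * (S_hat_i - S_i)

    over the full observation set (every echo of every volume), minimised
    with a trust-region-reflective bounded solver.  This is the estimator of
    record for high-susceptibility regions.

Whole-image fitting is exposed statsmodels-style: build a
:class:`T2StarModel` from a :class:`MultiEchoSeries` and call ``fit()`` to
obtain :class:`T2StarResults` (the parameter maps plus diagnostics); the
module-level :func:`fit_parameter_maps` is a thin functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .decay import (
    DEFAULT_TE_MS,
    DecayParams,
    monoexp_signal,
    noisefloor_signal,
    validate_echo_times,
)

__all__ = [
    "T2STAR_BOUNDS_MS",
    "FitDiagnostics",
    "MultiEchoSeries",
    "loglinear_fit",
    "monoexp_nls_fit",
    "noisefloor_fit",
    "T2StarModel",
    "T2StarResults",
    "fit_parameter_maps",
    "derive_mask",
]

#: Physiologic T2* search range at 3 T, with headroom (ms).
T2STAR_BOUNDS_MS = (1.0, 500.0)

#: Relative tolerance used for the objective/parameter convergence of the
#: bounded solver.  Tighter than the 1e-8 contract so noiseless problems
#: recover parameters to ~1e-6 relative.
_SOLVER_TOL = 1e-12

# Relative closeness to a bound at which a solution is flagged unconverged.
_BOUND_REL = 1e-6


@dataclass
class FitDiagnostics:
    """Per-fit bookkeeping.

    residual_norm is the 2-norm of the (possibly weighted) residuals at the
    solution — log-domain residuals for the log-linear fit, model-domain for
    the nonlinear fits.  n_obs counts (echo, volume) observations used.
    """

    residual_norm: float
    converged: bool
    n_obs: int
    method: str


@dataclass
class MultiEchoSeries:
    """Aligned per-echo 4-D BOLD stacks plus acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_echo, nx, ny, nz, nt)
        One 4-D grid per echo, identical spatial grid and time axis.
    echo_times : sequence of float
        Echo times in ms, ascending, one per data grid.
    tr_s : float
        Repetition time in seconds.
    mask : ndarray of bool, shape (nx, ny, nz), optional
        Analysis mask; derived from the data when absent.
    affine : ndarray (4, 4), optional
        NIfTI affine, carried through for writers and smoothing.
    """

    data: np.ndarray
    echo_times: np.ndarray
    tr_s: float
    mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.echo_times = validate_echo_times(self.echo_times)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("data must have shape (n_echo, nx, ny, nz, nt)")
        if self.data.shape[0] != self.echo_times.size:
            raise ValueError(
                f"{self.data.shape[0]} echo grids but "
                f"{self.echo_times.size} echo times"
            )
        if not self.tr_s > 0:
            raise ValueError("tr_s must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spatial_shape:
                raise ValueError("mask shape does not match data spatial grid")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self):
        return self.data.shape[1:4]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[4]


# ----------------------------------------------------------------------
# single-voxel estimators
# ----------------------------------------------------------------------

def _as_observations(signals, te: np.ndarray):
    """Flatten (n_echo,) or (n_echo, n_vol) signals into paired obs vectors."""
    s = np.asarray(signals, dtype=float)
    if s.ndim == 1:
        if s.size != te.size:
            raise ValueError("signals length must equal number of echoes")
        return s, te
    if s.ndim == 2:
        if s.shape[0] != te.size:
            raise ValueError("signals first axis must index echoes")
        te_obs = np.broadcast_to(te[:, None], s.shape)
        return s.ravel(), te_obs.ravel()
    raise ValueError("signals must be 1-D (per echo) or 2-D (echo x volume)")


def loglinear_fit(signals, echo_times=DEFAULT_TE_MS):
    """Log-linear (OLS on ln S vs TE) estimate of S0 and T2*.

    Signals must be strictly positive.  A non-negative slope (non-decaying
    data) cannot yield a positive T2*: the fit is flagged unconverged and
    T2* is set to the upper bound so downstream weights stay finite.

    Returns
    -------
    (DecayParams, FitDiagnostics) with ``x0 = 0``.
    """
    te = validate_echo_times(echo_times)
    s_obs, te_obs = _as_observations(signals, te)
    if np.any(~np.isfinite(s_obs)) or np.any(s_obs <= 0):
        raise ValueError("loglinear_fit requires strictly positive, finite signals")
    y = np.log(s_obs)
    slope, intercept = np.polyfit(te_obs, y, 1)
    resid = y - (slope * te_obs + intercept)
    rnorm = float(np.linalg.norm(resid))
    s0 = float(np.exp(intercept))
    # a slope at or above -1/cap implies T2* beyond the physiologic cap
    # (including the numerically-zero slope of constant data): flag failed
    if slope >= -1.0 / T2STAR_BOUNDS_MS[1]:
        params = DecayParams(s0=s0, t2star_ms=T2STAR_BOUNDS_MS[1], x0=0.0)
        diag = FitDiagnostics(rnorm, converged=False, n_obs=s_obs.size, method="loglinear")
        return params, diag
    params = DecayParams(s0=s0, t2star_ms=float(-1.0 / slope), x0=0.0)
    diag = FitDiagnostics(rnorm, converged=True, n_obs=s_obs.size, method="loglinear")
    return params, diag


def _default_init(s_obs, te_obs, te):
    """Log-linear initial values, robust to non-positive observations."""
    pos = s_obs > 0
    if pos.sum() >= 2 and np.unique(te_obs[pos]).size >= 2:
        slope, intercept = np.polyfit(te_obs[pos], np.log(s_obs[pos]), 1)
        if slope < -1.0 / T2STAR_BOUNDS_MS[1]:
            return float(np.exp(intercept)), float(-1.0 / slope)
        return float(np.exp(intercept)), T2STAR_BOUNDS_MS[1]
    smax = float(s_obs.max()) if s_obs.size else 1.0
    return max(smax, 1e-12), float(np.mean(te))


def _near_bound(x, lo, hi):
    span = hi - lo
    return (x - lo) <= _BOUND_REL * max(span, 1.0) or (hi - x) <= _BOUND_REL * max(span, 1.0)


def monoexp_nls_fit(signals, echo_times=DEFAULT_TE_MS, init: Optional[DecayParams] = None):
    """Bounded nonlinear least-squares fit of the monoexponential model.

    Unweighted residuals; bounds ``S0 in (0, 10*max(signal)]``,
    ``T2* in [1, 500] ms``.  Optimiser failure is not an exception: the
    initial (log-linear) values are returned with ``converged=False``.
    """
    te = validate_echo_times(echo_times)
    s_obs, te_obs = _as_observations(signals, te)
    if np.any(~np.isfinite(s_obs)):
        raise ValueError("signals must be finite")
    smax = float(np.max(s_obs))
    if smax <= 0:
        raise ValueError("monoexp_nls_fit requires some positive signal")
    if init is None:
        s0_init, t2_init = _default_init(s_obs, te_obs, te)
    else:
        s0_init, t2_init = init.s0, init.t2star_ms
    lo = np.array([1e-12 * smax, T2STAR_BOUNDS_MS[0]])
    hi = np.array([10.0 * smax, T2STAR_BOUNDS_MS[1]])
    x_init = np.clip([s0_init, t2_init], lo, hi)

    def fun(p):
        return monoexp_signal(p[0], p[1], te_obs) - s_obs

    fallback = DecayParams(
        s0=float(np.clip(s0_init, lo[0], hi[0])),
        t2star_ms=float(np.clip(t2_init, lo[1], hi[1])),
        x0=0.0,
    )
    try:
        res = least_squares(
            fun, x_init, bounds=(lo, hi), method="trf",
            xtol=_SOLVER_TOL, ftol=_SOLVER_TOL, gtol=_SOLVER_TOL,
        )
    except Exception:
        rnorm = float(np.linalg.norm(fun([fallback.s0, fallback.t2star_ms])))
        return fallback, FitDiagnostics(rnorm, False, s_obs.size, "monoexp_nls")
    s0_hat, t2_hat = res.x
    converged = bool(res.success) and not _near_bound(t2_hat, lo[1], hi[1])
    params = DecayParams(s0=float(s0_hat), t2star_ms=float(t2_hat), x0=0.0)
    return params, FitDiagnostics(float(np.linalg.norm(res.fun)), converged, s_obs.size, "monoexp_nls")


def noisefloor_fit(
    signals,
    echo_times=DEFAULT_TE_MS,
    init: Optional[DecayParams] = None,
    x0_bounds: Optional[tuple] = None,
):
    """Noise-floor model fit with signal-weighted residuals.

    Minimises ``sum_i r_i**2`` with ``r_i = (S_i / sum_j S_j) (S_hat_i - S_i)``
    over (S0, T2*, x0), where the normaliser runs over the voxel's full
    observation set (all echoes x all volumes) and ``S_hat`` is the
    noise-floor model at each observation's TE.  Bounds:
    ``S0 in (0, 10*max]``, ``T2* in [1, 500] ms``, ``x0 in [0, max(signal)]``
    (override the latter with ``x0_bounds``; a zero-width interval fixes x0,
    recovering the weighted monoexponential fit).

    x0 is initialised at half the minimum observed signal: the floor cannot
    exceed the smallest magnitude observed, and a mid-range start avoids the
    x0=0 boundary.
    """
    te = validate_echo_times(echo_times)
    s_obs, te_obs = _as_observations(signals, te)
    if np.any(~np.isfinite(s_obs)) or np.any(s_obs < 0):
        raise ValueError("signals must be finite and non-negative (magnitude data)")
    smax = float(np.max(s_obs))
    if smax <= 0:
        raise ValueError("noisefloor_fit requires some positive signal")
    ssum = float(np.sum(s_obs))
    w = s_obs / ssum

    if init is None:
        s0_init, t2_init = _default_init(s_obs, te_obs, te)
        x0_init = 0.5 * float(np.min(s_obs))
    else:
        s0_init, t2_init, x0_init = init.s0, init.t2star_ms, init.x0

    if x0_bounds is None:
        x0_lo, x0_hi = 0.0, smax
    else:
        x0_lo, x0_hi = float(x0_bounds[0]), float(x0_bounds[1])

    fix_x0 = (x0_hi - x0_lo) <= 1e-15
    lo = np.array([1e-12 * smax, T2STAR_BOUNDS_MS[0]])
    hi = np.array([10.0 * smax, T2STAR_BOUNDS_MS[1]])
    if not fix_x0:
        lo = np.append(lo, x0_lo)
        hi = np.append(hi, x0_hi)
    x0_fixed = 0.5 * (x0_lo + x0_hi)

    def fun(p):
        x0 = x0_fixed if fix_x0 else p[2]
        return w * (noisefloor_signal(p[0], p[1], x0, te_obs) - s_obs)

    x_init = [s0_init, t2_init] if fix_x0 else [s0_init, t2_init, x0_init]
    x_init = np.clip(x_init, lo, hi)
    fallback = DecayParams(
        s0=float(x_init[0]), t2star_ms=float(x_init[1]),
        x0=x0_fixed if fix_x0 else float(x_init[2] if len(x_init) > 2 else 0.0),
    )
    try:
        res = least_squares(
            fun, x_init, bounds=(lo, hi), method="trf",
            xtol=_SOLVER_TOL, ftol=_SOLVER_TOL, gtol=_SOLVER_TOL,
        )
    except Exception:
        rnorm = float(np.linalg.norm(fun(x_init)))
        return fallback, FitDiagnostics(rnorm, False, s_obs.size, "noisefloor")
    s0_hat, t2_hat = res.x[0], res.x[1]
    x0_hat = x0_fixed if fix_x0 else float(res.x[2])
    converged = bool(res.success) and not _near_bound(t2_hat, lo[1], hi[1])
    params = DecayParams(s0=float(s0_hat), t2star_ms=float(t2_hat), x0=x0_hat)
    return params, FitDiagnostics(float(np.linalg.norm(res.fun)), converged, s_obs.size, "noisefloor")


# ----------------------------------------------------------------------
# whole-image model / results
# ----------------------------------------------------------------------

def derive_mask(series: MultiEchoSeries, frac: float = 0.1) -> np.ndarray:
    """Default analysis mask: first-echo temporal mean above ``frac`` of the
    robust (98th percentile) image maximum."""
    mean0 = series.data[0].mean(axis=-1)
    robust_max = np.percentile(mean0, 98)
    if robust_max <= 0:
        raise ValueError("cannot derive a mask from a non-positive image")
    return mean0 > frac * robust_max


@dataclass
class T2StarResults:
    """Voxel-wise decay-parameter maps plus fit diagnostics.

    Maps share the input spatial grid.  ``failed_mask`` marks voxels whose
    data were degenerate (non-decaying or all-zero); those carry fallback
    parameters so downstream combination still has finite weights.
    """

    s0_map: np.ndarray
    t2star_map: np.ndarray
    x0_map: np.ndarray
    residual_map: np.ndarray
    converged_map: np.ndarray
    failed_mask: np.ndarray
    mask: np.ndarray
    method: str
    echo_times: np.ndarray
    n_obs_per_voxel: int
    affine: Optional[np.ndarray] = None

    @property
    def n_fitted(self) -> int:
        return int(self.mask.sum())

    @property
    def n_failed(self) -> int:
        return int(self.failed_mask.sum())

    def summary(self) -> str:
        ok = self.mask & ~self.failed_mask
        lines = [
            "T2* fit results",
            "=" * 40,
            f"method:            {self.method}",
            f"voxels in mask:    {self.n_fitted}",
            f"failed voxels:     {self.n_failed}",
            f"obs per voxel:     {self.n_obs_per_voxel}",
        ]
        if ok.any():
            lines += [
                f"T2* (ms) median:   {np.median(self.t2star_map[ok]):.2f}",
                f"T2* (ms) IQR:      [{np.percentile(self.t2star_map[ok], 25):.2f}, "
                f"{np.percentile(self.t2star_map[ok], 75):.2f}]",
                f"x0 median:         {np.median(self.x0_map[ok]):.3f}",
            ]
        return "\n".join(lines)


class T2StarModel:
    """Voxel-wise decay model over a multi-echo series.

    Parameters
    ----------
    series : MultiEchoSeries
    method : {"noisefloor", "monoexp_nls", "loglinear"}
        Estimator applied per voxel.
    use_all_volumes : bool
        When True (default) every (echo, volume) pair is an observation, as
        in whole-scan fitting; when False the per-echo temporal means are
        fitted (fast mode, n_obs = n_echo).
    mask : ndarray of bool, optional
        Overrides ``series.mask``; derived from the data when both absent.
    mask_frac : float
        Threshold fraction for the derived mask.
    """

    def __init__(self, series: MultiEchoSeries, method: str = "noisefloor",
                 use_all_volumes: bool = True, mask: Optional[np.ndarray] = None,
                 mask_frac: float = 0.1):
        if method not in ("noisefloor", "monoexp_nls", "loglinear"):
            raise ValueError(f"unknown fit method {method!r}")
        self.series = series
        self.method = method
        self.use_all_volumes = use_all_volumes
        if mask is None:
            mask = series.mask if series.mask is not None else derive_mask(series, mask_frac)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != series.spatial_shape:
            raise ValueError("mask shape does not match series spatial grid")
        if not self.mask.any():
            raise ValueError("mask is empty")

    def fit(self) -> T2StarResults:
        series, method = self.series, self.method
        shape = series.spatial_shape
        cap = T2STAR_BOUNDS_MS[1]
        s0_map = np.full(shape, np.nan)
        t2_map = np.full(shape, np.nan)
        x0_map = np.full(shape, np.nan)
        resid_map = np.full(shape, np.nan)
        conv_map = np.zeros(shape, dtype=bool)
        failed = np.zeros(shape, dtype=bool)

        te = series.echo_times
        n_obs = series.n_echoes * (series.n_volumes if self.use_all_volumes else 1)
        idx = np.argwhere(self.mask)
        for i, j, k in idx:
            sig = series.data[:, i, j, k, :]
            if not self.use_all_volumes:
                sig = sig.mean(axis=1)
            if not np.all(np.isfinite(sig)) or np.max(sig) <= 0:
                # degenerate voxel: nothing to fit
                failed[i, j, k] = True
                s0_map[i, j, k] = 0.0
                t2_map[i, j, k] = cap
                x0_map[i, j, k] = 0.0
                resid_map[i, j, k] = 0.0
                continue
            params, diag = self._fit_voxel(sig, te)
            if params is None:  # non-decaying: flagged failed with fallback
                failed[i, j, k] = True
                first_echo = sig[0] if sig.ndim > 0 else sig
                s0_map[i, j, k] = float(np.mean(first_echo))
                t2_map[i, j, k] = cap
                x0_map[i, j, k] = 0.0
                resid_map[i, j, k] = diag.residual_norm
                continue
            s0_map[i, j, k] = params.s0
            t2_map[i, j, k] = params.t2star_ms
            x0_map[i, j, k] = params.x0
            resid_map[i, j, k] = diag.residual_norm
            conv_map[i, j, k] = diag.converged

        return T2StarResults(
            s0_map=s0_map, t2star_map=t2_map, x0_map=x0_map,
            residual_map=resid_map, converged_map=conv_map, failed_mask=failed,
            mask=self.mask.copy(), method=method, echo_times=te.copy(),
            n_obs_per_voxel=n_obs, affine=series.affine,
        )

    def _fit_voxel(self, sig: np.ndarray, te: np.ndarray):
        """Fit one voxel; returns (params or None-if-failed, diagnostics)."""
        if self.method == "loglinear":
            # exclude non-positive observations from the log fit
            s_obs, te_obs = _as_observations(sig, te)
            pos = s_obs > 0
            if pos.sum() < 2 or np.unique(te_obs[pos]).size < 2:
                return None, FitDiagnostics(0.0, False, int(pos.sum()), "loglinear")
            slope, intercept = np.polyfit(te_obs[pos], np.log(s_obs[pos]), 1)
            resid = np.log(s_obs[pos]) - (slope * te_obs[pos] + intercept)
            diag = FitDiagnostics(float(np.linalg.norm(resid)), slope < 0,
                                  int(pos.sum()), "loglinear")
            if slope >= 0:
                return None, diag
            return DecayParams(float(np.exp(intercept)), float(-1.0 / slope), 0.0), diag

        # nonlinear methods: init from log-linear on positive observations
        s_obs, te_obs = _as_observations(sig, te)
        s0_i, t2_i = _default_init(s_obs, te_obs, te)
        # non-decaying log-linear slope: keep the fallback path explicit
        if t2_i >= T2STAR_BOUNDS_MS[1]:
            return None, FitDiagnostics(0.0, False, s_obs.size, self.method)
        init = DecayParams(s0_i, t2_i,
                           0.5 * float(np.min(s_obs)) if self.method == "noisefloor" else 0.0)
        if self.method == "monoexp_nls":
            return monoexp_nls_fit(sig, te, init=init)
        return noisefloor_fit(sig, te, init=init)


def fit_parameter_maps(series: MultiEchoSeries, method: str = "noisefloor",
                       use_all_volumes: bool = True, mask: Optional[np.ndarray] = None,
                       mask_frac: float = 0.1) -> T2StarResults:
    """Functional wrapper: ``T2StarModel(series, ...).fit()``."""
    return T2StarModel(series, method=method, use_all_volumes=use_all_volumes,
                       mask=mask, mask_frac=mask_frac).fit()
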