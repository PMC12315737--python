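"""Gradient-echo signal-decay models and T2*-weighted echo-combination weights.

These are the closed-form kernels the rest of the package is built on:

* the monoexponential decay ``S(TE) = S0 * exp(-TE / T2*)``,
* its magnitude-image extension with a thermal noise floor
  ``S(TE) = sqrt((S0 * exp(-TE / T2*))**2 + x0**2)``, and
* the T2*-weighted ("optimal combination") echo weights
  ``W_TE = TE * exp(-TE / T2*) / sum_n TE_n * exp(-TE_n / T2*)``.

Every function is a pure, vectorised NumPy function: scalar arguments give
scalars, parameter maps give maps, with identical semantics.  Echo times and
T2* are in **milliseconds** throughout the package; no implicit conversion to
seconds ever happens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_TE_MS",
    "EchoTimes",
    "DecayParams",
    "validate_echo_times",
    "monoexp_signal",
    "noisefloor_signal",
    "echo_weights",
]

#: Library default echo grid (ms): a five-echo multiband EPI protocol with a
#: short first echo to limit dropout in high-susceptibility regions.
DEFAULT_TE_MS = (10.60, 22.92, 35.24, 47.56, 59.88)


def validate_echo_times(te_ms) -> np.ndarray:
    """Validate an echo-time grid and return it as a float array (ms).

    Echo times must be a 1-D sequence of at least two strictly increasing,
    strictly positive, finite values.
    """
    te = np.atleast_1d(np.asarray(te_ms, dtype=float))
    if te.ndim != 1 or te.size < 2:
        raise ValueError("echo_times must be a 1-D sequence of >= 2 echo times")
    if not np.all(np.isfinite(te)):
        raise ValueError("echo_times must be finite")
    if np.any(te <= 0):
        raise ValueError("echo_times must be strictly positive (ms)")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo_times must be strictly increasing")
    return te


# Alias used in signatures elsewhere: an EchoTimes is simply a validated
# 1-D float array of echo times in ms.
EchoTimes = np.ndarray


@dataclass(frozen=True)
class DecayParams:
    """Voxel decay parameters.

    Parameters
    ----------
    s0 : float
        Initial signal magnitude at TE=0, arbitrary signal units (>= 0).
    t2star_ms : float
        Effective transverse relaxation time in ms (> 0).
    x0 : float
        Thermal noise floor in signal units (>= 0).  ``x0 = 0`` recovers the
        monoexponential model exactly.
    """

    s0: float
    t2star_ms: float
    x0: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.s0) or self.s0 < 0:
            raise ValueError(f"s0 must be finite and >= 0, got {self.s0}")
        if not np.isfinite(self.t2star_ms) or self.t2star_ms <= 0:
            raise ValueError(f"t2star_ms must be finite and > 0, got {self.t2star_ms}")
        if not np.isfinite(self.x0) or self.x0 < 0:
            raise ValueError(f"x0 must be finite and >= 0, got {self.x0}")

    def predict(self, te_ms):
        """Predicted signal magnitude at the given echo time(s)."""
        return noisefloor_signal(self.s0, self.t2star_ms, self.x0, te_ms)


def _check_te_nonneg(te_ms) -> np.ndarray:
    te = np.asarray(te_ms, dtype=float)
    if not np.all(np.isfinite(te)):
        raise ValueError("echo time must be finite")
    if np.any(te < 0):
        raise ValueError("echo time must be >= 0 ms")
    return te


def monoexp_signal(s0, t2star_ms, te_ms):
    """Monoexponential gradient-echo signal ``S0 * exp(-TE / T2*)``.

    All arguments broadcast; TE and T2* in ms.  Strictly decreasing in TE for
    ``s0 > 0`` and continuous everywhere.
    """
    te = _check_te_nonneg(te_ms)
    s0 = np.asarray(s0, dtype=float)
    t2 = np.asarray(t2star_ms, dtype=float)
    if np.any(~np.isfinite(t2)) or np.any(t2 <= 0):
        raise ValueError("t2star_ms must be finite and > 0")
    return s0 * np.exp(-te / t2)


def noisefloor_signal(s0, t2star_ms, x0, te_ms):
    """Magnitude signal with a thermal noise floor.

    ``sqrt((S0 * exp(-TE/T2*))**2 + x0**2)``: the TE-independent floor ``x0``
    dominates as the decaying component vanishes, so the value is >= x0 for
    every TE and tends to x0 as TE grows.  Models the positive bias of
    magnitude images where complex thermal noise is rectified.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(~np.isfinite(x0)) or np.any(x0 < 0):
        raise ValueError("x0 must be finite and >= 0")
    clean = monoexp_signal(s0, t2star_ms, te_ms)
    return np.sqrt(clean**2 + x0**2)


def echo_weights(t2star_ms, echo_times=DEFAULT_TE_MS):
    """T2*-weighted echo-combination weights for one or many voxels.

    ``W_TE = TE * exp(-TE/T2*) / sum_n TE_n * exp(-TE_n/T2*)``.

    The unnormalised weight ``TE * exp(-TE/T2*)`` peaks at ``TE = T2*``, the
    echo time of maximal BOLD contrast-to-noise, so each voxel's combination
    emphasises the echoes nearest its own T2*.

    Parameters
    ----------
    t2star_ms : scalar or ndarray
        T2* in ms; any shape.  Must be strictly positive — a non-positive T2*
        raises ``ValueError`` (degenerate voxels are the caller's fallback
        decision; see :func:`mebold.combine.compute_weight_map`).
    echo_times : sequence of float
        Echo grid in ms.

    Returns
    -------
    ndarray with shape ``t2star.shape + (n_echo,)``; weights are strictly
    positive and sum to 1 over the last axis.
    """
    te = validate_echo_times(echo_times)
    t2 = np.asarray(t2star_ms, dtype=float)
    if np.any(~np.isfinite(t2)) or np.any(t2 <= 0):
        raise ValueError("echo_weights requires finite t2star_ms > 0")
    unnorm = te * np.exp(-te / t2[..., np.newaxis])
    return unnorm / np.sum(unnorm, axis=-1, keepdims=True)
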