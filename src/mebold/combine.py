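"""T2*-weighted echo combination ("optimal combination", ME-WC).

Builds per-voxel, per-echo weight maps from fitted T2* and collapses the
multi-echo series into a single 4-D series by a voxel-wise weighted average.
Weights are fixed for the whole scan (time-invariant); per-volume dynamic
reweighting is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decay import echo_weights, validate_echo_times
from .fitting import MultiEchoSeries, T2StarResults

__all__ = [
    "EchoWeightMap",
    "CombinedSeries",
    "compute_weight_map",
    "weight_map_from_t2star",
    "combine_series",
]


@dataclass
class EchoWeightMap:
    """Per-voxel combination weights, shape (nx, ny, nz, n_echo).

    ``fallback_mask`` marks voxels (failed fits or voxels outside the fit
    mask) where equal weights 1/n_echo were substituted for the T2*-derived
    weights.  Weights are non-negative, time-invariant, and sum to 1 at
    every voxel.
    """

    weights: np.ndarray
    echo_times: np.ndarray
    fallback_mask: np.ndarray
    source_method: str = ""


@dataclass
class CombinedSeries:
    """Echo-combined 4-D series (x, y, z, t) with provenance."""

    data: np.ndarray
    tr_s: float
    provenance: dict = field(default_factory=dict)
    affine: Optional[np.ndarray] = None


def compute_weight_map(params: T2StarResults, echo_times=None) -> EchoWeightMap:
    """Voxel-wise combination weights from fitted T2* maps.

    Valid voxels get the T2*-weighted weights; failed voxels (and voxels
    outside the fit mask, which carry no T2* estimate) get equal weights so
    the combined image is defined everywhere.
    """
    te = validate_echo_times(params.echo_times if echo_times is None else echo_times)
    t2 = params.t2star_map
    shape = t2.shape
    n_echo = te.size
    valid = params.mask & ~params.failed_mask & np.isfinite(t2) & (t2 > 0)
    weights = np.full(shape + (n_echo,), 1.0 / n_echo)
    if valid.any():
        weights[valid] = echo_weights(t2[valid], te)
    return EchoWeightMap(
        weights=weights,
        echo_times=te.copy(),
        fallback_mask=~valid,
        source_method=params.method,
    )


def weight_map_from_t2star(t2star_map: np.ndarray, echo_times,
                           mask: Optional[np.ndarray] = None) -> EchoWeightMap:
    """Combination weights straight from a T2* map (e.g. one read from disk).

    Voxels with a finite positive T2* (inside ``mask`` when given) get
    T2*-derived weights; all others fall back to equal weights.
    """
    te = validate_echo_times(echo_times)
    t2 = np.asarray(t2star_map, dtype=float)
    valid = np.isfinite(t2) & (t2 > 0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    weights = np.full(t2.shape + (te.size,), 1.0 / te.size)
    if valid.any():
        weights[valid] = echo_weights(t2[valid], te)
    return EchoWeightMap(weights=weights, echo_times=te.copy(),
                         fallback_mask=~valid, source_method="t2star_map")


def combine_series(series: MultiEchoSeries, weights: EchoWeightMap) -> CombinedSeries:
    """Weighted average of the echo images at every time point.

    ``combined(x, t) = sum_e w(x, e) * data_e(x, t)``; with non-negative
    weights summing to 1 the result lies between the per-echo extremes at
    every voxel and time point.  Output keeps the native signal units of the
    input (no rescaling), so downstream variance comparisons remain
    meaningful after a common standardisation.
    """
    w = weights.weights
    if w.shape[:3] != series.spatial_shape:
        raise ValueError("weight map spatial grid does not match series")
    if w.shape[3] != series.n_echoes:
        raise ValueError(
            f"weight map has {w.shape[3]} echoes, series has {series.n_echoes}"
        )
    if not np.allclose(series.echo_times, weights.echo_times, atol=1e-3):
        raise ValueError("weight map echo times do not match series echo times")
    combined = np.einsum("exyzt,xyze->xyzt", series.data, w)
    return CombinedSeries(
        data=combined,
        tr_s=series.tr_s,
        provenance={
            "method": "ME-WC",
            "echo_times_ms": [float(t) for t in series.echo_times],
            "weighting": weights.source_method or "t2star",
        },
        affine=series.affine,
    )
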