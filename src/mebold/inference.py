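"""Variance comparison, multiplicity control and sample-size estimation.

* A vectorised classic (mean-centred) Levene test comparing residual
  variance between two pipelines voxel-by-voxel, with a one-sided
  alternative ("pipeline A has smaller variance than B") and a signed-Z
  representation.
* Benjamini-Hochberg FDR thresholding across voxels.
* One-sample t-test sample-size estimation by direct scan of the exact
  noncentral-t power function — the calculation behind "how many subjects
  would this effect size need?".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VarianceTestResult",
    "levene_variance_map",
    "fdr_threshold",
    "sample_size_one_sample_t",
    "percent_signal_change",
]


@dataclass
class VarianceTestResult:
    """Voxel-wise Levene statistics.

    ``p`` is one-sided for the requested direction; ``z`` is the signed
    standard-normal quantile of p (positive where the data favour the
    alternative).  ``direction`` records which group the alternative calls
    smaller.
    """

    w: np.ndarray
    p: np.ndarray
    z: np.ndarray
    direction: str
    p_two: np.ndarray | None = None


def percent_signal_change(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Scale each voxel's time series to percent of its own temporal mean.

    Puts series from different acquisitions (different native units) on a
    common scale before variance comparison.  Voxels with non-positive mean
    raise, since percent change is undefined there.
    """
    x = np.asarray(series, dtype=float)
    mean = x.mean(axis=axis, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("percent signal change undefined for non-positive means")
    return 100.0 * (x - mean) / mean


def levene_variance_map(residuals_a: np.ndarray, residuals_b: np.ndarray,
                        alternative: str = "A<B") -> VarianceTestResult:
    """Classic Levene test per voxel on two residual series.

    Inputs are (n_samples, n_voxels) arrays (a 1-D vector is treated as a
    single voxel).  The statistic is the one-way ANOVA F on absolute
    deviations from each group's mean; the two-sided p is half-split into a
    one-sided p using the observed direction of the variance difference.
    """
    if alternative not in ("A<B", "B<A"):
        raise ValueError("alternative must be 'A<B' or 'B<A'")
    a = np.atleast_2d(np.asarray(residuals_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(residuals_b, dtype=float).T).T
    if a.shape[1] != b.shape[1]:
        raise ValueError("residual series must share the voxel grid")
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 samples")

    za = np.abs(a - a.mean(axis=0))
    zb = np.abs(b - b.mean(axis=0))
    ma, mb = za.mean(axis=0), zb.mean(axis=0)
    grand = (za.sum(axis=0) + zb.sum(axis=0)) / (na + nb)
    between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    within = ((za - ma) ** 2).sum(axis=0) + ((zb - mb) ** 2).sum(axis=0)
    dof2 = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(within > 0, dof2 * between / within, 0.0)
    p_two = stats.f.sf(w, 1, dof2)

    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    observed_smaller_a = var_a < var_b
    favour = observed_smaller_a if alternative == "A<B" else ~observed_smaller_a
    p_one = np.where(favour, 0.5 * p_two, 1.0 - 0.5 * p_two)
    z = stats.norm.isf(np.clip(p_one, 1e-300, 1.0))
    direction = "A smaller" if alternative == "A<B" else "B smaller"
    return VarianceTestResult(w=w, p=p_one, z=z, direction=direction, p_two=p_two)


def fdr_threshold(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``.

    Accepts any array shape; NaNs (voxels outside the mask) are never
    rejected and do not count as tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    flat = p.ravel()
    valid = np.isfinite(flat)
    if np.any((flat[valid] < 0) | (flat[valid] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject = np.zeros(flat.size, dtype=bool)
    if valid.any():
        reject[valid] = multipletests(flat[valid], alpha=q, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def _one_sample_t_power(n: int, d: float, alpha: float, two_sided: bool) -> float:
    """Exact power of the one-sample t-test at effect size d (Cohen)."""
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        crit = stats.t.isf(alpha / 2.0, df)
        return stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
    crit = stats.t.isf(alpha, df)
    return stats.nct.sf(crit, df, nc)


def sample_size_one_sample_t(effect_size_d: float, alpha: float = 0.05,
                             power: float = 0.80, two_sided: bool = True,
                             n_max: int = 100000) -> int:
    """Smallest n whose one-sample t-test power reaches the target.

    Scans n = 2, 3, ... evaluating the exact noncentral-t power at
    noncentrality ``d * sqrt(n)``; no approximation is involved.
    """
    if not effect_size_d > 0:
        raise ValueError("effect_size_d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if _one_sample_t_power(n, effect_size_d, alpha, two_sided) >= power:
            return n
    raise ValueError(f"required n exceeds {n_max}")
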