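"""Mass-univariate GLM with global AR(1) prewhitening.

The estimator follows the standard task-fMRI recipe: a first-pass OLS fit,
a single lag-1 autoregressive coefficient pooled across all in-mask voxels,
prewhitening of both data and design with the AR(1) transform, and a
refit.  Contrast t statistics are mapped to Z scores through the
t -> standard-normal quantile map at the model's residual degrees of
freedom.

Exposed statsmodels-style: :class:`FMRIGLM` is the model,
:meth:`FMRIGLM.fit` returns :class:`GLMResults` carrying betas, residual
variance, the pooled rho, dof and contrast machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import linalg as sp_linalg
from scipy import ndimage
from scipy import stats

from .combine import CombinedSeries
from .design import DesignMatrix

__all__ = [
    "FMRIGLM",
    "GLMResults",
    "ContrastResult",
    "fit_glm_ar1",
    "contrast_zmap",
    "contrast_cnr",
    "smooth_gaussian",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _collinear_names(X: np.ndarray, names) -> list:
    """Columns implicated in a rank deficiency (pivoted-QR diagnostic)."""
    _, R, piv = sp_linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    bad = [names[piv[i]] for i in range(len(d)) if d[i] <= tol]
    return bad


def _ar1_whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) prewhitening transform along axis 0."""
    W = np.empty_like(A)
    W[0] = np.sqrt(1.0 - rho**2) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


def _debias_rho(rho_obs: float, X: np.ndarray) -> float:
    """Correct the OLS-residual lag-1 autocorrelation for projection bias.

    Residuals ``r = M e`` (M the residual-forming matrix of X) have
    ``E[sum r_t r_{t-1}] = tr(L M O(rho) M)`` and ``E[sum r^2] =
    tr(M O(rho) M)`` with O the AR(1) correlation matrix and L the
    symmetric lag-1 operator; the raw pooled ratio therefore underestimates
    rho.  Invert that expectation map for the observed ratio.
    """
    from scipy.optimize import brentq

    n = X.shape[0]
    M = np.eye(n) - X @ np.linalg.pinv(X)
    lag = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))

    def expected(rho):
        if rho == 0.0:
            omega = np.eye(n)
        else:
            omega = np.sign(rho) ** lag * np.abs(rho) ** lag
        momm = M @ omega @ M
        den = np.trace(momm)
        num = np.trace(momm, offset=1)
        return num / den

    f = lambda rho: expected(rho) - rho_obs
    lo, hi = -0.98, 0.98
    try:
        if f(lo) * f(hi) > 0:
            return rho_obs
        return float(brentq(f, lo, hi, xtol=1e-6))
    except Exception:
        return rho_obs


@dataclass
class ContrastResult:
    """Effect size, t and Z maps for one contrast."""

    effect: np.ndarray
    t: np.ndarray
    z: np.ndarray
    contrast: np.ndarray
    dof: float


class GLMResults:
    """Fitted mass-univariate GLM.

    Attributes
    ----------
    params : ndarray (n_regressors, n_voxels)
        Whitened-model beta estimates.
    sigma2 : ndarray (n_voxels,)
        Residual variance of the whitened model.
    rho : float
        Pooled global AR(1) coefficient estimated from first-pass residuals.
    dof : int
        Residual degrees of freedom (n_volumes - rank(X)).
    resid_white : ndarray (n_volumes, n_voxels)
        Whitened residuals (inputs to variance comparisons).
    """

    def __init__(self, model: "FMRIGLM", params, sigma2, rho, dof,
                 resid_white, xtx_inv):
        self.model = model
        self.design = model.design
        self.params = params
        self.sigma2 = sigma2
        self.rho = float(rho)
        self.dof = int(dof)
        self.resid_white = resid_white
        self._xtx_inv = xtx_inv

    # -- map helpers ----------------------------------------------------
    def _unmask(self, values: np.ndarray) -> np.ndarray:
        if self.model.spatial_shape is None:
            return values
        out = np.full(self.model.spatial_shape, np.nan)
        out[self.model.mask] = values
        return out

    def beta_map(self, name: str) -> np.ndarray:
        idx = self.design.names.index(name)
        return self._unmask(self.params[idx])

    @property
    def sigma2_map(self) -> np.ndarray:
        return self._unmask(self.sigma2)

    # -- inference ------------------------------------------------------
    def contrast(self, contrast) -> ContrastResult:
        """Contrast estimate, t and Z maps.

        ``t = c' beta / sqrt(sigma2 * c' (X'X)^-1 c)`` on whitened
        quantities; Z via the exact t -> normal quantile map at the model
        dof, so a null contrast yields Z ~ N(0, 1).
        """
        c = self.design.contrast_vector(contrast)
        var_c = float(c @ self._xtx_inv @ c)
        if var_c <= 0:
            raise ValueError("contrast has zero variance under this design")
        effect = c @ self.params
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(self.sigma2 * var_c)
        p_one = stats.t.sf(np.abs(t), self.dof)
        z = np.sign(t) * stats.norm.isf(np.clip(p_one, 1e-300, 1.0))
        return ContrastResult(
            effect=self._unmask(effect), t=self._unmask(t), z=self._unmask(z),
            contrast=c, dof=self.dof,
        )

    def cnr(self, contrast) -> np.ndarray:
        """Contrast-to-noise ratio: contrast estimate / residual SD.

        Noiseless voxels (zero residual variance) yield +/-inf, flagging a
        degenerate fit rather than hiding it.
        """
        c = self.design.contrast_vector(contrast)
        effect = c @ self.params
        with np.errstate(divide="ignore", invalid="ignore"):
            out = effect / np.sqrt(self.sigma2)
        return self._unmask(out)

    def summary(self) -> str:
        lines = [
            "GLM (global AR(1) prewhitening)",
            "=" * 40,
            f"volumes:         {self.design.n_volumes}",
            f"regressors:      {len(self.design.names)}",
            f"voxels:          {self.params.shape[1]}",
            f"AR(1) rho:       {self.rho:.4f}",
            f"residual dof:    {self.dof}",
            f"median sigma^2:  {np.median(self.sigma2):.4g}",
        ]
        return "\n".join(lines)


class FMRIGLM:
    """Mass-univariate GLM over a 4-D series (or an already-masked 2-D
    (time x voxel) array).

    Parameters
    ----------
    data : ndarray or CombinedSeries
        4-D (x, y, z, t), or 2-D (t, n_voxels).
    design : DesignMatrix
    mask : ndarray of bool, optional
        Required semantics for 4-D input: voxels to fit.  Default: voxels
        with nonzero temporal variance.
    """

    def __init__(self, data: Union[np.ndarray, CombinedSeries],
                 design: DesignMatrix, mask: Optional[np.ndarray] = None):
        if isinstance(data, CombinedSeries):
            data = data.data
        data = np.asarray(data, dtype=float)
        if data.ndim == 4:
            self.spatial_shape = data.shape[:3]
            if mask is None:
                mask = data.std(axis=-1) > 0
            self.mask = np.asarray(mask, dtype=bool)
            if self.mask.shape != self.spatial_shape:
                raise ValueError("mask shape does not match data grid")
            self.Y = data[self.mask].T  # (t, n_vox)
        elif data.ndim == 2:
            self.spatial_shape = None
            self.mask = None
            self.Y = data
        else:
            raise ValueError("data must be 4-D (x,y,z,t) or 2-D (t, voxels)")
        if self.Y.shape[0] != design.n_volumes:
            raise ValueError(
                f"data has {self.Y.shape[0]} volumes, design has {design.n_volumes}"
            )
        if self.Y.shape[1] == 0:
            raise ValueError("mask selects no voxels")
        self.design = design

    def fit(self) -> GLMResults:
        X = self.design.matrix
        names = self.design.names
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_names(X, names)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

        Y = self.Y
        # first pass: OLS
        pinv = np.linalg.pinv(X)
        beta0 = pinv @ Y
        resid = Y - X @ beta0
        # pooled global lag-1 autocorrelation
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid**2))
        rho_raw = num / den if den > 0 else 0.0
        rho = _debias_rho(rho_raw, X)
        rho = float(np.clip(rho, -0.999, 0.999))

        Xw = _ar1_whiten(X, rho)
        Yw = _ar1_whiten(Y, rho)
        pinv_w = np.linalg.pinv(Xw)
        beta = pinv_w @ Yw
        resid_w = Yw - Xw @ beta
        dof = X.shape[0] - rank
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        sigma2 = np.sum(resid_w**2, axis=0) / dof
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        return GLMResults(self, beta, sigma2, rho, dof, resid_w, xtx_inv)


def fit_glm_ar1(data, design: DesignMatrix, mask=None) -> GLMResults:
    """Functional wrapper: ``FMRIGLM(data, design, mask).fit()``."""
    return FMRIGLM(data, design, mask=mask).fit()


def contrast_zmap(result: GLMResults, contrast) -> ContrastResult:
    """Functional wrapper around :meth:`GLMResults.contrast`."""
    return result.contrast(contrast)


def contrast_cnr(result: GLMResults, contrast) -> np.ndarray:
    """Functional wrapper around :meth:`GLMResults.cnr`."""
    return result.cnr(contrast)


#: Boundary handling used by :func:`smooth_gaussian` (kernel mass is
#: preserved at interior voxels; edges use reflection).
SMOOTH_BOUNDARY_MODE = "reflect"


def smooth_gaussian(data: np.ndarray, fwhm_mm: float = 8.0,
                    voxel_size_mm=2.4) -> np.ndarray:
    """Spatial Gaussian smoothing of a 3-D map or 4-D series.

    ``sigma_mm = FWHM / (2 sqrt(2 ln 2))`` per spatial axis, applied
    separably; the time axis of a 4-D series is untouched.  ``fwhm_mm = 0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    data = np.asarray(data, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError("data must be 3-D or 4-D")
    if fwhm_mm == 0:
        return data.copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float).ravel(), (3,)) \
        if np.ndim(voxel_size_mm) else np.full(3, float(voxel_size_mm))
    if np.any(vox <= 0):
        raise ValueError("voxel sizes must be > 0")
    sigma_vox = (fwhm_mm * _FWHM_TO_SIGMA) / vox
    sigma = list(sigma_vox) + ([0.0] if data.ndim == 4 else [])
    return ndimage.gaussian_filter(data, sigma=sigma, mode=SMOOTH_BOUNDARY_MODE)
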