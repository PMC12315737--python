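"""GLM with global AR(1) prewhitening, contrasts, CNR and smoothing."""

import numpy as np
import pytest

import mebold as mb


def simple_design(n=200, tr=2.0):
    onsets = np.arange(10.0, n * tr - 40, 34.0)
    events = mb.make_event_table(onsets, np.full(onsets.size, 2.0),
                                 ["task"] * onsets.size)
    return mb.build_design_matrix(n, tr, events=events, conditions=["task"])


def ar1_noise(rng, rho, shape):
    n = shape[0]
    eps = rng.normal(size=shape)
    out = np.empty(shape)
    out[0] = eps[0] / np.sqrt(1 - rho**2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t]
    return out


class TestFitGlmAr1:
    def test_noiseless_recovery_is_exact(self):
        d = simple_design()
        X = d.matrix
        beta_true = np.array([2.0, 0.3, -0.1, 1.5, 10.0])[: X.shape[1]]
        beta_true = np.resize(beta_true, X.shape[1])
        Y = X @ np.tile(beta_true[:, None], (1, 4))
        res = mb.fit_glm_ar1(Y, d)
        np.testing.assert_allclose(res.params, np.tile(beta_true[:, None], (1, 4)),
                                   atol=1e-8)
        assert np.all(res.sigma2 < 1e-16)

    def test_ar1_rho_recovered_and_residuals_whitened(self):
        rng = np.random.default_rng(42)
        d = simple_design()
        n = d.n_volumes
        Y = ar1_noise(rng, 0.3, (n, 500))
        res = mb.fit_glm_ar1(Y, d)
        assert res.rho == pytest.approx(0.3, abs=0.05)
        r = res.resid_white
        lag1 = np.sum(r[1:] * r[:-1]) / np.sum(r**2)
        assert abs(lag1) < 0.05

    def test_voxel_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        d = simple_design()
        Y = rng.normal(size=(d.n_volumes, 20))
        perm = rng.permutation(20)
        res_a = mb.fit_glm_ar1(Y, d)
        res_b = mb.fit_glm_ar1(Y[:, perm], d)
        np.testing.assert_allclose(res_a.params[:, perm], res_b.params, atol=1e-12)

    def test_rank_deficiency_names_columns(self):
        d = simple_design()
        frame = d.frame.copy()
        frame["task_copy"] = frame["task"]
        dupe = mb.DesignMatrix(frame=frame, tr_s=d.tr_s,
                               groups={**d.groups, "task": ["task", "task_copy"]})
        Y = np.ones((d.n_volumes, 3))
        with pytest.raises(ValueError, match="task"):
            mb.fit_glm_ar1(Y, dupe)


class TestContrasts:
    def test_scale_invariance_of_z(self):
        rng = np.random.default_rng(5)
        d = simple_design()
        Y = rng.normal(size=(d.n_volumes, 50)) + 0.5 * d.frame["task"].to_numpy()[:, None]
        res = mb.fit_glm_ar1(Y, d)
        c = np.zeros(len(d.names)); c[d.names.index("task")] = 1.0
        z1 = res.contrast(c).z
        z2 = res.contrast(2.0 * c).z
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_null_contrast_z_is_standard_normal(self):
        rng = np.random.default_rng(6)
        d = simple_design()
        Y = rng.normal(size=(d.n_volumes, 4000))
        res = mb.fit_glm_ar1(Y, d)
        z = res.contrast("task").z
        assert abs(z.mean()) < 0.05
        assert z.std() == pytest.approx(1.0, abs=0.05)

    def test_4d_input_returns_maps(self):
        rng = np.random.default_rng(7)
        d = simple_design(n=60)
        data = rng.normal(10, 1, (4, 4, 2, 60))
        res = mb.fit_glm_ar1(data, d)
        con = res.contrast("task")
        assert con.z.shape == (4, 4, 2)
        assert np.isfinite(con.z).all()


class TestCnr:
    def test_doubling_noise_halves_cnr(self):
        rng = np.random.default_rng(8)
        d = simple_design()
        task = d.frame["task"].to_numpy()[:, None]
        noise = rng.normal(size=(d.n_volumes, 400))
        cnr1 = mb.fit_glm_ar1(2.0 * task + noise, d).cnr("task")
        cnr2 = mb.fit_glm_ar1(2.0 * task + 2.0 * noise, d).cnr("task")
        assert np.mean(cnr1) / np.mean(cnr2) == pytest.approx(2.0, rel=0.1)

    def test_inactive_voxels_centre_on_zero(self):
        rng = np.random.default_rng(9)
        d = simple_design()
        cnr = mb.fit_glm_ar1(rng.normal(size=(d.n_volumes, 2000)), d).cnr("task")
        assert abs(np.mean(cnr)) < 0.02

    def test_noiseless_voxel_flagged_infinite(self):
        d = simple_design(n=60)
        Y = np.tile(d.frame["task"].to_numpy()[:, None], (1, 2))
        res = mb.fit_glm_ar1(Y, d)
        cnr = res.cnr("task")
        # residual variance is zero up to float rounding: CNR blows up
        assert np.all(np.isinf(cnr) | (cnr > 1e10))


class TestSmoothGaussian:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(6, 6, 4))
        np.testing.assert_array_equal(mb.smooth_gaussian(data, 0.0, 2.4), data)

    def test_delta_mass_preserved_in_interior(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 5.0
        sm = mb.smooth_gaussian(data, 8.0, 2.4)
        assert sm.sum() == pytest.approx(5.0, rel=1e-6)

    def test_white_noise_variance_reduction_matches_kernel_norm(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(40, 40, 40))
        fwhm, vox = 8.0, 2.4
        sm = mb.smooth_gaussian(data, fwhm, vox)
        # discrete kernel sum of squares along one axis
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        half = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        expected = (k**2).sum() ** 3
        inner = sm[8:-8, 8:-8, 8:-8]
        assert inner.var() / data.var() == pytest.approx(expected, rel=0.1)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            mb.smooth_gaussian(np.zeros((4, 4, 4)), -1.0, 2.4)

    def test_time_axis_untouched(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(8, 8, 4, 10))
        sm = mb.smooth_gaussian(data, 8.0, 2.4)
        per_vol = [mb.smooth_gaussian(data[..., t], 8.0, 2.4) for t in range(10)]
        np.testing.assert_allclose(sm, np.stack(per_vol, axis=-1), atol=1e-10)
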