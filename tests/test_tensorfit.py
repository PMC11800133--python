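import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from alps_glymph.acquisition import make_scheme
from alps_glymph.phantom import DWIVolume, add_rician_noise, tensor_signal
from alps_glymph.tensorfit import (axis_diffusivities, color_fa, design_matrix,
                                   eigendecompose, fit_tensor_loglinear,
                                   fractional_anisotropy)
from conftest import random_spd_tensor

SCHEME = make_scheme(30, 1000.0, 1)


def _volume_from_tensors(tensors, scheme=SCHEME, s0=500.0):
    """Stack a list of tensors into a (n, 1, 1) DWI volume."""
    data = np.stack([tensor_signal(D, scheme, s0) for D in tensors])
    return DWIVolume(data[:, None, None, :], np.eye(4), scheme)


class TestLogLinearFit:
    def test_noiseless_round_trip(self):
        rng = np.random.default_rng(0)
        tensors = [random_spd_tensor(rng) for _ in range(50)]
        field = fit_tensor_loglinear(_volume_from_tensors(tensors))
        err = np.abs(field.as_matrices()[:, 0, 0] - np.stack(tensors))
        assert err.max() < 1e-10

    def test_isotropic_voxel_fa_zero(self):
        field = fit_tensor_loglinear(_volume_from_tensors([np.eye(3) * 0.9e-3]))
        feats = eigendecompose(field)
        assert np.allclose(feats.evals[0, 0, 0], 0.9e-3, rtol=1e-10)
        assert feats.fa[0, 0, 0] < 1e-8

    def test_matches_independent_lstsq_oracle(self):
        """OLS estimates agree with a from-scratch design-matrix solve."""
        rng = np.random.default_rng(1)
        tensors = [random_spd_tensor(rng) for _ in range(100)]
        dwi = _volume_from_tensors(tensors)
        noisy = add_rician_noise(dwi, sigma=5.0, seed=2)
        field = fit_tensor_loglinear(noisy)

        b, g = SCHEME.bvalues, SCHEME.bvectors
        X = np.column_stack([
            -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2], np.ones_like(b),
        ])
        for i in range(0, 100, 7):
            y = np.log(noisy.data[i, 0, 0])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.allclose(field.components[i, 0, 0], beta[:6], rtol=0, atol=1e-12)

    def test_wls_agrees_with_ols_on_noiseless_data(self):
        rng = np.random.default_rng(3)
        tensors = [random_spd_tensor(rng) for _ in range(100)]
        dwi = _volume_from_tensors(tensors)
        ols = fit_tensor_loglinear(dwi, weighted=False)
        wls = fit_tensor_loglinear(dwi, weighted=True)
        rel = np.abs(wls.components - ols.components) / np.abs(ols.components).max()
        assert rel.max() < 1e-6

    def test_all_zero_voxel_dropped_from_mask(self):
        dwi = _volume_from_tensors([np.eye(3) * 1e-3, np.eye(3) * 1e-3])
        dwi.data[1] = 0.0
        field = fit_tensor_loglinear(dwi)
        assert field.mask[0, 0, 0]
        assert not field.mask[1, 0, 0]

    def test_median_bias_small_under_rician_noise(self):
        """1% Rician noise: median component bias below 2% of the truth."""
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        D = Q @ np.diag([1.6e-3, 0.5e-3, 0.3e-3]) @ Q.T
        s0 = 1000.0
        dwi = _volume_from_tensors([D] * 1000, s0=s0)
        noisy = add_rician_noise(dwi, sigma=0.01 * s0, seed=5)
        field = fit_tensor_loglinear(noisy)
        est = field.as_matrices()[:, 0, 0]
        bias = np.median(est, axis=0) - D
        assert np.all(np.abs(bias) < 0.02 * np.abs(D))


class TestEigenFeatures:
    def test_diagonal_tensor(self):
        field = fit_tensor_loglinear(_volume_from_tensors([np.diag([3e-3, 2e-3, 1e-3])]))
        feats = eigendecompose(field)
        assert np.allclose(feats.evals[0, 0, 0], [3e-3, 2e-3, 1e-3], rtol=1e-9)
        assert np.allclose(np.abs(feats.evecs[0, 0, 0, :, 0]), [1, 0, 0], atol=1e-9)

    def test_eigenvalues_rotation_invariant(self):
        rng = np.random.default_rng(6)
        D = np.diag([1.8e-3, 0.6e-3, 0.2e-3])
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = Q @ D @ Q.T
        f1 = fit_tensor_loglinear(_volume_from_tensors([D]))
        f2 = fit_tensor_loglinear(_volume_from_tensors([rotated]))
        e1 = eigendecompose(f1).evals[0, 0, 0]
        e2 = eigendecompose(f2).evals[0, 0, 0]
        assert np.allclose(e1, e2, atol=1e-12)

    def test_eigenvector_sign_convention(self):
        field = fit_tensor_loglinear(_volume_from_tensors([np.diag([3e-3, 2e-3, 1e-3])]))
        v1 = eigendecompose(field).evecs[0, 0, 0, :, 0]
        nonzero = v1[np.abs(v1) > 1e-12]
        assert nonzero[0] > 0


class TestFractionalAnisotropy:
    def test_equal_eigenvalues_zero(self):
        assert fractional_anisotropy(np.array([1e-3, 1e-3, 1e-3])) == 0.0

    def test_stick_is_one(self):
        assert fractional_anisotropy(np.array([2e-3, 0.0, 0.0])) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        fa = fractional_anisotropy(np.array([1.2e-3, 0.3e-3, 0.3e-3]))
        assert fa == pytest.approx(np.sqrt(1.5) * np.sqrt(0.54 / 1.62), rel=1e-12)
        assert fa == pytest.approx(0.7071, abs=1e-4)

    def test_all_zero_returns_zero(self):
        assert fractional_anisotropy(np.zeros(3)) == 0.0

    @given(
        lams=hst.lists(hst.floats(1e-5, 3e-3), min_size=3, max_size=3),
        c=hst.floats(0.1, 50.0),
    )
    def test_scale_invariance(self, lams, c):
        lams = np.array(lams)
        assert fractional_anisotropy(c * lams) == pytest.approx(
            fractional_anisotropy(lams), abs=1e-12
        )


class TestColorFA:
    def test_pure_z_fiber(self):
        field = fit_tensor_loglinear(_volume_from_tensors([np.diag([0.2e-3, 0.2e-3, 1.51e-3])]))
        feats = eigendecompose(field)
        rgb = color_fa(feats)[0, 0, 0]
        assert rgb[0] == pytest.approx(0.0, abs=1e-9)
        assert rgb[1] == pytest.approx(0.0, abs=1e-9)
        assert rgb[2] == pytest.approx(feats.fa[0, 0, 0], rel=1e-9)

    def test_isotropic_is_black(self):
        field = fit_tensor_loglinear(_volume_from_tensors([np.eye(3) * 1e-3]))
        assert np.allclose(color_fa(eigendecompose(field))[0, 0, 0], 0.0, atol=1e-8)

    def test_oblique_fiber_hand_value(self):
        # v1 = (1,1,1)/sqrt(3), FA = 0.6 -> each channel 0.6/sqrt(3) = 0.3464
        v1 = np.ones(3) / np.sqrt(3)
        from alps_glymph.tensorfit import TensorFeatures
        feats = TensorFeatures(
            evals=np.zeros((1, 3)), evecs=v1.reshape(1, 3, 1) * np.ones((1, 3, 3)),
            fa=np.array([0.6]), color=np.clip(0.6 * np.abs(v1)[None, :], 0, 1),
            dxx=None, dyy=None, dzz=None, mask=None, affine=np.eye(4),
        )
        assert np.allclose(color_fa(feats), 0.3464, atol=1e-4)


class TestAxisDiffusivities:
    def test_diagonal_tensor_maps(self):
        D = np.diag([1.2e-3, 0.8e-3, 1.7e-3])
        field = fit_tensor_loglinear(_volume_from_tensors([D]))
        dxx, dyy, dzz = axis_diffusivities(field)
        assert dxx[0, 0, 0] == pytest.approx(1.2e-3, rel=1e-10)
        assert dyy[0, 0, 0] == pytest.approx(0.8e-3, rel=1e-10)
        assert dzz[0, 0, 0] == pytest.approx(1.7e-3, rel=1e-10)

    def test_trace_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(7)
        tensors = [random_spd_tensor(rng) for _ in range(20)]
        field = fit_tensor_loglinear(_volume_from_tensors(tensors))
        dxx, dyy, dzz = axis_diffusivities(field)
        trace = dxx + dyy + dzz
        esum = eigendecompose(field).evals.sum(axis=-1)
        assert np.allclose(trace, esum, rtol=1e-12)

    def test_rotation_about_z_swaps_dxx_dyy(self):
        D = np.diag([1.5e-3, 0.4e-3, 0.9e-3])
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rotated = Rz @ D @ Rz.T
        field = fit_tensor_loglinear(_volume_from_tensors([D, rotated]))
        dxx, dyy, _ = axis_diffusivities(field)
        assert dxx[1, 0, 0] == pytest.approx(dyy[0, 0, 0], rel=1e-9)
        assert dyy[1, 0, 0] == pytest.approx(dxx[0, 0, 0], rel=1e-9)
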