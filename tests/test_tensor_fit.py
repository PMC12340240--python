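"""Tensor fitting: exact recovery, oracles, metrics, invariances."""

import numpy as np
import pytest

from bsdti import (DwiDataset, Geometry, PhantomSpec, axisymmetric_tensor,
                   compute_metrics, fit_tensor, make_field, make_protocol,
                   simulate_dwi, simulate_phantom_pair)
from bsdti.bsd_calibration import BMatrixField
from bsdti.gradient_scheme import GradientScheme, design_matrix, nominal_b_matrix


def _tiny_dataset(scheme, tensors, geometry=None, noise=0.0, seed=0,
                  scales=None, s0=1000.0):
    """Noise-controlled dataset on a tiny grid from per-voxel tensors."""
    tensors = np.asarray(tensors)
    n_vox = tensors.shape[0]
    geometry = geometry or Geometry.centered((n_vox, 1, 1), 2.5)
    X = design_matrix(scheme.bmats)                   # (n_entries, 6)
    d6 = np.stack([tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2],
                   tensors[:, 0, 1], tensors[:, 0, 2], tensors[:, 1, 2]], axis=1)
    expo = d6 @ X.T                                   # (V, n)
    if scales is not None:
        expo[:, scheme.weighted_mask] *= scales       # (V, n_weighted)
    sig = s0 * np.exp(-expo)
    if noise:
        sig = sig + np.random.default_rng(seed).normal(0, noise, sig.shape)
    return DwiDataset(geometry=geometry,
                      signals=sig.reshape(geometry.shape + (len(scheme),)),
                      scheme=scheme)


def _random_tensors(n, seed=0, fa_max=0.8):
    rng = np.random.default_rng(seed)
    return np.array([
        axisymmetric_tensor(rng.uniform(0, fa_max), rng.uniform(4e-4, 2e-3),
                            rng.standard_normal(3))
        for _ in range(n)
    ])


class TestExactRecovery:
    @pytest.mark.parametrize("name", ["1000/2000(40)", "1000(20)", "1000(6)"])
    def test_noise_free_recovery(self, name):
        scheme = make_protocol(name)
        T = _random_tensors(8, seed=1)
        ds = _tiny_dataset(scheme, T)
        tf = fit_tensor(ds, mode="STD", weighting="wlls")
        rel = np.abs(tf.tensors.reshape(-1, 3, 3) - T).max() / np.abs(T).max()
        assert rel < 1e-10

    def test_six_direction_fit_equals_direct_solve(self):
        scheme = make_protocol("1000(6)")
        T = _random_tensors(5, seed=2)
        ds = _tiny_dataset(scheme, T)
        tf = fit_tensor(ds, mode="STD", weighting="ols")
        X = design_matrix(scheme.bmats[scheme.weighted_mask])  # 6x6, invertible
        a0 = ds.signals[..., scheme.b0_mask].mean(axis=-1).reshape(-1)
        aw = ds.signals[..., scheme.weighted_mask].reshape(-1, 6)
        for v in range(5):
            y = -np.log(aw[v] / a0[v])
            d6 = np.linalg.inv(X) @ y
            D = np.array([[d6[0], d6[3], d6[4]],
                          [d6[3], d6[1], d6[5]],
                          [d6[4], d6[5], d6[2]]])
            np.testing.assert_allclose(tf.tensors.reshape(-1, 3, 3)[v], D,
                                       rtol=1e-9, atol=1e-15)


class TestOracleEquivalence:
    def test_ols_matches_normal_equations(self):
        scheme = make_protocol("1000(20)")
        T = _random_tensors(10, seed=3)
        ds = _tiny_dataset(scheme, T, noise=5.0, seed=4)
        tf = fit_tensor(ds, mode="STD", weighting="ols")
        X = design_matrix(scheme.bmats[scheme.weighted_mask])
        a0 = ds.signals[..., scheme.b0_mask].mean(axis=-1).reshape(-1)
        aw = ds.signals[..., scheme.weighted_mask].reshape(-1, 20)
        for v in range(10):
            y = -np.log(aw[v] / a0[v])
            d6 = np.linalg.solve(X.T @ X, X.T @ y)
            got = tf.tensors.reshape(-1, 3, 3)[v]
            assert np.isclose(got[0, 0], d6[0], rtol=1e-9)
            assert np.isclose(got[0, 1], d6[3], rtol=1e-9)

    def test_wlls_matches_one_step_reweighted_solve(self):
        scheme = make_protocol("1000(11)")
        T = _random_tensors(6, seed=5)
        ds = _tiny_dataset(scheme, T, noise=5.0, seed=6)
        tf = fit_tensor(ds, mode="STD", weighting="wlls")
        X = design_matrix(scheme.bmats[scheme.weighted_mask])
        a0 = ds.signals[..., scheme.b0_mask].mean(axis=-1).reshape(-1)
        aw = ds.signals[..., scheme.weighted_mask].reshape(-1, 11)
        for v in range(6):
            y = -np.log(aw[v] / a0[v])
            W = np.diag(aw[v] ** 2)
            d6 = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
            assert np.isclose(tf.tensors.reshape(-1, 3, 3)[v][0, 0], d6[0],
                              rtol=1e-9)

    def test_bsd_uses_per_voxel_scales(self):
        scheme = make_protocol("1000(20)")
        T = _random_tensors(4, seed=7)
        geom = Geometry.centered((4, 1, 1), 2.5)
        rng = np.random.default_rng(8)
        scales = 1.0 + 0.05 * rng.uniform(-1, 1, size=(4, scheme.n_weighted))
        full_scales = np.ones((4, 1, 1, len(scheme)))
        full_scales[..., scheme.weighted_mask] = scales.reshape(4, 1, 1, -1)
        ds = _tiny_dataset(scheme, T, geometry=geom, scales=scales)
        bf = BMatrixField(geometry=geom, scheme=scheme, scales=full_scales,
                          valid=np.ones(geom.shape, dtype=bool))
        tf = fit_tensor(ds, field=bf, mode="BSD", weighting="ols")
        rel = np.abs(tf.tensors.reshape(-1, 3, 3) - T).max() / np.abs(T).max()
        assert rel < 1e-10


class TestMetrics:
    def test_isotropic_eigenvalues(self):
        tf = _metric_stub(np.array([[2e-3, 2e-3, 2e-3]]))
        mm = compute_metrics(tf)
        assert np.isclose(mm.fa.ravel()[0], 0.0)
        for vol in (mm.md, mm.ad, mm.rd):
            assert np.isclose(vol.ravel()[0], 2e-3)

    def test_stick_eigenvalues(self):
        tf = _metric_stub(np.array([[1e-3, 0.0, 0.0]]))
        mm = compute_metrics(tf)
        assert np.isclose(mm.fa.ravel()[0], 1.0)
        assert np.isclose(mm.md.ravel()[0], 1e-3 / 3, rtol=1e-6)
        assert np.isclose(mm.ad.ravel()[0], 1e-3)
        assert np.isclose(mm.rd.ravel()[0], 0.0)

    def test_all_zero_eigenvalues_define_fa_zero(self):
        mm = compute_metrics(_metric_stub(np.array([[0.0, 0.0, 0.0]])))
        assert mm.fa.ravel()[0] == 0.0

    def test_round_trip_with_generator_tensor(self):
        T = axisymmetric_tensor(0.3, 8.3e-4, (0, 1, 0))
        lam = np.linalg.eigvalsh(T)[::-1]
        mm = compute_metrics(_metric_stub(lam[None]))
        assert np.isclose(mm.fa.ravel()[0], 0.3, atol=1e-12)
        assert np.isclose(mm.md.ravel()[0], 8.3e-4, rtol=1e-12)


def _metric_stub(eigenvalues):
    from bsdti.tensor_fit import TensorField

    n = eigenvalues.shape[0]
    geom = Geometry.centered((n, 1, 1), 1.0)
    return TensorField(geometry=geom,
                       tensors=np.zeros((n, 1, 1, 3, 3)),
                       eigenvalues=eigenvalues.reshape(n, 1, 1, 3),
                       principal_axis=np.zeros((n, 1, 1, 3)),
                       mask=np.ones((n, 1, 1), dtype=bool),
                       mode="STD", weighting="ols",
                       residual=np.zeros((n, 1, 1)))


class TestInvariances:
    def test_rotation_equivariance_of_metrics(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [31.0, -12.0, 57.0], degrees=True).as_matrix()
        base = make_protocol("1000(20)")
        T = _random_tensors(6, seed=10)
        ds = _tiny_dataset(base, T)
        mm = compute_metrics(fit_tensor(ds, mode="STD", weighting="ols"))

        dirs_rot = base.directions.copy()
        wm = base.weighted_mask
        dirs_rot[wm] = base.directions[wm] @ R.T
        rot_scheme = GradientScheme.from_bvals_bvecs(base.bvals, dirs_rot)
        T_rot = np.einsum("ij,vjk,lk->vil", R, T, R)
        ds_rot = _tiny_dataset(rot_scheme, T_rot)
        mm_rot = compute_metrics(fit_tensor(ds_rot, mode="STD", weighting="ols"))
        for a, b in zip(mm.as_dict().values(), mm_rot.as_dict().values()):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_std_equals_bsd_under_unit_field(self):
        scheme = make_protocol("1000(11)")
        T = _random_tensors(5, seed=11)
        ds = _tiny_dataset(scheme, T, noise=5.0, seed=12)
        unit = BMatrixField.unit(ds.geometry, scheme)
        m_std = compute_metrics(fit_tensor(ds, mode="STD"))
        m_bsd = compute_metrics(fit_tensor(ds, field=unit, mode="BSD"))
        for a, b in zip(m_std.as_dict().values(), m_bsd.as_dict().values()):
            np.testing.assert_array_equal(a, b)

    def test_phantom_fa_nondecreasing_in_noise(self):
        geom = Geometry.centered((14, 14, 14), 2.5)
        field = make_field(geom, 0.0, seed=0)
        scheme = make_protocol("1000(20)")
        means = []
        for sigma in (0.0, 1.0, 2.5, 5.0):
            spec = PhantomSpec(noise_sigma=sigma, radius_mm=15.0, seed=42)
            p1, _ = simulate_phantom_pair(spec, field, scheme)
            mm = compute_metrics(fit_tensor(p1, mode="STD"))
            means.append(mm.fa[p1.mask].mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_phantom_fa_nondecreasing_in_field_amplitude(self):
        geom = Geometry.centered((14, 14, 14), 2.5)
        scheme = make_protocol("1000(20)")
        means = []
        for amp in (0.0, 0.02, 0.05):
            field = make_field(geom, amp, seed=5)
            spec = PhantomSpec(noise_sigma=0.0, radius_mm=15.0, seed=42)
            p1, _ = simulate_phantom_pair(spec, field, scheme)
            mm = compute_metrics(fit_tensor(p1, mode="STD"))
            means.append(mm.fa[p1.mask].mean())
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestErrors:
    def test_coplanar_directions_rejected(self):
        angles = np.linspace(0, np.pi, 6, endpoint=False)
        dirs = np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1)
        bvals = np.array([0.0] + [1000.0] * 6)
        bvecs = np.vstack([np.zeros(3), dirs])
        scheme = GradientScheme.from_bvals_bvecs(bvals, bvecs)
        ds = _tiny_dataset(scheme, _random_tensors(2, seed=13))
        with pytest.raises(ValueError, match="coplanar"):
            fit_tensor(ds, mode="STD")

    def test_bsd_without_field_rejected(self):
        scheme = make_protocol("1000(6)")
        ds = _tiny_dataset(scheme, _random_tensors(2, seed=14))
        with pytest.raises(ValueError, match="field"):
            fit_tensor(ds, mode="BSD")

    def test_nonpositive_signal_voxels_masked_and_counted(self):
        scheme = make_protocol("1000(6)")
        ds = _tiny_dataset(scheme, _random_tensors(3, seed=15))
        ds.signals[1, 0, 0, 3] = 0.0
        tf = fit_tensor(ds, mode="STD")
        assert tf.n_masked_out == 1
        assert not tf.mask[1, 0, 0]
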