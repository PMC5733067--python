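"""swLORETA inverse: weights, operator algebra, standardized power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sourcetf.forward import build_leadfield, build_source_grid, make_cap_montage
from sourcetf.inverse import (
    apply_inverse,
    build_inverse,
    depth_weights,
    source_power_map,
    standardized_power,
)
from sourcetf.synth import Scenario, SourceSpec, simulate_trials


class TestDepthWeights:
    def test_identical_gain_blocks_get_equal_weights(self, leadfield32):
        w = depth_weights(leadfield32, gamma=1.0)
        # duplicate a voxel's block by constructing a lead field with two
        # identical column triplets
        import copy

        lf = copy.copy(leadfield32)
        gain = leadfield32.gain.copy()
        gain[:, 3:6] = gain[:, 0:3]
        lf.gain = gain
        w2 = depth_weights(lf, gamma=1.0)
        assert w2[0] == pytest.approx(w2[1], rel=1e-12)
        assert w[0] != pytest.approx(w[1], rel=1e-3)  # originals differ

    def test_scaling_homogeneity(self, leadfield32):
        import copy

        for gamma in (0.5, 1.0, 2.0):
            w = depth_weights(leadfield32, gamma=gamma)
            lf = copy.copy(leadfield32)
            gain = leadfield32.gain.copy()
            gain[:, 0:3] *= 5.0
            lf.gain = gain
            w2 = depth_weights(lf, gamma=gamma)
            assert w2[0] == pytest.approx(w[0] * 5.0 ** (-gamma), rel=1e-12)

    def test_known_block_against_eigensolver_oracle(self, sphere):
        # weight must equal 1/s1 with s1 from an independent eigen-solve of G'G
        montage = make_cap_montage(3, sphere)
        grid = build_source_grid(("box", [0.0, 0.0, 30.0], [0.0, 0.0, 30.0]), 5.0)
        lf = build_leadfield(montage, grid, sphere)
        G = lf.gain  # (3, 3)
        s1 = np.sqrt(max(np.linalg.eigvals(G.T @ G).real))
        w = depth_weights(lf, gamma=1.0)
        assert w[0] == pytest.approx(1.0 / s1, rel=1e-10)

    def test_gamma_zero_gives_unit_weights(self, leadfield32):
        np.testing.assert_allclose(depth_weights(leadfield32, gamma=0.0), 1.0)


class TestBuildInverse:
    def test_average_reference_invariance(self, inverse_op):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(inverse_op.n_channels, 4))
        j1 = apply_inverse(inverse_op, x)
        j2 = apply_inverse(inverse_op, x + 7.3)  # constant added to all channels
        np.testing.assert_allclose(j1, j2, atol=1e-10 * np.abs(j1).max())

    def test_standardization_blocks_match_dense_oracle(self, leadfield32):
        # independent dense-algebra route: explicit 3V x 3V resolution form
        L = leadfield32.gain
        M = L.shape[0]
        H = np.eye(M) - 1.0 / M
        Lb = H @ L
        w = depth_weights(leadfield32, gamma=1.0)
        W = np.kron(np.diag(w), np.eye(3))
        C = Lb @ W @ Lb.T
        lam = np.trace(C) / M / 9.0
        T = W @ Lb.T @ np.linalg.pinv(C + lam * H, rcond=1e-12, hermitian=True)
        S_dense = T @ (C + lam * H) @ T.T
        op = build_inverse(leadfield32, snr=3.0, gamma=1.0)
        for v in (0, 17, leadfield32.n_voxels - 1):
            block = S_dense[3 * v : 3 * v + 3, 3 * v : 3 * v + 3]
            np.testing.assert_allclose(op.s_blocks[v], block, rtol=1e-6, atol=1e-12)

    def test_single_voxel_identifiability(self, sphere):
        montage = make_cap_montage(16, sphere)
        grid = build_source_grid(("box", [10.0, 0.0, 40.0], [10.0, 0.0, 40.0]), 5.0)
        lf = build_leadfield(montage, grid, sphere)
        op = build_inverse(lf, lam=0.0)
        H = np.eye(16) - 1.0 / 16
        TL = op.transfer @ (H @ lf.gain)  # 3 x 3 resolution matrix
        # proportional to a full-rank map: reconstructing a moment then
        # standardizing must recover it exactly up to scale
        g = np.array([0.2, -0.4, 0.9])
        j = apply_inverse(op, lf.gain @ g)
        q = source_power_map(op, j[:, None] if j.ndim == 1 else j)
        assert np.linalg.matrix_rank(TL, tol=1e-8) == 3
        assert q.max() > 0

    def test_negative_lambda_rejected(self, leadfield32):
        with pytest.raises(ValueError, match="lambda"):
            build_inverse(leadfield32, lam=-1.0)


class TestApplyInverse:
    def test_zero_data_zero_estimates(self, inverse_op):
        j = apply_inverse(inverse_op, np.zeros((inverse_op.n_channels, 5)))
        assert np.all(j == 0)

    def test_linearity(self, inverse_op):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(inverse_op.n_channels, 3))
        y = rng.normal(size=(inverse_op.n_channels, 3))
        lhs = apply_inverse(inverse_op, 2.0 * x - 0.5 * y)
        rhs = 2.0 * apply_inverse(inverse_op, x) - 0.5 * apply_inverse(inverse_op, y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())

    def test_channel_mismatch_rejected(self, inverse_op):
        with pytest.raises(ValueError, match="channels"):
            apply_inverse(inverse_op, np.zeros((inverse_op.n_channels + 1, 2)))

    def test_complex_data_componentwise(self, inverse_op):
        rng = np.random.default_rng(3)
        xr = rng.normal(size=(inverse_op.n_channels, 2))
        xi = rng.normal(size=(inverse_op.n_channels, 2))
        jc = apply_inverse(inverse_op, xr + 1j * xi)
        np.testing.assert_allclose(jc.real, apply_inverse(inverse_op, xr), atol=1e-12)
        np.testing.assert_allclose(jc.imag, apply_inverse(inverse_op, xi), atol=1e-12)


class TestExactLocalization:
    def test_noiseless_dipoles_localize_exactly_on_test_grid(self, sphere):
        montage = make_cap_montage(64, sphere)
        grid = build_source_grid(("box", [-50.0] * 3, [50.0] * 3), 20.0)
        lf = build_leadfield(montage, grid, sphere)
        op = build_inverse(lf, lam=0.0)
        rng = np.random.default_rng(4)
        for v in range(0, grid.n_voxels, 7):
            g = lf.voxel_block(v) @ rng.normal(size=3)
            q = source_power_map(op, apply_inverse(op, g[:, None]))[:, 0]
            assert np.argmax(q) == v

    def test_scaling_invariance_of_standardized_power(self, leadfield32):
        # rescaling the lead field and the data consistently with the
        # forward model leaves the plain-sLORETA (gamma=0) map unchanged and
        # the depth-weighted map unchanged up to one global factor
        import copy

        rng = np.random.default_rng(5)
        g = rng.normal(size=3)
        v = 40
        x = leadfield32.voxel_block(v) @ g
        lf2 = copy.copy(leadfield32)
        lf2.gain = leadfield32.gain * 3.7  # rescaled forward model
        op = build_inverse(leadfield32, snr=3.0, gamma=0.0)
        op2 = build_inverse(lf2, snr=3.0, gamma=0.0)
        q1 = source_power_map(op, apply_inverse(op, x[:, None]))
        q2 = source_power_map(op2, apply_inverse(op2, 3.7 * x[:, None]))
        np.testing.assert_allclose(q1, q2, rtol=1e-8)
        opw = build_inverse(leadfield32, snr=3.0, gamma=1.0)
        opw2 = build_inverse(lf2, snr=3.0, gamma=1.0)
        qw1 = source_power_map(opw, apply_inverse(opw, x[:, None]))
        qw2 = source_power_map(opw2, apply_inverse(opw2, 3.7 * x[:, None]))
        ratio = qw2 / qw1
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-8)


class TestStandardizedPower:
    def test_zero_estimate_zero_power(self):
        assert standardized_power(np.zeros(3), np.eye(3)) == 0

    def test_identity_block_gives_squared_norm(self):
        j = np.array([1.0 + 2.0j, -0.5, 3.0j])
        q = standardized_power(j, np.eye(3))
        assert q == pytest.approx(np.sum(np.abs(j) ** 2), rel=1e-14)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.integers(0, 2**32 - 1))
    def test_matches_linear_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        S = A @ A.T + 0.1 * np.eye(3)  # strictly PD -> solve is valid
        j = rng.normal(size=3) + 1j * rng.normal(size=3)
        q = standardized_power(j, S)
        q_oracle = np.real(np.conj(j) @ np.linalg.solve(S, j))
        assert q == pytest.approx(q_oracle, rel=1e-10)

    def test_degenerate_block_uses_pseudoinverse(self):
        S = np.diag([1.0, 1.0, 0.0])
        j = np.array([1.0, 1.0, 5.0])
        q = standardized_power(j, S)  # component in the null space is ignored
        assert q == pytest.approx(2.0, rel=1e-12)


def test_depth_weighting_does_not_worsen_deep_localization(sphere):
    """Monitored property: with noise, gamma=1 should localize a deep source
    at least as well as gamma=0 on average over seeds."""
    montage = make_cap_montage(32, sphere)
    grid = build_source_grid(("sphere", 70.0), 20.0)
    lf = build_leadfield(montage, grid, sphere)
    deep = SourceSpec(position=(10.0, 5.0, 10.0), band_center=10.0, amplitude=20.0)
    errs = {0.0: [], 1.0: []}
    for seed in range(4):
        scen = Scenario(
            sources=[deep],
            n_background=10,
            background_amplitude=5.0,
            sensor_noise_sd=1.0,
            n_subjects=2,
            n_trials=1,
            subject_jitter_sd=0.0,
            srate=128.0,
            condition_names=("MI",),
        )
        sim = simulate_trials(scen, lf, seed=seed, sphere=sphere)
        tv = sim.true_voxels[0]
        data = sim.epochs["S01"]["MI"].data[:, :, 0]
        for gamma in errs:
            op = build_inverse(lf, snr=3.0, gamma=gamma)
            q = source_power_map(op, apply_inverse(op, data)).mean(axis=1)
            vhat = int(np.argmax(q))
            errs[gamma].append(
                np.linalg.norm(grid.positions[vhat] - grid.positions[tv])
            )
    # average error with SVD weighting <= without, plus one grid spacing slack
    assert np.mean(errs[1.0]) <= np.mean(errs[0.0]) + grid.spacing
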