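"""Temporal subspace, forward/adjoint operators, LLR shrinkage and ADMM."""

import numpy as np
import pytest

from qti.acquisition import (KSpaceData, acquire, make_coils, make_phantom,
                             make_spiral, voxel_signals)
from qti.design import RampSpec, default_prior, make_ramp_design
from qti.epg import simulate_signals
from qti.nufft import FramewiseNufft
from qti.recon import (ReconConfig, SubspaceBasis, SubspaceImageSet,
                       SubspaceNormalOperator, adjoint, admm_reconstruct,
                       build_subspace, forward, llr_shrink, project_to_time)


@pytest.fixture(scope="module")
def small():
    """32x32 grid, 32-rep ramp, rank-4 subspace problem."""
    design = make_ramp_design(RampSpec(7, 70, N=32))
    prior = default_prior()
    basis = build_subspace(design, prior, n_signals=200, R=4, seed=2)
    sampling = make_spiral(matrix=32, n_repetitions=32)
    coils = make_coils((32, 32), 3, seed=3)
    nufft = FramewiseNufft((32, 32), sampling.omega_all())
    return design, prior, basis, sampling, coils, nufft


class TestSubspace:
    def test_orthonormal(self, small):
        basis = small[2]
        g = basis.basis.conj().T @ basis.basis
        assert np.abs(g - np.eye(basis.R)).max() < 1e-10

    def test_full_rank_is_lossless(self, ramp_design, brain_prior):
        basis = build_subspace(ramp_design, brain_prior, n_signals=300,
                               R=260, seed=0, K=130)
        rng = np.random.default_rng(1)
        T1, T2 = brain_prior.sample(20, rng)
        sigs = simulate_signals(ramp_design, T1, T2, K=130, trunc_tol=None)
        proj = basis.basis @ (basis.basis.conj().T @ sigs)
        assert np.linalg.norm(proj - sigs) / np.linalg.norm(sigs) < 1e-9

    def test_rank10_held_out_error(self, ramp_design, brain_prior):
        basis = build_subspace(ramp_design, brain_prior, n_signals=1000,
                               R=10, seed=0, K=130)
        rng = np.random.default_rng(77)
        T1, T2 = brain_prior.sample(300, rng)
        v = np.where(rng.random(300) < 0.5, rng.uniform(0, 100, 300), 0.0)
        sigs = simulate_signals(ramp_design, T1, T2, v, K=130, trunc_tol=None)
        proj = basis.basis @ (basis.basis.conj().T @ sigs)
        rel = np.linalg.norm(sigs - proj, axis=0) / np.linalg.norm(sigs, axis=0)
        assert np.median(rel) < 0.01

    def test_needs_enough_signals(self, small):
        with pytest.raises(ValueError):
            build_subspace(small[0], small[1], n_signals=3, R=4, seed=0)


class TestForwardAdjoint:
    def test_zero_coefficients(self, small):
        design, _, basis, sampling, coils, nufft = small
        z = SubspaceImageSet(np.zeros((4, 32, 32), complex), basis)
        assert np.abs(forward(z, sampling, coils, nufft=nufft)).max() == 0.0

    def test_linearity(self, small, rng):
        design, _, basis, sampling, coils, nufft = small
        c1 = rng.standard_normal((4, 32, 32)) + 1j * rng.standard_normal((4, 32, 32))
        c2 = rng.standard_normal((4, 32, 32)) + 1j * rng.standard_normal((4, 32, 32))
        f = lambda c: forward(SubspaceImageSet(c, basis), sampling, coils,
                              nufft=nufft)
        lhs = f(1.7 * c1 + c2)
        rhs = 1.7 * f(c1) + f(c2)
        assert np.abs(lhs - rhs).max() / np.abs(rhs).max() < 1e-10

    def test_adjoint_inner_product(self, small, rng):
        design, _, basis, sampling, coils, nufft = small
        c = rng.standard_normal((4, 32, 32)) + 1j * rng.standard_normal((4, 32, 32))
        y = forward(SubspaceImageSet(c, basis), sampling, coils, nufft=nufft)
        yr = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        a = adjoint(yr, sampling, coils, basis, nufft=nufft)
        lhs = np.vdot(yr, y)
        rhs = np.vdot(a.coeffs, c)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_matches_acquire_for_in_span_phantom(self, small):
        """A phantom whose voxel signals lie exactly in the basis span is
        predicted identically by the subspace forward model."""
        design, _, _, sampling, coils, nufft = small
        ph = make_phantom("brain2d", (32, 32), seed=4)
        frames = voxel_signals(ph, design)
        # basis from the phantom's own unique signals: exact span
        sup = frames[:, ph.support]
        u, s, _ = np.linalg.svd(sup, full_matrices=False)
        R = int((s > s[0] * 1e-10).sum())
        basis = SubspaceBasis(u[:, :R])
        coeffs = np.einsum("tr,tyx->ryx", basis.basis.conj(), frames)
        y_sub = forward(SubspaceImageSet(coeffs, basis), sampling, coils,
                        nufft=nufft)
        y_ref = acquire(ph, design, sampling, coils, noise_sd=0.0, seed=0).y
        assert np.abs(y_sub - y_ref).max() / np.abs(y_ref).max() < 1e-8

    def test_normal_operator_matches_composition(self, small, rng):
        design, _, basis, sampling, coils, nufft = small
        c = rng.standard_normal((4, 32, 32)) + 1j * rng.standard_normal((4, 32, 32))
        nop = SubspaceNormalOperator(sampling, coils, basis)
        ref = adjoint(forward(SubspaceImageSet(c, basis), sampling, coils,
                              nufft=nufft), sampling, coils, basis,
                      nufft=nufft).coeffs
        got = nop(c)
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) < 1e-6


class TestLlrShrink:
    def _random_imgs(self, rng, basis):
        c = rng.standard_normal((basis.R, 32, 32)) \
            + 1j * rng.standard_normal((basis.R, 32, 32))
        return SubspaceImageSet(c, basis)

    def test_zero_threshold_identity(self, small, rng):
        imgs = self._random_imgs(rng, small[2])
        out = llr_shrink(imgs, patch=8, threshold=0.0)
        np.testing.assert_array_equal(out.coeffs, imgs.coeffs)

    def test_huge_threshold_annihilates(self, small, rng):
        imgs = self._random_imgs(rng, small[2])
        out = llr_shrink(imgs, patch=8, threshold=1e6)
        assert np.abs(out.coeffs).max() == 0.0

    def test_singular_values_soft_thresholded(self, small, rng):
        imgs = self._random_imgs(rng, small[2])
        thr = 3.0
        out = llr_shrink(imgs, patch=8, threshold=thr)
        R = small[2].R
        # direct per-patch SVD oracle on the first patch
        pin = imgs.coeffs[:, :8, :8].reshape(R, -1).T
        pout = out.coeffs[:, :8, :8].reshape(R, -1).T
        s_in = np.linalg.svd(pin, compute_uv=False)
        s_out = np.linalg.svd(pout, compute_uv=False)
        np.testing.assert_allclose(s_out, np.maximum(s_in - thr, 0),
                                   atol=1e-10)

    def test_patch_shift_round_trip(self, small, rng):
        imgs = self._random_imgs(rng, small[2])
        out = llr_shrink(imgs, patch=8, threshold=0.0, shift=(3, 5))
        np.testing.assert_array_equal(out.coeffs, imgs.coeffs)

    def test_patch_larger_than_grid(self, small, rng):
        with pytest.raises(ValueError):
            llr_shrink(self._random_imgs(rng, small[2]), patch=64,
                       threshold=1.0)


class TestAdmm:
    def test_fully_sampled_noiseless_recovery(self, small, rng):
        """With every k-space location of a Cartesian grid measured each
        repetition and no regularization, ADMM reduces to least squares and
        recovers the true coefficients."""
        design, _, basis, _, coils, _ = small
        kx = (np.arange(32) - 16) / 32 * 2 * np.pi
        om = np.stack(np.meshgrid(kx, kx, indexing="ij"), axis=-1).reshape(-1, 2)
        om_frames = np.repeat(om[None], 32, axis=0)
        full_nufft = FramewiseNufft((32, 32), om_frames)
        from qti.acquisition import SpiralSampling
        sampling = SpiralSampling(
            base_k=om_frames / (2 * np.pi / 32), interleave_idx=np.arange(32),
            angle_deg=np.zeros(32), n_dense=0, matrix=32, fov_mm=225.0,
        )
        truth = rng.standard_normal((4, 32, 32)) + 1j * rng.standard_normal((4, 32, 32))
        y = forward(SubspaceImageSet(truth, basis), sampling, coils,
                    nufft=full_nufft)
        data = KSpaceData(y=y, noise_sd=0.0, design=design, sampling=sampling,
                          coils=coils)
        cfg = ReconConfig(lam=1e-12, n_iters=3, cg_iters=30, patch=8,
                          log_objective=False)
        rec, _ = admm_reconstruct(data, basis, cfg, seed=0, nufft=full_nufft)
        err = np.linalg.norm(rec.coeffs - truth) / np.linalg.norm(truth)
        assert err < 1e-3

    def test_zero_data_zero_solution(self, small):
        design, _, basis, sampling, coils, nufft = small
        y = np.zeros((32, coils.n_coils, sampling.samples_per_readout), complex)
        data = KSpaceData(y=y, noise_sd=0.0, design=design, sampling=sampling,
                          coils=coils)
        cfg = ReconConfig(lam=0.1, n_iters=5, cg_iters=5, log_objective=False)
        rec, _ = admm_reconstruct(data, basis, cfg, seed=0, nufft=nufft)
        assert np.abs(rec.coeffs).max() < 1e-12

    def test_objective_nonincreasing_after_burn_in(self, small, rng):
        design, _, basis, sampling, coils, nufft = small
        ph = make_phantom("brain2d", (32, 32), seed=6)
        data = acquire(ph, design, sampling, coils, noise_sd=0.005, seed=1)
        # fixed patch tiling: the random shifts deliberately perturb the
        # regularizer between iterations, so monotonicity is only a property
        # of the deterministic variant
        cfg = ReconConfig(lam=0.02, n_iters=12, cg_iters=8,
                          random_shifts=False)
        _, info = admm_reconstruct(data, basis, cfg, seed=0, nufft=nufft)
        obj = np.asarray(info["objective"][3:])
        assert np.all(np.diff(obj) <= np.abs(obj[:-1]) * 1e-3)


class TestProjectToTime:
    def test_round_trip_full_rank(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((12, 12))
                            + 1j * rng.standard_normal((12, 12)))
        basis = SubspaceBasis(q)
        frames = rng.standard_normal((12, 8, 8)) + 1j * rng.standard_normal((12, 8, 8))
        coeffs = np.einsum("tr,tyx->ryx", basis.basis.conj(), frames)
        back = project_to_time(SubspaceImageSet(coeffs, basis))
        assert np.abs(back - frames).max() < 1e-10

    def test_frame_count_matches_design(self, ramp_design, brain_prior):
        basis = build_subspace(ramp_design, brain_prior, n_signals=50, R=4,
                               seed=1, K=130)
        imgs = SubspaceImageSet(np.zeros((4, 8, 8), complex), basis)
        assert project_to_time(imgs).shape[0] == 260
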