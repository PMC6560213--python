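"""Likelihood, posterior sampling, dictionary matching and map fitting."""

import numpy as np
import pytest

from qti.design import RampSpec, make_ramp_design
from qti.epg import TissueParameters, simulate_signal, simulate_signals
from qti.inference import (InferencePrior, build_dictionary,
                           dictionary_match, fit_maps, log_likelihood,
                           posterior_sample)


@pytest.fixture(scope="module")
def design():
    return make_ramp_design(RampSpec(7, 70, N=260))


@pytest.fixture(scope="module")
def gm_signal(design):
    return simulate_signal(design, TissueParameters(1450, 85, rho=0.8 + 0.2j)).s


class TestLogLikelihood:
    def test_exact_signal_is_maximal(self, design, gm_signal):
        ll = log_likelihood(gm_signal, np.array([1450.0, 85.0]), design,
                            noise_sd=0.01, K=130)
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance_of_profiled_fit(self, design, gm_signal):
        scaled = gm_signal * (3.0 * np.exp(1.2j))
        ll = log_likelihood(scaled, np.array([1450.0, 85.0]), design,
                            noise_sd=0.01, K=130)
        assert ll == pytest.approx(0.0, abs=1e-4)

    def test_ordering_matches_residual(self, design, gm_signal):
        """Likelihood ordering over a two-point grid agrees with the direct
        least-squares residual computed independently."""
        cands = np.array([[1450.0, 85.0], [900.0, 60.0]])
        ll = log_likelihood(gm_signal, cands, design, noise_sd=0.01, K=130)
        res = []
        for t1, t2 in cands:
            f = simulate_signal(design, TissueParameters(t1, t2)).s
            rho = np.vdot(f, gm_signal) / np.vdot(f, f)
            res.append(np.linalg.norm(gm_signal - rho * f))
        assert (ll[0] > ll[1]) == (res[0] < res[1])

    def test_requires_positive_noise(self, design, gm_signal):
        with pytest.raises(ValueError):
            log_likelihood(gm_signal, np.array([1000.0, 80.0]), design, 0.0)


class TestPosterior:
    def test_noiseless_ml_recovery(self, design, gm_signal):
        prior = InferencePrior()
        s = posterior_sample(gm_signal, design, prior, noise_sd=1e-3,
                             seed=1, K=130)
        assert abs(s.ml[0] - 1450) / 1450 < 0.01
        assert abs(s.ml[1] - 85) / 85 < 0.01
        assert s.residual < 1e-4

    def test_bounds_respected(self, design, gm_signal):
        prior = InferencePrior(T1_bounds=(1000.0, 2000.0),
                               T2_bounds=(50.0, 150.0))
        s = posterior_sample(gm_signal, design, prior, noise_sd=0.01,
                             seed=2, K=130, keep_samples=True)
        b = prior.bounds
        assert np.all(s.samples >= b[:, 0]) and np.all(s.samples <= b[:, 1])
        assert np.all((s.ml >= b[:, 0]) & (s.ml <= b[:, 1]))
        assert np.all((s.ci95[:, 0] <= s.mean) & (s.mean <= s.ci95[:, 1]))

    def test_determinism(self, design, gm_signal):
        prior = InferencePrior()
        kw = dict(noise_sd=0.01, seed=5, K=130, n_steps=120, n_burn=40)
        a = posterior_sample(gm_signal, design, prior, **kw)
        b = posterior_sample(gm_signal, design, prior, **kw)
        assert np.array_equal(a.ml, b.ml) and np.array_equal(a.sd, b.sd)

    def test_zero_signal_rejected(self, design):
        with pytest.raises(ValueError):
            posterior_sample(np.zeros(260, complex), design,
                             InferencePrior(), noise_sd=0.01)

    def test_posterior_tightens_with_snr(self, design):
        """Posterior spread shrinks monotonically as noise decreases, and the
        ML point approaches the generating parameters."""
        truth = TissueParameters(1100.0, 95.0)
        clean = simulate_signal(design, truth).s
        rng = np.random.default_rng(8)
        noise = rng.standard_normal(260) + 1j * rng.standard_normal(260)
        sds, ml_errs = [], []
        for ns in (0.02, 0.005, 0.00125):
            sig = clean + ns * noise
            s = posterior_sample(sig, design, InferencePrior(), noise_sd=ns,
                                 seed=3, K=130, n_steps=250, n_burn=100)
            sds.append(s.sd.sum())
            ml_errs.append(abs(s.ml[0] - 1100) / 1100)
        assert sds[0] > sds[1] > sds[2]
        assert ml_errs[2] < 0.01


class TestDictionary:
    @staticmethod
    @pytest.fixture(scope="class")
    def dic(design):
        return build_dictionary(design, T1_grid=np.geomspace(200, 4500, 40),
                                T2_grid=np.geomspace(20, 2500, 40), K=130)

    def test_atom_matches_itself(self, dic):
        i = dic.atoms.shape[1] // 3
        params, corr = dictionary_match(dic.atoms[:, i], dic)
        np.testing.assert_array_equal(params, dic.params[i])
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_complex_scale_invariance(self, dic, design, gm_signal):
        p1, c1 = dictionary_match(gm_signal, dic)
        p2, c2 = dictionary_match(gm_signal * (5 * np.exp(0.7j)), dic)
        np.testing.assert_array_equal(p1, p2)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_unit_norm_atoms(self, dic):
        np.testing.assert_allclose(np.linalg.norm(dic.atoms, axis=0), 1.0,
                                   atol=1e-12)

    def test_agrees_with_posterior_ml(self, design, dic):
        """High-SNR dictionary match lands within one grid cell of the
        posterior maximum-likelihood point."""
        rng = np.random.default_rng(4)
        for _ in range(3):
            t1 = float(rng.uniform(600, 2500))
            t2 = float(rng.uniform(40, min(300, t1 / 3)))
            sig = simulate_signal(design, TissueParameters(t1, t2)).s
            sig = sig + 1e-4 * (rng.standard_normal(260)
                                + 1j * rng.standard_normal(260))
            p_dict, _ = dictionary_match(sig, dic)
            s = posterior_sample(sig, design, InferencePrior(), noise_sd=1e-4,
                                 seed=6, K=130, n_steps=200, n_burn=80)
            # one log-grid step of this dictionary is ~17%/~13%
            assert abs(np.log(p_dict[0] / s.ml[0])) < np.log(4500 / 200) / 39
            assert abs(np.log(p_dict[1] / s.ml[1])) < np.log(2500 / 20) / 39


class TestFitMaps:
    @staticmethod
    @pytest.fixture(scope="class")
    def phantom_frames(design):
        from qti.acquisition import make_phantom, voxel_signals

        ph = make_phantom("brain2d", (32, 32), seed=2)
        return ph, voxel_signals(ph, design)

    def test_noiseless_recovery_fine_grid(self, design, phantom_frames):
        """On noiseless in-span frames the matcher must land on the atoms of
        the generating tissues when the grid resolves them (the grid includes
        the class values; off-grid truth is instead limited by the T1-T2
        correlation ridge, exercised in the lsq test)."""
        ph, frames = phantom_frames
        t1_grid = np.unique(np.concatenate(
            [np.geomspace(700, 4000, 90), [900.0, 1450.0, 3600.0]]))
        t2_grid = np.unique(np.concatenate(
            [np.geomspace(40, 2000, 90), [60.0, 85.0, 1750.0]]))
        dic = build_dictionary(design, T1_grid=t1_grid, T2_grid=t2_grid, K=130)
        maps = fit_maps(frames, ph.support, design, method="dict",
                        dictionary=dic, noise_sd=1e-4)
        for lbl in (1, 2, 3):
            m = ph.labels == lbl
            assert abs(np.median(maps["T1"][m]) - ph.T1[m].max()) \
                / ph.T1[m].max() < 0.02
            assert abs(np.median(maps["T2"][m]) - ph.T2[m].max()) \
                / ph.T2[m].max() < 0.02

    def test_single_voxel_reduces_to_match(self, design, phantom_frames):
        ph, frames = phantom_frames
        dic = build_dictionary(design, T1_grid=np.geomspace(300, 4000, 30),
                               T2_grid=np.geomspace(20, 2000, 30), K=130)
        iy, ix = np.argwhere(ph.labels == 1)[0]
        mask = np.zeros(ph.shape, bool)
        mask[iy, ix] = True
        maps = fit_maps(frames, mask, design, method="dict", dictionary=dic,
                        noise_sd=1e-4)
        p, _ = dictionary_match(frames[:, iy, ix], dic)
        assert maps["T1"][iy, ix] == p[0] and maps["T2"][iy, ix] == p[1]

    def test_background_pd_zero(self, design, phantom_frames):
        ph, frames = phantom_frames
        mask = np.ones(ph.shape, bool)
        dic = build_dictionary(design, T1_grid=np.geomspace(300, 4000, 20),
                               T2_grid=np.geomspace(20, 2000, 20), K=130)
        maps = fit_maps(frames, mask, design, method="dict", dictionary=dic,
                        noise_sd=1e-6)
        assert np.all(maps["PD"][~ph.support] < 1e-10)

    def test_empty_mask(self, design, phantom_frames):
        ph, frames = phantom_frames
        with pytest.raises(ValueError):
            fit_maps(frames, np.zeros(ph.shape, bool), design)

    def test_lsq_refines_dictionary(self, design):
        """Bounded least squares from the dictionary initialization recovers
        off-grid parameters to higher accuracy than the grid itself."""
        truth = TissueParameters(1234.0, 77.0, rho=0.9)
        sig = simulate_signal(design, truth).s
        frames = sig[:, None, None] * np.ones((1, 1))
        mask = np.ones((1, 1), bool)
        dic = build_dictionary(design, T1_grid=np.geomspace(300, 4000, 25),
                               T2_grid=np.geomspace(20, 2000, 25), K=130)
        maps = fit_maps(frames, mask, design, method="lsq", dictionary=dic,
                        noise_sd=1e-5, K=130)
        assert abs(maps["T1"][0, 0] - 1234) / 1234 < 0.005
        assert abs(maps["T2"][0, 0] - 77) / 77 < 0.005

    def test_methods_agree_high_snr(self, design):
        rng = np.random.default_rng(9)
        dic = build_dictionary(design, T1_grid=np.geomspace(300, 4000, 60),
                               T2_grid=np.geomspace(20, 2000, 60), K=130)
        n = 4
        T1 = rng.uniform(700, 2500, n)
        T2 = np.minimum(rng.uniform(50, 400, n), T1 / 3)
        sigs = simulate_signals(design, T1, T2, K=130, trunc_tol=None)
        sigs = sigs + 3e-4 * (rng.standard_normal(sigs.shape)
                              + 1j * rng.standard_normal(sigs.shape))
        frames = sigs.reshape(260, 1, n)
        mask = np.ones((1, n), bool)
        md = fit_maps(frames, mask, design, method="dict", dictionary=dic,
                      noise_sd=3e-4, K=130)
        ml = fit_maps(frames, mask, design, method="lsq", dictionary=dic,
                      noise_sd=3e-4, K=130)
        step = np.log(4000 / 300) / 59  # one grid cell on the log axis
        assert np.all(np.abs(np.log(md["T1"][mask] / ml["T1"][mask])) < step)
        assert np.all(np.abs(np.log(md["T2"][mask] / ml["T2"][mask]))
                      < np.log(2000 / 20) / 59)
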