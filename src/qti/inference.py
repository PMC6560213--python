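"""Per-voxel probabilistic inversion of the transient-state signal model.

Given a reconstructed voxel time-course x_t and the EPG forward model
f_t(T1, T2[, v]), the posterior p(theta | x) is sampled under a Gaussian
noise model and a uniform prior.  The complex proton-density scale rho is a
linear nuisance parameter and is profiled analytically inside the
likelihood, so only the nonlinear parameters are sampled.  Dictionary
matching and bounded least squares are provided as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import emcee
from scipy.optimize import least_squares, minimize

from qti.epg import AcquisitionDesign, TissueParameters, simulate_signals

__all__ = [
    "InferencePrior",
    "PosteriorSummary",
    "Dictionary",
    "log_likelihood",
    "posterior_sample",
    "build_dictionary",
    "dictionary_match",
    "fit_maps",
]


@dataclass(frozen=True)
class InferencePrior:
    """Uniform (flat) prior box over the sampled parameters, in ms / mm/s."""

    T1_bounds: tuple[float, float] = (100.0, 5000.0)
    T2_bounds: tuple[float, float] = (10.0, 3000.0)
    v_bounds: tuple[float, float] = (0.0, 200.0)
    include_v: bool = False

    def __post_init__(self):
        for lo, hi in (self.T1_bounds, self.T2_bounds, self.v_bounds):
            if not lo < hi:
                raise ValueError("prior bounds must satisfy lower < upper")

    @property
    def names(self) -> tuple[str, ...]:
        return ("T1", "T2", "v") if self.include_v else ("T1", "T2")

    @property
    def bounds(self) -> np.ndarray:
        b = [self.T1_bounds, self.T2_bounds]
        if self.include_v:
            b.append(self.v_bounds)
        return np.asarray(b)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        b = self.bounds
        return np.all((theta >= b[:, 0]) & (theta <= b[:, 1]), axis=-1)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries for one voxel."""

    names: tuple[str, ...]
    mean: np.ndarray
    ml: np.ndarray
    sd: np.ndarray
    ci95: np.ndarray          # (p, 2) central interval
    rho_ml: complex
    residual: float           # relative model-fit residual at the ML point
    ess: float
    converged: bool
    samples: np.ndarray | None = None


def _model_signals(theta: np.ndarray, design: AcquisitionDesign,
                   include_v: bool, K: int | None) -> np.ndarray:
    """Unit-rho model signals for a (n, p) parameter stack -> (N, n)."""
    theta = np.atleast_2d(theta)
    v = theta[:, 2] if include_v else np.zeros(theta.shape[0])
    return simulate_signals(design, theta[:, 0], theta[:, 1], v, K=K,
                            trunc_tol=None)


def _profiled_residual(signal: np.ndarray, model: np.ndarray) -> np.ndarray:
    """||signal - rho_hat * model||^2 with rho_hat = <model, signal>/||model||^2,
    for model columns; returns (n,) nonnegative residuals."""
    num = np.abs(np.sum(model.conj() * signal[:, None], axis=0)) ** 2
    den = np.sum(np.abs(model) ** 2, axis=0)
    e2 = np.sum(np.abs(signal) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = e2 - np.where(den > 0, num / den, 0.0)
    return np.maximum(res, 0.0)


def log_likelihood(
    signal: np.ndarray,
    params: TissueParameters | np.ndarray,
    design: AcquisitionDesign,
    noise_sd: float,
    include_v: bool = False,
    K: int | None = None,
) -> float | np.ndarray:
    """Gaussian log-likelihood with the complex scale rho profiled out.

    ``params`` may be a TissueParameters or an (n, p) array of (T1, T2[, v])
    rows; returns a scalar or an (n,) array.  A zero model signal gives
    -inf.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if isinstance(params, TissueParameters):
        theta = np.array([[params.T1, params.T2, params.v]])
        theta = theta[:, : (3 if include_v else 2)]
        scalar = True
    else:
        theta = np.atleast_2d(np.asarray(params, dtype=float))
        scalar = theta.shape[0] == 1 and np.ndim(params) == 1
    model = _model_signals(theta, design, include_v, K)
    dead = np.sum(np.abs(model) ** 2, axis=0) == 0
    ll = -_profiled_residual(signal, model) / (2 * noise_sd**2)
    ll[dead] = -np.inf
    return float(ll[0]) if scalar else ll


def _rho_hat(signal: np.ndarray, model: np.ndarray) -> complex:
    den = np.vdot(model, model).real
    return np.vdot(model, signal) / den if den > 0 else 0.0


def posterior_sample(
    signal: np.ndarray,
    design: AcquisitionDesign,
    prior: InferencePrior,
    noise_sd: float,
    seed: int = 0,
    n_walkers: int = 24,
    n_steps: int = 400,
    n_burn: int = 150,
    K: int | None = None,
    init: np.ndarray | None = None,
    keep_samples: bool = False,
    polish_ml: bool = True,
) -> PosteriorSummary:
    """Sample p(theta | signal) with an affine-invariant ensemble sampler.

    Walkers start in a ball around ``init`` (or the prior-box centre on a
    log scale); the maximum-likelihood point is the best posterior sample,
    optionally polished by a bounded Nelder-Mead refinement.  Convergence is
    flagged (not fatal) when the mean acceptance is below 5% or the effective
    sample size below 50.
    """
    if not np.any(signal):
        raise ValueError("signal is identically zero")
    bounds = prior.bounds
    p = bounds.shape[0]
    rng = np.random.default_rng(seed)

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = prior.contains(theta)
        if np.any(ok):
            out[ok] = log_likelihood(signal, theta[ok], design, noise_sd,
                                     include_v=prior.include_v, K=K)
        return out

    if init is None:
        # coarse log-spaced likelihood scan; the landscape is multimodal
        # enough that a fixed starting point can trap the walkers
        grids = [np.geomspace(max(lo, 1e-3), hi, 24) for lo, hi in bounds]
        if prior.include_v:
            grids[2] = np.linspace(bounds[2, 0], bounds[2, 1], 8)
        mesh = np.meshgrid(*grids, indexing="ij")
        cand = np.stack([m.ravel() for m in mesh], axis=1)
        ll = log_likelihood(signal, cand, design, noise_sd,
                            include_v=prior.include_v, K=K)
        init = cand[int(np.argmax(ll))]
    init = np.clip(init, bounds[:, 0] * 1.01, bounds[:, 1] * 0.99)
    p0 = init * np.exp(0.05 * rng.standard_normal((n_walkers, p)))
    p0 = np.clip(p0, bounds[:, 0], bounds[:, 1])

    sampler = emcee.EnsembleSampler(n_walkers, p, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(
        rng.integers(2**31)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    lp = sampler.get_log_prob(discard=n_burn, flat=True)
    accept = float(np.mean(sampler.acceptance_fraction))

    i_best = int(np.argmax(lp))
    ml = chain[i_best].copy()
    if polish_ml:
        res = minimize(
            lambda th: -log_prob(th[None])[0], ml, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 400},
        )
        if np.isfinite(res.fun) and -res.fun >= lp[i_best]:
            ml = np.clip(res.x, bounds[:, 0], bounds[:, 1])

    mean = chain.mean(axis=0)
    sd = chain.std(axis=0, ddof=1)
    ci = np.percentile(chain, [2.5, 97.5], axis=0).T
    try:
        tau = sampler.get_autocorr_time(discard=n_burn, quiet=True)
        ess = float(chain.shape[0] / np.nanmax(tau)) if np.all(np.isfinite(tau)) \
            else float(chain.shape[0])
    except Exception:  # pragma: no cover - emcee raises on very short chains
        ess = float(chain.shape[0])
    model = _model_signals(ml[None], design, prior.include_v, K)[:, 0]
    rho = _rho_hat(signal, model)
    resid = np.linalg.norm(signal - rho * model) / np.linalg.norm(signal)
    return PosteriorSummary(
        names=prior.names, mean=mean, ml=ml, sd=sd, ci95=ci, rho_ml=rho,
        residual=float(resid), ess=ess,
        converged=(accept >= 0.05 and ess >= 50),
        samples=chain if keep_samples else None,
    )


# --------------------------------------------------------------- dictionary

@dataclass
class Dictionary:
    """Precomputed unit-norm signal atoms on a (T1, T2[, v]) grid."""

    params: np.ndarray  # (n_atoms, p)
    atoms: np.ndarray   # (N, n_atoms), unit L2 columns
    names: tuple[str, ...]


def build_dictionary(
    design: AcquisitionDesign,
    T1_grid: np.ndarray | None = None,
    T2_grid: np.ndarray | None = None,
    v_grid: np.ndarray | None = None,
    K: int | None = 130,
    t2_le_t1: bool = True,
) -> Dictionary:
    """Simulate a dictionary over a (log-spaced by default) parameter grid."""
    if T1_grid is None:
        T1_grid = np.geomspace(100, 5000, 100)
    if T2_grid is None:
        T2_grid = np.geomspace(10, 3000, 100)
    if not (np.all(np.diff(T1_grid) > 0) and np.all(np.diff(T2_grid) > 0)):
        raise ValueError("grids must be strictly increasing")
    grids = [T1_grid, T2_grid] + ([v_grid] if v_grid is not None else [])
    names = ("T1", "T2") + (("v",) if v_grid is not None else ())
    mesh = np.meshgrid(*grids, indexing="ij")
    params = np.stack([m.ravel() for m in mesh], axis=1)
    if t2_le_t1:
        params = params[params[:, 1] <= params[:, 0]]
    v = params[:, 2] if v_grid is not None else np.zeros(len(params))
    atoms = simulate_signals(design, params[:, 0], params[:, 1], v, K=K,
                             trunc_tol=None)
    norms = np.linalg.norm(atoms, axis=0)
    keep = norms > 0
    return Dictionary(params=params[keep], atoms=atoms[:, keep] / norms[keep],
                      names=names)


def dictionary_match(
    signal: np.ndarray, dictionary: Dictionary
) -> tuple[np.ndarray, float]:
    """Best-matching atom by normalized inner product magnitude.

    Returns the grid parameters and the correlation |<atom, signal>| /
    ||signal|| (1 for a perfect match, invariant to complex scaling).
    """
    corr = np.abs(dictionary.atoms.conj().T @ signal)
    i = int(np.argmax(corr))
    nrm = np.linalg.norm(signal)
    return dictionary.params[i], float(corr[i] / nrm) if nrm > 0 else 0.0


def _match_all(signals: np.ndarray, dictionary: Dictionary):
    """Vectorized matching of (N, n_vox) signals; returns (params, rho)."""
    corr = dictionary.atoms.conj().T @ signals          # (n_atoms, n_vox)
    best = np.argmax(np.abs(corr), axis=0)
    params = dictionary.params[best]
    rho = corr[best, np.arange(signals.shape[1])]        # atoms are unit-norm
    return params, rho


# ----------------------------------------------------------------- mapping

def fit_maps(
    frames: np.ndarray,
    mask: np.ndarray,
    design: AcquisitionDesign,
    prior: InferencePrior | None = None,
    method: str = "dict",
    seed: int = 0,
    noise_sd: float | None = None,
    dictionary: Dictionary | None = None,
    K: int | None = 130,
    mcmc_kwargs: dict | None = None,
) -> dict[str, np.ndarray]:
    """Voxel-wise parameter maps from a reconstructed time series.

    ``frames``: (N, ny, nx) complex; ``mask``: boolean map of voxels to fit.
    Methods: ``dict`` (grid matching), ``lsq`` (bounded nonlinear least
    squares from the dictionary initialization), ``bayes`` (posterior
    sampling; additionally returns sd maps).  PD is the profiled complex
    scale; its magnitude is returned.
    """
    prior = prior or InferencePrior()
    if mask.shape != frames.shape[1:]:
        raise ValueError("mask does not match the frame grid")
    if not mask.any():
        raise ValueError("empty mask")
    sig = frames[:, mask]  # (N, n_vox)
    n_vox = sig.shape[1]
    if noise_sd is None:
        bg = ~mask
        noise_sd = (np.std(frames[:, bg]) / np.sqrt(2)) if bg.any() else 1e-3
        noise_sd = max(float(noise_sd), 1e-12)
    if dictionary is None:
        dictionary = build_dictionary(design, K=K)

    p_match, rho = _match_all(sig, dictionary)
    T1 = p_match[:, 0].astype(float).copy()
    T2 = p_match[:, 1].astype(float).copy()
    PD = np.abs(rho)
    sd_maps = None

    if method == "lsq":
        b = prior.bounds[:2]
        for i in range(n_vox):
            def cost(th):
                m = _model_signals(th[None], design, False, K)[:, 0]
                r = sig[:, i] - _rho_hat(sig[:, i], m) * m
                return np.concatenate([r.real, r.imag])
            res = least_squares(cost, np.array([T1[i], T2[i]]),
                                bounds=(b[:, 0], b[:, 1]), xtol=1e-8)
            T1[i], T2[i] = res.x
            m = _model_signals(res.x[None], design, False, K)[:, 0]
            PD[i] = abs(_rho_hat(sig[:, i], m))
    elif method == "bayes":
        kw = mcmc_kwargs or {}
        sds = np.zeros((2, n_vox))
        for i in range(n_vox):
            summ = posterior_sample(
                sig[:, i], design, prior, noise_sd, seed=seed + i,
                K=K, init=np.array([T1[i], T2[i]])[: len(prior.names)], **kw,
            )
            T1[i], T2[i] = summ.ml[0], summ.ml[1]
            PD[i] = abs(summ.rho_ml)
            sds[:, i] = summ.sd[:2]
        sd_maps = sds
    elif method != "dict":
        raise ValueError(f"unknown method {method!r}")

    def to_map(vals):
        out = np.zeros(mask.shape)
        out[mask] = vals
        return out

    maps = {"PD": to_map(PD), "T1": to_map(T1), "T2": to_map(T2)}
    if sd_maps is not None:
        maps["T1_sd"] = to_map(sd_maps[0])
        maps["T2_sd"] = to_map(sd_maps[1])
    return maps
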