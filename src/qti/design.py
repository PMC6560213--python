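"""Bayesian experimental design of transient-state flip-angle schedules.

The design problem: choose the flip-angle train (here a linear ramp between
two control points ``alpha_a``/``alpha_b``) that simultaneously

* maximizes parameter encoding, measured by the expected log-determinant of
  the Fisher information matrix of the signal with respect to (T1, T2, rho)
  under Gaussian noise, marginalized over a Gaussian tissue-class prior; and
* maximizes the worst-case signal contrast between the mean tissues of each
  class, weighted per class by ``mu_c``.

The combined cost is ``C = -((1 - sum(mu_c)) * U + sum_c mu_c * contrast_c)``
and is minimized by exhaustive search over the two control points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qti.epg import AcquisitionDesign, TissueParameters, simulate_signals

__all__ = [
    "TissueClass",
    "TissueClassPrior",
    "RampSpec",
    "DesignCostBreakdown",
    "default_prior",
    "make_ramp_design",
    "signal_jacobian",
    "information_utility",
    "marginal_utility",
    "contrast_term",
    "design_cost",
    "optimize_ramp",
]

#: floor used for log(u) when the information matrix is singular
LOG_U_FLOOR = np.log(1e-300)

#: EPG order cap used throughout the design search.  For smooth ramps the
#: population of orders above ~N/2 is negligible (the truncation check
#: guards this); 130 is lossless to machine precision for the 260-rep ramp.
DESIGN_SIM_ORDER = 130


@dataclass(frozen=True)
class TissueClass:
    """A named tissue class: mean relaxation times (ms) and their Gaussian
    dispersions (standard deviations, ms)."""

    name: str
    T1: float
    T2: float
    sigma_T1: float
    sigma_T2: float

    def __post_init__(self):
        if self.sigma_T1 <= 0 or self.sigma_T2 <= 0:
            raise ValueError("dispersions must be positive")


@dataclass(frozen=True)
class TissueClassPrior:
    """Mixture-of-Gaussians tissue prior with per-class contrast weights.

    ``weights[c]`` is the contrast weight mu_c of class c; the remaining
    weight ``1 - sum(mu_c)`` multiplies the information utility.
    """

    classes: tuple[TissueClass, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.classes) != len(self.weights):
            raise ValueError("one weight per class required")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() > 1 + 1e-12:
            raise ValueError("need mu_c >= 0 and sum(mu_c) <= 1")

    @property
    def utility_weight(self) -> float:
        return 1.0 - float(np.sum(self.weights))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (T1, T2) pairs from the equal-weight class mixture,
        truncated at zero (negative draws are rejected)."""
        idx = rng.integers(len(self.classes), size=n)
        m1 = np.array([c.T1 for c in self.classes])[idx]
        m2 = np.array([c.T2 for c in self.classes])[idx]
        s1 = np.array([c.sigma_T1 for c in self.classes])[idx]
        s2 = np.array([c.sigma_T2 for c in self.classes])[idx]
        T1 = m1 + s1 * rng.standard_normal(n)
        T2 = m2 + s2 * rng.standard_normal(n)
        bad = (T1 <= 0) | (T2 <= 0)
        while np.any(bad):  # pragma: no cover - needs CoV >> 10%
            T1[bad] = m1[bad] + s1[bad] * rng.standard_normal(bad.sum())
            T2[bad] = m2[bad] + s2[bad] * rng.standard_normal(bad.sum())
            bad = (T1 <= 0) | (T2 <= 0)
        return T1, T2


def default_prior(cov: float = 0.10) -> TissueClassPrior:
    """Brain tissue-class prior: grey matter, white matter, cerebrospinal
    fluid and stationary blood, with contrast weights [0.05, 0.05, 0.1, 0.3]
    and Gaussian dispersions at the given coefficient of variation."""
    means = [("GM", 1450.0, 85.0), ("WM", 900.0, 60.0),
             ("CSF", 3600.0, 1750.0), ("SB", 1740.0, 275.0)]
    classes = tuple(
        TissueClass(n, t1, t2, cov * t1, cov * t2) for n, t1, t2 in means
    )
    return TissueClassPrior(classes=classes, weights=(0.05, 0.05, 0.1, 0.3))


@dataclass(frozen=True)
class RampSpec:
    """Two-control-point linear flip-angle ramp plus fixed timing."""

    alpha_a: float
    alpha_b: float
    N: int = 260
    TR: float = 14.0
    TE: float = 2.0
    d: float = 2.0
    invert: bool = True

    def __post_init__(self):
        if not (0 < self.alpha_a <= self.alpha_b <= 180):
            raise ValueError("need 0 < alpha_a <= alpha_b <= 180")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass(frozen=True)
class DesignCostBreakdown:
    """Utility, per-class contrast terms and the combined scalar cost."""

    utility: float
    contrast: dict[str, float]
    weights: dict[str, float]
    utility_weight: float

    @property
    def total_cost(self) -> float:
        c = sum(self.weights[k] * self.contrast[k] for k in self.contrast)
        return -(self.utility_weight * self.utility + c)


def make_ramp_design(spec: RampSpec) -> AcquisitionDesign:
    """Linear interpolation of N flip angles from alpha_a to alpha_b."""
    flips = np.linspace(spec.alpha_a, spec.alpha_b, spec.N)
    return AcquisitionDesign(
        flip_deg=flips, TR=spec.TR, TE=spec.TE, d=spec.d, invert=spec.invert
    )


def signal_jacobian(
    design: AcquisitionDesign,
    params: TissueParameters,
    which: tuple[str, ...] = ("T1", "T2", "rho"),
    rel_step: float = 1e-4,
    K: int | None = None,
) -> np.ndarray:
    """Central-difference Jacobian of the signal, shape (N, len(which)).

    The derivative with respect to rho is analytic (the signal is linear in
    rho); the others use a symmetric step of ``rel_step`` times the value.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    base = {"T1": params.T1, "T2": params.T2, "v": params.v, "rho": params.rho}
    cols = []
    for name in which:
        if name == "rho":
            s = simulate_signals(design, params.T1, params.T2, params.v,
                                 params.rho, K=K, trunc_tol=None)
            cols.append(s / params.rho)
            continue
        val = base[name]
        h = rel_step * abs(val) if val != 0 else rel_step
        if h == 0:
            raise ValueError(f"degenerate step for parameter {name}")
        lo, hi = dict(base), dict(base)
        lo[name] = val - h
        hi[name] = val + h
        s_hi = simulate_signals(design, hi["T1"], hi["T2"], hi["v"], hi["rho"], K=K,
                                trunc_tol=None)
        s_lo = simulate_signals(design, lo["T1"], lo["T2"], lo["v"], lo["rho"], K=K,
                                trunc_tol=None)
        cols.append((s_hi - s_lo) / (2 * h))
    return np.stack(cols, axis=-1)


def _fisher_det(jac: np.ndarray, noise_sd: float) -> np.ndarray:
    """det of the Gaussian-noise Fisher matrix from a complex Jacobian of
    shape (N, ..., p); batch axes pass through."""
    fim = np.einsum("t...i,t...j->...ij", jac, np.conj(jac)).real
    fim /= noise_sd**2
    det = np.linalg.det(fim)
    return np.maximum(det, 0.0)


def information_utility(
    design: AcquisitionDesign,
    params: TissueParameters,
    noise_sd: float = 0.01,
    which: tuple[str, ...] = ("T1", "T2", "rho"),
    rel_step: float = 1e-4,
    K: int | None = None,
) -> float:
    """u(design; theta) = det of the Fisher information matrix of the signal
    with respect to ``which`` under i.i.d. complex Gaussian noise."""
    jac = signal_jacobian(design, params, which=which, rel_step=rel_step, K=K)
    return float(_fisher_det(jac, noise_sd))


def _batched_log_u(
    design: AcquisitionDesign,
    T1: np.ndarray,
    T2: np.ndarray,
    noise_sd: float,
    rel_step: float,
    K: int | None,
) -> np.ndarray:
    """log u for a batch of stationary (T1, T2) draws with rho = 1.

    All five required simulations per draw (base, T1 +/-, T2 +/-) are run as
    one EPG batch, which is what makes the exhaustive grid search tractable.
    """
    h1, h2 = rel_step * T1, rel_step * T2
    T1b = np.concatenate([T1, T1 + h1, T1 - h1, T1, T1])
    T2b = np.concatenate([T2, T2, T2, T2 + h2, T2 - h2])
    sigs = simulate_signals(design, T1b, T2b, K=K, trunc_tol=None)
    n = T1.size
    s0 = sigs[:, :n]
    dT1 = (sigs[:, n:2 * n] - sigs[:, 2 * n:3 * n]) / (2 * h1)
    dT2 = (sigs[:, 3 * n:4 * n] - sigs[:, 4 * n:5 * n]) / (2 * h2)
    jac = np.stack([dT1, dT2, s0], axis=-1)  # rho derivative = signal at rho=1
    u = _fisher_det(jac, noise_sd)
    out = np.full(n, LOG_U_FLOOR)
    pos = u > 0
    out[pos] = np.log(u[pos])
    return out


def marginal_utility(
    design: AcquisitionDesign,
    prior: TissueClassPrior,
    n_samples: int = 200,
    seed: int = 0,
    noise_sd: float = 0.01,
    rel_step: float = 1e-4,
    K: int | None = DESIGN_SIM_ORDER,
    samples: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Monte-Carlo estimate of U = E_prior[log u]; deterministic given seed.

    ``samples`` may supply pre-drawn (T1, T2) arrays to share common random
    numbers across design evaluations.
    """
    if samples is None:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        samples = prior.sample(n_samples, rng)
    T1, T2 = samples
    return float(np.mean(_batched_log_u(design, T1, T2, noise_sd, rel_step, K)))


def contrast_term(
    design: AcquisitionDesign,
    prior: TissueClassPrior,
    K: int | None = DESIGN_SIM_ORDER,
) -> dict[str, float]:
    """Worst-case peak contrast per class at the class means.

    contrast_c = min over other classes d of max over t of
    |f_t(theta_c) - f_t(theta_d)|, evaluated with rho = 1 and no flow.
    """
    if len(prior.classes) < 2:
        raise ValueError("contrast needs at least two classes")
    T1 = np.array([c.T1 for c in prior.classes])
    T2 = np.array([c.T2 for c in prior.classes])
    sigs = simulate_signals(design, T1, T2, K=K, trunc_tol=None)  # (N, C)
    diff = np.abs(sigs[:, :, None] - sigs[:, None, :]).max(axis=0)  # (C, C)
    np.fill_diagonal(diff, np.inf)
    worst = diff.min(axis=1)
    return {c.name: float(w) for c, w in zip(prior.classes, worst)}


def design_cost(
    design: AcquisitionDesign,
    prior: TissueClassPrior,
    n_samples: int = 200,
    seed: int = 0,
    noise_sd: float = 0.01,
    rel_step: float = 1e-4,
    K: int | None = DESIGN_SIM_ORDER,
    samples: tuple[np.ndarray, np.ndarray] | None = None,
) -> DesignCostBreakdown:
    """Combined design cost: weighted sum of marginal utility and per-class
    contrast, negated so that lower is better."""
    U = marginal_utility(design, prior, n_samples, seed, noise_sd, rel_step, K,
                         samples=samples)
    con = contrast_term(design, prior, K=K)
    weights = {c.name: float(w) for c, w in zip(prior.classes, prior.weights)}
    return DesignCostBreakdown(
        utility=U, contrast=con, weights=weights,
        utility_weight=prior.utility_weight,
    )


def optimize_ramp(
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    prior: TissueClassPrior,
    n_samples: int = 200,
    seed: int = 0,
    noise_sd: float = 0.01,
    ramp_kwargs: dict | None = None,
    K: int | None = DESIGN_SIM_ORDER,
    normalize: bool = False,
) -> tuple[RampSpec, list[dict]]:
    """Exhaustive search of the design cost over a (alpha_a, alpha_b) grid.

    The same prior draws (common random numbers) are reused at every grid
    point.  Points with alpha_a > alpha_b are skipped.  Ties break toward
    smaller alpha_a, then smaller alpha_b.  Returns the best ramp and the
    full landscape as a list of records for inspection/plotting.

    With ``normalize=True`` the utility and each per-class contrast term are
    min-max normalized over the evaluated grid before weighting, making the
    log-scale utility and the linear-scale contrasts commensurate; the raw
    cost is recorded in the landscape either way.
    """
    grid_a = np.atleast_1d(np.asarray(grid_a, dtype=float))
    grid_b = np.atleast_1d(np.asarray(grid_b, dtype=float))
    if grid_a.size == 0 or grid_b.size == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    samples = prior.sample(n_samples, rng)
    kwargs = ramp_kwargs or {}
    landscape: list[dict] = []
    specs: list[RampSpec] = []
    for aa in np.sort(grid_a):
        for ab in np.sort(grid_b):
            if aa > ab:
                continue
            spec = RampSpec(alpha_a=float(aa), alpha_b=float(ab), **kwargs)
            bd = design_cost(make_ramp_design(spec), prior, noise_sd=noise_sd,
                             K=K, samples=samples)
            rec = {"alpha_a": float(aa), "alpha_b": float(ab),
                   "utility": bd.utility, "cost": bd.total_cost}
            rec.update({f"contrast_{k}": v for k, v in bd.contrast.items()})
            landscape.append(rec)
            specs.append(spec)
    if not landscape:
        raise ValueError("no feasible grid point (alpha_a <= alpha_b)")
    cost = np.array([r["cost"] for r in landscape])
    if normalize:
        def mm(x):
            x = np.asarray(x, dtype=float)
            rng_ = x.max() - x.min()
            return (x - x.min()) / rng_ if rng_ > 0 else np.zeros_like(x)

        total = prior.utility_weight * mm([r["utility"] for r in landscape])
        for cls, w in zip(prior.classes, prior.weights):
            total = total + w * mm([r[f"contrast_{cls.name}"]
                                    for r in landscape])
        cost = -total
        for r, cn in zip(landscape, cost):
            r["cost_normalized"] = float(cn)
    i_best = int(np.argmin(cost))  # scan order already breaks ties as specified
    return specs[i_best], landscape
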