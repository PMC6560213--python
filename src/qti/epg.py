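"""Extended Phase Graph (EPG) simulation of transient-state sequences with inflow.

The magnetization of a voxel is tracked as a matrix of Fourier configuration
states: ``F[k]`` (transverse, dephasing), ``Fstar[k]`` (transverse, rephasing,
stored as the conjugate states so that ``Fstar[0] == conj(F[0])``) and ``Z[k]``
(longitudinal), for dephasing orders ``k = 0..K-1``.  RF excitation, relaxation
and unbalanced gradient dephasing act as linear operators on this matrix;
through-plane flow is modelled as plug-flow washout that replaces a fraction of
the slice magnetization with fresh, fully relaxed spins every repetition.

All operators broadcast over trailing axes of the state arrays, so the same
code simulates a single tissue or a whole batch of parameter draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from qti import _epg_kernel as _kernel

__all__ = [
    "AcquisitionDesign",
    "TissueParameters",
    "ConfigurationStateMatrix",
    "SignalEvolution",
    "TruncationWarning",
    "apply_rf",
    "apply_relaxation",
    "apply_gradient_shift",
    "washout_fraction",
    "apply_flow",
    "simulate_signal",
    "simulate_signals",
]


class TruncationWarning(UserWarning):
    """Raised when magnetization reaching the highest retained EPG order is
    above tolerance, i.e. the state-order cap ``K`` is too small."""


@dataclass(frozen=True)
class AcquisitionDesign:
    """Design variables of a transient-state acquisition.

    Parameters
    ----------
    flip_deg : array of N flip angles, degrees.
    phase_deg : scalar or array of RF phases, degrees (default 0: no RF
        spoiling; the sequence relies on unbalanced gradients only).
    TR, TE : repetition / echo time, ms.
    d : slice thickness, mm.
    invert : apply an ideal 180 degree inversion before the first repetition.
    inv_delay_ms : delay between inversion and first excitation, ms.
    inv_duration_ms : duration of the inversion event; counted toward scan
        time only (the magnetization model treats the pulse as instantaneous).
    """

    flip_deg: np.ndarray
    TR: float
    TE: float
    d: float = 2.0
    invert: bool = True
    phase_deg: np.ndarray | float = 0.0
    inv_delay_ms: float = 0.0
    inv_duration_ms: float = 20.0

    def __post_init__(self):
        flips = np.atleast_1d(np.asarray(self.flip_deg, dtype=float))
        object.__setattr__(self, "flip_deg", flips)
        phases = np.broadcast_to(
            np.asarray(self.phase_deg, dtype=float), flips.shape
        ).copy()
        object.__setattr__(self, "phase_deg", phases)
        if flips.size < 1:
            raise ValueError("design needs at least one repetition")
        if np.any((flips < 0) | (flips > 180)):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if not (0 < self.TE < self.TR):
            raise ValueError("need 0 < TE < TR")
        if self.d <= 0:
            raise ValueError("slice thickness must be positive")

    @property
    def N(self) -> int:
        return int(self.flip_deg.size)

    @property
    def duration_s(self) -> float:
        """Scan time per slice in seconds (inversion event included)."""
        dur_ms = self.N * self.TR
        if self.invert:
            dur_ms += self.inv_duration_ms
        return dur_ms / 1000.0

    @property
    def t_echo_ms(self) -> np.ndarray:
        """Echo timestamps, ms from the start of the acquisition."""
        t0 = self.inv_duration_ms + self.inv_delay_ms if self.invert else 0.0
        return t0 + np.arange(self.N) * self.TR + self.TE


@dataclass(frozen=True)
class TissueParameters:
    """Biophysical voxel parameters: relaxation times (ms), through-plane
    velocity (mm/s) and complex proton-density scale."""

    T1: float
    T2: float
    v: float = 0.0
    rho: complex = 1.0

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("relaxation times must be positive")
        if self.v < 0:
            raise ValueError("velocity must be nonnegative")


@dataclass
class ConfigurationStateMatrix:
    """EPG state: complex arrays of shape ``(K, ...)`` indexed by order k.

    ``Fstar[k]`` stores the conjugate rephasing states, so the physical
    relation F*_0 = conj(F_0) reads ``Fstar[0] == conj(F[0])`` here.
    """

    F: np.ndarray
    Fstar: np.ndarray
    Z: np.ndarray

    @property
    def K(self) -> int:
        return self.F.shape[0]

    @classmethod
    def equilibrium(cls, K: int, batch_shape: tuple = ()) -> "ConfigurationStateMatrix":
        if K < 1:
            raise ValueError("K must be >= 1")
        shape = (K,) + tuple(batch_shape)
        F = np.zeros(shape, dtype=complex)
        Z = np.zeros(shape, dtype=complex)
        Z[0] = 1.0
        return cls(F=F, Fstar=F.copy(), Z=Z)

    def copy(self) -> "ConfigurationStateMatrix":
        return ConfigurationStateMatrix(self.F.copy(), self.Fstar.copy(), self.Z.copy())


@dataclass
class SignalEvolution:
    """Complex signal rho * F_0(t) sampled at the N echo times."""

    s: np.ndarray
    t_echo: np.ndarray


def apply_rf(
    state: ConfigurationStateMatrix, flip: float, phase: float = 0.0
) -> ConfigurationStateMatrix:
    """Mix (F, Fstar, Z) at every order k by the standard 3x3 EPG rotation."""
    if not 0.0 <= flip <= 180.0:
        raise ValueError("flip must be in [0, 180] degrees")
    if not np.isfinite(phase):
        raise ValueError("phase must be finite")
    a = np.deg2rad(flip)
    p = np.deg2rad(phase)
    ca2, sa2 = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2
    sa, ca = np.sin(a), np.cos(a)
    ep, e2p = np.exp(1j * p), np.exp(2j * p)
    F, Fs, Z = state.F, state.Fstar, state.Z
    Fn = ca2 * F + e2p * sa2 * Fs - 1j * ep * sa * Z
    Fsn = sa2 / e2p * F + ca2 * Fs + 1j / ep * sa * Z
    Zn = -0.5j / ep * sa * F + 0.5j * ep * sa * Fs + ca * Z
    return ConfigurationStateMatrix(Fn, Fsn, Zn)


def apply_relaxation(state, T1, T2, dt) -> ConfigurationStateMatrix:
    """T2 decay on transverse orders, T1 decay plus Z0 recovery toward 1."""
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be nonnegative")
    E1 = np.exp(-dt / np.asarray(T1))
    E2 = np.exp(-dt / np.asarray(T2))
    Z = E1 * state.Z
    Z[0] = Z[0] + (1.0 - E1)
    return ConfigurationStateMatrix(E2 * state.F, E2 * state.Fstar, Z)


def apply_gradient_shift(
    state: ConfigurationStateMatrix, trunc_tol: float | None = None
) -> ConfigurationStateMatrix:
    """One unit of gradient dephasing: F_k -> F_{k+1}, rephasing states move
    toward and across k = 0 (with conjugation at the crossing); Z unchanged.

    If ``trunc_tol`` is given, warn when the population pushed past the
    highest retained order exceeds it.
    """
    F, Fs = state.F, state.Fstar
    if trunc_tol is not None:
        lost = np.max(np.abs(F[-1]))
        if lost > trunc_tol:
            warnings.warn(
                f"EPG order cap too small: |F[K-1]| = {lost:.3g} > {trunc_tol:.3g}",
                TruncationWarning,
                stacklevel=2,
            )
    Fn = np.empty_like(F)
    Fn[1:] = F[:-1]
    Fsn = np.empty_like(Fs)
    Fsn[:-1] = Fs[1:]
    Fsn[-1] = 0.0
    Fn[0] = np.conj(Fsn[0])
    return ConfigurationStateMatrix(Fn, Fsn, state.Z.copy())


def washout_fraction(dt, v, d):
    """Fraction of slice spins remaining after time ``dt`` under plug flow at
    velocity ``v`` through a slice of thickness ``d``: max(0, 1 - dt*v/d).

    dt in ms, v in mm/s, d in mm.  Returns 1 when v = 0 or dt = 0.
    """
    dt = np.asarray(dt, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(dt < 0) or np.any(v < 0):
        raise ValueError("dt and v must be nonnegative")
    if d <= 0:
        raise ValueError("slice thickness must be positive")
    h = 1.0 - (dt / 1000.0) * v / d
    return np.maximum(0.0, h)[()] if h.ndim == 0 else np.maximum(0.0, h)


def apply_flow(state: ConfigurationStateMatrix, h) -> ConfigurationStateMatrix:
    """Plug-flow washout: scale every state by h, add (1-h) of fresh
    equilibrium magnetization to Z_0."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("washout fraction must lie in [0, 1]")
    Z = h * state.Z
    Z[0] = Z[0] + (1.0 - h)
    return ConfigurationStateMatrix(h * state.F, h * state.Fstar, Z)


def _run_sequence(design: AcquisitionDesign, T1, T2, v, rho, K, trunc_tol):
    """Shared event loop; T1/T2/v/rho may be scalars or 1-d batches."""
    batch = np.broadcast(
        np.asarray(T1, float), np.asarray(T2, float), np.asarray(v, float),
        np.asarray(rho, complex),
    )
    state = ConfigurationStateMatrix.equilibrium(K, batch.shape)
    if design.invert:
        state = apply_rf(state, 180.0, 0.0)
        if design.inv_delay_ms > 0:
            state = apply_relaxation(state, T1, T2, design.inv_delay_ms)
    h = washout_fraction(design.TR, v, design.d)
    sig = np.empty((design.N,) + batch.shape, dtype=complex)
    TE, Trec = design.TE, design.TR - design.TE
    lost = 0.0
    for t in range(design.N):
        state = apply_rf(state, design.flip_deg[t], design.phase_deg[t])
        state = apply_relaxation(state, T1, T2, TE)
        sig[t] = np.asarray(rho) * state.F[0]
        state = apply_relaxation(state, T1, T2, Trec)
        if trunc_tol is not None:
            lost = max(lost, np.max(np.abs(state.F[-1])))
        state = apply_gradient_shift(state)
        state = apply_flow(state, h)
    if trunc_tol is not None and lost > trunc_tol:
        warnings.warn(
            f"EPG order cap K={K} too small: truncated population "
            f"{lost:.3g} > {trunc_tol:.3g}",
            TruncationWarning,
            stacklevel=3,
        )
    return sig


def simulate_signal(
    design: AcquisitionDesign,
    params: TissueParameters,
    K: int | None = None,
    trunc_tol: float = 1e-6,
) -> SignalEvolution:
    """Simulate the complex transient-state signal f_t = rho * F_0(t).

    Per repetition: RF pulse, relax over TE, record the echo, relax over
    TR - TE, one unit of gradient dephasing, then plug-flow washout with the
    per-repetition remaining fraction h = max(0, 1 - TR*v/d).  An optional
    ideal inversion precedes the first repetition.

    ``K`` defaults to N + 1, which is lossless for one dephasing unit per TR.
    """
    if K is None:
        K = design.N + 1
    s = _run_sequence(
        design, params.T1, params.T2, params.v, params.rho, K, trunc_tol
    )
    return SignalEvolution(s=s, t_echo=design.t_echo_ms)


def simulate_signals(
    design: AcquisitionDesign,
    T1,
    T2,
    v=0.0,
    rho=1.0,
    K: int | None = None,
    trunc_tol: float | None = 1e-6,
) -> np.ndarray:
    """Vectorized :func:`simulate_signal` over batches of tissue parameters.

    Returns a complex array of shape ``(N,) + broadcast(T1, T2, v, rho)``.
    A reduced order cap ``K`` trades accuracy for speed; the truncation
    warning fires if the cap is too aggressive.  With ``trunc_tol=None`` a
    JIT-compiled event loop (numerically equivalent to the operator
    composition) is used when available.
    """
    if K is None:
        K = design.N + 1
    if trunc_tol is None and _kernel.HAVE_NUMBA:
        shape = np.broadcast(
            np.asarray(T1, float), np.asarray(T2, float),
            np.asarray(v, float), np.asarray(rho, complex),
        ).shape
        T1b, T2b, vb, rb = np.broadcast_arrays(
            np.asarray(T1, float), np.asarray(T2, float),
            np.asarray(v, float), np.asarray(rho, complex),
        )
        out = _kernel.run_fast(design, T1b.ravel(), T2b.ravel(), vb.ravel(),
                               rb.ravel(), K)
        return out.reshape((design.N,) + shape)
    return _run_sequence(design, T1, T2, v, rho, K, trunc_tol)
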