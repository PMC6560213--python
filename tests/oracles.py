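"""Independent brute-force oracles used to validate the fast implementations.

The isochromat simulator integrates the Bloch equations for an ensemble of
spins with uniform intra-voxel gradient dephasing — no configuration-state
bookkeeping — and must agree with the EPG engine for stationary tissue.
"""

from __future__ import annotations

import numpy as np


def _rot_rf(flip_deg: float, phase_deg: float) -> np.ndarray:
    """Rotation by flip about an axis in the transverse plane at angle phase."""
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(a), -np.sin(a)],
                   [0, np.sin(a), np.cos(a)]])
    rz = np.array([[np.cos(p), -np.sin(p), 0],
                   [np.sin(p), np.cos(p), 0],
                   [0, 0, 1]])
    return rz @ rx @ rz.T


def isochromat_signal(design, T1, T2, v=0.0, rho=1.0, n_spins=256):
    """Mean transverse magnetization of a uniformly dephased spin ensemble.

    Follows the same event schedule as the EPG engine: (inversion) ->
    [RF -> relax TE -> echo -> relax TR-TE -> gradient precession ->
    flow replacement] per repetition.  Gradient dephasing advances spin j by
    2*pi*j/n_spins per repetition.
    """
    M = np.zeros((n_spins, 3))
    M[:, 2] = 1.0
    phis = 2 * np.pi * np.arange(n_spins) / n_spins

    def relax(M, dt):
        e1, e2 = np.exp(-dt / T1), np.exp(-dt / T2)
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1 - e1)
        return M

    if design.invert:
        M = M @ _rot_rf(180.0, 0.0).T
        if design.inv_delay_ms > 0:
            M = relax(M, design.inv_delay_ms)
    h = max(0.0, 1.0 - (design.TR / 1000.0) * v / design.d)
    out = np.empty(design.N, dtype=complex)
    for t in range(design.N):
        M = M @ _rot_rf(design.flip_deg[t], design.phase_deg[t]).T
        M = relax(M, design.TE)
        out[t] = rho * np.mean(M[:, 0] + 1j * M[:, 1])
        M = relax(M, design.TR - design.TE)
        c, s = np.cos(phis), np.sin(phis)
        mx = M[:, 0] * c - M[:, 1] * s
        my = M[:, 0] * s + M[:, 1] * c
        M[:, 0], M[:, 1] = mx, my
        M = h * M + (1 - h) * np.array([0.0, 0.0, 1.0])
    return out
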