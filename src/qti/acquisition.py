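"""Digital phantoms, variable-density spiral sampling, coil maps and the
simulated transient-state acquisition.

The forward model per repetition t is  y_t = U_t F S x_t : the voxel-wise
transient signal image x_t (from the EPG engine) is weighted by each coil
sensitivity S, transformed by the non-uniform Fourier operator F and sampled
on the spiral interleave U_t assigned to that repetition by the golden-angle
schedule; circular complex Gaussian noise is added per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qti.epg import AcquisitionDesign, simulate_signals
from qti.nufft import FramewiseNufft

__all__ = [
    "DigitalPhantom",
    "SpiralSampling",
    "CoilSet",
    "KSpaceData",
    "GOLDEN_ANGLE_DEG",
    "make_phantom",
    "make_spiral",
    "make_coils",
    "acquire",
    "voxel_signals",
]

GOLDEN_ANGLE_DEG = 111.246117975


@dataclass
class DigitalPhantom:
    """Single-slice parameter maps on an n_y x n_x grid.

    T1/T2 in ms, rho dimensionless, v in mm/s (nonzero only inside vessels),
    labels: integer class map with ``label_names[i]`` naming class i
    (0 is background).
    """

    T1: np.ndarray
    T2: np.ndarray
    rho: np.ndarray
    v: np.ndarray
    labels: np.ndarray
    label_names: tuple[str, ...]
    fov_mm: float

    def __post_init__(self):
        shapes = {m.shape for m in (self.T1, self.T2, self.rho, self.v, self.labels)}
        if len(shapes) != 1:
            raise ValueError("phantom maps must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.T1.shape

    @property
    def support(self) -> np.ndarray:
        return self.rho != 0


@dataclass
class SpiralSampling:
    """Variable-density spiral readout with a per-repetition rotation.

    ``base_k``: (n_interleaves, M, 2) base interleave coordinates in
    cycles/FOV (ky, kx); repetition t reads interleave ``interleave_idx[t]``
    rotated by ``angle_deg[t]``.
    """

    base_k: np.ndarray
    interleave_idx: np.ndarray
    angle_deg: np.ndarray
    n_dense: int
    matrix: int
    fov_mm: float

    @property
    def n_interleaves(self) -> int:
        return self.base_k.shape[0]

    @property
    def samples_per_readout(self) -> int:
        return self.base_k.shape[1]

    @property
    def n_repetitions(self) -> int:
        return self.interleave_idx.size

    def coords(self, t: int) -> np.ndarray:
        """Rotated (ky, kx) coordinates of repetition t, cycles/FOV."""
        k = self.base_k[self.interleave_idx[t]]
        a = np.deg2rad(self.angle_deg[t])
        rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        return k @ rot.T

    def omega(self, t: int) -> np.ndarray:
        """Coordinates of repetition t in radians/pixel for the NUFFT."""
        return self.coords(t) * (2 * np.pi / self.matrix)

    def omega_all(self) -> np.ndarray:
        """(N, M, 2) radian coordinates for every repetition."""
        return np.stack([self.omega(t) for t in range(self.n_repetitions)])


@dataclass
class CoilSet:
    """Complex receive sensitivity maps, root-sum-of-squares normalized."""

    maps: np.ndarray  # (n_coils, ny, nx)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass
class KSpaceData:
    """Simulated multi-coil spiral samples: (repetition, coil, sample)."""

    y: np.ndarray
    noise_sd: float
    design: AcquisitionDesign
    sampling: SpiralSampling
    coils: CoilSet


# ----------------------------------------------------------------- phantoms

_CLASS_TABLE = {  # name -> (T1 ms, T2 ms)
    "GM": (1450.0, 85.0),
    "WM": (900.0, 60.0),
    "CSF": (3600.0, 1750.0),
    "blood": (1740.0, 275.0),
}


def _disk(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ellipse(shape, cy, cx, ry, rx):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_phantom(
    kind: str,
    shape: tuple[int, int] = (64, 64),
    fov_mm: float = 225.0,
    seed: int = 0,
    vessel_velocity: float = 50.0,
    tube_values: list[tuple[float, float]] | None = None,
) -> DigitalPhantom:
    """Build a deterministic 2-D digital phantom.

    ``tubes``: disks with specified (T1, T2) on an empty background;
    ``brain2d``: head ellipse with WM/GM/CSF compartments at the brain class
    means plus vessel disks carrying blood relaxation times and
    through-plane velocity ``vessel_velocity``.
    """
    if min(shape) < 32:
        raise ValueError("phantom grid must be at least 32 x 32")
    ny, nx = shape
    T1 = np.zeros(shape)
    T2 = np.zeros(shape)
    rho = np.zeros(shape)
    v = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)

    if kind == "tubes":
        vals = tube_values or [
            (250, 40), (500, 60), (900, 80), (1400, 110), (2000, 200), (3000, 800)
        ]
        names = ["background"]
        n = len(vals)
        r = min(ny, nx) / (2.5 * np.ceil(np.sqrt(n)) + 1)
        cols = int(np.ceil(np.sqrt(n)))
        for i, (t1, t2) in enumerate(vals):
            cy = (i // cols + 0.5) * ny / cols
            cx = (i % cols + 0.5) * nx / cols
            m = _disk(shape, cy, cx, r)
            T1[m], T2[m], rho[m], labels[m] = t1, t2, 1.0, i + 1
            names.append(f"tube{i}")
    elif kind == "brain2d":
        names = ["background", "WM", "GM", "CSF", "vessel"]
        cy, cx = ny / 2 - 0.5, nx / 2 - 0.5
        head = _ellipse(shape, cy, cx, 0.45 * ny, 0.40 * nx)
        wm = _ellipse(shape, cy, cx, 0.34 * ny, 0.29 * nx)
        # GM: cortical ribbon between head and WM
        gm = head & ~wm
        T1[gm], T2[gm], labels[gm] = *_CLASS_TABLE["GM"], 2
        T1[wm], T2[wm], labels[wm] = *_CLASS_TABLE["WM"], 1
        for dy, dx in ((-0.10, -0.07), (-0.10, 0.07)):  # lateral ventricles
            vent = _ellipse(shape, cy + dy * ny, cx + dx * nx, 0.10 * ny, 0.045 * nx)
            T1[vent], T2[vent], labels[vent] = *_CLASS_TABLE["CSF"], 3
        rng = np.random.default_rng(seed)
        n_vessel = 4
        placed = 0
        while placed < n_vessel:
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.15, 0.38)
            vy, vx = cy + rad * ny * np.sin(ang), cx + rad * nx * np.cos(ang)
            m = _disk(shape, vy, vx, max(1.5, 0.022 * nx))
            if not (m & head).any() or (labels[m] == 4).any():
                continue
            m &= head
            T1[m], T2[m], labels[m] = *_CLASS_TABLE["blood"], 4
            v[m] = vessel_velocity
            placed += 1
        rho[head] = 1.0
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")
    return DigitalPhantom(T1, T2, rho, v, labels, tuple(names), fov_mm)


# ------------------------------------------------------------------- spiral

def make_spiral(
    fov_mm: float = 225.0,
    resolution_mm: float | None = None,
    matrix: int | None = 64,
    n_interleaves: int = 89,
    n_dense: int = 18,
    samples_per_readout: int | None = None,
    core_fraction: float = 0.2,
    n_repetitions: int = 260,
    rotation: str = "golden",
) -> SpiralSampling:
    """Analytic variable-density spiral with golden-angle rotation.

    Each interleave reaches ``k_max = matrix/2`` cycles/FOV (i.e. 1/(2 *
    resolution)); the inner ``core_fraction`` of k-space is fully sampled by
    ``n_dense`` interleaves and the periphery by all ``n_interleaves``.
    ``rotation='golden'`` rotates the interleave of repetition t by
    t * 111.246 degrees; ``rotation='permute'`` cycles through golden-ratio
    permuted interleaves without continuous rotation.
    """
    if resolution_mm is not None:
        matrix = int(round(fov_mm / resolution_mm))
    if matrix is None or matrix < 8:
        raise ValueError("resolution incompatible with FOV (matrix too small)")
    if n_dense > n_interleaves:
        raise ValueError("n_dense must not exceed n_interleaves")
    kmax = matrix / 2.0
    r_core = core_fraction * kmax

    # azimuthal rate: with n_eff(r) interleaves the spiral pitch keeps the
    # full interleave set at Nyquist density; blend smoothly across the core
    def n_eff(r):
        ramp = np.clip((r - r_core) / max(kmax - r_core, 1e-9), 0, 1)
        return n_dense + (n_interleaves - n_dense) * ramp

    # integrate dtheta/dr = 2*pi / n_eff(r) on a fine radial grid
    rr = np.linspace(0, kmax, 4096)
    theta = np.concatenate(
        [[0], np.cumsum(2 * np.pi / n_eff(rr[1:]) * np.diff(rr))]
    )
    # arc length to place samples ~1 k-space unit apart (critically sampled)
    dtheta = np.gradient(theta, rr)
    ds = np.sqrt(1 + (rr * dtheta) ** 2)
    s = np.concatenate([[0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(rr))])
    if samples_per_readout is None:
        samples_per_readout = int(np.ceil(s[-1]))
    s_t = np.linspace(0, s[-1], samples_per_readout)
    r_t = np.interp(s_t, s, rr)
    th_t = np.interp(r_t, rr, theta)
    base = np.stack([r_t * np.sin(th_t), r_t * np.cos(th_t)], axis=-1)

    arm_angles = 360.0 * np.arange(n_interleaves) / n_interleaves
    base_k = np.empty((n_interleaves, samples_per_readout, 2))
    for i, a in enumerate(np.deg2rad(arm_angles)):
        rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        base_k[i] = base @ rot.T

    t = np.arange(n_repetitions)
    if rotation == "golden":
        interleave_idx = np.zeros(n_repetitions, dtype=int)
        angle = (t * GOLDEN_ANGLE_DEG) % 360.0
    elif rotation == "permute":
        step = int(round(n_interleaves * (GOLDEN_ANGLE_DEG / 360.0)))
        interleave_idx = (t * step) % n_interleaves
        angle = np.zeros(n_repetitions)
    else:
        raise ValueError("rotation must be 'golden' or 'permute'")
    return SpiralSampling(
        base_k=base_k, interleave_idx=interleave_idx, angle_deg=angle,
        n_dense=n_dense, matrix=matrix, fov_mm=fov_mm,
    )


# -------------------------------------------------------------------- coils

def make_coils(shape: tuple[int, int], n_coils: int = 8, seed: int = 0) -> CoilSet:
    """Smooth synthetic receive maps: Gaussian magnitude lobes placed around
    the FOV with gentle linear phase, RSS-normalized at every voxel."""
    if n_coils < 1:
        raise ValueError("need at least one coil")
    ny, nx = shape
    if n_coils == 1:
        return CoilSet(maps=np.ones((1, ny, nx), dtype=complex))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:ny, :nx]
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
        cy = ny / 2 + 0.55 * ny * np.sin(ang)
        cx = nx / 2 + 0.55 * nx * np.cos(ang)
        w = 0.6 * max(ny, nx) * (1 + rng.normal(0, 0.05))
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w**2))
        ph = rng.normal(0, 0.5) + (rng.normal(0, 1.5) * (xx - nx / 2)
                                   + rng.normal(0, 1.5) * (yy - ny / 2)) / nx
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return CoilSet(maps=maps / rss)


# ------------------------------------------------------------------ acquire

def voxel_signals(
    phantom: DigitalPhantom,
    design: AcquisitionDesign,
    K: int | None = None,
) -> np.ndarray:
    """Per-voxel transient signals x_t as an (N, ny, nx) stack.

    Signals are simulated once per unique (T1, T2, v) tuple on the phantom
    support and mapped back exactly (no interpolation), then scaled by rho.
    """
    sup = phantom.support
    frames = np.zeros((design.N,) + phantom.shape, dtype=complex)
    if not sup.any():
        return frames
    keys = np.stack([phantom.T1[sup], phantom.T2[sup], phantom.v[sup]], axis=1)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    sigs = simulate_signals(design, uniq[:, 0], uniq[:, 1], uniq[:, 2])
    frames[:, sup] = sigs[:, inv] * phantom.rho[sup]
    return frames


def acquire(
    phantom: DigitalPhantom,
    design: AcquisitionDesign,
    sampling: SpiralSampling,
    coils: CoilSet,
    noise_sd: float = 0.0,
    seed: int = 0,
    nufft: FramewiseNufft | None = None,
) -> KSpaceData:
    """Simulate the undersampled multi-coil spiral acquisition."""
    if phantom.shape != coils.maps.shape[1:]:
        raise ValueError("phantom and coil geometry mismatch")
    if sampling.n_repetitions != design.N:
        raise ValueError("sampling schedule does not match the design")
    if sampling.matrix != phantom.shape[0] or phantom.shape[0] != phantom.shape[1]:
        raise ValueError("sampling matrix must match the (square) phantom grid")
    frames = voxel_signals(phantom, design)
    if nufft is None:
        nufft = FramewiseNufft(phantom.shape, sampling.omega_all())
    # (coil, N, ny, nx) -> (coil, N, M) -> (N, coil, M)
    weighted = coils.maps[:, None, :, :] * frames[None]
    y = np.transpose(nufft.forward(weighted), (1, 0, 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * (
            rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        )
    return KSpaceData(y=y, noise_sd=noise_sd, design=design,
                      sampling=sampling, coils=coils)
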