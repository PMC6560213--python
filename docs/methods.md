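# Methods

## Signal model

A voxel's magnetization is tracked in the Extended Phase Graph (EPG) basis:
complex configuration states `F[k]` (transverse, dephasing), `Fstar[k]`
(transverse, rephasing; stored as conjugates so `Fstar[0] == conj(F[0])`)
and `Z[k]` (longitudinal) over integer dephasing orders `k`.  Each
repetition of the sequence applies, in order:

1. an instantaneous RF rotation (the standard 3×3 mixing of
   `(F, Fstar, Z)` at every order, parameterized by flip and phase);
2. relaxation over TE (`F` scaled by `exp(−TE/T2)`, `Z` by `exp(−TE/T1)`
   with recovery of `Z[0]` toward 1), after which the echo
   `f_t = ρ·F[0]` is recorded;
3. relaxation over TR − TE;
4. one unit of gradient dephasing from the unbalanced gradient
   (`F_k → F_{k+1}`, rephasing states shifted toward and across k = 0 with
   conjugation at the crossing, `Z` unchanged);
5. plug-flow washout: every state is scaled by
   `h = max(0, 1 − TR·v/d)` and `(1 − h)` of fresh equilibrium
   magnetization is added to `Z[0]`.

An ideal 180° inversion (optionally followed by a delay) precedes the first
repetition.  The washout fraction is applied per repetition with the
constant `h` above rather than accumulated over elapsed time: the recursion
multiplies the surviving fraction every TR, so a per-TR fraction is the form
that reproduces plug-flow washout without double counting.  Assumptions:
constant through-plane velocity, rectangular slice profile, instantaneous
pulses, no diffusion, magnetization transfer, B0/B1 inhomogeneity or
in-plane motion.

RF phase defaults to 0° throughout (no RF spoiling — the sequence relies on
the unbalanced gradient); the phase argument is exposed for other schemes.

**Validation.**  For v = 0 the EPG signal must equal the mean transverse
magnetization of a brute-force isochromat ensemble (256 spins with uniform
per-TR dephasing, same event schedule); the suite checks this to < 1e−6
relative error over random designs.  For `TR·v ≥ d` the model must collapse
to the closed form `ρ·sin(α_t)·exp(−TE/T2)` (fresh equilibrium every
repetition), checked to < 1e−9.

**Order cap.**  `K = N + 1` retains every state a one-shift-per-TR sequence
can populate and is the default.  Batched workloads (design search,
dictionaries, MCMC) use `K = 130` for the 260-repetition ramp: amplitude
that would pass order ~N/2 never returns to the echo through the RF mixing
pathways at double precision, and a test asserts the reduced-order signals
equal the full-order ones to 1e−13.  A truncation warning monitors the
population reaching the top retained order.  A numba-compiled event loop
(numerically identical to the operator composition; asserted in the suite)
accelerates batched simulation ~50×.

## Sequence design

Design variables are the two control points (α_a, α_b) of a linear
flip-angle ramp at fixed N = 260, TE/TR = 2/14 ms, d = 2 mm, with initial
inversion (total 3.66 s per slice including the 20 ms inversion event).
Two criteria are combined:

* **Encoding utility.**  Under i.i.d. complex Gaussian noise the Fisher
  information matrix of the signal with respect to θ = (T1, T2, ρ) is
  `F_ij = Σ_t Re(∂f_t/∂θ_i · conj(∂f_t/∂θ_j))/σ²`; the per-tissue utility is
  `u = det F` and the design utility is `U = E_π[log u]`, a Monte-Carlo
  average over the tissue prior (common random numbers across design
  points).  The first-derivative (Gauss–Newton/CRB) Fisher form is used: it
  is the exact Fisher information for this noise model and is positive
  semidefinite by construction.  Derivatives of T1/T2 are central finite
  differences with relative step 1e−4 (ρ is analytic); `u = 0` contributes
  `log(1e−300)`.  σ defaults to 0.01 of the equilibrium magnetization;
  σ only shifts U by a constant (−2p·log σ) and never moves the argmin.
* **Tissue contrast.**  For each class c at its prior mean (ρ = 1, v = 0),
  `contrast_c = min_{d≠c} max_t |f_t(θ_c) − f_t(θ_d)|` — the worst-case peak
  separation from the competing classes, on complex signals.

The combined cost is
`C = −((1−Σμ_c)·U + Σ_c μ_c·contrast_c)` with the default prior's
μ = [0.05, 0.05, 0.1, 0.3] (GM, WM, CSF, stationary blood) and Gaussian
class dispersions at 10% coefficient of variation.

**A caveat the package is explicit about.**  U is a log-determinant (spans
several log units over a typical grid) while the contrast terms are signal
amplitudes (span ~0.02); in the raw combination the utility term therefore
dominates the landscape, and because the information content of this ramp
family grows monotonically with both control points over the searched range
(1–15° × 40–90°), the raw cost is minimized at the largest grid angles.
`optimize_ramp(..., normalize=True)` offers a min–max normalization of each
term over the evaluated grid, which makes the terms commensurate; the
μ-weighted contrast alone favors a small initial angle (< 10°, driven by the
blood and white/grey-matter terms) and a final angle near 65–75° (driven by
the heavily weighted stationary-blood term).  The landscape CSV records all
raw terms so any weighting can be re-examined offline.  Exhaustive search is
used throughout; ties break toward smaller α_a, then smaller α_b.

## Synthetic acquisition

* **Phantoms.**  `brain2d`: a head ellipse with a white-matter core, a
  cortical grey-matter ribbon, two CSF ventricles at the class means above,
  and four 1.5-voxel-radius vessels carrying blood relaxation times and a
  configurable through-plane velocity (default 50 mm/s, a mid-range arterial
  value); `tubes`: disks with specified (T1, T2).  Deterministic given the
  seed.
* **Spiral.**  An analytic variable-density spiral: the azimuthal rate
  follows a Nyquist pitch for 18 interleaves inside the central 20% of
  k-space, blending to 89 outside, each interleave reaching
  `k_max = matrix/2` cycles/FOV; samples are placed by arc length at ~1
  k-space unit spacing (samples per readout default to critical sampling of
  the arc).  Repetition t reads the base interleave rotated by t × 111.246°
  (continuous golden-angle; a golden-ratio interleave-permutation mode is
  available).  Gradient-hardware constraints are out of scope — the sampling
  geometry, not gradient physics, drives the reconstruction problem.
* **Coils.**  Gaussian-lobe magnitude with gentle linear phase, placed
  around the FOV, root-sum-of-squares normalized; n = 1 gives a uniform
  coil.
* **Forward model.**  Per-voxel signals are simulated once per unique
  (T1, T2, v) tuple and mapped back exactly (no interpolation); each frame
  is coil-weighted and evaluated at that repetition's spiral coordinates
  with the gridding NUFFT; circular complex Gaussian noise is added per
  sample.  30 dB SNR in the studies means `noise_sd = rms(y)/10^(30/20)`.

**NUFFT.**  Type-2/adjoint pair via Kaiser–Bessel gridding: 2× oversampled
FFT, width-8 kernel with the standard shape parameter, analytic
deapodization.  Accuracy vs a direct DFT is ~1e−7 relative; the adjoint is
exact to machine precision by construction (checked by inner-product tests).

## Reconstruction

The frame series x_t is expanded as `x_t = Φ_t·c` with Φ an orthonormal
temporal basis (default rank 10) from the SVD of 1,000 prior signal draws —
half of them carrying velocities uniform in 0–100 mm/s, since inflowing
blood must be representable.  Coefficients solve

    min_c  ½‖A c − y‖² + λ Σ_patches ‖P(c)‖_*

by ADMM: a conjugate-gradient data-consistency step, a singular-value
soft-threshold (threshold λ/ρ) on 8×8 spatial patches of the (voxels × R)
coefficient matrices — equivalent to thresholding the full-time Casorati
matrix restricted to the subspace, at a fraction of the cost — and the
scaled dual update.  Patch tilings are cyclically shifted at random each
outer iteration to avoid block artifacts (disable with
`random_shifts=False`; the logged objective uses a fixed tiling so
iterations are comparable, and monotonicity holds for the deterministic
variant).  The normal operator A^H A is applied through precomputed R×R
Toeplitz kernels on a 2× grid (two batched FFTs per coil per application),
making iteration cost independent of the sample count; the kernels are
validated against the explicit forward/adjoint composition.

λ is specified relative to the largest patch singular value of the
zero-filled (adjoint) reconstruction.  Defaults — λ = 0.001, ADMM penalty
ρ = λ_abs, 50 outer × 10 CG iterations — were calibrated by
reconstruction-NRMSE sweep on the package's standard synthetic problem (64²
brain phantom, one interleave per repetition, 4 coils, 30 dB SNR), where
regularization roughly halves the error of the unregularized solution.
Density compensation is not used (CG handles the Gram structure).

## Inference

The likelihood of a voxel time-course x given (T1, T2) is Gaussian with the
complex proton-density scale profiled analytically:
`ρ̂ = ⟨f, x⟩/‖f‖²`, so `−2σ²·log L = ‖x‖² − |⟨f, x⟩|²/‖f‖²`.  Velocity is
excluded from map fitting by default (the sequence has little sensitivity
to it) but can be enabled.  The posterior under a uniform box prior
(T1 ∈ [100, 5000], T2 ∈ [10, 3000] ms) is sampled with emcee's
affine-invariant ensemble (24 walkers × 400 steps, 150 burn-in),
initialized at the best point of a coarse log-spaced likelihood scan — the
likelihood surface is multimodal enough that a fixed start can trap the
walkers.  The maximum-likelihood point is the best posterior sample,
polished by a bounded Nelder–Mead step.  Non-convergence (acceptance < 5%
or effective sample size < 50) is flagged, not fatal.  Noise is estimated
from background voxels when not supplied.

**Dictionary matching** maximizes `|⟨atom, x⟩|` over unit-norm atoms on a
log-spaced grid (default ~100×100 over the prior box, T2 ≤ T1).  A caveat
measured by the diagnostics in this package: T1 and T2 are strongly
anti-correlated along a ridge for long-T2 (CSF-like) tissue, so the T1 grid
quantization projects into a T2 error several times larger (~10–25% at the
default grid, noiselessly).  Where grid matching is the end product, a
T1-dense anisotropic grid (e.g. 400×120) reduces this; the `lsq` method
(bounded least squares from the dictionary initialization) or the posterior
ML remove it entirely.  This is a property of grid matching, not of the
reconstruction.

## Angiography

`combine_frames` sums |x_t| over an inclusive frame range — default the last
160 of 260 frames (indices 100–259), where stationary tissue is saturated
by the large late flip angles while inflowing blood remains bright — and
`mip` takes the maximum along a chosen axis (frame summation first, then
projection).  On the standard synthetic study the suite asserts
vessel-voxel means exceed white-matter means.

## What the synthetic studies do and do not show

The generator emulates: tissue-class relaxation contrast, plug through-plane
flow, coil-array reception, variable-density spiral undersampling with
golden-angle incoherence, and white complex noise.  It does not emulate:
B0/B1 field inhomogeneity, slice profiles, pulsatile or in-plane flow,
partial-volume mixtures (phantom classes are piecewise constant), gradient
imperfections, or physiological motion.  Passing the suite therefore
demonstrates the internal consistency and numerical correctness of the
chain under its own model assumptions — not performance on scanner data.

## Problem sizes used in the shipped studies

Design search: 15 × 11 control-point grid, 200 prior samples, K = 130.
Standard reconstruction study: 64² grid, 260 repetitions, 74 spiral samples
per readout (critical sampling of the 64-matrix arc), 4 coils, rank 10,
50 ADMM iterations.  Inference checks: single voxels at 260 frames.  These
sizes are deliberate package defaults for a complete, reproducible study on
one CPU; every component accepts larger grids, coil counts and ranks.
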