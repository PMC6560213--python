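# qti — quantitative transient-state imaging

`qti` is a Python toolbox for simulating, designing, reconstructing and
analysing **transient-state quantitative MRI** acquisitions of the brain —
sequences in which the flip angle changes every repetition so that no steady
state forms and the evolving signal simultaneously encodes T1, T2 and proton
density, while flowing blood leaves an exploitable angiographic fingerprint.
It is aimed at MR physicists and methods researchers who want a
self-contained, fully synthetic testbed for this class of methods: every
experiment runs on digital phantoms produced by the package itself.

The toolbox covers the whole chain:

1. **Flow-aware EPG simulation** (`qti.epg`).  Magnetization is propagated
   through the sequence in the Extended Phase Graph basis Ω = {F_k, F*_k,
   Z_k} with per-repetition operators for RF mixing, relaxation and
   unbalanced gradient dephasing.  Through-plane flow at velocity *v* through
   a slice of thickness *d* is modelled as plug-flow washout: each TR a
   fraction `1 − h`, with `h = max(0, 1 − TR·v/d)`, of the slice
   magnetization is replaced by fresh, fully relaxed spins
   (`Ω_t = h·g·Ω_{t−1} + (1−h)·e_z`).  The echo is the k = 0 state:
   `f_t(η; θ) = ρ·F_0(t)`.
2. **Bayesian sequence design** (`qti.design`).  For a linear flip-angle ramp
   between control points (α_a, α_b), the design cost combines the expected
   log-determinant of the Fisher information matrix of (T1, T2, ρ) under
   Gaussian noise, marginalized over a four-class Gaussian tissue prior
   (GM 1450/85, WM 900/60, CSF 3600/1750, stationary blood 1740/275 ms),
   with per-class worst-case peak contrast terms weighted by
   μ_c = [0.05, 0.05, 0.1, 0.3]:
   `C(η) = −((1−Σμ_c)·E_π[log det F(η;θ)] + Σ_c μ_c·min_{d≠c} max_t |f_t(θ_c) − f_t(θ_d)|)`,
   minimized by exhaustive grid search.
3. **Synthetic spiral acquisition** (`qti.acquisition`).  Digital brain/tube
   phantoms, variable-density spiral trajectories (89 interleaves, 18
   covering the dense k-space core, golden-angle rotated by 111.246° per
   repetition), smooth complex coil maps, and the forward model
   `y_t = U_t F S x_t` evaluated with a Kaiser–Bessel gridding NUFFT
   (`qti.nufft`) plus complex Gaussian noise.
4. **Subspace + local-low-rank reconstruction** (`qti.recon`).  The 260-frame
   series is expanded in a rank-10 temporal basis learned by SVD from prior
   signal simulations; coefficients are recovered by ADMM alternating
   conjugate-gradient data consistency (via precomputed Toeplitz kernels)
   with singular-value soft-thresholding of 8×8 spatial patches.
5. **Probabilistic inference** (`qti.inference`).  Per-voxel posteriors
   p(T1, T2 | x) under a Gaussian likelihood with the complex scale ρ
   profiled analytically and a uniform prior, sampled with an ensemble MCMC
   sampler; dictionary matching and bounded least squares as baselines;
   map fitting over masked voxels with uncertainty maps.
6. **Angiography** (`qti.projections`).  Magnitude summation of late frames
   (default: the last 160 of 260) and maximum intensity projection.

## Worked example

```bash
cd examples
python 01_simulate_signals.py
python 03_synthetic_acquisition.py   # writes brain_kspace.h5
python 04_reconstruct.py             # writes frames.nii.gz
python 06_angiography.py
```

`01_simulate_signals.py` prints the per-tissue signal magnitude (units of
the equilibrium magnetization) at four echo times of the 7/70° ramp:

```
sequence duration: 3.66 s per slice

tissue            t=  372 ms  t=  862 ms  t= 1842 ms  t= 3648 ms
WM                  0.0295     0.0495     0.0960     0.0561
GM                  0.0558     0.0007     0.0714     0.0490
CSF                 0.0630     0.0922     0.0605     0.0787
blood v=0           0.0523     0.0290     0.0696     0.1154
blood v=50 mm/s     0.2102     0.3099     0.4267     0.4784
```

White and grey matter swap brightness between the early inversion-recovery
segment and the later ramp (GM passes through its null near 860 ms), and
blood flowing at 50 mm/s is several-fold brighter than any stationary tissue
— the inflow effect the angiographic combination exploits.  After simulation
and reconstruction the chain reports

```
k-space data: (260, 4, 74) (repetition, coil, sample) -> 1.8% of Nyquist per frame
NRMSE vs ground-truth time series: 0.078
mean combined intensity: vessels 70.9 vs white matter 12.7 (5.6x hyperintense)
```

i.e. from 1.8%-sampled frames the subspace + local-low-rank reconstruction
recovers the time series to ~8% error and the late-frame combination leaves
vessels 5.6× brighter than white matter.  `05_infer_uncertainty.py` shows the
posterior widening from WM to CSF at matched noise — the uncertainty trend
that motivates probabilistic inversion.

A thin CLI mirrors the library: `qti design`, `qti recon`, `qti run
config.yaml` (see `qti --help`).

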