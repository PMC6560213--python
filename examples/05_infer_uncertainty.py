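"""Posterior inference of (T1, T2) with uncertainty for single voxels.

Samples the posterior under a Gaussian noise model and a uniform prior; the
complex proton-density scale is profiled out analytically.  Shows the trend
of growing uncertainty from white matter to CSF at identical noise.
"""

import numpy as np

from qti.design import RampSpec, make_ramp_design
from qti.epg import TissueParameters, simulate_signal
from qti.inference import InferencePrior, posterior_sample

design = make_ramp_design(RampSpec(7, 70))
prior = InferencePrior()  # T1 in [100, 5000] ms, T2 in [10, 3000] ms
noise_sd = 0.01
rng = np.random.default_rng(0)
noise = noise_sd * (rng.standard_normal(260) + 1j * rng.standard_normal(260))

print("tissue   truth (T1/T2)    ML estimate        posterior sd     95% CI (T1)")
for name, t1, t2 in [("WM", 900, 60), ("GM", 1450, 85), ("CSF", 3600, 1750)]:
    sig = simulate_signal(design, TissueParameters(t1, t2)).s + noise
    post = posterior_sample(sig, design, prior, noise_sd=noise_sd, seed=1,
                            K=130)
    print(f"{name:6s}  {t1:5d}/{t2:5d}     "
          f"{post.ml[0]:7.0f}/{post.ml[1]:7.1f}    "
          f"{post.sd[0]:6.1f}/{post.sd[1]:6.2f}    "
          f"[{post.ci95[0, 0]:.0f}, {post.ci95[0, 1]:.0f}]")

print(
    "\nAll units ms.  The posterior widens from WM to CSF: long relaxation"
    "\ntimes are encoded more weakly by the 3.66 s acquisition, so their"
    "\nuncertainty is intrinsically larger - the per-voxel error bars the"
    "\nprobabilistic inversion provides on top of the point estimates."
)
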