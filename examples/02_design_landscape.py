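"""Evaluate the Bayesian design cost over a small flip-angle-ramp grid.

The cost combines (i) the expected log-determinant of the Fisher information
of (T1, T2, PD) marginalized over the tissue prior and (ii) the worst-case
peak contrast of each tissue class, weighted by mu_c.  A coarse 4 x 4 grid
keeps this example fast; the full study grid is alpha_a 1..15, alpha_b
40..90.
"""

import numpy as np

from qti.design import default_prior, make_ramp_design, optimize_ramp

prior = default_prior()
best, landscape = optimize_ramp(
    grid_a=np.array([3.0, 7.0, 11.0, 15.0]),
    grid_b=np.array([50.0, 60.0, 70.0, 80.0]),
    prior=prior, n_samples=100, seed=7,
)

print("alpha_a  alpha_b   utility   contrast_SB   cost")
for rec in landscape:
    print(f"{rec['alpha_a']:7.0f}  {rec['alpha_b']:7.0f}  {rec['utility']:8.3f}"
          f"  {rec['contrast_SB']:11.4f}  {rec['cost']:8.4f}")
print(f"\nminimum cost at alpha_a/alpha_b = {best.alpha_a:.0f}/{best.alpha_b:.0f}")
print(
    "\nThe utility (parameter-encoding) term grows with larger flip angles,"
    "\nwhile the stationary-blood contrast term favors small initial angles;"
    "\nthe cost is their mu-weighted combination (lower is better)."
)
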