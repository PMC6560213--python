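"""Simulate transient-state signal evolutions for brain tissues and flowing blood.

Builds the 7->70 degree flip-angle ramp (260 repetitions, TE/TR = 2/14 ms,
2 mm slice, initial inversion) and prints the signal magnitude of each tissue
class at a few time points, plus the inflow enhancement of fast-flowing blood.
"""

import numpy as np

from qti import TissueParameters, simulate_signal
from qti.design import RampSpec, make_ramp_design

design = make_ramp_design(RampSpec(alpha_a=7, alpha_b=70))
print(f"sequence duration: {design.duration_s:.2f} s per slice\n")

tissues = {
    "WM": TissueParameters(T1=900, T2=60),
    "GM": TissueParameters(T1=1450, T2=85),
    "CSF": TissueParameters(T1=3600, T2=1750),
    "blood v=0": TissueParameters(T1=1740, T2=275),
    "blood v=50 mm/s": TissueParameters(T1=1740, T2=275, v=50.0),
}

frames = [25, 60, 130, 259]
header = "tissue".ljust(18) + "".join(f"t={design.t_echo_ms[i]:5.0f} ms  " for i in frames)
print(header)
for name, p in tissues.items():
    s = simulate_signal(design, p).s
    row = "".join(f"{abs(s[i]):8.4f}   " for i in frames)
    print(name.ljust(18) + row)

print(
    "\n|signal| is in units of the equilibrium magnetization."
    "\nShort-T1 white matter recovers from the inversion first (brightest"
    "\nearly); CSF's long T2 sustains large stimulated echoes late; flowing"
    "\nblood stays bright throughout because fresh unsaturated spins wash"
    "\ninto the slice every repetition - the source of angiographic contrast."
)
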