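"""Angiographic projection from the reconstructed time series.

Run 03_synthetic_acquisition.py and 04_reconstruct.py first.  Summing the
magnitudes of the last 160 frames accumulates the inflow hyperintensity of
flowing blood while stationary tissue is saturated; a maximum intensity
projection across slices then renders the vasculature (a single slice here,
so the MIP is the identity).
"""

import nibabel as nib
import numpy as np

from qti.io import load_kspace
from qti.projections import ProjectionSpec, combine_frames, mip

frames_mag = np.asarray(nib.load("frames.nii.gz").dataobj)  # (y, x, t)
frames = np.moveaxis(frames_mag, -1, 0)
n = frames.shape[0]

spec = ProjectionSpec(start=n - 160, end=n - 1)
combined = combine_frames(frames, spec)
projection = mip(combined[None], axis=0)

_, phantom = load_kspace("brain_kspace.h5")
vessel = combined[phantom.labels == 4].mean()
wm = combined[phantom.labels == 1].mean()
print(f"combined frames {spec.start}..{spec.end} (inclusive)")
print(f"mean combined intensity: vessels {vessel:.1f} vs white matter {wm:.1f} "
      f"({vessel / wm:.1f}x hyperintense)")
print(f"projection image: {projection.shape}, max {projection.max():.1f}")
print(
    "\nVessel voxels are several-fold brighter than parenchyma because"
    "\nfresh magnetization flows into the 2 mm slice every repetition -"
    "\nthe same mechanism as time-of-flight angiography, here obtained"
    "\nfrom the quantitative acquisition at no extra scan time."
)
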