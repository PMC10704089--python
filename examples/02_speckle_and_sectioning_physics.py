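"""The physical mechanism of HiLo sectioning: speckle contrast vs defocus.

Generates fully developed laser speckle (exponential intensity statistics,
contrast = std/mean = 1), shows how detection-side defocus blur washes the
imaged contrast out, and measures the same decay through the full contrast
estimator on a rendered uniform fluorescent plane swept through focus.
That decay is what lets the reconstruction distinguish in-focus from
out-of-focus light.
"""

import numpy as np

from specklehilo.experiments import contrast_defocus_sweep
from specklehilo.simulator import PSFModel, defocus_speckle, generate_speckle

field = generate_speckle((512, 512), grain_size_px=4.0, seed=1)
print(f"fully developed speckle, 512x512, grain 4 px: contrast = {field.contrast:.3f} (theory: 1)")

psf = PSFModel()  # NA 0.8, 520 nm emission, water immersion
print("\nimaged speckle contrast vs defocus (detection blur only):")
for dz in (0.0, 1.0, 2.0, 4.0, 8.0):
    print(f"  dz = {dz:3.0f} um   contrast = {defocus_speckle(field, dz, psf).contrast:.3f}")

defocus = (0.0, 2.0, 4.0, 6.0, 8.0)
means = contrast_defocus_sweep(defocus_um=defocus, shape=(256, 256), seed=2)
print("\nbias-corrected contrast map mean for a uniform plane swept through focus:")
for dz, c in zip(defocus, means):
    print(f"  dz = {dz:3.0f} um   <C> = {c:.4f}")
print("\nThe monotone decay encodes depth: the contrast-weighted image keeps only light")
print("from within roughly one speckle axial length of the focal plane.")
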