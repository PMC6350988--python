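"""Normalize one cell to a size-invariant ratio map and extract both
descriptors.

The 49×49 OPL/PL map divides each pixel's optical path length by the
chord length through a sphere of the cell's predicted diameter; for a
smooth spherical cell the result is flat, so any remaining texture is
subcellular structure.
"""

import numpy as np

from qpmcell import (
    PhantomSpec, compute_hog, make_phantom, preprocess_cell, stat_features,
)

cell = make_phantom(PhantomSpec(base="hemi_ellipsoid", diameter_px=60,
                                plateau_opl_nm=450, bump_height_frac=0.11))
print(f"cell crop {cell.crop.shape}, peak OPL {cell.crop.max():.0f} nm")

ncell = preprocess_cell(cell, mode="OPL_PL")
print(f"predicted diameter D = {ncell.diameter_px:.1f} px, resize factors "
      f"m_x = {ncell.m_x:.3f}, m_y = {ncell.m_y:.3f}, m = {ncell.m:.3f}")

hog = compute_hog(ncell)
print(f"HOG descriptor: {hog.values.size} elements, "
      f"{np.count_nonzero(hog.values)} nonzero")

stats = stat_features(ncell)
names = ("mean", "std", "max", "skewness", "kurtosis")
print("statistics of the in-mask OPL/PL values:")
for name, value in zip(names, stats.values):
    print(f"  {name:9s} {value:+.5f}")

# The mean OPL/PL of ~0.03 is the dimensionless refractive-index
# contrast signature; std/skewness/kurtosis quantify the bump texture
# that distinguishes organelle-rich cells from smooth ones.
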