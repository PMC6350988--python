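"""Simulate a full-field phase image and segment the cells out of it.

A quantitative phase microscope's raw field carries a curved background
(wavefront mismatch) on top of which the cells sit.  This example builds
such a field synthetically, removes the curvature with the two-pass
paraboloid fit, and segments single cells with the triangle threshold.
"""

import numpy as np

from qpmcell import FieldSpec, flatten_background, make_field, segment_cells

field, truth = make_field(FieldSpec(shape=(480, 640), n_cells=8, seed=7))
print(f"field: {field.values.shape}, OPL range "
      f"{field.values.min():.0f}..{field.values.max():.0f} nm")

flat, background, mask = flatten_background(field)
print(f"fitted background curvature (a..f): "
      f"{np.array2string(background.coefficients, precision=4)}")
print(f"background pixels after flattening: mean "
      f"{flat.values[~mask].mean():+.2f} nm, std {flat.values[~mask].std():.2f} nm")

cells = segment_cells(flat, min_area_px=50)
print(f"segmented {len(cells)} cells (planted: {len(truth)})")
for cell in cells[:3]:
    print(f"  {cell.source_id}: origin {cell.bbox_origin}, "
          f"area {cell.area_px} px")

# The background statistics show the curvature is gone (mean ~ 0 nm, std
# ~ the 5 nm instrument noise), and every planted cell is recovered.
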