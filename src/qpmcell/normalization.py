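"""Size-invariant preprocessing of segmented cells.

Cell size confounds label-free classification: larger cells are both
wider (more pixels) and optically thicker (larger OPL).  Both axes are
normalized here:

* **longitudinal** — the OPL map is divided either by the predicted
  diameter D (``OPL_D``) or, assuming a floating cell is a sphere of
  diameter D, by the chord length PL(x, y) = 2·√((D/2)² − x² − y²)
  through that sphere (``OPL_PL``).  Both ratios are dimensionless;
  OPL/PL additionally flattens the hemispherical envelope so subcellular
  texture dominates.
* **lateral** — the crop is resampled to a fixed 49×49 raster.  Resizing
  a w×h crop by factors m_x = 49/w, m_y = 49/h rescales spatial
  gradients by ≈1/m, so the resized values are multiplied by the mean
  factor m = (m_x + m_y)/2 to restore gradient magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _resize

from qpmcell.phase_field import SegmentedCell

Mode = Literal["OPL_PL", "OPL_D"]

#: pixels where PL < RIM_FLOOR·D are zeroed in OPL/PL maps; the chord
#: length vanishes at the sphere rim and the quotient would blow up.
RIM_FLOOR = 0.05

TARGET = 49


@dataclass
class NormalizedCell:
    """A 49×49 dimensionless ratio map ready for feature extraction."""

    ratio_map: np.ndarray
    mode: Mode
    m_x: float
    m_y: float
    diameter_px: float
    mask49: np.ndarray
    cell_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.ratio_map = np.asarray(self.ratio_map, dtype=np.float64)
        self.mask49 = np.asarray(self.mask49, dtype=bool)
        if self.ratio_map.shape != (TARGET, TARGET):
            raise ValueError(f"ratio_map must be {TARGET}x{TARGET}")
        if self.mask49.shape != (TARGET, TARGET):
            raise ValueError(f"mask49 must be {TARGET}x{TARGET}")
        if not np.all(np.isfinite(self.ratio_map)):
            raise ValueError("ratio_map values must all be finite")

    @property
    def m(self) -> float:
        """Mean resize factor, (m_x + m_y)/2 exactly."""
        return (self.m_x + self.m_y) / 2.0


def predict_diameter(cell: SegmentedCell) -> float:
    """Predicted diameter D in pixels: mean of the tight mask bounding-box
    width and height (sphere assumption for a floating cell)."""
    r0, c0, r1, c1 = cell.mask_bbox()
    return ((c1 - c0) + (r1 - r0)) / 2.0


def path_length_map(cell: SegmentedCell, D: float) -> np.ndarray:
    """Geometric chord length through a sphere of diameter D (pixels).

    PL(x, y) = 2·√((D/2)² − x² − y²) with (x, y) measured from the mask
    centroid; zero outside the projected sphere.  Units follow D.
    """
    if D <= 0:
        raise ValueError("diameter must be positive")
    rc, cc = ndimage.center_of_mass(cell.mask)
    yy, xx = np.mgrid[0 : cell.mask.shape[0], 0 : cell.mask.shape[1]].astype(float)
    r2 = (xx - cc) ** 2 + (yy - rc) ** 2
    inside = r2 < (D / 2.0) ** 2
    pl = np.zeros_like(r2)
    pl[inside] = 2.0 * np.sqrt((D / 2.0) ** 2 - r2[inside])
    return pl


def normalize_longitudinal(
    cell: SegmentedCell, mode: Mode = "OPL_PL", rim_floor: float = RIM_FLOOR
) -> tuple[np.ndarray, float]:
    """Divide the OPL crop (nm) by D or by PL(x, y), both expressed in nm.

    Returns the dimensionless ratio map and the predicted diameter in
    pixels.  For ``OPL_PL``, pixels with PL ≤ rim_floor·D are set to 0;
    the division is otherwise pointwise.
    """
    D_px = predict_diameter(cell)
    if D_px <= 0:
        raise ValueError("predicted diameter is zero")
    nm_per_px = cell.pixel_pitch_um * 1000.0
    if mode == "OPL_D":
        ratio = cell.crop / (D_px * nm_per_px)
    elif mode == "OPL_PL":
        pl_nm = path_length_map(cell, D_px) * nm_per_px
        floor = rim_floor * D_px * nm_per_px
        ratio = np.where(pl_nm > floor, cell.crop / np.where(pl_nm > floor, pl_nm, 1.0), 0.0)
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return ratio * cell.mask, D_px


def resize_and_compensate(
    ratio_map: np.ndarray, mask: np.ndarray, target: int = TARGET
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Resample to target×target and compensate gradient scaling.

    Bilinear interpolation for values, nearest-neighbour for the mask
    (re-binarized at 0.5).  Every resized value is multiplied by
    m = (m_x + m_y)/2 where m_x = target/w, m_y = target/h.
    Returns (values, mask, m_x, m_y).
    """
    ratio_map = np.asarray(ratio_map, dtype=np.float64)
    h, w = ratio_map.shape
    if h < 2 or w < 2:
        raise ValueError("input crop must be at least 2x2")
    m_x = target / w
    m_y = target / h
    m = (m_x + m_y) / 2.0
    if (h, w) == (target, target):
        values = ratio_map.copy()
        mask49 = np.asarray(mask, bool).copy()
    else:
        values = _resize(
            ratio_map, (target, target), order=1, anti_aliasing=False,
            preserve_range=True, mode="edge",
        )
        mask49 = _resize(
            np.asarray(mask, float), (target, target), order=0,
            anti_aliasing=False, preserve_range=True, mode="edge",
        ) > 0.5
    return values * m, mask49, m_x, m_y


def preprocess_cell(
    cell: SegmentedCell,
    mode: Mode = "OPL_PL",
    rim_floor: float = RIM_FLOOR,
    label: str | None = None,
) -> NormalizedCell:
    """Full normalization chain: diameter → longitudinal ratio → lateral
    resize with gradient compensation.  Deterministic; records D, m_x,
    m_y on the result."""
    ratio, D_px = normalize_longitudinal(cell, mode=mode, rim_floor=rim_floor)
    values, mask49, m_x, m_y = resize_and_compensate(ratio, cell.mask)
    values = np.where(mask49, values, 0.0)
    return NormalizedCell(
        ratio_map=values,
        mode=mode,
        m_x=m_x,
        m_y=m_y,
        diameter_px=D_px,
        mask49=mask49,
        cell_id=cell.source_id,
        label=label,
    )
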