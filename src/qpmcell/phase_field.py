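"""Full-field phase image handling: OPL conversion, background flattening,
and rule-based single-cell segmentation.

A reflection-geometry quantitative phase microscope measures a wrapped
phase delay Δϕ(x, y) that, once unwrapped, is proportional to the optical
path length (OPL) of the sample: light traverses the cell twice, so
Δϕ = (4π/λ)·OPL.  The raw field carries a smooth background curvature
(wavefront mismatch between sample and reference arms) that is removed by
fitting a paraboloid to the background and subtracting it; cells are then
trivially separable from the flat background with an automatic triangle
threshold and connected-component labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from skimage.measure import label as _cc_label, regionprops


class FlattenError(RuntimeError):
    """Background flattening failed (no usable background pixels)."""


class ThresholdError(ValueError):
    """Automatic thresholding failed (degenerate value distribution)."""


class FitError(RuntimeError):
    """Surface fit failed (rank-deficient design)."""


@dataclass
class PhaseImage:
    """A 2-D optical-path-length (or raw phase) map with optics metadata.

    Parameters
    ----------
    values : ndarray
        2-D float grid; OPL in nanometres when ``unit == "opl_nm"``,
        unwrapped phase in radians when ``unit == "phase_rad"``.
    pixel_pitch_um : float
        Object-space size of one pixel in micrometres.
    wavelength_nm : float, optional
        Illumination centre wavelength; required for phase→OPL conversion.
    unit : {"opl_nm", "phase_rad"}
    """

    values: np.ndarray
    pixel_pitch_um: float = 0.27
    wavelength_nm: float | None = 625.0
    unit: Literal["opl_nm", "phase_rad"] = "opl_nm"
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("PhaseImage requires a 2-D value grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PhaseImage values must all be finite")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def height_px(self) -> int:
        return self.values.shape[0]

    @property
    def width_px(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BackgroundModel:
    """Quadratic background surface z(x, y) = a·x² + b·y² + c·x·y + d·x + e·y + f.

    ``x`` is the column index and ``y`` the row index (0-based, origin at
    the top-left pixel); coefficients are in image units.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    def surface(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the model on a pixel grid of the given (rows, cols) shape."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        return (
            self.a * xx**2 + self.b * yy**2 + self.c * xx * yy
            + self.d * xx + self.e * yy + self.f
        )


@dataclass
class SegmentedCell:
    """A single-cell OPL crop with its binary mask and source location.

    ``mask`` is True on cell pixels; it is one 8-connected component and
    ``bbox_origin`` is the (row, col) of the crop's top-left corner in the
    source image (half-open box convention).
    """

    crop: np.ndarray
    mask: np.ndarray
    bbox_origin: tuple[int, int] = (0, 0)
    source_id: str = ""
    pixel_pitch_um: float = 0.27

    def __post_init__(self) -> None:
        self.crop = np.asarray(self.crop, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.crop.shape != self.mask.shape:
            raise ValueError("crop and mask shapes must match")
        if not self.mask.any():
            raise ValueError("mask must contain at least one cell pixel")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def mask_bbox(self) -> tuple[int, int, int, int]:
        """Tight (row0, col0, row1, col1) half-open bounding box of the mask."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def phase_to_opl(image: PhaseImage, single_pass: bool = False) -> PhaseImage:
    """Convert an unwrapped-phase map to OPL in nanometres.

    In reflection geometry the light passes through the sample twice, so
    OPL = Δϕ·λ/(4π).  With ``single_pass=True`` the 2π (transmission)
    convention OPL = Δϕ·λ/(2π) is used instead.
    """
    if image.unit == "opl_nm":
        warnings.warn("image is already in OPL units; returning unchanged")
        return image
    if image.wavelength_nm is None:
        raise ValueError("phase_to_opl requires wavelength_nm metadata")
    factor = 2.0 * np.pi if single_pass else 4.0 * np.pi
    return replace(image, values=image.values * image.wavelength_nm / factor, unit="opl_nm")


def _design_matrix(xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    return np.column_stack([xx**2, yy**2, xx * yy, xx, yy, np.ones_like(xx)])


def fit_paraboloid(
    image: PhaseImage | np.ndarray, exclude_mask: np.ndarray | None = None
) -> BackgroundModel:
    """Least-squares fit of a full bivariate quadratic surface.

    Pixels where ``exclude_mask`` is True (e.g. cells) are ignored.  The
    general 6-coefficient family subsumes tilted paraboloids, which is
    what wavefront-mismatch curvature looks like in practice.
    """
    values = image.values if isinstance(image, PhaseImage) else np.asarray(image, float)
    yy, xx = np.mgrid[0 : values.shape[0], 0 : values.shape[1]].astype(np.float64)
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, bool)
        xx, yy, z = xx[keep], yy[keep], values[keep]
    else:
        xx, yy, z = xx.ravel(), yy.ravel(), values.ravel()
    if z.size < 6:
        raise FitError("need at least 6 background pixels to fit a paraboloid")
    A = _design_matrix(xx, yy)
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < 6:
        raise FitError("degenerate pixel layout: quadratic design is rank-deficient")
    return BackgroundModel(*coef)


def triangle_threshold(values: Sequence[float] | np.ndarray, n_bins: int = 256) -> float:
    """Automatic threshold by the triangle (peak-to-tail chord) algorithm.

    The histogram of ``values`` is built over ``n_bins`` equal-width bins
    spanning the data range.  A straight line is drawn from the histogram
    peak to the farthest non-empty tail bin; the threshold is the bin
    centre maximizing the perpendicular distance between the histogram
    curve and that line (the ImageJ variant).  Works for either tail: the
    longer side of the peak is used.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        raise ThresholdError("triangle threshold undefined for constant input")
    counts, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    peak = int(np.argmax(counts))
    nonempty = np.flatnonzero(counts)
    lo, hi = int(nonempty[0]), int(nonempty[-1])
    # chord runs from the peak to the farther non-empty tail
    tail = hi if (hi - peak) >= (peak - lo) else lo

    i0, i1 = (peak, tail) if tail > peak else (tail, peak)
    idx = np.arange(i0, i1 + 1, dtype=np.float64)
    h = counts[i0 : i1 + 1].astype(np.float64)
    # perpendicular distance from (idx, h) to the line through
    # (peak, counts[peak]) and (tail, counts[tail])
    x1, y1 = float(peak), float(counts[peak])
    x2, y2 = float(tail), float(counts[tail])
    denom = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * idx - (x2 - x1) * h + x2 * y1 - y2 * x1) / denom
    best = int(idx[int(np.argmax(dist))])
    return float(centers[best])


def flatten_background(
    image: PhaseImage, n_bins: int = 256, max_mask_fraction: float = 0.9
) -> tuple[PhaseImage, BackgroundModel, np.ndarray]:
    """Two-pass paraboloid background removal.

    Pass 1 fits a paraboloid to the *whole* image (cells included),
    subtracts it, and triangle-thresholds the residual to get a cell
    mask.  Pass 2 refits the paraboloid to the background-only pixels of
    the *original* image and subtracts that refined surface.  Returns the
    flattened image, the second-pass model, and the cell mask.
    """
    if image.unit != "opl_nm":
        raise ValueError("flatten_background expects an OPL image")
    first = fit_paraboloid(image)
    residual = image.values - first.surface(image.values.shape)
    scale = max(np.ptp(image.values), 1.0)
    if np.ptp(residual) < 1e-8 * scale:
        # image is (numerically) a pure quadratic surface: nothing to mask
        mask = np.zeros_like(residual, dtype=bool)
    else:
        thr = triangle_threshold(residual.ravel(), n_bins=n_bins)
        mask = residual > thr
    if mask.mean() > max_mask_fraction:
        raise FlattenError(
            f"cell mask covers {mask.mean():.0%} of the field; no background to fit"
        )
    second = fit_paraboloid(image, exclude_mask=mask)
    flat = replace(image, values=image.values - second.surface(image.values.shape))
    return flat, second, mask


def segment_cells(
    image: PhaseImage,
    min_area_px: int = 50,
    margin_px: int = 0,
    threshold: float | None = None,
    n_bins: int = 256,
) -> list[SegmentedCell]:
    """Segment single cells from a flattened (background ≈ 0) OPL field.

    Binarizes at the triangle threshold (or an explicit one), labels
    8-connected components, and drops components that are smaller than
    ``min_area_px`` or touch the image border (cells cut by the field of
    view are not valid samples).  Each surviving component is cropped at
    its bounding box padded by ``margin_px``; within a crop, pixels that
    belong to other components or background are False in the mask.
    """
    values = image.values
    if threshold is None:
        threshold = triangle_threshold(values.ravel(), n_bins=n_bins)
    binary = values > threshold
    labels = _cc_label(binary, connectivity=2)
    h, w = values.shape
    out: list[SegmentedCell] = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        r0m, c0m = max(r0 - margin_px, 0), max(c0 - margin_px, 0)
        r1m, c1m = min(r1 + margin_px, h), min(c1 + margin_px, w)
        crop = values[r0m:r1m, c0m:c1m].copy()
        mask = labels[r0m:r1m, c0m:c1m] == region.label
        out.append(
            SegmentedCell(
                crop=crop,
                mask=mask,
                bbox_origin=(r0m, c0m),
                source_id=f"{image.source or 'field'}:{region.label}",
                pixel_pitch_um=image.pixel_pitch_um,
            )
        )
    return out
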