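"""Synthetic OPL phantoms, cell populations, and full-field images.

No real phase images ship with the package, so all tests and simulated
experiments run on generated objects:

* **Phantoms** (:func:`make_phantom`) — geometric OPL maps: a smooth
  base (hemi-ellipsoid cap or a top-hat plateau with a raised-cosine
  shoulder) optionally decorated with a 7×7 grid of radially symmetric
  raised-cosine bumps whose peak height is a fraction of the plateau
  height.  Bumps imitate organelles; sweeping their height from 0 to
  14 % probes what the classifier responds to.
* **Populations** (:func:`sample_population`) — class-labelled cells:
  smooth, smaller "WBC-like" hemispheroids versus larger,
  intracellularly bumpy "cell-line-like" cells, with additive Gaussian
  OPL noise (σ = 5 nm by default, the background noise level of the
  instrument being emulated).
* **Fields** (:func:`make_field`) — full-field images: a curved
  paraboloid background plus disjointly planted cells plus noise, with
  ground truth for segmentation testing.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from qpmcell.phase_field import BackgroundModel, PhaseImage, SegmentedCell

#: Default bump-height series for the interpretation sweep (fractions of
#: plateau height): a smooth phantom plus four heterogeneity levels.
DEFAULT_HEIGHT_SERIES: tuple[float, ...] = (0.0, 0.035, 0.071, 0.11, 0.14)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a single synthetic cell phantom.

    ``bump_height_frac`` is the bump peak height as a fraction of the
    plateau (base apex) height.  ``bump_span_frac`` controls how far the
    7×7 bump grid extends from the centre, as a fraction of the cell
    radius; ``shoulder_frac`` is the top-hat's raised-cosine roll-off
    width as a fraction of the radius.
    """

    base: Literal["top_hat", "hemi_ellipsoid"] = "top_hat"
    plateau_opl_nm: float = 300.0
    diameter_px: float = 40.0
    bump_grid: tuple[int, int] = (7, 7)
    bump_height_frac: float = 0.0
    bump_radius_px: float | None = None
    bump_span_frac: float = 0.6
    shoulder_frac: float = 0.2
    rotation_deg: float = 0.0
    margin_px: int = 5
    pixel_pitch_um: float = 0.27

    def __post_init__(self) -> None:
        if not 0.0 <= self.bump_height_frac <= 1.0:
            raise ValueError("bump_height_frac must lie in [0, 1]")
        if self.diameter_px <= 0 or self.plateau_opl_nm <= 0:
            raise ValueError("diameter and plateau height must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Two-class synthetic training population.

    Diameters are Gaussian in micrometres (truncated positive); bump
    height fractions are uniform over the given (lo, hi) ranges.  Peak
    OPL scales linearly with diameter (``opl_per_um_nm``), so bigger
    cells are optically thicker, as Eq-1-style physics dictates.
    """

    n_per_class: int = 250
    wbc_diameter_um: tuple[float, float] = (10.0, 1.0)
    cl_diameter_um: tuple[float, float] = (18.0, 3.0)
    wbc_bump_height_frac: tuple[float, float] = (0.0, 0.0)
    cl_bump_height_frac: tuple[float, float] = (0.07, 0.14)
    noise_sigma_nm: float = 5.0
    opl_per_um_nm: float = 30.0
    pixel_pitch_um: float = 0.27
    seed: int = 0


@dataclass(frozen=True)
class FieldSpec:
    """A full-field image: curved background plus planted cells."""

    shape: tuple[int, int] = (480, 640)
    background: BackgroundModel = field(
        default_factory=lambda: BackgroundModel(
            a=2e-4, b=3e-4, c=1e-4, d=-0.05, e=-0.08, f=40.0)
    )
    n_cells: int = 8
    population: PopulationSpec = field(default_factory=PopulationSpec)
    noise_sigma_nm: float = 5.0
    seed: int = 0


def _radial_base(spec: PhantomSpec, r: np.ndarray) -> np.ndarray:
    """Noise-free base profile as a function of radius from the centre."""
    R = spec.diameter_px / 2.0
    h = spec.plateau_opl_nm
    if spec.base == "hemi_ellipsoid":
        z = np.zeros_like(r)
        inside = r < R
        z[inside] = h * np.sqrt(1.0 - (r[inside] / R) ** 2)
        return z
    if spec.base == "top_hat":
        Rp = R * (1.0 - spec.shoulder_frac)
        z = np.where(r <= Rp, h, 0.0)
        sh = (r > Rp) & (r < R)
        z[sh] = h * 0.5 * (1.0 + np.cos(np.pi * (r[sh] - Rp) / (R - Rp)))
        return z
    raise ValueError(f"unknown base profile {spec.base!r}")


def make_phantom(spec: PhantomSpec, source_id: str = "phantom") -> SegmentedCell:
    """Render a phantom to a SegmentedCell with its exact support mask.

    The bump grid (default 7×7 raised-cosine bumps of peak height
    ``bump_height_frac`` × plateau) is laid out on a square lattice
    spanning ±``bump_span_frac``·R about the centre and rotated by
    ``rotation_deg``; bump centres are kept on the plateau so a centre
    bump peaks at plateau × (1 + bump_height_frac).
    """
    R = spec.diameter_px / 2.0
    size = int(np.ceil(spec.diameter_px)) + 2 * spec.margin_px
    size += 1 - size % 2   # odd size: a pixel sits at the exact centre
    c0 = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    xr, yr = xx - c0, yy - c0
    r = np.hypot(xr, yr)
    z = _radial_base(spec, r)
    mask = z > 0

    if spec.bump_height_frac > 0:
        gy, gx = spec.bump_grid
        span = spec.bump_span_frac * R
        spacing = 2.0 * span / (max(gx, gy) - 1) if max(gx, gy) > 1 else 0.0
        rb = spec.bump_radius_px if spec.bump_radius_px is not None else 0.45 * spacing
        if rb <= 0:
            raise ValueError("bump radius must be positive")
        if span + rb > R + 1e-9:
            raise ValueError("bump grid exceeds the phantom support")
        hb = spec.bump_height_frac * spec.plateau_opl_nm
        cy = np.linspace(-span, span, gy)
        cx = np.linspace(-span, span, gx)
        theta = np.deg2rad(spec.rotation_deg)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        bumps = np.zeros_like(z)
        for by in cy:
            for bx in cx:
                # analytic rotation of the lattice about the centre
                rx = bx * cos_t - by * sin_t
                ry = bx * sin_t + by * cos_t
                rho = np.hypot(xr - rx, yr - ry)
                hit = rho < rb
                bumps[hit] += hb * 0.5 * (1.0 + np.cos(np.pi * rho[hit] / rb))
        z = z + bumps * mask

    return SegmentedCell(crop=z, mask=mask, source_id=source_id,
                         pixel_pitch_um=spec.pixel_pitch_um)


def interpretation_series_spec() -> PhantomSpec:
    """Base spec of the bump-height interpretation sweep.

    A hemispheroid OPL base is used so that the phantom's OPL/PL map is
    a flat "top hat" whose only texture is the bump grid: the decision
    value then isolates the classifier's response to subcellular
    heterogeneity.  The size is cell-line-like (organelle-bearing cells
    are what the bumps imitate).
    """
    return PhantomSpec(base="hemi_ellipsoid", diameter_px=60.0,
                       plateau_opl_nm=450.0)


def rotation_reference_phantoms() -> dict[str, "SegmentedCell"]:
    """The two reference phantoms of the rotation-robustness sweep: a
    smooth WBC-like hemispheroid and a bumpy (11 %) CL-like one."""
    return {
        "WBC": make_phantom(PhantomSpec(base="hemi_ellipsoid",
                                        diameter_px=37.0,
                                        plateau_opl_nm=300.0,
                                        bump_height_frac=0.0),
                            source_id="wbc_reference"),
        "CL": make_phantom(PhantomSpec(base="hemi_ellipsoid",
                                       diameter_px=60.0,
                                       plateau_opl_nm=450.0,
                                       bump_height_frac=0.11),
                           source_id="cl_reference"),
    }


def make_phantom_series(
    spec: PhantomSpec, heights: Sequence[float] = DEFAULT_HEIGHT_SERIES
) -> list[SegmentedCell]:
    """One phantom per bump height, all other parameters fixed."""
    if any(h < 0 or h > 1 for h in heights):
        raise ValueError("heights must lie in [0, 1]")
    return [
        make_phantom(replace(spec, bump_height_frac=float(h)),
                     source_id=f"phantom_h{h:.3f}")
        for h in heights
    ]


def rotate_phantom(cell: SegmentedCell, angle_deg: float) -> SegmentedCell:
    """Rotate a segmented cell about its mask centroid.

    Multiples of 90° are index permutations (lossless); other angles use
    bilinear interpolation for the crop and nearest-neighbour for the
    mask.
    """
    angle = angle_deg % 360.0
    if angle == 0.0:
        return SegmentedCell(crop=cell.crop.copy(), mask=cell.mask.copy(),
                             bbox_origin=cell.bbox_origin,
                             source_id=cell.source_id,
                             pixel_pitch_um=cell.pixel_pitch_um)
    if angle % 90.0 == 0.0:
        k = int(angle // 90.0)
        crop, mask = np.rot90(cell.crop, k), np.rot90(cell.mask, k)
    else:
        rc, cc = ndimage.center_of_mass(cell.mask)
        crop = _sk_rotate(cell.crop, angle, center=(cc, rc), order=1,
                          preserve_range=True, mode="constant", cval=0.0)
        mask = _sk_rotate(cell.mask.astype(float), angle, center=(cc, rc),
                          order=0, preserve_range=True, mode="constant",
                          cval=0.0) > 0.5
    return SegmentedCell(crop=np.ascontiguousarray(crop),
                         mask=np.ascontiguousarray(mask),
                         bbox_origin=cell.bbox_origin,
                         source_id=f"{cell.source_id}_rot{angle_deg:g}",
                         pixel_pitch_um=cell.pixel_pitch_um)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    raise RuntimeError("truncated normal sampling failed")


def _sample_cell(
    rng: np.random.Generator, spec: PopulationSpec, cls: str, idx: int,
    noise: bool = True,
) -> SegmentedCell:
    if cls == "WBC":
        d_um = _truncated_normal(rng, *spec.wbc_diameter_um, lo=4.0)
        lo, hi = spec.wbc_bump_height_frac
        base = "hemi_ellipsoid"
    else:
        d_um = _truncated_normal(rng, *spec.cl_diameter_um, lo=6.0)
        lo, hi = spec.cl_bump_height_frac
        base = "hemi_ellipsoid"
    bump = float(rng.uniform(lo, hi))
    plateau = spec.opl_per_um_nm * d_um * float(rng.normal(1.0, 0.05))
    pspec = PhantomSpec(
        base=base,
        plateau_opl_nm=max(plateau, 50.0),
        diameter_px=d_um / spec.pixel_pitch_um,
        bump_height_frac=bump,
        rotation_deg=float(rng.uniform(0.0, 360.0)),
        pixel_pitch_um=spec.pixel_pitch_um,
    )
    cell = make_phantom(pspec, source_id=f"{cls.lower()}_{idx:04d}")
    if noise and spec.noise_sigma_nm > 0:
        cell.crop = cell.crop + rng.normal(0.0, spec.noise_sigma_nm,
                                           size=cell.crop.shape)
    return cell


def sample_population(
    spec: PopulationSpec, noise: bool = True
) -> list[tuple[SegmentedCell, str]]:
    """Draw the two-class training population (default 250 + 250 cells).

    WBC-like cells are smooth hemispheroids with small diameters; CL-like
    cells are larger with pronounced organelle-like bumps.  Additive
    Gaussian OPL noise is applied to every crop pixel.  Bit-reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[SegmentedCell, str]] = []
    for i in range(spec.n_per_class):
        out.append((_sample_cell(rng, spec, "WBC", i, noise), "WBC"))
    for i in range(spec.n_per_class):
        out.append((_sample_cell(rng, spec, "CL", i, noise), "CL"))
    return out


def make_field(
    spec: FieldSpec,
    placements: Sequence[tuple[int, int]] | None = None,
) -> tuple[PhaseImage, list[dict]]:
    """Compose a full-field OPL image with ground truth.

    Paraboloid background + noise-free planted cells (noise is added
    once, field-wide) + i.i.d. Gaussian noise.  Cells are placed at
    ``placements`` (crop-origin row/col) or at random non-overlapping
    positions; overlapping or out-of-bounds placements raise.  Returns
    the field and a ground-truth record per cell.
    """
    rng = np.random.default_rng(spec.seed)
    pop_rng = np.random.default_rng(spec.seed + 1)
    canvas = spec.background.surface(spec.shape)
    H, W = spec.shape

    cells = [
        _sample_cell(pop_rng, spec.population,
                     "WBC" if i % 2 == 0 else "CL", i, noise=False)
        for i in range(spec.n_cells)
    ]
    boxes: list[tuple[int, int, int, int]] = []
    truth: list[dict] = []

    def overlaps(r0, c0, r1, c1) -> bool:
        return any(not (r1 <= br0 or br1 <= r0 or c1 <= bc0 or bc1 <= c0)
                   for br0, bc0, br1, bc1 in boxes)

    for i, cell in enumerate(cells):
        h, w = cell.crop.shape
        if placements is not None:
            r0, c0 = placements[i]
            if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
                raise ValueError(f"placement {i} out of bounds")
            if overlaps(r0, c0, r0 + h, c0 + w):
                raise ValueError(f"placement {i} overlaps an earlier cell")
        else:
            for _ in range(2000):
                r0 = int(rng.integers(1, H - h - 1))
                c0 = int(rng.integers(1, W - w - 1))
                if not overlaps(r0, c0, r0 + h, c0 + w):
                    break
            else:
                raise ValueError("could not place cells disjointly; "
                                 "reduce n_cells or enlarge the field")
        boxes.append((r0, c0, r0 + h, c0 + w))
        canvas[r0:r0 + h, c0:c0 + w] += cell.crop * cell.mask
        truth.append({
            "index": i,
            "label": "WBC" if i % 2 == 0 else "CL",
            "origin": (r0, c0),
            "shape": (h, w),
            "area_px": cell.area_px,
        })

    if spec.noise_sigma_nm > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma_nm, size=canvas.shape)
    img = PhaseImage(values=canvas, pixel_pitch_um=spec.population.pixel_pitch_um,
                     unit="opl_nm", source="synthetic_field")
    return img, truth
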