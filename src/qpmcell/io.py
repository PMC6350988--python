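"""Raster and tabular I/O: 32-bit float TIFF with JSON sidecar metadata.

The raster currency is a single-channel float TIFF whose pixel value is
OPL in nanometres; optics metadata (pixel pitch, wavelength, unit)
travels in a ``<name>.json`` sidecar next to the image.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from qpmcell.phase_field import PhaseImage, SegmentedCell

SCHEMA_VERSION = 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_phase_tiff(image: PhaseImage, path: str | Path) -> None:
    """Write a PhaseImage as float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.values.astype(np.float32))
    meta = {
        "schema": SCHEMA_VERSION,
        "pixel_pitch_um": image.pixel_pitch_um,
        "wavelength_nm": image.wavelength_nm,
        "unit": image.unit,
        "source": image.source,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_phase_tiff(path: str | Path) -> PhaseImage:
    """Read a float TIFF (+ optional sidecar) back into a PhaseImage.

    Missing sidecar ⇒ defaults (unit opl_nm) with a warning; integer
    rasters are converted to float with a warning.
    """
    path = Path(path)
    values = tifffile.imread(path)
    if not np.issubdtype(values.dtype, np.floating):
        warnings.warn(f"{path.name}: non-float TIFF, converting to float64")
    values = values.astype(np.float64)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"{path.name}: no metadata sidecar; assuming OPL in nm")
        meta = {}
    return PhaseImage(
        values=values,
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 0.27)),
        wavelength_nm=meta.get("wavelength_nm", 625.0),
        unit=meta.get("unit", "opl_nm"),
        source=meta.get("source", path.stem),
    )


def write_cell(cell: SegmentedCell, path: str | Path) -> None:
    """Write a segmented cell crop as TIFF with mask and bbox in the sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, cell.crop.astype(np.float32))
    meta = {
        "schema": SCHEMA_VERSION,
        "pixel_pitch_um": cell.pixel_pitch_um,
        "bbox_origin": list(cell.bbox_origin),
        "source_id": cell.source_id,
        "mask_rle": _rle_encode(cell.mask),
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_cell(path: str | Path) -> SegmentedCell:
    path = Path(path)
    crop = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar_path(path).read_text())
    mask = _rle_decode(meta["mask_rle"], crop.shape)
    return SegmentedCell(
        crop=crop,
        mask=mask,
        bbox_origin=tuple(meta.get("bbox_origin", (0, 0))),
        source_id=meta.get("source_id", path.stem),
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 0.27)),
    )


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Flat run-length encoding starting with the count of False pixels."""
    flat = np.asarray(mask, bool).ravel()
    runs: list[int] = []
    current, count = False, 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current, count = v, 1
    runs.append(count)
    return runs


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)
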