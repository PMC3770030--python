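"""File I/O: images (PNG / DICOM / NIfTI), masks, and annotation JSON."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .energy import StandardLine
from .fast_marching import SeedSet

__all__ = [
    "read_image",
    "read_annotations",
    "write_annotations",
    "write_mask_png",
    "read_mask_png",
    "write_float_map",
]


def read_image(path, nifti_slice: int = 0) -> np.ndarray:
    """Read a single 2-D grayscale slice as float64.

    PNG (8/16-bit grey), single-slice DICOM (rescale slope/intercept
    applied), or one axial slice of a NIfTI volume (``nifti_slice``
    indexes the last axis).
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".dcm") or suffix == "":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
    elif suffix.endswith(".nii") or suffix.endswith(".nii.gz"):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim == 2:
            arr = vol
        else:
            arr = vol[..., nifti_slice] if vol.ndim == 3 else vol[..., nifti_slice, 0]
    else:
        arr = np.asarray(iio.imread(path)).astype(np.float64)
        if arr.ndim == 3:  # collapse RGB(A) greyscale exports
            arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {arr.shape} from {path}")
    return arr


def read_annotations(path) -> tuple[SeedSet, StandardLine | None]:
    """Read the seeds / standard-line JSON document.

    Format: ``{"seeds": [[r, c], ...], "standard_line": [[r, c], ...]}``
    with 0-based row/col; ``standard_line`` is optional — its absence
    switches the pipeline to the automatic (line-free) variants.
    """
    data = json.loads(Path(path).read_text())
    if "seeds" not in data or not data["seeds"]:
        raise ValueError(f"annotation file {path} must contain a nonempty 'seeds' list")
    seeds = SeedSet(data["seeds"])
    line = None
    if data.get("standard_line"):
        line = StandardLine(data["standard_line"])
    return seeds, line


def write_annotations(path, seeds: SeedSet, line: StandardLine | None = None) -> None:
    doc = {"seeds": [list(p) for p in seeds]}
    if line is not None:
        doc["standard_line"] = [list(v) for v in line.vertices]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_mask_png(path, mask: np.ndarray) -> None:
    """Binary mask as 8-bit PNG (0 / 255)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_float_map(path, values: np.ndarray) -> None:
    """Floating-point intermediate map (TIFF for .tif/.tiff, else .npy)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, np.asarray(values, dtype=np.float32))
    else:
        np.save(path.with_suffix(".npy"), np.asarray(values, dtype=np.float64))
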