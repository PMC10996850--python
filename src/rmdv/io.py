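"""File I/O: NIfTI slices, masks, and provenance-stamped CSV."""

from __future__ import annotations

import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .densitometry import ImageSlice
from .errors import SchemaError

PROVENANCE_PREFIX = "# rmdv"


def save_slice(path: Path, slc: ImageSlice) -> None:
    """Write a slice as a single-slice NIfTI volume (int16 HU, identity scaling)."""
    affine = np.diag([slc.spacing[0], slc.spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(slc.pixels.astype(np.int16), affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def save_mask(path: Path, mask: np.ndarray, spacing: tuple[float, float]) -> None:
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_slice(path: Path, midline: int, brain_mask_path: Path) -> ImageSlice:
    img = nib.load(str(path))
    pixels = np.asarray(img.dataobj).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:2])
    mask = np.asarray(nib.load(str(brain_mask_path)).dataobj).astype(bool)
    return ImageSlice(pixels=pixels, spacing=spacing, midline=midline, brain_mask=mask)


def load_mask(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)


def write_csv(path: Path, frame: pd.DataFrame, seed: int, version: str) -> None:
    """CSV with a provenance comment line (seed + package version)."""
    buf = _io.StringIO()
    buf.write(f"{PROVENANCE_PREFIX} version={version} seed={seed}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_csv(path: Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name} is missing columns: {missing}")
    return frame
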