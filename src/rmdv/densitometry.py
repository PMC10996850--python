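"""Hounsfield-unit densitometry on axial CT rasters.

Implements the measurement procedure for post-interventional cerebral
hyperdensities (PCHDs): detection by the >= 5 HU contralateral-excess rule,
placement of the largest circular/elliptical region of interest (ROI)
confined to the highest-density area, and measurement of the venous-sinus
maximum with skull/artifact exclusion.

Conventions: coordinates are (row, col), 0-based, pixel centers; the
midline is a column index about which the slice is mirror-symmetric, so
the contralateral partner of column ``c`` is ``2 * midline - c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import InputError, SinusUnmeasurableError

__all__ = [
    "ImageSlice",
    "PCHDRegion",
    "RoiMeasurement",
    "detect_pchds",
    "place_max_roi",
    "measure_sinus_max",
]

HU_MIN, HU_MAX = -1024, 3071


@dataclass
class ImageSlice:
    """A 2-D CT raster in Hounsfield units with geometry metadata.

    ``pixels`` is a signed-integer HU array; ``spacing`` is (row, col) mm
    per pixel; ``midline`` the column index of the anatomical symmetry
    axis; ``brain_mask`` the intracranial parenchyma (skull excluded).
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    midline: int
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise InputError("pixels must be a 2-D raster")
        if self.brain_mask.shape != self.pixels.shape:
            raise InputError("brain_mask shape must match pixels")
        if not (0 <= self.midline < self.pixels.shape[1]):
            raise InputError(f"midline {self.midline} outside [0, n_cols)")
        if self.pixels.min() < HU_MIN or self.pixels.max() > HU_MAX:
            raise InputError("HU values outside the physical CT range")


@dataclass
class PCHDRegion:
    """A connected hyperdense region with its summary densitometry."""

    pixel_set: np.ndarray  # (N, 2) array of (row, col) coordinates
    max_hu: float
    argmax: tuple[int, int]
    contralateral_excess: float

    @property
    def area(self) -> int:
        return len(self.pixel_set)


@dataclass
class RoiMeasurement:
    """A circular or axis-aligned elliptical ROI and its maximum HU."""

    shape: str  # "circle" or "ellipse"
    center: tuple[int, int]
    radii: tuple[float, float]  # (row semi-axis, col semi-axis); equal for circles
    max_hu: float
    n_pixels: int
    pixel_set: np.ndarray


def _mirror_excess(slc: ImageSlice) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel HU excess over the mirrored pixel, and its validity mask."""
    n_rows, n_cols = slc.pixels.shape
    cols = np.arange(n_cols)
    mirror = 2 * slc.midline - cols
    valid_cols = (mirror >= 0) & (mirror < n_cols)
    mirror_safe = np.clip(mirror, 0, n_cols - 1)
    mirrored = slc.pixels[:, mirror_safe]
    excess = slc.pixels.astype(np.int64) - mirrored.astype(np.int64)
    valid = np.broadcast_to(valid_cols, (n_rows, n_cols)).copy()
    return excess, valid


def detect_pchds(
    slc: ImageSlice, min_excess: float = 5, min_area: int = 5
) -> list[PCHDRegion]:
    """Detect hyperdense regions by the contralateral-excess rule.

    A pixel is hyperdense when it lies in the brain mask and its HU exceeds
    the mirrored pixel's HU by at least ``min_excess`` (default 5 HU).
    8-connected components of such pixels with area >= ``min_area`` are
    returned, sorted by their maximum HU (descending).
    """
    if not slc.brain_mask.any():
        raise InputError("brain mask is empty")
    excess, valid = _mirror_excess(slc)
    hyper = slc.brain_mask & valid & (excess >= min_excess)
    labels = skmeasure.label(hyper, connectivity=2)
    regions: list[PCHDRegion] = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_area:
            continue
        rows, cols = coords[:, 0], coords[:, 1]
        values = slc.pixels[rows, cols]
        k = int(np.argmax(values))
        mirror_cols = 2 * slc.midline - cols
        mean_excess = float(
            values.mean() - slc.pixels[rows, mirror_cols].mean()
        )
        regions.append(
            PCHDRegion(
                pixel_set=coords,
                max_hu=float(values.max()),
                argmax=(int(rows[k]), int(cols[k])),
                contralateral_excess=mean_excess,
            )
        )
    regions.sort(key=lambda r: (-r.max_hu, -r.area, r.argmax))
    return regions


def _disc_pixels(
    shape: tuple[int, int], center: tuple[int, int], radius: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.argwhere(d2 <= radius**2 + 1e-9)

def _largest_inscribed_circle(
    admissible: np.ndarray, pixels: np.ndarray
) -> tuple[tuple[int, int], float]:
    """Center and radius of the largest pixel-disc inside ``admissible``.

    The disc of radius r at a pixel is the set of pixels whose centers lie
    within Euclidean distance r.  With EDT clearance e (distance to the
    nearest inadmissible pixel, out-of-image counting as inadmissible),
    radius e - 1 is the largest guaranteed-contained disc; ties on radius
    are broken toward the densest disc.
    """
    padded = np.pad(admissible, 1)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    edt = np.where(admissible, edt, 0.0)
    best_clearance = edt.max()
    candidates = np.argwhere(edt > best_clearance - 1e-9)

    best = None
    for r0, c0 in candidates:
        radius = float(edt[r0, c0] - 1.0)
        disc = _disc_pixels(admissible.shape, (r0, c0), radius)
        dens = pixels[disc[:, 0], disc[:, 1]].max()
        key = (len(disc), dens)
        if best is None or key > best[0]:
            best = (key, (int(r0), int(c0)), radius, disc)
    assert best is not None
    _, center, radius, disc = best
    return center, radius, disc


def _best_axis_ellipse(
    admissible: np.ndarray, pixels: np.ndarray, max_semi: int = 24
) -> tuple[tuple[int, int], tuple[int, int], np.ndarray] | None:
    """Largest axis-aligned elliptical pixel set inside ``admissible``.

    Exhaustive over admissible centers and integer semi-axes; returns None
    when nothing beats a single pixel.
    """
    coords = np.argwhere(admissible)
    n_rows, n_cols = admissible.shape
    rr_all, cc_all = np.ogrid[:n_rows, :n_cols]
    best = None
    for r0, c0 in coords:
        for ra in range(0, max_semi + 1):
            if ra:
                va = ((rr_all - r0) ** 2).astype(float) / (ra * ra)
            else:
                va = np.where(rr_all == r0, 0.0, np.inf)
            for rb in range(0, max_semi + 1):
                if ra == 0 and rb == 0:
                    continue
                if rb:
                    vb = ((cc_all - c0) ** 2).astype(float) / (rb * rb)
                else:
                    vb = np.where(cc_all == c0, 0.0, np.inf)
                inside = (va + vb) <= 1.0 + 1e-9
                if np.any(inside & ~admissible):
                    # larger col semi-axes only grow the set; move to next ra
                    break
                n = int(inside.sum())
                dens = pixels[inside].max()
                key = (n, dens)
                if best is None or key > best[0]:
                    best = (key, (int(r0), int(c0)), (ra, rb), np.argwhere(inside))
    if best is None or best[0][0] <= 1:
        return None
    _, center, radii, pixel_set = best
    return center, radii, pixel_set


def place_max_roi(
    slc: ImageSlice, region: PCHDRegion, hu_tolerance: float = 5
) -> RoiMeasurement:
    """Place the largest ROI confined to a region's highest-density area.

    The admissible set is the region's pixels within ``hu_tolerance`` HU of
    the region maximum.  The ROI is the largest inscribed circle; when that
    degenerates to a single pixel, the best axis-aligned ellipse is tried
    instead.  A one-pixel ROI at the region argmax is always valid.
    """
    if region.area == 0:
        raise InputError("empty region")
    admissible = np.zeros(slc.pixels.shape, dtype=bool)
    rows, cols = region.pixel_set[:, 0], region.pixel_set[:, 1]
    keep = slc.pixels[rows, cols] >= region.max_hu - hu_tolerance
    admissible[rows[keep], cols[keep]] = True

    center, radius, disc = _largest_inscribed_circle(admissible, slc.pixels)
    if radius < 1e-9:
        ell = _best_axis_ellipse(admissible, slc.pixels)
        if ell is not None:
            center, radii, pixel_set = ell
            return RoiMeasurement(
                shape="ellipse",
                center=center,
                radii=(float(radii[0]), float(radii[1])),
                max_hu=float(slc.pixels[pixel_set[:, 0], pixel_set[:, 1]].max()),
                n_pixels=len(pixel_set),
                pixel_set=pixel_set,
            )
    return RoiMeasurement(
        shape="circle",
        center=center,
        radii=(radius, radius),
        max_hu=float(slc.pixels[disc[:, 0], disc[:, 1]].max()),
        n_pixels=len(disc),
        pixel_set=disc,
    )


def measure_sinus_max(
    slc: ImageSlice,
    sinus_mask: np.ndarray,
    skull_hu_threshold: float = 200,
    exclusion_dilation: float = 2,
    hu_tolerance: float = 5,
) -> RoiMeasurement:
    """Maximum venous-sinus HU, excluding skull-adjacent pixels.

    Admissible sinus pixels are those of ``sinus_mask`` farther than
    ``exclusion_dilation`` pixels (Euclidean) from any pixel at or above
    ``skull_hu_threshold``.  Raises :class:`SinusUnmeasurableError` when the
    exclusion empties the mask.  The returned ROI follows the same
    largest-inscribed rule as :func:`place_max_roi`, restricted to the
    admissible high-density area containing the sinus argmax.
    """
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if sinus_mask.shape != slc.pixels.shape:
        raise InputError("sinus mask shape must match pixels")
    if not sinus_mask.any():
        raise InputError("sinus mask is empty")
    dense = slc.pixels >= skull_hu_threshold
    if dense.any():
        dist_to_dense = ndimage.distance_transform_edt(~dense)
        admissible = sinus_mask & (dist_to_dense > exclusion_dilation)
    else:
        admissible = sinus_mask
    if not admissible.any():
        raise SinusUnmeasurableError(
            "sinus mask fully excluded by the skull/artifact rule"
        )
    coords = np.argwhere(admissible)
    values = slc.pixels[coords[:, 0], coords[:, 1]]
    k = int(np.argmax(values))
    region = PCHDRegion(
        pixel_set=coords,
        max_hu=float(values.max()),
        argmax=(int(coords[k, 0]), int(coords[k, 1])),
        contralateral_excess=0.0,
    )
    roi = place_max_roi(slc, region, hu_tolerance=hu_tolerance)
    return roi
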