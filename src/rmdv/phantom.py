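"""Synthetic axial NCCT phantoms.

Renders paired "immediate" and "24 h follow-up" head-CT-like slices for a
patient record: an elliptical skull ring around mirror-symmetric
parenchyma, a venous-sinus band straddling the posterior midline, and —
for PCHD cases — an off-midline hyperdense lesion with radial HU falloff
whose planted peak realizes the record's latent RMDV positivity.  Contrast
extravasation (CE) cases wash out: the lesion is absent at follow-up.
Hemorrhagic-transformation (HT) cases persist.

The geometry is deliberately minimal: just enough anatomy to exercise the
contralateral detection rule, the ROI placement rule, and the
skull-exclusion rule of the sinus measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import CE, PatientRecord
from .densitometry import HU_MAX, HU_MIN, ImageSlice
from .errors import GeometryError

__all__ = ["PhantomSpec", "PatientCase", "render_case"]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the head phantom.

    HU defaults: parenchyma 35 (gray/white average), skull 1000 (compact
    bone), venous sinus peak 75 (opacified venous blood after contrast).
    ``lesion_peak_hu`` of None lets :func:`render_case` draw the peak from
    the record's latent positivity; a number forces that exact peak.
    """

    image_shape: tuple[int, int] = (129, 129)
    pixel_spacing: tuple[float, float] = (1.75, 1.75)
    background_hu: int = 35
    skull_hu: int = 1000
    sinus_peak_hu: int = 75
    lesion_peak_hu: Optional[int] = None
    lesion_center: tuple[int, int] = (76, 40)
    lesion_radius: int = 10
    sinus_center: tuple[int, int] = (104, 64)
    sinus_radii: tuple[int, int] = (4, 12)
    skull_outer: tuple[int, int] = (58, 50)
    skull_inner: tuple[int, int] = (52, 44)
    # Default noise is kept below the reliability limit of the pixelwise
    # 5 HU elimination rule: the adjudicator takes a maximum over ~300
    # footprint pixels of a difference image with sd = sqrt(2) * noise_sd,
    # so noise_sd must satisfy 5 / (sqrt(2) * noise_sd) >~ 4.5.
    noise_sd: float = 0.75
    washout: bool = False
    artifact_streaks: int = 0
    air_hu: int = -1000

    @property
    def center(self) -> tuple[int, int]:
        return (self.image_shape[0] // 2, self.image_shape[1] // 2)

    @property
    def midline(self) -> int:
        return self.image_shape[1] // 2

    def _ellipse(self, center: tuple[int, int], radii: tuple[float, float]) -> np.ndarray:
        rr, cc = np.ogrid[: self.image_shape[0], : self.image_shape[1]]
        return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0

    def brain_mask(self) -> np.ndarray:
        return self._ellipse(self.center, self.skull_inner)

    def sinus_mask(self) -> np.ndarray:
        return self._ellipse(self.sinus_center, self.sinus_radii)

    def lesion_mask(self) -> np.ndarray:
        rr, cc = np.ogrid[: self.image_shape[0], : self.image_shape[1]]
        d2 = (rr - self.lesion_center[0]) ** 2 + (cc - self.lesion_center[1]) ** 2
        return d2 <= self.lesion_radius**2

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be non-negative")
        for name, v in (("background_hu", self.background_hu),
                        ("skull_hu", self.skull_hu),
                        ("sinus_peak_hu", self.sinus_peak_hu),
                        ("air_hu", self.air_hu)):
            if not (HU_MIN <= v <= HU_MAX):
                raise GeometryError(f"{name}={v} outside the HU range")
        if self.skull_inner[0] >= self.skull_outer[0] or self.skull_inner[1] >= self.skull_outer[1]:
            raise GeometryError("inner skull ellipse must be inside the outer one")
        brain = self.brain_mask()
        sinus = self.sinus_mask()
        lesion = self.lesion_mask()
        if not sinus.any() or np.any(sinus & ~brain):
            raise GeometryError("sinus region must lie inside the skull ring")
        if np.any(lesion & ~brain):
            raise GeometryError("lesion must lie inside the skull ring")
        if np.any(lesion & sinus):
            raise GeometryError("lesion and sinus regions overlap")


@dataclass
class PatientCase:
    """Paired immediate/follow-up slices with masks and ground truth."""

    patient_id: str
    immediate: ImageSlice
    followup: Optional[ImageSlice]
    sinus_mask: np.ndarray
    lesion_peak_hu: Optional[int]
    sinus_peak_hu: int
    washout: bool
    record: Optional[PatientRecord] = None


def _base_slice(spec: PhantomSpec) -> np.ndarray:
    """Noise-free background: air, skull ring, parenchyma, sinus profile."""
    img = np.full(spec.image_shape, float(spec.air_hu))
    outer = spec._ellipse(spec.center, spec.skull_outer)
    inner = spec.brain_mask()
    img[outer] = spec.skull_hu
    img[inner] = spec.background_hu
    # sinus: elliptical falloff from peak at the band center to parenchyma
    rr, cc = np.ogrid[: spec.image_shape[0], : spec.image_shape[1]]
    d = np.sqrt(((rr - spec.sinus_center[0]) / spec.sinus_radii[0]) ** 2
                + ((cc - spec.sinus_center[1]) / spec.sinus_radii[1]) ** 2)
    sinus = d <= 1.0
    profile = spec.background_hu + (spec.sinus_peak_hu - spec.background_hu) * (1.0 - d)
    img[sinus] = np.rint(profile[sinus])
    return img


def _add_lesion(img: np.ndarray, spec: PhantomSpec, peak_hu: int) -> np.ndarray:
    """Plant a disc lesion with linear radial falloff from peak to background."""
    out = img.copy()
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    d = np.sqrt((rr - spec.lesion_center[0]) ** 2 + (cc - spec.lesion_center[1]) ** 2)
    mask = d <= spec.lesion_radius
    profile = spec.background_hu + (peak_hu - spec.background_hu) * (
        1.0 - d / spec.lesion_radius
    )
    out[mask] = np.rint(profile[mask])
    return out


def _add_streaks(img: np.ndarray, rng: np.random.Generator, n: int, spec: PhantomSpec) -> np.ndarray:
    """Crude linear artifacts: bright lines crossing the brain."""
    from skimage.draw import line

    out = img.copy()
    n_rows, n_cols = img.shape
    brain = spec.brain_mask()
    for _ in range(n):
        r0, c0 = rng.integers(0, n_rows), 0
        r1, c1 = rng.integers(0, n_rows), n_cols - 1
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        keep = brain[rr, cc]
        out[rr[keep], cc[keep]] = 300
    return out


def _finalize(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> ImageSlice:
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), HU_MIN, HU_MAX).astype(np.int16)
    return ImageSlice(
        pixels=img,
        spacing=spec.pixel_spacing,
        midline=spec.midline,
        brain_mask=spec.brain_mask(),
    )


def draw_lesion_peak(
    rng: np.random.Generator, positive: bool, sinus_peak_hu: int
) -> int:
    """Lesion peak realizing the latent positivity geometrically.

    Positive cases draw the peak uniformly in (1.05, 1.6) x sinus peak,
    negative cases in (0.6, 0.95) x sinus peak, so the classifier's
    decision is attributable to the image with a margin exceeding noise.
    """
    lo, hi = (1.05, 1.6) if positive else (0.6, 0.95)
    return int(np.rint(rng.uniform(lo, hi) * sinus_peak_hu))


def render_case(
    record: PatientRecord, spec: PhantomSpec, seed: int
) -> PatientCase:
    """Render the paired immediate / 24 h follow-up slices for one patient.

    PCHD records get a lesion on the immediate slice whose planted peak
    equals ``spec.lesion_peak_hu`` (before noise) when given, else a peak
    drawn from the record's latent positivity.  CE cases lose the lesion at
    follow-up (washout); HT cases keep it.  Records flagged as missing the
    follow-up scan get ``followup=None``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    lesion_peak: Optional[int] = None
    if record.has_pchd:
        if spec.lesion_peak_hu is not None:
            lesion_peak = int(spec.lesion_peak_hu)
        else:
            lesion_peak = draw_lesion_peak(
                rng, bool(record.rmdv_positive), spec.sinus_peak_hu
            )

    washout = spec.washout or (record.true_outcome == CE)
    base = _base_slice(spec)
    immediate = base if lesion_peak is None else _add_lesion(base, spec, lesion_peak)
    followup_img = (
        immediate.copy() if (lesion_peak is not None and not washout) else base.copy()
    )
    if spec.artifact_streaks > 0:
        immediate = _add_streaks(immediate, rng, spec.artifact_streaks, spec)

    immediate_slice = _finalize(immediate, spec, rng)
    followup_slice = (
        None
        if record.excluded_no_followup
        else _finalize(followup_img, spec, rng)
    )
    return PatientCase(
        patient_id=record.patient_id,
        immediate=immediate_slice,
        followup=followup_slice,
        sinus_mask=spec.sinus_mask(),
        lesion_peak_hu=lesion_peak,
        sinus_peak_hu=spec.sinus_peak_hu,
        washout=washout,
        record=record,
    )
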