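"""The RMDV statistic, its decision rule, and follow-up adjudication.

RMDV — the ratio of the maximum density value of the post-interventional
cerebral hyperdensities (PCHDs) to the maximum density value of the venous
sinuses on the immediate post-thrombectomy scan — exceeds 1 when the
lesion is denser than fully contrast-opacified venous blood, which is the
signature of blood products (hemorrhagic transformation, HT) rather than
contrast extravasation (CE).  Ground truth is adjudicated from the 24 h
follow-up scan: a hyperdensity that has washed out is CE, one that
persists is HT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .densitometry import (
    PCHDRegion,
    detect_pchds,
    measure_sinus_max,
    place_max_roi,
)
from .errors import FollowupMissingError, MeasurementError
from .phantom import PatientCase

HT = "HT"
CE = "CE"

__all__ = [
    "DensityMeasurement",
    "OutcomeLabel",
    "compute_rmdv",
    "classify_rmdv",
    "adjudicate_followup",
    "measure_case",
]


@dataclass
class DensityMeasurement:
    """Per-patient maxima, their ratio, and the predicted class."""

    patient_id: str
    lesion_max_hu: float
    sinus_max_hu: float
    rmdv: float
    predicted: str  # HT or CE


@dataclass
class OutcomeLabel:
    """Adjudicated outcome from the follow-up scan."""

    patient_id: str
    outcome: str  # HT or CE
    residual_excess_hu: float


def compute_rmdv(lesion_max_hu: float, sinus_max_hu: float) -> float:
    """Ratio of the lesion maximum to the venous-sinus maximum."""
    if sinus_max_hu <= 0:
        raise MeasurementError(
            f"sinus maximum {sinus_max_hu} HU is not a plausible venous reference"
        )
    return lesion_max_hu / sinus_max_hu


def classify_rmdv(rmdv: float) -> str:
    """HT when RMDV > 1 (strict); CE otherwise, including exactly 1."""
    return HT if rmdv > 1 else CE


def adjudicate_followup(
    case: PatientCase, region: PCHDRegion, elimination_excess: float = 5
) -> OutcomeLabel:
    """Re-read an immediate-scan region on the 24 h follow-up image.

    The region's footprint is re-evaluated on the follow-up slice with the
    same contralateral-excess rule used for detection: if no footprint
    pixel retains an excess of at least ``elimination_excess`` HU over its
    mirrored pixel, the hyperdensity has been eliminated and the case is
    CE; otherwise it is HT.
    """
    if case.followup is None:
        raise FollowupMissingError(
            f"case {case.patient_id} has no follow-up scan and must be excluded"
        )
    slc = case.followup
    rows, cols = region.pixel_set[:, 0], region.pixel_set[:, 1]
    mirror_cols = 2 * slc.midline - cols
    n_cols = slc.pixels.shape[1]
    ok = (mirror_cols >= 0) & (mirror_cols < n_cols)
    excess = (
        slc.pixels[rows[ok], cols[ok]].astype(np.int64)
        - slc.pixels[rows[ok], mirror_cols[ok]].astype(np.int64)
    )
    residual = float(excess.max()) if excess.size else 0.0
    outcome = HT if residual >= elimination_excess else CE
    return OutcomeLabel(
        patient_id=case.patient_id, outcome=outcome, residual_excess_hu=residual
    )


def measure_case(
    case: PatientCase,
    min_excess: float = 5,
    min_area: int = 5,
    hu_tolerance: float = 5,
    skull_hu_threshold: float = 200,
    exclusion_dilation: float = 2,
) -> Optional[tuple[DensityMeasurement, PCHDRegion]]:
    """Full densitometry of one case: detect, place ROIs, form the ratio.

    Returns None when no hyperdensity is detected on the immediate scan
    (a non-PCHD case).  When several PCHDs are present the single global
    maximum over all of them enters the ratio — per-site analysis is out
    of scope.
    """
    regions = detect_pchds(case.immediate, min_excess=min_excess, min_area=min_area)
    # Exclude detections overlying the venous sinus reference.
    regions = [
        r
        for r in regions
        if not case.sinus_mask[r.pixel_set[:, 0], r.pixel_set[:, 1]].all()
    ]
    if not regions:
        return None
    top = regions[0]  # sorted by max HU descending
    lesion_roi = place_max_roi(case.immediate, top, hu_tolerance=hu_tolerance)
    sinus_roi = measure_sinus_max(
        case.immediate,
        case.sinus_mask,
        skull_hu_threshold=skull_hu_threshold,
        exclusion_dilation=exclusion_dilation,
        hu_tolerance=hu_tolerance,
    )
    rmdv = compute_rmdv(lesion_roi.max_hu, sinus_roi.max_hu)
    measurement = DensityMeasurement(
        patient_id=case.patient_id,
        lesion_max_hu=lesion_roi.max_hu,
        sinus_max_hu=sinus_roi.max_hu,
        rmdv=rmdv,
        predicted=classify_rmdv(rmdv),
    )
    return measurement, top
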