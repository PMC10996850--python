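import numpy as np
import pytest

from rmdv.cohort import PatientRecord
from rmdv.densitometry import ImageSlice
from rmdv.phantom import PhantomSpec, render_case


def make_slice(pixels, midline=None, brain=None) -> ImageSlice:
    """Small hand-built slice: full-frame brain mask, central midline."""
    pixels = np.asarray(pixels, dtype=np.int16)
    if midline is None:
        midline = pixels.shape[1] // 2
    if brain is None:
        brain = np.ones_like(pixels, dtype=bool)
    return ImageSlice(pixels=pixels, spacing=(1.0, 1.0), midline=midline, brain_mask=brain)


@pytest.fixture
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(noise_sd=0)


@pytest.fixture
def fig2_case():
    """Phantom mimicking the worked example: lesion peak 115 HU, sinus 75 HU."""
    spec = PhantomSpec(lesion_peak_hu=115, noise_sd=0)
    rec = PatientRecord("FIG2", enrolled=True, has_pchd=True,
                        true_outcome="HT", rmdv_positive=True)
    return render_case(rec, spec, seed=42)


def pchd_record(pid="P1", outcome="HT", positive=True) -> PatientRecord:
    return PatientRecord(pid, enrolled=True, has_pchd=True,
                         true_outcome=outcome, rmdv_positive=positive)
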