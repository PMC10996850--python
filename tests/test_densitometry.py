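"""Detection, ROI placement, and sinus measurement on CT rasters."""

import numpy as np
import pytest

from rmdv.cohort import PatientRecord
from rmdv.densitometry import detect_pchds, measure_sinus_max, place_max_roi
from rmdv.errors import InputError, SinusUnmeasurableError
from rmdv.phantom import PhantomSpec, render_case

from .conftest import make_slice
from .oracles import brute_detect


def _symmetric_base(shape=(21, 21), value=30):
    return np.full(shape, value, dtype=int)


class TestDetect:
    def test_planted_lesion_recovers_peak(self, fig2_case):
        regions = detect_pchds(fig2_case.immediate)
        lesions = [
            r for r in regions
            if not fig2_case.sinus_mask[r.pixel_set[:, 0], r.pixel_set[:, 1]].all()
        ]
        assert len(lesions) == 1
        assert lesions[0].max_hu == 115
        assert lesions[0].contralateral_excess >= 5

    def test_symmetric_slice_yields_nothing(self):
        img = _symmetric_base()
        img[5:10, 3:8] = 80
        img[5:10, 13:18] = 80  # mirrored twin at equal density
        assert detect_pchds(make_slice(img)) == []

    def test_two_lesions_sorted_by_max(self):
        img = _symmetric_base((31, 31))
        img[3:8, 2:7] = 90
        img[20:25, 2:7] = 110
        regions = detect_pchds(make_slice(img))
        assert [r.max_hu for r in regions] == [110, 90]

    @pytest.mark.parametrize("excess,found", [(5, True), (4, False)])
    def test_threshold_sharpness(self, excess, found):
        img = _symmetric_base()
        img[8:12, 2:6] = 30 + excess
        regions = detect_pchds(make_slice(img), min_excess=5)
        assert bool(regions) is found

    def test_min_area_suppresses_specks(self):
        img = _symmetric_base()
        img[4, 4] = 200  # single hot pixel
        assert detect_pchds(make_slice(img), min_area=5) == []
        assert len(detect_pchds(make_slice(img), min_area=1)) == 1

    def test_empty_brain_mask_rejected(self):
        slc = make_slice(_symmetric_base(), brain=np.zeros((21, 21), dtype=bool))
        with pytest.raises(InputError):
            detect_pchds(slc)

    def test_matches_bruteforce_on_random_rasters(self):
        """Oracle equivalence: vectorized detection == per-pixel loops + BFS."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            img = rng.integers(20, 40, size=(33, 33))
            for _ in range(rng.integers(1, 4)):
                r0, c0 = rng.integers(2, 28, size=2)
                h, w = rng.integers(2, 7, size=2)
                img[r0:r0 + h, c0:c0 + w] += rng.integers(3, 60)
            slc = make_slice(img)
            got = detect_pchds(slc, min_excess=5, min_area=3)
            expected = brute_detect(slc, min_excess=5, min_area=3)
            got_sets = [set(map(tuple, r.pixel_set)) for r in got]
            assert sorted(map(sorted, got_sets)) == sorted(map(sorted, expected))

    def test_monotone_in_planted_peak(self):
        rec = PatientRecord("M", enrolled=True, has_pchd=True,
                            true_outcome="HT", rmdv_positive=True)
        maxima = []
        for peak in (60, 80, 100, 120, 140):
            case = render_case(rec, PhantomSpec(lesion_peak_hu=peak, noise_sd=0), seed=0)
            regions = detect_pchds(case.immediate)
            maxima.append(max(r.max_hu for r in regions))
        assert maxima == sorted(maxima)


class TestPlaceMaxRoi:
    def test_constant_region_gets_inscribed_disc(self):
        img = _symmetric_base((15, 15), 10)
        img[3:10, 0:7] = 100  # 7x7 plateau, clear of the midline
        region = detect_pchds(make_slice(img))[0]
        roi = place_max_roi(make_slice(img), region, hu_tolerance=0)
        assert roi.max_hu == 100
        assert roi.shape == "circle"
        assert roi.radii[0] == pytest.approx(3.0)

    def test_plateau_5x5_radius_two(self):
        img = _symmetric_base((13, 13), 10)
        img[4:9, 1:6] = 100  # 5x5 plateau, clear of the midline
        region = detect_pchds(make_slice(img))[0]
        roi = place_max_roi(make_slice(img), region, hu_tolerance=0)
        assert roi.radii[0] == pytest.approx(2.0)
        assert roi.max_hu == 100
        assert roi.n_pixels == 13  # disc of radius 2

    def test_radial_falloff_tolerance_zero_is_argmax_pixel(self, fig2_case):
        regions = detect_pchds(fig2_case.immediate)
        lesion = [
            r for r in regions
            if not fig2_case.sinus_mask[r.pixel_set[:, 0], r.pixel_set[:, 1]].all()
        ][0]
        roi = place_max_roi(fig2_case.immediate, lesion, hu_tolerance=0)
        assert roi.n_pixels == 1
        assert roi.center == lesion.argmax
        assert roi.max_hu == 115

    def test_roi_contained_in_admissible_set(self):
        rng = np.random.default_rng(11)
        for _ in range(6):
            img = rng.integers(20, 40, size=(25, 25))
            r0, c0 = rng.integers(3, 18, size=2)
            img[r0:r0 + 6, c0:c0 + 6] += rng.integers(20, 60)
            slc = make_slice(img)
            for region in detect_pchds(slc, min_area=3):
                for tol in (0, 5, 10):
                    roi = place_max_roi(slc, region, hu_tolerance=tol)
                    region_set = set(map(tuple, region.pixel_set))
                    admissible = {
                        p for p in region_set
                        if slc.pixels[p] >= region.max_hu - tol
                    }
                    assert set(map(tuple, roi.pixel_set)) <= admissible
                    vals = [slc.pixels[p] for p in map(tuple, roi.pixel_set)]
                    assert roi.max_hu == max(vals)

    def test_single_row_plateau_falls_back_to_ellipse(self):
        img = _symmetric_base((11, 11), 10)
        img[5, 0:5] = 100  # 1x5 strip, clear of the midline
        region = detect_pchds(make_slice(img), min_area=3)[0]
        roi = place_max_roi(make_slice(img), region, hu_tolerance=0)
        assert roi.shape == "ellipse"
        assert roi.n_pixels == 5
        assert roi.max_hu == 100


class TestSinus:
    def test_phantom_sinus_peak(self, fig2_case):
        roi = measure_sinus_max(fig2_case.immediate, fig2_case.sinus_mask)
        assert roi.max_hu == 75

    def test_singleton_sinus_pixel(self):
        img = _symmetric_base((9, 9), 30)
        img[4, 4] = 60
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        roi = measure_sinus_max(make_slice(img), mask)
        assert roi.max_hu == 60
        assert roi.n_pixels == 1

    def test_skull_adjacent_pixels_excluded(self):
        """Sinus band abutting a skull wall: only pixels > 2 px away count."""
        img = _symmetric_base((15, 15), 30)
        img[:, 12] = 1000              # skull wall
        img[7, 4:12] = 70              # sinus band running into the wall
        img[7, 11] = 90                # hottest pixel sits against the skull
        mask = np.zeros((15, 15), dtype=bool)
        mask[7, 4:12] = True
        roi = measure_sinus_max(make_slice(img), mask,
                                skull_hu_threshold=200, exclusion_dilation=2)
        # brute-force exclusion: admissible columns are those with distance
        # to column 12 strictly greater than 2, i.e. cols 4..9
        assert roi.max_hu == 70

    def test_fully_excluded_mask_raises(self):
        img = _symmetric_base((9, 9), 30)
        img[:, :] = 30
        img[4, 4] = 60
        img[4, 5] = 1000
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        with pytest.raises(SinusUnmeasurableError):
            measure_sinus_max(make_slice(img), mask, exclusion_dilation=2)
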