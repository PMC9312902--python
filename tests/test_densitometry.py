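"""Phantom calibration formulas, ROI placement, classification."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinefe.ct import LABEL_PHANTOM_WATER, LABEL_VERTEBRA, rasterize_ct
from spinefe.densitometry import (
    PhantomCalibration,
    bmd_mdct_to_qct,
    classify,
    hu_to_bmd_mdct,
    measure_phantom,
    roi_mean_hu,
    subject_bmd,
)
from spinefe.errors import CalibrationError, DensitometryError
from spinefe.geometry import build_spine_geometry

from conftest import TINY

# The twelve printed subject-level BMD_QCT-L1-3 values (mg/mL): six healthy
# controls followed by six osteoporotic patients.
HC_BMD = [108.04, 107.82, 106.91, 103.86, 82.44, 95.54]
OP_BMD = [67.67, 62.44, 61.20, 57.14, 56.44, 62.69]


class TestFormulas:
    @pytest.fixture()
    def calib(self):
        return PhantomCalibration(hu_bone=500.0, hu_water=0.0)

    @pytest.mark.parametrize("hu,expected", [(0.0, 0.0), (500.0, 200.0),
                                             (250.0, 100.0)])
    def test_hu_to_bmd_mdct(self, calib, hu, expected):
        assert hu_to_bmd_mdct(hu, calib) == pytest.approx(expected)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(CalibrationError, match="HUb"):
            PhantomCalibration(hu_bone=100.0, hu_water=100.0)

    @pytest.mark.parametrize("mdct,expected", [
        (0.0, -11.0), (100.0, 58.0), (172.52, 108.04),
    ])
    def test_bmd_mdct_to_qct(self, mdct, expected):
        assert bmd_mdct_to_qct(mdct) == pytest.approx(expected, abs=0.01)

    @settings(max_examples=50, deadline=None)
    @given(hu=st.floats(-200, 1500), scale=st.floats(1.1, 4.0))
    def test_affine_in_hu(self, hu, scale):
        """Doubling (HU - HUw) doubles BMD_MDCT (exact linearity)."""
        calib = PhantomCalibration(hu_bone=400.0, hu_water=10.0)
        base = hu_to_bmd_mdct(calib.hu_water + hu, calib) - hu_to_bmd_mdct(
            calib.hu_water, calib
        )
        scaled = hu_to_bmd_mdct(calib.hu_water + scale * hu, calib) - \
            hu_to_bmd_mdct(calib.hu_water, calib)
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


class TestClassification:
    def test_printed_cohort_split(self):
        labels = [classify(v) for v in HC_BMD + OP_BMD]
        assert labels.count("healthy") == 6
        assert labels.count("osteoporotic") == 6

    def test_boundary_is_healthy_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert classify(80.0) == "healthy"
        assert any("threshold" in r.message for r in caplog.records)

    def test_full_chain_on_printed_values(self):
        """Noiseless synthetic subjects at the printed targets re-classify
        into the printed 6/6 cohort split."""
        geom = build_spine_geometry(TINY, seed=2)
        cohorts = []
        for target in HC_BMD + OP_BMD:
            vol, mask = rasterize_ct(geom, target, noise_sd=0.0, seed=0)
            res = subject_bmd(vol, mask)
            assert abs(res.bmd_qct_l1_3 - target) < 1.0
            cohorts.append(res.cohort)
        assert cohorts[:6] == ["healthy"] * 6
        assert cohorts[6:] == ["osteoporotic"] * 6


class TestROI:
    def test_noiseless_roi_exact(self, tiny_subject):
        geom, vol, mask = tiny_subject
        from spinefe.ct import CTConfig, invert_bmd_to_hu

        mu = invert_bmd_to_hu(100.0, CTConfig())
        for level in ("L1", "L2", "L3"):
            assert roi_mean_hu(vol, mask, level) == pytest.approx(mu, abs=1e-3)

    def test_noisy_roi_within_sem_bound(self):
        geom = build_spine_geometry(seed=6)  # full-size body -> large ROI
        vol, mask = rasterize_ct(geom, 100.0, noise_sd=30.0, seed=6)
        from spinefe.ct import CTConfig, invert_bmd_to_hu

        mu = invert_bmd_to_hu(100.0, CTConfig())
        hu, roi = roi_mean_hu(vol, mask, "L2", radius_fraction=0.55,
                              height_fraction=0.9, return_roi=True)
        assert roi.sum() >= 500
        assert abs(hu - mu) < 4.0  # ~3 sigma of the ROI mean

    def test_roi_shrink_then_error(self, tiny_subject):
        _, vol, mask = tiny_subject
        with pytest.raises(DensitometryError, match="voxels"):
            roi_mean_hu(vol, mask, "L1", min_voxels=10**6)
        with pytest.raises(DensitometryError, match="erosion"):
            roi_mean_hu(vol, mask, "L1", erosion_mm=6.0)

    def test_missing_vertebra_listed(self, tiny_subject):
        _, vol, mask = tiny_subject
        import copy

        m2 = copy.deepcopy(mask)
        m2.data[m2.data == LABEL_VERTEBRA["L2"]] = 0
        with pytest.raises(DensitometryError, match="L2"):
            subject_bmd(vol, m2)

    def test_missing_insert_is_calibration_error(self, tiny_subject):
        _, vol, mask = tiny_subject
        import copy

        m2 = copy.deepcopy(mask)
        m2.data[m2.data == LABEL_PHANTOM_WATER] = 0
        with pytest.raises(CalibrationError, match="water"):
            measure_phantom(vol, m2)


def test_subject_bmd_averages_l1_l3(tiny_subject):
    _, vol, mask = tiny_subject
    res = subject_bmd(vol, mask, extra_levels=("L4", "L5"))
    l13 = np.mean([res.bmd_qct[lv] for lv in ("L1", "L2", "L3")])
    assert res.bmd_qct_l1_3 == pytest.approx(l13)
    assert set(res.bmd_qct) == {"L1", "L2", "L3", "L4", "L5"}
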