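import numpy as np
import pytest

from osteosect import (
    CalibrationStandards,
    CalciumMap,
    SectionSpec,
    apply_calibration,
    fit_calibration,
    measure_standard_gray,
    simulate_section,
)
from osteosect.calibration import rect_roi_mask


def make_map(values, pixel_size_um=1.8):
    """CalciumMap from a raw value array, everything valid."""
    values = np.asarray(values, dtype=np.float64)
    return CalciumMap(
        wtpct_ca=values,
        valid_mask=np.ones_like(values, dtype=bool),
        pixel_size_um=pixel_size_um,
    )


def calibrate_from_patches(image, truth):
    """Fit the calibration from a simulated section's embedded patches."""
    roi_c = rect_roi_mask(image.shape, truth.standard_rois["carbon"])
    roi_al = rect_roi_mask(image.shape, truth.standard_rois["aluminum"])
    standards = CalibrationStandards(
        gl_carbon=measure_standard_gray(image, roi_c),
        gl_aluminum=measure_standard_gray(image, roi_al),
    )
    return fit_calibration(standards)


@pytest.fixture(scope="session")
def noiseless_section():
    """Default section without detector noise, simulated once per session."""
    spec = SectionSpec(gray_noise_sd=0.0)
    return simulate_section(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_section():
    """Default section with detector noise."""
    return simulate_section(SectionSpec(), seed=7)


@pytest.fixture(scope="session")
def noiseless_calcium_map(noiseless_section):
    image, _, truth = noiseless_section
    curve = calibrate_from_patches(image, truth)
    return apply_calibration(image, curve)
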