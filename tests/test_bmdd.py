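import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_map
from osteosect.bmdd import (
    BmddHistogram,
    BmddParameters,
    CompartmentMasks,
    EmptyCompartmentError,
    average_parameters,
    bmdd_parameters,
    compartment_bmdd,
    compute_bmdd,
    mineralized_mask,
)
from osteosect.synthetic_section import true_parameters

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def full_mask(m):
    return np.ones(m.shape, dtype=bool)


@pytest.fixture(scope="module")
def gaussian_map():
    """10^6 samples from N(21, 1.5^2), the law-of-large-numbers oracle."""
    rng = np.random.default_rng(123)
    values = rng.normal(21.0, 1.5, size=(1000, 1000))
    return make_map(values)


class TestMineralizedMask:
    def test_uniform_above_threshold(self):
        m = make_map(np.full((5, 5), 22.0))
        assert mineralized_mask(m, 5.2).all()

    def test_uniform_below_threshold(self):
        m = make_map(np.full((5, 5), 2.0))
        assert not mineralized_mask(m, 5.2).any()

    def test_half_and_half(self):
        values = np.full((4, 4), 2.0)
        values[:, 2:] = 22.0
        mask = mineralized_mask(make_map(values), 5.2)
        assert np.array_equal(mask, values == 22.0)

    def test_invalid_pixels_excluded(self):
        m = make_map(np.full((2, 2), 22.0))
        m.valid_mask[0, 0] = False
        assert mineralized_mask(m, 5.2).sum() == 3


class TestComputeBmdd:
    def test_uniform_map_single_bin(self):
        hist = compute_bmdd(make_map(np.full((10, 10), 22.0)), np.ones((10, 10), bool))
        assert (hist.area_pct > 0).sum() == 1
        assert hist.area_pct.max() == 100.0

    def test_empty_mask_raises(self):
        m = make_map(np.full((5, 5), 22.0))
        with pytest.raises(EmptyCompartmentError):
            compute_bmdd(m, np.zeros((5, 5), bool))

    @given(
        values=st.lists(
            st.floats(0.01, 39.5), min_size=1, max_size=200
        ),
        bin_width=st.floats(0.05, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_normalization_property(self, values, bin_width):
        m = make_map(np.asarray(values).reshape(1, -1))
        hist = compute_bmdd(m, full_mask(m), bin_width=bin_width)
        assert hist.area_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_gaussian_mean_recovered(self, gaussian_map):
        hist = compute_bmdd(gaussian_map, full_mask(gaussian_map))
        params = bmdd_parameters(hist)
        assert params.ca_mean_wtpct == pytest.approx(21.0, abs=0.01)

    def test_mask_restricts_pixels(self):
        values = np.full((4, 4), 20.0)
        values[:2] = 30.0
        m = make_map(values)
        mask = values == 20.0
        hist = compute_bmdd(m, mask)
        assert bmdd_parameters(hist).ca_mean_wtpct == pytest.approx(20.0, abs=0.1)
        assert hist.n_pixels == 8


class TestBmddParameters:
    def test_single_bin_degenerate(self):
        hist = compute_bmdd(make_map(np.full((3, 3), 22.0)), np.ones((3, 3), bool))
        p = bmdd_parameters(hist)
        assert p.ca_mean_wtpct == pytest.approx(22.0, abs=hist.bin_width / 2)
        assert p.ca_peak_wtpct == p.ca_mean_wtpct
        assert p.ca_width_wtpct == pytest.approx(hist.bin_width)
        assert p.ca_high_pct_area == 0.0

    def test_two_equal_bins_symmetry_and_tiebreak(self):
        # equal mass exactly at the centers of the bins holding 20.0 and 24.0
        values = np.array([[20.0] * 5 + [24.0] * 5])
        hist = compute_bmdd(make_map(values), np.ones((1, 10), bool), bin_width=0.5)
        p = bmdd_parameters(hist)
        assert p.ca_mean_wtpct == pytest.approx(22.0, abs=hist.bin_width / 2)
        assert p.ca_peak_wtpct < 21.0  # lowest-bin tie break

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            BmddHistogram(
                bin_edges=np.array([0.0, 0.17, 0.34]),
                area_pct=np.array([0.0, 0.0]),
                n_pixels=0,
            )

    def test_gaussian_fwhm_closed_form(self, gaussian_map):
        hist = compute_bmdd(gaussian_map, full_mask(gaussian_map))
        p = bmdd_parameters(hist)
        expected = FWHM_FACTOR * 1.5
        assert p.ca_width_wtpct == pytest.approx(expected, rel=0.02)

    def test_gaussian_calow_normal_cdf(self, gaussian_map):
        hist = compute_bmdd(gaussian_map, full_mask(gaussian_map))
        p = bmdd_parameters(hist)
        expected = 100.0 * stats.norm.cdf((17.68 - 21.0) / 1.5)
        assert p.ca_low_pct_area == pytest.approx(expected, abs=0.3)

    def test_gaussian_cahigh_normal_cdf(self, gaussian_map):
        hist = compute_bmdd(gaussian_map, full_mask(gaussian_map))
        p = bmdd_parameters(hist)
        expected = 100.0 * stats.norm.sf((25.30 - 21.0) / 1.5)
        assert p.ca_high_pct_area == pytest.approx(expected, abs=0.3)

    def test_histogram_below_low_threshold(self):
        rng = np.random.default_rng(0)
        m = make_map(rng.uniform(8.0, 15.0, size=(50, 50)))
        p = bmdd_parameters(compute_bmdd(m, full_mask(m)))
        assert p.ca_low_pct_area == pytest.approx(100.0, abs=1e-9)
        assert p.ca_high_pct_area == pytest.approx(0.0, abs=1e-9)

    def test_boundary_bin_apportionment(self):
        # with 0.3-wide bins the bin [17.4, 17.7) straddles 17.68; linear
        # overlap assigns (17.68-17.4)/0.3 = 93.33% of its mass to CaLow
        m = make_map(np.full((2, 2), 17.5))
        hist = compute_bmdd(m, np.ones((2, 2), bool), bin_width=0.3)
        p = bmdd_parameters(hist)
        assert p.ca_low_pct_area == pytest.approx(100 * (17.68 - 17.4) / 0.3, abs=1e-9)

    def test_smoothing_changes_only_peak(self, gaussian_map):
        hist = compute_bmdd(gaussian_map, full_mask(gaussian_map))
        raw = bmdd_parameters(hist, smooth=False)
        smoothed = bmdd_parameters(hist, smooth=True)
        assert raw.ca_mean_wtpct == smoothed.ca_mean_wtpct
        assert raw.ca_width_wtpct == smoothed.ca_width_wtpct
        assert abs(raw.ca_peak_wtpct - smoothed.ca_peak_wtpct) <= 2 * hist.bin_width


class TestShiftAndScaleProperties:
    def test_shift_equivariance_whole_bins(self):
        rng = np.random.default_rng(5)
        values = rng.normal(21.0, 1.5, size=(100, 100))
        delta = 10 * 0.17  # a whole number of bins keeps the grid aligned
        p0 = bmdd_parameters(compute_bmdd(make_map(values), np.ones((100, 100), bool)))
        p1 = bmdd_parameters(
            compute_bmdd(make_map(values + delta), np.ones((100, 100), bool))
        )
        assert p1.ca_mean_wtpct - p0.ca_mean_wtpct == pytest.approx(delta, abs=1e-9)
        assert p1.ca_peak_wtpct - p0.ca_peak_wtpct == pytest.approx(delta, abs=1e-9)

    @given(delta=st.floats(-3.0, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance_arbitrary_delta(self, delta):
        rng = np.random.default_rng(17)
        values = rng.normal(22.0, 1.0, size=(40, 40))
        mask = np.ones((40, 40), bool)
        p0 = bmdd_parameters(compute_bmdd(make_map(values), mask))
        # shifting the binning grid together with the data keeps it exact
        p1 = bmdd_parameters(
            compute_bmdd(make_map(values + delta), mask, bin_origin=delta)
        )
        assert p1.ca_mean_wtpct - p0.ca_mean_wtpct == pytest.approx(delta, abs=1e-9)
        assert p1.ca_peak_wtpct - p0.ca_peak_wtpct == pytest.approx(delta, abs=1e-9)

    @pytest.mark.parametrize("sigma", [0.51, 1.0, 2.0])
    def test_fwhm_tracks_gaussian_sigma(self, sigma):
        rng = np.random.default_rng(29)
        values = rng.normal(22.0, sigma, size=(700, 700))
        p = bmdd_parameters(compute_bmdd(make_map(values), np.ones((700, 700), bool)))
        assert p.ca_width_wtpct == pytest.approx(FWHM_FACTOR * sigma, rel=0.02)


class TestCompartmentBmdd:
    def test_cortical_mean_of_identical_cortices(self):
        p = BmddParameters(21.0, 22.0, 3.5, 5.0, 1.0)
        avg = average_parameters([p, p])
        assert avg == p

    def test_cortical_mean_patient_values(self):
        # per-cortex CaMean 20.31 and 19.09 average to 19.70
        p1 = BmddParameters(20.31, 21.83, 4.68, 15.24, 0.37)
        p2 = BmddParameters(19.09, 20.45, 4.51, 24.90, 0.02)
        avg = average_parameters([p1, p2])
        assert avg.ca_mean_wtpct == pytest.approx(19.70, abs=1e-12)
        assert avg.ca_peak_wtpct == pytest.approx(21.14, abs=1e-12)

    def test_single_cortex_summary(self):
        values = np.full((20, 20), 21.0)
        masks = CompartmentMasks(
            trabecular=np.pad(np.ones((10, 20), bool), ((0, 10), (0, 0))),
            cortex1=np.pad(np.ones((10, 20), bool), ((10, 0), (0, 0))),
        )
        out = compartment_bmdd(make_map(values), masks)
        assert out["cortical"] == out["cortex1"]
        assert "cortex2" not in out

    def test_empty_compartment_not_evaluable(self):
        values = np.full((20, 20), 21.0)
        values[10:] = 1.0  # cortex1 all below mineralization cut
        masks = CompartmentMasks(
            trabecular=np.pad(np.ones((10, 20), bool), ((0, 10), (0, 0))),
            cortex1=np.pad(np.ones((10, 20), bool), ((10, 0), (0, 0))),
        )
        out = compartment_bmdd(make_map(values), masks)
        assert out["cortex1"] is None
        assert out["cortical"] is None
        assert out["trabecular"] is not None


class TestOracleEquivalence:
    def test_binned_parameters_match_exhaustive_oracle(
        self, noiseless_section, noiseless_calcium_map
    ):
        """Fine-binned histogram statistics reproduce per-pixel enumeration."""
        from conftest import calibrate_from_patches

        image, _, truth = noiseless_section
        cam = noiseless_calcium_map
        oracle = true_parameters(truth)
        step = calibrate_from_patches(image, truth).slope  # gray quantization step
        mineral = mineralized_mask(cam)
        for name, comp_mask in truth.compartments.items():
            pixels = comp_mask & mineral
            # bins aligned so every quantized value sits at a bin center
            hist = compute_bmdd(cam, pixels, bin_width=step, bin_origin=-step / 2)
            p = bmdd_parameters(hist)
            ref = oracle[name]
            assert p.ca_mean_wtpct == pytest.approx(
                ref.ca_mean_wtpct, abs=step / 2
            )
            assert p.ca_peak_wtpct == pytest.approx(
                ref.ca_peak_wtpct, abs=step / 2
            )
            assert p.ca_low_pct_area == pytest.approx(ref.ca_low_pct_area, abs=0.2)
            assert p.ca_high_pct_area == pytest.approx(ref.ca_high_pct_area, abs=0.2)
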