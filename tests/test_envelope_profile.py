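import math

import numpy as np
import pytest

from sporesort import (
    DensityProfile,
    GreyImage,
    ProfileLine,
    extract_profile,
    measure_envelope_width,
    summarize_widths,
)
from sporesort.datasets import envelope_width_measurements
from sporesort.errors import (
    AmbiguousFeatureError,
    EmptyInputError,
    FeatureNotFoundError,
    OutOfBoundsError,
)
from sporesort.synthetic_data import BandImageModel, generate_band_image


def _image(pixels, pixel_size=1.0):
    return GreyImage(np.asarray(pixels, float), pixel_size)


class TestExtractProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = _image(np.full((64, 64), 7.0))
        prof = extract_profile(img, ProfileLine((20, 32), (44, 32)))
        assert np.allclose(prof.values, 7.0)
        assert prof.distances[0] == 0.0
        assert np.allclose(np.diff(prof.distances), 1.0)

    def test_vertical_step_with_horizontal_line(self):
        pixels = np.zeros((64, 64))
        pixels[:, 32:] = 10.0
        prof = extract_profile(_image(pixels), ProfileLine((5, 32), (58, 32)))
        vals = prof.values
        assert np.all(vals[:26] == 0.0)
        assert np.all(vals[-26:] == 10.0)
        # a single transition sample between the two plateaus
        assert np.count_nonzero((vals > 0) & (vals < 10)) <= 1

    def test_affine_grey_rescaling_commutes_exactly(self):
        rng = np.random.default_rng(0)
        pixels = rng.uniform(0, 255, (64, 64))
        line = ProfileLine((10.3, 12.7), (50.1, 48.9), 11)
        base = extract_profile(_image(pixels), line)
        scaled = extract_profile(_image(2.5 * pixels + 7.0), line)
        assert np.allclose(scaled.values, 2.5 * base.values + 7.0, rtol=0, atol=1e-9)

    def test_distances_scale_with_pixel_size(self):
        pixels = np.zeros((32, 32))
        a = extract_profile(_image(pixels, 1.0), ProfileLine((5, 16), (25, 16)))
        b = extract_profile(_image(pixels, 4.0), ProfileLine((5, 16), (25, 16)))
        assert np.allclose(b.distances, 4.0 * a.distances)

    def test_band_leaving_image_is_out_of_bounds(self):
        img = _image(np.zeros((32, 32)))
        with pytest.raises(OutOfBoundsError):
            extract_profile(img, ProfileLine((2, 1), (30, 1), 23))

    def test_rotated_band_profile_matches_unrotated(self):
        """Profiles across a 0-degree and a 45-degree band agree within 2% RMS
        of the contrast once both are taken perpendicular to the band."""
        kwargs = dict(width_nm=60.0, pixel_size=1.0, shape=(257, 257), noise_sd=0.0)
        img0, _ = generate_band_image(BandImageModel(angle_deg=0.0, **kwargs))
        img45, _ = generate_band_image(BandImageModel(angle_deg=45.0, **kwargs))
        c = 128.0
        p0 = extract_profile(img0, ProfileLine((c - 80, c), (c + 80, c)))
        # the 45-degree band's perpendicular runs along (1, -1)
        r = 80 / math.sqrt(2.0)
        p45 = extract_profile(
            img45, ProfileLine((c - r, c + r), (c + r, c - r))
        )
        # compare on the common distance grid
        v45 = np.interp(p0.distances, p45.distances, p45.values)
        sel = p0.distances <= p45.distances[-1]
        rms = np.sqrt(np.mean((p0.values[sel] - v45[sel]) ** 2))
        assert rms <= 0.02 * 100.0  # default contrast is 100 grey units


class TestMeasureWidth:
    def test_rectangular_dip_width_is_its_breadth(self):
        d = np.arange(0.0, 120.0)
        v = np.full(d.size, 50.0)
        v[40:80] = 40.0  # 40 samples of 1 nm spacing
        width = measure_envelope_width(DensityProfile(d, v), baseline_region=(0, 30))
        assert width == pytest.approx(40.0)

    def test_gaussian_dip_recovers_fwhm(self):
        sigma = 17.0
        d = np.arange(0.0, 301.0)
        v = 100.0 - 10.0 * np.exp(-0.5 * ((d - 150.0) / sigma) ** 2)
        width = measure_envelope_width(DensityProfile(d, v), baseline_region=(0, 60))
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma  # ~40.04 nm
        assert width == pytest.approx(expected, abs=0.5)

    def test_bright_rise_is_measured_like_a_dip(self):
        d = np.arange(0.0, 100.0)
        v = np.zeros(d.size)
        v[30:60] = 8.0
        width = measure_envelope_width(DensityProfile(d, v), baseline_region=(0, 20))
        assert width == pytest.approx(30.0)

    def test_affine_grey_invariance(self):
        d = np.arange(0.0, 200.0)
        v = 120.0 - 30.0 * np.exp(-0.5 * ((d - 100.0) / 12.0) ** 2)
        w1 = measure_envelope_width(DensityProfile(d, v), (0, 40))
        w2 = measure_envelope_width(DensityProfile(d, 3.0 * v - 50.0), (0, 40))
        assert w2 == pytest.approx(w1, rel=1e-12)

    def test_blurred_noisy_band_recovered_within_tolerance(self):
        model = BandImageModel(width_nm=213.7, seed=123)
        img, truth = generate_band_image(model)
        prof = extract_profile(img, ProfileLine((4, 127.5), (251, 127.5)))
        width = measure_envelope_width(prof, baseline_region=(0, 80))
        assert width == pytest.approx(truth["width_nm"], rel=0.05)

    def test_two_features_are_ambiguous(self):
        d = np.arange(0.0, 200.0)
        v = np.full(d.size, 20.0)
        v[40:60] = 10.0
        v[120:140] = 10.0
        with pytest.raises(AmbiguousFeatureError) as err:
            measure_envelope_width(DensityProfile(d, v), (0, 30))
        assert len(err.value.candidates) == 2

    def test_unbracketed_feature_is_not_found(self):
        d = np.arange(0.0, 100.0)
        v = np.full(d.size, 20.0)
        v[80:] = 5.0  # dip runs off the profile end
        with pytest.raises(FeatureNotFoundError):
            measure_envelope_width(DensityProfile(d, v), (0, 30))

    def test_flat_profile_has_no_feature(self):
        d = np.arange(0.0, 50.0)
        with pytest.raises(FeatureNotFoundError):
            measure_envelope_width(DensityProfile(d, np.full(d.size, 3.0)), (0, 20))


class TestSummarizeWidths:
    # species -> (vegetative mean, spore mean) printed to 2 decimals
    EXPECTED = {
        "B. subtilis": (44.72, 213.70),
        "S. violaceoruber": (36.28, 96.76),
        "M. xanthus": (31.04, 243.24),
        "A. cylindrica": (58.72, 216.80),
    }

    @pytest.mark.parametrize("species", sorted(EXPECTED))
    def test_reproduces_published_average_lengths(self, species):
        data = envelope_width_measurements()[species]
        veg, spo = self.EXPECTED[species]
        assert round(
            summarize_widths([[v] for v in data["VEG"]]).overall_mean, 2
        ) == veg
        assert round(
            summarize_widths([[v] for v in data["SPO"]]).overall_mean, 2
        ) == spo

    def test_hierarchical_means(self):
        s = summarize_widths([[10.0, 20.0], [40.0]])
        assert s.cell_means == [15.0, 40.0]
        assert s.overall_mean == 27.5

    def test_single_measurement_is_its_own_mean(self):
        assert summarize_widths([[213.7]]).overall_mean == 213.7

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_widths([])
        with pytest.raises(EmptyInputError):
            summarize_widths([[1.0], []])
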