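"""I/O, calibration, segmentation and preprocessing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shikispec import hsio, synth
from shikispec.hsio import HyperCube, Spectrum


def make_cube(value, shape=(4, 5, 6)):
    wl = np.linspace(500, 900, shape[2])
    return HyperCube(np.full(shape, float(value)), wl)


class TestReflectanceCalibrate:
    def test_raw_equals_white_gives_ones(self):
        raw = white = make_cube(0.9)
        dark = make_cube(0.1)
        out = hsio.reflectance_calibrate(raw, white, dark)
        np.testing.assert_allclose(out.data, 1.0)

    def test_raw_equals_dark_gives_zeros(self):
        white = make_cube(0.9)
        dark = raw = make_cube(0.1)
        out = hsio.reflectance_calibrate(raw, white, dark)
        np.testing.assert_allclose(out.data, 0.0)

    def test_midway_gives_half(self):
        raw, white, dark = make_cube(0.5), make_cube(0.9), make_cube(0.1)
        out = hsio.reflectance_calibrate(raw, white, dark)
        np.testing.assert_allclose(out.data, 0.5)

    def test_known_reflectance_recovered_exactly(self):
        rng = np.random.default_rng(0)
        wl = np.linspace(500, 900, 8)
        R = rng.uniform(0.05, 0.95, (6, 7, 8))
        dark = rng.uniform(0.01, 0.05, R.shape)
        white = dark + rng.uniform(0.5, 1.0, R.shape)
        raw = dark + R * (white - dark)
        out = hsio.reflectance_calibrate(
            HyperCube(raw, wl), HyperCube(white, wl), HyperCube(dark, wl)
        )
        np.testing.assert_allclose(out.data, R, atol=1e-12)

    def test_zero_denominator_names_voxel_count(self):
        white = make_cube(0.5)
        dark = make_cube(0.5)
        with pytest.raises(hsio.CalibrationError, match="120 voxel"):
            hsio.reflectance_calibrate(make_cube(0.5), white, dark)


class TestSegmentPlant:
    def test_matches_generator_foreground(self, library):
        cube, _ = synth.simulate_cube(library, 100.0, pixel_heterogeneity_sd=5.0, seed=3)
        mask = hsio.segment_plant(cube)
        assert np.mean(mask != cube.mask) <= 0.01

    def test_zero_threshold_keeps_everything(self):
        cube = make_cube(0.4)  # axis 500..900 in steps of 80
        mask = hsio.segment_plant(cube, red_band=660, nir_band=820, ratio_threshold=0.0)
        assert mask.all()

    def test_no_vegetation_raises(self):
        cube = make_cube(0.4)  # ratio 1 everywhere
        with pytest.raises(hsio.EmptyMaskError):
            hsio.segment_plant(cube, red_band=660, nir_band=820, ratio_threshold=2.0)

    def test_band_outside_axis_rejected(self):
        cube = make_cube(0.4)
        with pytest.raises(hsio.BandLookupError):
            hsio.segment_plant(cube, red_band=450, nir_band=800)


class TestMeanRoiSpectrum:
    def test_uniform_cube(self):
        cube = make_cube(0.7)
        s = hsio.mean_roi_spectrum(cube, np.ones((4, 5), dtype=bool))
        np.testing.assert_allclose(s.values, 0.7)

    def test_two_pixel_average(self):
        wl = np.array([500.0, 600.0])
        data = np.zeros((1, 2, 2))
        data[0, 0] = [0.2, 0.2]
        data[0, 1] = [0.4, 0.4]
        s = hsio.mean_roi_spectrum(HyperCube(data, wl), np.ones((1, 2), dtype=bool))
        np.testing.assert_allclose(s.values, 0.3)

    def test_matches_naive_double_loop(self, library):
        cube, _ = synth.simulate_cube(library, 60.0, canopy_shape=(10, 10), seed=4)
        mask = np.ones((10, 10), dtype=bool)
        s = hsio.mean_roi_spectrum(cube, mask)
        naive = np.zeros(cube.wavelengths.size)
        for i in range(10):
            for j in range(10):
                naive += cube.data[i, j]
        np.testing.assert_allclose(s.values, naive / 100.0, rtol=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(hsio.EmptyMaskError):
            hsio.mean_roi_spectrum(make_cube(0.5), np.zeros((4, 5), dtype=bool))


class TestCropSpectrum:
    def test_instrument_range_keeps_412_of_wider_axis(self):
        wl = np.linspace(380.67, 1030.03, 512)
        s = Spectrum(wl, np.ones_like(wl))
        out = hsio.crop_spectrum(s, 427.75, 948.49)
        keep = (wl >= 427.75) & (wl <= 948.49)
        assert len(out) == keep.sum()

    def test_synthetic_axis_fully_retained(self, library):
        s = Spectrum(library.wavelengths, library.baseline)
        out = hsio.crop_spectrum(s, 427.75, 948.49)
        assert len(out) == 412

    def test_full_extent_is_identity(self, library):
        s = Spectrum(library.wavelengths, library.baseline)
        out = hsio.crop_spectrum(s, library.wavelengths[0], library.wavelengths[-1])
        np.testing.assert_array_equal(out.values, s.values)

    def test_disjoint_window_rejected(self, library):
        s = Spectrum(library.wavelengths, library.baseline)
        with pytest.raises(ValueError):
            hsio.crop_spectrum(s, 5000, 6000)


class TestWaveletDetrend:
    def test_constant_debaselines_to_zero(self, library):
        s = Spectrum(library.wavelengths, np.full(412, 0.37))
        out = hsio.wavelet_detrend(s, mode="debaseline")
        assert np.max(np.abs(out.values)) < 1e-8

    def test_noiseless_smooth_signal_survives_denoise(self, library):
        s = Spectrum(library.wavelengths, library.baseline)
        out = hsio.wavelet_detrend(s, mode="denoise")
        rms = np.sqrt(np.mean((out.values - s.values) ** 2))
        assert rms < 1e-6

    def test_denoise_shrinks_white_noise_variance(self, library):
        wins = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(0, 1, 412)
            out = hsio.wavelet_detrend(Spectrum(library.wavelengths, v), mode="denoise")
            wins += out.values.var() < v.var()
        assert wins == 100

    def test_axis_and_length_preserved(self, library):
        s = Spectrum(library.wavelengths, library.baseline + 0.01)
        for mode in ("denoise", "debaseline"):
            out = hsio.wavelet_detrend(s, mode=mode)
            assert len(out) == 412
            np.testing.assert_array_equal(out.wavelengths, s.wavelengths)

    def test_short_spectrum_rejected(self):
        s = Spectrum(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            hsio.wavelet_detrend(s, level=3)


class TestScatterCorrections:
    def test_snv_two_band_hand_value(self):
        s = Spectrum(np.array([500.0, 600.0]), np.array([1.0, 3.0]))
        out = hsio.snv(s)
        np.testing.assert_allclose(out.values, [-0.70710678, 0.70710678])

    def test_snv_constant_rejected(self):
        with pytest.raises(ValueError):
            hsio.snv(Spectrum(np.array([500.0, 600.0]), np.array([1.0, 1.0])))

    def test_msc_self_reference_is_identity(self, library):
        s = Spectrum(library.wavelengths, library.baseline)
        out = hsio.msc(s, s)
        np.testing.assert_allclose(out.values, s.values, atol=1e-10)

    def test_msc_undoes_scatter(self, library):
        ref = Spectrum(library.wavelengths, library.baseline)
        scattered = ref.with_values(1.3 * ref.values + 0.05)
        out = hsio.msc(scattered, ref)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-10)

    def test_savgol_reproduces_linear_signal(self, library):
        v = 0.001 * library.wavelengths + 0.1
        out = hsio.savgol(Spectrum(library.wavelengths, v), window=11, polyorder=2)
        np.testing.assert_allclose(out.values, v, atol=1e-10)

    def test_savgol_even_window_rejected(self, library):
        with pytest.raises(ValueError):
            hsio.savgol(Spectrum(library.wavelengths, library.baseline), window=10)


@settings(max_examples=25, deadline=None)
@given(
    values=st.lists(
        st.floats(min_value=0.0, max_value=1.2, allow_nan=False), min_size=16, max_size=64
    )
)
def test_snv_output_standardized(values):
    """SNV always yields zero mean and unit sample sd (or raises on constants)."""
    v = np.asarray(values)
    wl = np.arange(v.size, dtype=float) + 400.0
    if np.std(v, ddof=1) == 0:
        with pytest.raises(ValueError):
            hsio.snv(Spectrum(wl, v))
    else:
        out = hsio.snv(Spectrum(wl, v))
        assert abs(out.values.mean()) < 1e-10
        assert np.std(out.values, ddof=1) == pytest.approx(1.0)


class TestBandLookup:
    def test_nearest_within_tolerance(self, library):
        i = hsio.band_index(library.wavelengths, 670.0)
        assert abs(library.wavelengths[i] - 670.0) <= 1.5

    def test_beyond_tolerance_raises(self):
        wl = np.array([500.0, 510.0, 520.0])
        with pytest.raises(hsio.BandLookupError):
            hsio.band_index(wl, 505.0)
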