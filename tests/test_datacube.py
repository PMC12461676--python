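import numpy as np
import pytest

from demsi.datacube import (
    MSIDataCube,
    bin_peaks_ppm,
    get_ion_image,
    load_cube,
    write_cube,
)


class TestNpzRoundTrip:
    def test_known_values_survive(self, tmp_path):
        intens = np.arange(12, dtype=float).reshape(2, 2, 3)
        cube = MSIDataCube(intensities=intens, mz_axis=[100.0, 200.0, 300.0])
        p = tmp_path / "c.npz"
        write_cube(cube, str(p))
        back = load_cube(str(p))
        np.testing.assert_array_equal(back.intensities, intens)
        np.testing.assert_array_equal(back.mz_axis, cube.mz_axis)
        assert back.pixel_mask.all()

    def test_random_cube_bitwise(self, tmp_path, random_cube):
        p = tmp_path / "c.npz"
        write_cube(random_cube, str(p))
        back = load_cube(str(p))
        np.testing.assert_array_equal(back.intensities, random_cube.intensities)
        np.testing.assert_array_equal(back.mz_axis, random_cube.mz_axis)
        np.testing.assert_array_equal(back.pixel_mask, random_cube.pixel_mask)
        assert back.meta["unit"] == "au"

    def test_masked_pixels_reload_as_zero(self, tmp_path, random_cube):
        random_cube.intensities[~random_cube.pixel_mask, :] = 0.0
        p = tmp_path / "c.npz"
        write_cube(random_cube, str(p))
        back = load_cube(str(p))
        assert (back.intensities[~back.pixel_mask, :] == 0).all()

    def test_degenerate_1x1x1(self, tmp_path):
        cube = MSIDataCube(intensities=np.full((1, 1, 1), 3.5), mz_axis=[42.0])
        p = tmp_path / "tiny.npz"
        write_cube(cube, str(p))
        back = load_cube(str(p))
        assert back.intensities[0, 0, 0] == 3.5

    def test_missing_file_raises(self):
        with pytest.raises(IOError):
            load_cube("/nonexistent/cube.npz")


class TestImzml:
    def test_continuous_round_trip(self, tmp_path, random_cube):
        p = tmp_path / "c.imzML"
        write_cube(random_cube, str(p), format="imzml")
        back = load_cube(str(p))
        assert back.shape == random_cube.shape
        np.testing.assert_allclose(back.mz_axis, random_cube.mz_axis, rtol=1e-6)
        np.testing.assert_allclose(back.intensities, random_cube.intensities, rtol=1e-6)
        np.testing.assert_array_equal(back.pixel_mask, random_cube.pixel_mask)

    def test_processed_mode_ppm_binning(self, tmp_path):
        # two pixels with peaks 5 ppm apart must merge into one channel;
        # window: 100.000 * (1 ± 5e-6) contains both 100.000 and 100.0005
        from pyimzml.ImzMLWriter import ImzMLWriter

        p = tmp_path / "proc.imzML"
        with ImzMLWriter(str(p), mode="processed") as w:
            w.addSpectrum([100.000, 150.0], [1.0, 2.0], (1, 1, 1))
            w.addSpectrum([100.0005], [3.0], (2, 1, 1))
        cube = load_cube(str(p), bin_tol_ppm=10.0)
        assert cube.n_channels == 2
        merged = cube.intensities[:, 0, 0]  # first channel, both pixels
        assert merged[0] == 1.0 and merged[1] == 3.0

    def test_binning_respects_tolerance(self):
        # peaks 100 ppm apart must NOT merge at 10 ppm
        axis, binned = bin_peaks_ppm(
            [np.array([100.0]), np.array([100.01])],
            [np.array([1.0]), np.array([1.0])],
            tol_ppm=10.0,
        )
        assert len(axis) == 2


class TestGetIonImage:
    def test_slice_values_and_mz(self):
        intens = np.zeros((3, 3, 2))
        intens[:, :, 0] = 0.5
        intens[:, :, 1] = 0.7
        cube = MSIDataCube(intensities=intens, mz_axis=[100.0, 101.0])
        img0 = get_ion_image(cube, 0)
        assert (img0.pixels == 0.5).all() and img0.mz == 100.0
        assert (get_ion_image(cube, 1).pixels == 0.7).all()

    def test_all_channels_match_slices(self, random_cube):
        for k in range(random_cube.n_channels):
            np.testing.assert_array_equal(
                get_ion_image(random_cube, k).pixels, random_cube.intensities[:, :, k]
            )

    def test_result_is_independent_of_cube(self, random_cube):
        img = get_ion_image(random_cube, 2)
        before = random_cube.intensities[:, :, 2].copy()
        img.pixels[:] = 999.0
        np.testing.assert_array_equal(random_cube.intensities[:, :, 2], before)

    def test_out_of_range_channel(self, random_cube):
        with pytest.raises(IndexError):
            get_ion_image(random_cube, random_cube.n_channels)


class TestValidation:
    def test_decreasing_mz_axis_rejected(self):
        with pytest.raises(ValueError):
            MSIDataCube(intensities=np.zeros((2, 2, 2)), mz_axis=[200.0, 100.0])

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            MSIDataCube(intensities=np.full((2, 2, 1), -1.0), mz_axis=[100.0])

    def test_mz_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MSIDataCube(intensities=np.zeros((2, 2, 3)), mz_axis=[100.0, 200.0])
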