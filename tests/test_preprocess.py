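import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demsi.datacube import IonImage, MSIDataCube
from demsi.preprocess import (
    PreprocessConfig,
    max_normalize,
    preprocess_cube,
    tic_normalize,
    truncate_hotspots,
)


def _img(values):
    return IonImage(np.asarray(values, dtype=float), mz=100.0)


class TestTicNormalize:
    def test_pixel_spectrum_divided_by_sum(self):
        intens = np.zeros((1, 1, 3))
        intens[0, 0] = [2.0, 2.0, 4.0]
        cube = MSIDataCube(intensities=intens, mz_axis=[1.0, 2.0, 3.0])
        out = tic_normalize(cube)
        np.testing.assert_allclose(out.intensities[0, 0], [0.25, 0.25, 0.5])

    def test_zero_tic_pixel_stays_zero(self):
        intens = np.zeros((2, 1, 2))
        intens[0, 0] = [1.0, 3.0]
        cube = MSIDataCube(intensities=intens, mz_axis=[1.0, 2.0])
        out = tic_normalize(cube)
        assert (out.intensities[1, 0] == 0).all()

    def test_nonzero_spectra_sum_to_one(self, random_cube):
        out = tic_normalize(random_cube)
        sums = out.intensities.sum(axis=2)
        nz = sums > 0
        np.testing.assert_allclose(sums[nz], 1.0, atol=1e-9)

    def test_input_not_mutated(self, random_cube):
        before = random_cube.intensities.copy()
        tic_normalize(random_cube)
        np.testing.assert_array_equal(random_cube.intensities, before)


class TestHotspotTruncation:
    def test_paper_toy_example(self):
        out = truncate_hotspots(_img([[0.0, 0.5, 1.0]]), q=0.99)
        np.testing.assert_allclose(out.pixels, [[0.0, 0.5, 0.99]])

    def test_constant_image_clips_everywhere(self):
        # every pixel exceeds 0.99 * max: the literal rule clips them all
        out = truncate_hotspots(_img(np.full((3, 3), 2.0)), q=0.99)
        np.testing.assert_allclose(out.pixels, 0.99 * 2.0)

    def test_q_one_is_identity(self, rng):
        x = rng.random((5, 5))
        out = truncate_hotspots(IonImage(x, 100.0), q=1.0)
        np.testing.assert_array_equal(out.pixels, x)

    def test_all_zero_unchanged(self):
        out = truncate_hotspots(_img(np.zeros((4, 4))), q=0.99)
        assert (out.pixels == 0).all()

    def test_reapplication_contracts_by_q(self, rng):
        # the literal "exceed q * max" rule is not idempotent: after one pass
        # the max is q * m, so a second pass clips at q^2 * m
        img = IonImage(rng.random((6, 6)), 100.0)
        once = truncate_hotspots(img, 0.99)
        twice = truncate_hotspots(once, 0.99)
        np.testing.assert_allclose(
            twice.pixels, np.minimum(once.pixels, 0.99 * once.pixels.max())
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_preserves_pixel_ordering(self, seed):
        x = np.random.default_rng(seed).random((5, 5))
        out = truncate_hotspots(IonImage(x, 100.0), 0.99).pixels
        i, j = np.unravel_index(np.argsort(x, axis=None), x.shape)
        assert (np.diff(out[i, j]) >= -1e-12).all()


class TestMaxNormalize:
    def test_simple_values(self):
        out = max_normalize(_img([[1.0, 2.0, 4.0]]))
        np.testing.assert_allclose(out.pixels, [[0.25, 0.5, 1.0]])

    def test_all_zero_passthrough(self):
        assert (max_normalize(_img(np.zeros((3, 3)))).pixels == 0).all()

    def test_range_and_idempotence(self, rng):
        img = IonImage(rng.random((7, 7)) * 13.0, 100.0)
        out = max_normalize(img)
        assert out.pixels.min() >= 0 and out.pixels.max() == pytest.approx(1.0)
        again = max_normalize(out)
        np.testing.assert_allclose(again.pixels, out.pixels)


class TestPreprocessCube:
    def test_all_steps_off_is_identity(self, random_cube):
        cfg = PreprocessConfig(do_tic=False, do_hotspot=False, do_max_norm=False)
        out = preprocess_cube(random_cube, cfg)
        np.testing.assert_array_equal(out.intensities, random_cube.intensities)

    def test_matches_manual_composition_single_channel(self, rng):
        intens = rng.random((6, 6, 1)) * 5.0
        cube = MSIDataCube(intensities=intens, mz_axis=[100.0])
        out = preprocess_cube(cube, PreprocessConfig())
        # manual: TIC (single channel -> nonzero pixels become 1), hotspot, max
        manual = tic_normalize(cube).intensities[:, :, 0]
        m = manual.max()
        manual = np.minimum(manual, 0.99 * m)
        manual = manual / manual.max()
        np.testing.assert_allclose(out.intensities[:, :, 0], manual)

    def test_every_channel_max_is_zero_or_one(self, small_phantom):
        noisy, _ = small_phantom
        out = preprocess_cube(noisy, PreprocessConfig())
        for k in range(out.n_channels):
            assert out.intensities[:, :, k].max() == pytest.approx(1.0) or (
                out.intensities[:, :, k] == 0
            ).all()

    def test_output_in_unit_interval(self, random_cube):
        out = preprocess_cube(random_cube, PreprocessConfig())
        assert out.intensities.min() >= 0
        assert out.intensities.max() <= 1.0 + 1e-12

    def test_channel_max_recorded_for_ratio_recovery(self, random_cube):
        out = preprocess_cube(random_cube, PreprocessConfig())
        assert len(out.meta["channel_max"]) == out.n_channels
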