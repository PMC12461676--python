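import numpy as np
import pytest

from demsi.datacube import MSIDataCube
from demsi.isopair import PairConfig, build_training_set, find_pairs, pairs_to_table
from demsi.phantom import ISOTOPE_SPACING, PhantomConfig, generate_phantom, phantom_report
from demsi.preprocess import PreprocessConfig, preprocess_cube


def _cube(channels, mzs, mask=None):
    intens = np.stack(channels, axis=2)
    return MSIDataCube(intensities=intens, mz_axis=np.asarray(mzs, float), pixel_mask=mask)


class TestFindPairs:
    def test_planted_pairs_recovered(self, small_phantom):
        noisy, truth = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        pairs = find_pairs(prep, PairConfig())
        rep = phantom_report(truth, pairs)
        assert rep["recall"] >= 0.9
        assert rep["precision"] >= 0.9

    def test_single_channel_gives_empty(self, rng):
        cube = _cube([rng.random((8, 8))], [100.0])
        assert find_pairs(cube) == []

    def test_uncorrelated_channels_rejected(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))  # independent noise: correlation ~ 0
        cube = _cube([a, 0.5 * b], [400.0, 400.0 + ISOTOPE_SPACING])
        assert find_pairs(cube) == []

    def test_wrong_spacing_rejected(self, rng):
        a = rng.random((16, 16)) + 0.1
        cube = _cube([a, 0.5 * a], [400.0, 400.5])
        assert find_pairs(cube) == []

    def test_heavier_channel_cannot_be_mono_of_lighter(self, rng):
        a = rng.random((16, 16)) + 0.1
        # iso BELOW mono in m/z: must not pair
        cube = _cube([0.5 * a, a], [400.0, 400.0 + ISOTOPE_SPACING])
        pairs = find_pairs(cube)
        for p in pairs:
            assert p.iso_mz > p.mono_mz

    def test_ratio_above_one_rejected(self, rng):
        a = rng.random((16, 16)) + 0.1
        cube = _cube([a, 2.0 * a], [400.0, 400.0 + ISOTOPE_SPACING])
        assert find_pairs(cube) == []

    def test_no_channel_in_both_roles(self, rng):
        # chain m0 -> m1 -> m2 at consecutive isotope spacings
        a = rng.random((16, 16)) + 0.1
        cube = _cube(
            [a, 0.5 * a, 0.25 * a],
            [400.0, 400.0 + ISOTOPE_SPACING, 400.0 + 2 * ISOTOPE_SPACING],
        )
        pairs = find_pairs(cube)
        monos = {p.mono_channel for p in pairs}
        isos = {p.iso_channel for p in pairs}
        assert not monos & isos

    def test_output_sorted_by_mono_mz(self, small_phantom):
        noisy, _ = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        pairs = find_pairs(prep)
        mzs = [p.mono_mz for p in pairs]
        assert mzs == sorted(mzs)

    def test_recall_monotone_in_min_corr(self, small_phantom):
        noisy, truth = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        recalls = []
        for mc in (0.3, 0.6, 0.9, 0.97):
            pairs = find_pairs(prep, PairConfig(min_corr=mc))
            recalls.append(phantom_report(truth, pairs)["recall"])
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_invariant_under_channel_permutation(self, small_phantom):
        # reversing-safe check: shift all m/z by a constant offset and confirm
        # the same channel pairs come back (cube channels must stay sorted by
        # m/z, so we perturb provenance instead of order)
        noisy, _ = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        base = {(p.mono_channel, p.iso_channel) for p in find_pairs(prep)}
        shifted = prep.copy()
        shifted.mz_axis = prep.mz_axis + 50.0
        again = {(p.mono_channel, p.iso_channel) for p in find_pairs(shifted)}
        assert base == again


class TestBuildTrainingSet:
    def test_empty_pairs(self, small_phantom):
        noisy, _ = small_phantom
        assert build_training_set(noisy, []) == []

    def test_shapes_and_count(self, small_phantom):
        noisy, truth = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        pairs = find_pairs(prep)[:5]
        ts = build_training_set(prep, pairs)
        assert len(ts) == 5
        for iso, mono in ts:
            assert iso.shape == prep.intensities.shape[:2]
            assert mono.shape == iso.shape
            assert iso.max() == pytest.approx(1.0)
            assert mono.max() == pytest.approx(1.0)

    def test_inputs_have_more_missing_than_targets(self, small_phantom):
        noisy, truth = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        ts = build_training_set(prep, find_pairs(prep))
        iso_zero = np.mean([(iso == 0).mean() for iso, _ in ts])
        mono_zero = np.mean([(mono == 0).mean() for _, mono in ts])
        assert iso_zero > mono_zero

    def test_dangling_channel_rejected(self, small_phantom):
        noisy, _ = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        pairs = find_pairs(prep)[:1]
        pairs[0].iso_channel = 10_000
        with pytest.raises(ValueError):
            build_training_set(prep, pairs)


class TestPairsTable:
    def test_columns_and_roundtrip(self, small_phantom):
        noisy, _ = small_phantom
        prep = preprocess_cube(noisy, PreprocessConfig())
        table = pairs_to_table(find_pairs(prep))
        assert list(table.columns) == [
            "mono_mz", "iso_mz", "delta_mz", "corr", "ratio", "mono_channel", "iso_channel",
        ]
        assert (table["delta_mz"] - ISOTOPE_SPACING).abs().max() < 1e-6
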