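import numpy as np
import pytest

from demsi.datacube import MSIDataCube
from demsi.denoiser import (
    MSIDenoiser,
    TrainConfig,
    denoise_cube,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
    train_denoiser,
)


def _smooth_stack(rng, n, hw=16):
    from scipy import ndimage

    X = np.stack(
        [ndimage.gaussian_filter(rng.random((hw, hw)), 2.0) for _ in range(n)]
    )
    X -= X.min(axis=(1, 2), keepdims=True)
    X /= X.max(axis=(1, 2), keepdims=True)
    return X


class TestReconstructionLoss:
    def test_zero_when_equal(self, rng):
        x = rng.random((3, 8, 8))
        assert reconstruction_loss(x, x) == 0.0

    def test_half_offset(self):
        assert reconstruction_loss(np.zeros((2, 4, 4)), np.full((2, 4, 4), 0.5)) == 0.5


class TestFit:
    def test_training_loss_decreases(self, rng):
        X = _smooth_stack(rng, 8)
        y = X.copy()
        noisy = np.clip(X + rng.normal(0, 0.1, X.shape), 0, None)
        est = MSIDenoiser(base_channels=4, depth=2, epochs=60, random_state=0)
        est.fit(noisy, y)
        hist = est.loss_history_["train"]
        assert len(hist) == 60
        assert min(hist) < hist[0]

    def test_learns_identity_on_smooth_images(self, rng):
        # generalization sanity check: with 8 training and 2 validation
        # images the held-out reconstruction MAE settles near 0.02-0.03
        X = _smooth_stack(rng, 10)
        est = MSIDenoiser(base_channels=8, depth=2, epochs=300, random_state=1)
        est.fit(X, X)
        assert est.best_val_loss_ < 0.03

    def test_fit_reproducible(self, rng):
        X = _smooth_stack(rng, 6)
        y = np.clip(X + rng.normal(0, 0.05, X.shape), 0, None)
        a = MSIDenoiser(base_channels=4, depth=1, epochs=20, random_state=3).fit(X, y)
        b = MSIDenoiser(base_channels=4, depth=1, epochs=20, random_state=3).fit(X, y)
        assert a.loss_history_["train"] == b.loss_history_["train"]
        for wa, wb in zip(a.model_.get_weights(), b.model_.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_too_few_pairs_rejected(self, rng):
        X = rng.random((1, 16, 16))
        with pytest.raises(ValueError):
            MSIDenoiser().fit(X, X)

    def test_sklearn_param_protocol(self):
        est = MSIDenoiser(epochs=10)
        params = est.get_params()
        assert params["epochs"] == 10
        est.set_params(learning_rate=0.001)
        assert est.get_params()["learning_rate"] == 0.001
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)


class TestTransform:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        X = _smooth_stack(rng, 8)
        noisy = np.clip(X + rng.normal(0, 0.1, X.shape), 0, None)
        est = MSIDenoiser(base_channels=4, depth=2, epochs=80, random_state=0)
        return est.fit(noisy, X)

    def test_output_shape_arbitrary_sizes(self, fitted, rng):
        # shapes not divisible by 2**depth are padded and cropped back
        for shape in [(16, 16), (33, 47), (20, 12)]:
            out = fitted.transform(rng.random((2, *shape)))
            assert out.shape == (2, *shape)

    def test_output_nonnegative(self, fitted, rng):
        assert fitted.transform(rng.random((3, 16, 16))).min() >= 0

    def test_unfitted_transform_rejected(self, rng):
        with pytest.raises(RuntimeError):
            MSIDenoiser().transform(rng.random((2, 16, 16)))


class TestCubeWrappers:
    def test_denoise_cube_contract(self, rng):
        X = _smooth_stack(rng, 6)
        est = MSIDenoiser(base_channels=4, depth=2, epochs=40, random_state=0).fit(X, X)
        intens = np.moveaxis(_smooth_stack(rng, 4), 0, 2)
        mask = np.ones((16, 16), dtype=bool)
        mask[0, :] = False
        intens[~mask, :] = 0
        cube = MSIDataCube(intensities=intens, mz_axis=100.0 + np.arange(4), pixel_mask=mask)
        out = denoise_cube(est, cube)
        assert out.shape == cube.shape
        assert (out.intensities[~mask, :] == 0).all()
        np.testing.assert_array_equal(out.mz_axis, cube.mz_axis)

    def test_train_denoiser_empty_set_rejected(self):
        with pytest.raises(ValueError):
            train_denoiser([], TrainConfig())


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        X = _smooth_stack(rng, 6)
        est = MSIDenoiser(base_channels=4, depth=1, epochs=15, random_state=2).fit(X, X)
        p = tmp_path / "model.npz"
        save_checkpoint(est, str(p))
        back = load_checkpoint(str(p))
        q = rng.random((2, 16, 16))
        np.testing.assert_allclose(back.transform(q), est.transform(q), atol=1e-6)
        assert back.get_params() == est.get_params()

    def test_unfitted_checkpoint_rejected(self, tmp_path):
        with pytest.raises(RuntimeError):
            save_checkpoint(MSIDenoiser(), str(tmp_path / "x.npz"))
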