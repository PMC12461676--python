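"""Classical denoising baselines: Gaussian filtering and wavelet shrinkage.

Both are the standard comparators for image denoising.  Gaussian filtering
replaces each pixel by a Gaussian-weighted local average (assumes spatially
smooth signal, independent noise); wavelet denoising soft-thresholds detail
coefficients of a multilevel 2-D wavelet transform at the universal
threshold ``sigma_hat * sqrt(2 ln n)``, with the noise level estimated from
the median absolute deviation of the finest-scale diagonal coefficients.

Both are deterministic and exposed as scikit-learn style transformers over
image stacks of shape ``(n_images, X, Y)``, with plain-function wrappers for
single ion images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .datacube import IonImage, MSIDataCube

__all__ = [
    "BaselineConfig",
    "gaussian_denoise",
    "wavelet_denoise",
    "GaussianDenoiser",
    "WaveletDenoiser",
    "denoise_cube_baseline",
]


@dataclass
class BaselineConfig:
    gaussian_sigma: float = 1.0
    wavelet_name: str = "db4"
    wavelet_levels: int = 3
    wavelet_threshold: str = "universal_soft"

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.wavelet_levels < 1:
            raise ValueError("wavelet_levels must be >= 1")
        if self.wavelet_threshold != "universal_soft":
            raise ValueError("only universal_soft thresholding is supported")


def _pixels(img) -> np.ndarray:
    return img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)


def _wrap(img, out: np.ndarray):
    if hasattr(img, "pixels"):
        return IonImage(out, img.mz, img.channel_index)
    return out


def gaussian_denoise(image, sigma: float = 1.0):
    """2-D Gaussian convolution with reflective boundary handling."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(_pixels(image), sigma, mode="reflect")
    return _wrap(image, out)


def wavelet_denoise(image, cfg: BaselineConfig | None = None):
    """Universal soft-threshold wavelet shrinkage; output clipped to >= 0."""
    cfg = cfg or BaselineConfig()
    x = _pixels(image)
    wav = pywt.Wavelet(cfg.wavelet_name)
    max_lv = pywt.dwtn_max_level(x.shape, wav)
    if max_lv < 1:
        raise ValueError(
            f"image {x.shape} too small for wavelet {cfg.wavelet_name}"
        )
    levels = min(cfg.wavelet_levels, max_lv)
    coeffs = pywt.wavedec2(x, wav, level=levels, mode="symmetric")
    # noise level from the finest-scale diagonal detail (MAD estimator)
    detail = coeffs[-1][-1]
    sigma_hat = np.median(np.abs(detail)) / 0.6745
    thr = sigma_hat * np.sqrt(2.0 * np.log(x.size))
    if thr == 0:  # noise-free input: nothing to shrink
        return _wrap(image, np.clip(x, 0.0, None))
    shrunk = [coeffs[0]] + [
        tuple(pywt.threshold(d, thr, mode="soft") for d in lvl) for lvl in coeffs[1:]
    ]
    y = pywt.waverec2(shrunk, wav, mode="symmetric")
    y = y[: x.shape[0], : x.shape[1]]  # waverec2 may pad odd sizes by one
    return _wrap(image, np.clip(y, 0.0, None))


class _StackTransformer:
    """Minimal sklearn-compatible base: stateless fit, get/set_params."""

    def get_params(self, deep: bool = True) -> dict:
        return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected an image stack of shape (n_images, X, Y)")
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class GaussianDenoiser(_StackTransformer):
    """Gaussian-filtering baseline over an image stack (n_images, X, Y)."""

    def __init__(self, sigma: float = 1.0):
        self.sigma = sigma

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.stack([gaussian_denoise(x, self.sigma) for x in X])


class WaveletDenoiser(_StackTransformer):
    """Wavelet-shrinkage baseline over an image stack (n_images, X, Y)."""

    def __init__(self, wavelet: str = "db4", levels: int = 3):
        self.wavelet = wavelet
        self.levels = levels

    def transform(self, X) -> np.ndarray:
        cfg = BaselineConfig(wavelet_name=self.wavelet, wavelet_levels=self.levels)
        X = np.asarray(X, dtype=float)
        return np.stack([wavelet_denoise(x, cfg) for x in X])


def denoise_cube_baseline(
    cube: MSIDataCube, method: str, cfg: BaselineConfig | None = None
) -> MSIDataCube:
    """Apply a classical baseline channel-wise to a whole cube."""
    cfg = cfg or BaselineConfig()
    out = cube.copy()
    for k in range(cube.n_channels):
        img = cube.intensities[:, :, k]
        if method == "gaussian":
            out.intensities[:, :, k] = gaussian_denoise(img, cfg.gaussian_sigma)
        elif method == "wavelet":
            out.intensities[:, :, k] = wavelet_denoise(img, cfg)
        else:
            raise ValueError(f"unknown baseline method {method!r}")
    out.intensities[~out.pixel_mask, :] = 0.0
    return out
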