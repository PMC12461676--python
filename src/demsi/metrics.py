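"""Image-quality metrics: PSNR and SSIM, mask-aware.

PSNR is ``10 log10(data_range^2 / MSE)`` in dB; SSIM is the mean local
structural similarity of Wang et al. with an 11-tap Gaussian window
(sigma 1.5), constants K1 = 0.01, K2 = 0.03 and population covariances.
Both are computed against a reference image over mask-true pixels only:
SSIM's local statistics are filtered over the full frame (windows may
straddle masked pixels) and the mask is applied when aggregating, which
keeps the local maps well-defined near tissue borders.

Preprocessed MSI channels live in [0, 1], so ``data_range`` defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .datacube import MSIDataCube

__all__ = ["psnr", "ssim", "evaluate_methods", "EvalReport"]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # 11-tap window: radius = int(3.5 * 1.5 + 0.5) = 5


def _check_pair(test: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    return test, ref


def _as_pixels(img) -> np.ndarray:
    return img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)


def psnr(test, ref, data_range: float = 1.0, mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    test, ref = _check_pair(_as_pixels(test), _as_pixels(ref))
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if mask is not None:
        diff = (test - ref)[mask]
    else:
        diff = test - ref
    mse = float(np.mean(diff**2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(
    test,
    ref,
    data_range: float = 1.0,
    mask: np.ndarray | None = None,
    K1: float = 0.01,
    K2: float = 0.03,
    sigma: float = _SSIM_SIGMA,
) -> float:
    """Mean structural similarity in [-1, 1]; identical images give 1."""
    x, y = _check_pair(_as_pixels(test), _as_pixels(ref))
    r = int(_SSIM_TRUNCATE * sigma + 0.5)
    win = 2 * r + 1
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")

    def g(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sigma, truncate=_SSIM_TRUNCATE, mode="reflect")

    ux, uy = g(x), g(y)
    uxx, uyy, uxy = g(x * x), g(y * y), g(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / ((ux**2 + uy**2 + C1) * (vx + vy + C2))

    interior = np.zeros(S.shape, dtype=bool)
    interior[r:-r, r:-r] = True
    if mask is not None:
        interior &= mask
    if not interior.any():
        raise ValueError("no valid pixels to aggregate SSIM over")
    return float(S[interior].mean())


@dataclass
class EvalReport:
    """Per-channel and aggregate PSNR/SSIM for a set of denoising methods."""

    per_channel: pd.DataFrame  # columns: channel, mz, method, psnr, ssim
    aggregate: pd.DataFrame    # index: method; psnr_mean/sd, ssim_mean/sd


def evaluate_methods(
    clean: MSIDataCube,
    noisy: MSIDataCube,
    denoised_by_method: dict[str, MSIDataCube],
    data_range: float = 1.0,
    channels: list[int] | None = None,
) -> EvalReport:
    """Score each method's cube against the clean reference, channel by channel.

    The noisy cube is included under the method name ``"noisy"`` as the
    no-denoising baseline.  PSNR values that come out infinite (identical
    images) are excluded from the PSNR mean/sd with a remaining-count in
    the aggregate table.
    """
    cubes = {"noisy": noisy, **denoised_by_method}
    for name, c in cubes.items():
        if c.shape != clean.shape:
            raise ValueError(f"cube for {name!r} has shape {c.shape}, expected {clean.shape}")
    if channels is None:
        channels = list(range(clean.n_channels))
    mask = clean.pixel_mask
    rows = []
    for name, c in cubes.items():
        for k in channels:
            t = c.intensities[:, :, k]
            rfc = clean.intensities[:, :, k]
            rows.append(
                {
                    "channel": k,
                    "mz": float(clean.mz_axis[k]),
                    "method": name,
                    "psnr": psnr(t, rfc, data_range=data_range, mask=mask),
                    "ssim": ssim(t, rfc, data_range=data_range, mask=mask),
                }
            )
    per_channel = pd.DataFrame(rows)
    agg_rows = []
    for name in cubes:
        sub = per_channel[per_channel["method"] == name]
        finite = sub["psnr"][np.isfinite(sub["psnr"])]
        agg_rows.append(
            {
                "method": name,
                "psnr_mean": float(finite.mean()) if len(finite) else float("inf"),
                "psnr_sd": float(finite.std(ddof=0)) if len(finite) else 0.0,
                "ssim_mean": float(sub["ssim"].mean()),
                "ssim_sd": float(sub["ssim"].std(ddof=0)),
                "n_channels": len(sub),
            }
        )
    aggregate = pd.DataFrame(agg_rows).set_index("method")
    return EvalReport(per_channel=per_channel, aggregate=aggregate)
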