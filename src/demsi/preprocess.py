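"""Preprocessing of MSI datacubes.

Three steps, applied in a fixed order:

1. **TIC normalisation** — each acquired pixel's spectrum is divided by its
   total ion current (the summed intensity across all channels), correcting
   pixel-to-pixel variation in ionisation/acquisition efficiency.
2. **Hotspot truncation** — per ion image, values that *exceed* 99% of the
   image maximum are clipped to that threshold; isolated anomalously hot
   pixels otherwise dominate the dynamic range.
3. **Per-ion max normalisation** — each ion image is divided by its maximum
   so every channel lives in [0, 1], the range the denoiser and the
   image-quality metrics assume.

An optional occupancy filter drops near-empty channels (fraction of nonzero
mask-true pixels below a floor) before the three steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datacube import IonImage, MSIDataCube

__all__ = [
    "PreprocessConfig",
    "tic_normalize",
    "truncate_hotspots",
    "max_normalize",
    "preprocess_cube",
    "drop_low_occupancy",
]


@dataclass
class PreprocessConfig:
    """Settings for :func:`preprocess_cube`.

    ``hotspot_quantile_of_max`` is a fraction of the per-image maximum
    (default 0.99): intensities strictly above it are truncated to it.
    """

    hotspot_quantile_of_max: float = 0.99
    do_tic: bool = True
    do_hotspot: bool = True
    do_max_norm: bool = True
    min_occupancy: float = 0.0  # 0 disables the channel-occupancy filter

    def __post_init__(self) -> None:
        if not 0 < self.hotspot_quantile_of_max <= 1:
            raise ValueError("hotspot_quantile_of_max must be in (0, 1]")
        if not 0 <= self.min_occupancy < 1:
            raise ValueError("min_occupancy must be in [0, 1)")


def tic_normalize(cube: MSIDataCube) -> MSIDataCube:
    """Divide each mask-true pixel's spectrum by its total ion current.

    Pixels with TIC = 0 are left as zeros; afterwards every pixel with
    positive TIC has a spectrum summing to 1.
    """
    out = cube.copy()
    tic = out.intensities.sum(axis=2)
    scale = np.where(tic > 0, tic, 1.0)
    out.intensities = out.intensities / scale[:, :, None]
    out.intensities[~out.pixel_mask, :] = 0.0
    return out


def _masked_max(pixels: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is None:
        return float(pixels.max()) if pixels.size else 0.0
    if not mask.any():
        return 0.0
    return float(pixels[mask].max())


def truncate_hotspots(image: IonImage, q: float = 0.99, mask: np.ndarray | None = None) -> IonImage:
    """Clip intensities strictly above ``q`` times the image maximum.

    The maximum is taken over mask-true pixels when a mask is given.  Values
    equal to the threshold are kept (strict "exceeds" rule), so the
    operation is idempotent.  An all-zero image is returned unchanged.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    m = _masked_max(image.pixels, mask)
    if m <= 0:
        return IonImage(image.pixels.copy(), image.mz, image.channel_index)
    thr = q * m
    return IonImage(np.minimum(image.pixels, thr), image.mz, image.channel_index)


def max_normalize(image: IonImage, mask: np.ndarray | None = None) -> IonImage:
    """Scale an ion image so its maximum equals 1 (all-zero images pass through)."""
    m = _masked_max(image.pixels, mask)
    if m <= 0:
        return IonImage(image.pixels.copy(), image.mz, image.channel_index)
    return IonImage(image.pixels / m, image.mz, image.channel_index)


def drop_low_occupancy(cube: MSIDataCube, min_occupancy: float) -> MSIDataCube:
    """Drop channels whose fraction of nonzero mask-true pixels is below the floor."""
    n_mask = int(cube.pixel_mask.sum())
    if n_mask == 0:
        return cube.copy()
    occ = (cube.intensities[cube.pixel_mask, :] > 0).mean(axis=0)
    keep = occ >= min_occupancy
    out = cube.copy()
    out.intensities = out.intensities[:, :, keep]
    out.mz_axis = out.mz_axis[keep]
    if not keep.all():
        out.meta["dropped_channels"] = int((~keep).sum())
    return out


def preprocess_cube(cube: MSIDataCube, cfg: PreprocessConfig | None = None) -> MSIDataCube:
    """Run the full preprocessing chain: TIC → hotspot truncation → max norm.

    The per-channel maximum *before* max normalisation is recorded in
    ``meta["channel_max"]`` so that downstream steps (isotope-pair mining)
    can recover abundance ratios on the un-normalised scale.
    """
    cfg = cfg or PreprocessConfig()
    out = cube.copy()
    if cfg.min_occupancy > 0:
        out = drop_low_occupancy(out, cfg.min_occupancy)
    if cfg.do_tic:
        out = tic_normalize(out)
    mask = out.pixel_mask
    H = out.n_channels
    channel_max = np.zeros(H)
    for k in range(H):
        img = IonImage(out.intensities[:, :, k], float(out.mz_axis[k]), k)
        if cfg.do_hotspot:
            img = truncate_hotspots(img, cfg.hotspot_quantile_of_max, mask=mask)
        channel_max[k] = _masked_max(img.pixels, mask)
        if cfg.do_max_norm:
            img = max_normalize(img, mask=mask)
        out.intensities[:, :, k] = img.pixels
    if cfg.do_max_norm:
        out.meta["channel_max"] = channel_max.tolist()
    return out
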