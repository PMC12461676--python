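"""Simulated corruption for quantitative evaluation.

Because noise-free MSI data cannot be measured, denoisers are scored by
corrupting a reference image and checking how well each method recovers it.
Two mechanisms emulate what mass analysers do to ion counts:

* **Poisson resampling** — each pixel is replaced by a draw from a Poisson
  distribution whose mean is the pixel value (shot noise).  On data already
  scaled to [0, 1] a literal unit-scale draw is extremely destructive; the
  ``poisson_scale`` parameter S draws ``Poisson(S * v) / S`` instead, which
  keeps the mean at ``v`` while emulating an underlying count level of S
  counts per intensity unit.  S = 1 is the literal, harshest setting and
  the default.
* **Random missing values** — an exact fraction of the acquired pixels is
  set to zero (sampling without replacement), emulating dropped pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datacube import IonImage, MSIDataCube

__all__ = ["CorruptionConfig", "poisson_corrupt", "missing_corrupt", "corrupt_cube"]


@dataclass
class CorruptionConfig:
    missing_frac: float = 0.20
    poisson_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.poisson_scale <= 0:
            raise ValueError("poisson_scale must be positive")


def poisson_corrupt(
    image: IonImage, S: float = 1.0, seed: int | np.random.Generator = 0
) -> IonImage:
    """Replace each pixel by ``Poisson(S * value) / S``.

    Zero pixels stay exactly zero (a Poisson with mean 0 is degenerate at 0),
    and the output is unbiased: E[output] = input for any S.
    """
    if np.any(image.pixels < 0):
        raise ValueError("poisson_corrupt requires nonnegative intensities")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = S * image.pixels
    out = rng.poisson(lam).astype(float) / S
    return IonImage(out, image.mz, image.channel_index)


def missing_corrupt(
    image: IonImage,
    frac: float = 0.20,
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> IonImage:
    """Zero out exactly ``floor(frac * n_mask_true)`` distinct acquired pixels."""
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = image.pixels.copy()
    if mask is None:
        mask = np.ones(out.shape, dtype=bool)
    eligible = np.flatnonzero(mask.reshape(-1))
    k = int(np.floor(frac * len(eligible)))
    if k:
        hit = rng.choice(eligible, size=k, replace=False)
        out.reshape(-1)[hit] = 0.0
    return IonImage(out, image.mz, image.channel_index)


def corrupt_cube(cube: MSIDataCube, cfg: CorruptionConfig | None = None) -> MSIDataCube:
    """Apply Poisson then missing-value corruption to every channel.

    Each channel uses an independent substream derived from ``cfg.seed``, so
    the result is reproducible and channel-order independent.  The input
    cube is not modified.
    """
    cfg = cfg or CorruptionConfig()
    out = cube.copy()
    for k in range(cube.n_channels):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, k]))
        img = IonImage(cube.intensities[:, :, k], float(cube.mz_axis[k]), k)
        img = poisson_corrupt(img, S=cfg.poisson_scale, seed=rng)
        img = missing_corrupt(img, frac=cfg.missing_frac, seed=rng, mask=cube.pixel_mask)
        out.intensities[:, :, k] = img.pixels
    out.intensities[~out.pixel_mask, :] = 0.0
    out.meta["corruption"] = {
        "missing_frac": cfg.missing_frac,
        "poisson_scale": cfg.poisson_scale,
        "seed": cfg.seed,
    }
    return out
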