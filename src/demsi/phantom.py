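"""Synthetic MSI phantoms with planted isotope pairs and known ground truth.

Real MSI data never comes with a noise-free reference, so every stage of the
pipeline is exercised on phantoms where the truth exists by construction.
A phantom cube contains:

* organ-like regions — smooth random blobs shared across channels, mimicking
  the fact that metabolites localise to anatomical structures;
* ``n_pairs`` molecules observed twice: a *monoisotopic* channel and an
  *isotopic* (+1 isotopologue) channel exactly 1.003355 Th above it.  The
  isotopic channel is an abundance-scaled copy of the monoisotopic one that
  additionally suffers extra missing values and outlier pixels — the
  degradation asymmetry the denoiser's pseudo-ground-truth trick relies on;
* unpaired singleton ions and pure-noise channels, so pair mining has
  realistic negatives.

All randomness fans out from one seed through per-channel substreams, so the
same seed reproduces the cube bitwise and adding channels does not perturb
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datacube import MSIDataCube

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "phantom_report"]

ISOTOPE_SPACING = 1.003355  # Th; 13C - 12C mass difference


@dataclass
class PhantomConfig:
    """Generator settings; defaults give a 64x64 cube with 20 planted pairs."""

    shape: tuple[int, int] = (64, 64)
    n_regions: int = 5
    n_pairs: int = 20
    n_unpaired: int = 10
    n_noise_channels: int = 5
    iso_abundance: float = 0.3     # isotopic / monoisotopic abundance ratio
    iso_extra_missing: float = 0.15  # missing fraction added on top of base_missing
    iso_outlier_frac: float = 0.02
    base_missing: float = 0.05
    noise_sigma: float = 0.2       # sigma of multiplicative lognormal pixel noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("phantom shape must be at least 8x8")
        for name in ("iso_extra_missing", "iso_outlier_frac", "base_missing"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.iso_abundance < 1:
            raise ValueError("iso_abundance must be in (0, 1)")
        if min(self.n_regions, self.n_pairs, self.n_unpaired, self.n_noise_channels) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom cube."""

    clean_cube: MSIDataCube
    pair_manifest: list[tuple[int, int]]  # (mono_channel, iso_channel) indices
    region_masks: np.ndarray = field(default=None)  # (n_regions, X, Y) bool


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _make_regions(rng: np.random.Generator, shape: tuple[int, int], n: int) -> np.ndarray:
    sigma = min(shape) / 8.0
    masks = np.zeros((n, *shape), dtype=bool)
    for r in range(n):
        field_ = _smooth_field(rng, shape, sigma)
        frac = rng.uniform(0.10, 0.30)  # region occupies 10-30% of the frame
        masks[r] = field_ > np.quantile(field_, 1 - frac)
    return masks


BACKGROUND_LEVEL = 0.08  # weak tissue-wide signal under the region structure


def _clean_molecule_image(
    rng: np.random.Generator, regions: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    n_regions = len(regions)
    k = int(rng.integers(1, min(3, n_regions) + 1)) if n_regions else 0
    img = np.zeros(shape)
    if k:
        chosen = rng.choice(n_regions, size=k, replace=False)
        weights = rng.uniform(0.15, 1.0, size=k)
        for c, w in zip(chosen, weights):
            img += w * regions[c]
    # two-scale multiplicative texture (squared smooth fields give the skewed,
    # high-contrast intensity profiles real ion images show) over a weak
    # tissue-wide background, so region/background contrast dominates
    coarse = _smooth_field(rng, shape, min(shape) / 6.0) ** 2
    fine = _smooth_field(rng, shape, min(shape) / 16.0) ** 2
    profile = 0.1 + 0.9 * (0.6 * coarse + 0.4 * fine)
    img = (BACKGROUND_LEVEL + img) * profile
    m = img.max()
    return img / m if m > 0 else img


def _apply_missing(rng: np.random.Generator, img: np.ndarray, frac: float) -> np.ndarray:
    out = img.copy()
    n = img.size
    k = int(np.floor(frac * n))
    if k:
        idx = rng.choice(n, size=k, replace=False)
        out.reshape(-1)[idx] = 0.0
    return out


def generate_phantom(cfg: PhantomConfig | None = None) -> tuple[MSIDataCube, PhantomTruth]:
    """Generate a (noisy cube, truth) pair.

    The noisy cube is what an instrument would deliver after peak picking:
    monoisotopic channels carry multiplicative lognormal noise plus a base
    fraction of missing pixels; isotopic channels are the abundance-scaled
    copies with extra missing values and hot outlier pixels; noise channels
    carry structure-free speckle.  The truth holds the noise-free channel
    images (max-normalised) and the planted pair manifest.
    """
    cfg = cfg or PhantomConfig()
    shape = tuple(cfg.shape)
    rng_global = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    regions = _make_regions(rng_global, shape, cfg.n_regions)

    n_molecules = cfg.n_pairs + cfg.n_unpaired
    # molecule slots on a 20-Th grid keep non-pair channel spacings far from
    # the isotope spacing, so mining negatives are unambiguous
    entries: list[tuple[float, str, int]] = []  # (mz, kind, molecule slot)
    for j in range(cfg.n_pairs):
        base = 300.0 + 20.0 * j
        entries.append((base, "mono", j))
        entries.append((base + ISOTOPE_SPACING, "iso", j))
    for j in range(cfg.n_unpaired):
        base = 310.0 + 20.0 * j
        entries.append((base, "single", cfg.n_pairs + j))
    for j in range(cfg.n_noise_channels):
        base = 303.0 + 20.0 * j
        entries.append((base, "noise", n_molecules + j))
    entries.sort(key=lambda e: e[0])

    H = len(entries)
    if H == 0:
        raise ValueError("phantom must contain at least one channel")
    mz_axis = np.asarray([e[0] for e in entries])

    clean_mol: dict[int, np.ndarray] = {}
    for slot in range(n_molecules):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, slot]))
        clean_mol[slot] = _clean_molecule_image(rng, regions, shape)

    noisy = np.zeros((*shape, H))
    clean = np.zeros((*shape, H))
    manifest_by_slot: dict[int, dict[str, int]] = {}
    for ch, (mz, kind, slot) in enumerate(entries):
        kind_code = {"mono": 0, "iso": 1, "single": 2, "noise": 3}[kind]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, slot, kind_code]))
        if kind == "noise":
            speckle = rng.uniform(0.0, 0.2, size=shape) * (rng.random(shape) < 0.3)
            noisy[:, :, ch] = speckle
            clean[:, :, ch] = 0.0
            continue
        base = clean_mol[slot]
        clean[:, :, ch] = base  # max-normalised, identical spatial truth for mono & iso
        lognoise = rng.lognormal(mean=0.0, sigma=cfg.noise_sigma, size=shape)
        if kind in ("mono", "single"):
            img = base * lognoise
            img = _apply_missing(rng, img, cfg.base_missing)
        else:  # iso
            img = cfg.iso_abundance * base * lognoise
            img = _apply_missing(rng, img, cfg.base_missing + cfg.iso_extra_missing)
            n_out = int(np.floor(cfg.iso_outlier_frac * img.size))
            if n_out:
                idx = rng.choice(img.size, size=n_out, replace=False)
                img.reshape(-1)[idx] = rng.uniform(2.0, 4.0, size=n_out) * cfg.iso_abundance
        noisy[:, :, ch] = img
        manifest_by_slot.setdefault(slot, {})[kind] = ch

    manifest = [
        (d["mono"], d["iso"]) for d in manifest_by_slot.values() if "mono" in d and "iso" in d
    ]
    manifest.sort()

    meta = {"phantom": True, "seed": cfg.seed, "n_pairs": cfg.n_pairs}
    noisy_cube = MSIDataCube(intensities=noisy, mz_axis=mz_axis, meta=dict(meta))
    clean_cube = MSIDataCube(intensities=clean, mz_axis=mz_axis.copy(), meta=dict(meta))
    truth = PhantomTruth(clean_cube=clean_cube, pair_manifest=manifest, region_masks=regions)
    return noisy_cube, truth


def phantom_report(truth: PhantomTruth, pairs) -> dict:
    """Recall / precision of mined pairs against the planted manifest.

    With no reported pairs, precision is 1.0 by convention and flagged.
    """
    true_set = set(truth.pair_manifest)
    found = {(p.mono_channel, p.iso_channel) for p in pairs}
    recall = len(found & true_set) / len(true_set) if true_set else 1.0
    if found:
        precision = len(found & true_set) / len(found)
        empty = False
    else:
        precision = 1.0
        empty = True
    return {
        "recall": recall,
        "precision": precision,
        "n_true": len(true_set),
        "n_found": len(found),
        "empty_report": empty,
    }
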