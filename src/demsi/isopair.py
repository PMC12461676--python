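"""Mining (isotopic, monoisotopic) ion-image pairs from a preprocessed cube.

A molecule detected in MSI appears as an isotope cluster: the monoisotopic
peak (all most-abundant isotopes) and, 1.003355 Th above it, the +1
isotopologue carrying one 13C.  The two ion images share the molecule's
spatial distribution, but the isotopic image is dimmer and noisier.  This
module finds such channel pairs by three filters:

* m/z spacing within a ppm tolerance of the 13C-12C mass difference;
* spatial colocalization — Spearman rank correlation over jointly nonzero,
  mask-true pixels.  Rank correlation is used because ion intensities are
  heavy-tailed and isotopic images carry hot outlier pixels; a plain
  product-moment correlation on raw intensities is dominated by a handful
  of such pixels;
* abundance ratio mean(iso)/mean(mono) at most 1 on the un-normalised
  intensity scale (the isotopologue cannot be more abundant).

Accepted pairs become the self-supervised training set: the noisy isotopic
image is the input, the cleaner monoisotopic image the pseudo ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datacube import MSIDataCube
from .phantom import ISOTOPE_SPACING

__all__ = ["PairConfig", "IonPair", "find_pairs", "build_training_set", "pairs_to_table"]

MIN_JOINT_PIXELS = 10  # below this, a Pearson correlation is meaningless


@dataclass
class PairConfig:
    """Thresholds for pair acceptance."""

    isotope_spacing: float = ISOTOPE_SPACING
    mz_tol_ppm: float = 10.0
    min_corr: float = 0.6
    max_ratio: float = 1.0
    min_occupancy: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.min_corr < 1:
            raise ValueError("min_corr must be in (0, 1)")
        if min(self.isotope_spacing, self.mz_tol_ppm, self.max_ratio) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class IonPair:
    """An accepted (monoisotopic, isotopic) channel pair with diagnostics."""

    mono_channel: int
    iso_channel: int
    mono_mz: float
    iso_mz: float
    delta_mz: float
    spatial_corr: float
    intensity_ratio: float


def _channel_stats(cube: MSIDataCube) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy and raw-scale mean per channel over mask-true pixels.

    If preprocessing stored ``meta["channel_max"]``, means are rescaled back
    to the pre-normalisation intensity scale so abundance ratios are
    physically meaningful.
    """
    vals = cube.intensities[cube.pixel_mask, :]  # (n_pixels, H)
    occupancy = (vals > 0).mean(axis=0) if len(vals) else np.zeros(cube.n_channels)
    means = vals.mean(axis=0) if len(vals) else np.zeros(cube.n_channels)
    scale = cube.meta.get("channel_max")
    if scale is not None and len(scale) == cube.n_channels:
        means = means * np.asarray(scale, dtype=float)
    return occupancy, means


def _pair_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Spearman rank correlation over jointly nonzero, mask-true pixels."""
    joint = mask & (a > 0) & (b > 0)
    if joint.sum() < MIN_JOINT_PIXELS:
        return np.nan
    x, y = a[joint], b[joint]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(spearmanr(x, y).statistic)


def find_pairs(cube: MSIDataCube, cfg: PairConfig | None = None) -> list[IonPair]:
    """Return accepted pairs, sorted by ascending monoisotopic m/z.

    Each monoisotopic channel is matched to at most one isotopic channel
    (highest correlation wins; ties broken by spacing closest to the
    isotope spacing), and no channel serves both roles: a channel accepted
    as isotopic cannot anchor a pair of its own, which breaks +2 chains.
    """
    cfg = cfg or PairConfig()
    H = cube.n_channels
    if H < 2:
        return []
    occupancy, means = _channel_stats(cube)
    mz = cube.mz_axis
    mask = cube.pixel_mask

    candidates: list[IonPair] = []
    for i in range(H):  # i = mono
        if occupancy[i] < cfg.min_occupancy or means[i] <= 0:
            continue
        tol = cfg.mz_tol_ppm * 1e-6 * mz[i]
        lo = np.searchsorted(mz, mz[i] + cfg.isotope_spacing - tol)
        hi = np.searchsorted(mz, mz[i] + cfg.isotope_spacing + tol, side="right")
        for j in range(lo, hi):
            if j == i or occupancy[j] < cfg.min_occupancy:
                continue
            ratio = means[j] / means[i]
            if ratio <= 0 or ratio > cfg.max_ratio:
                continue
            r = _pair_correlation(
                cube.intensities[:, :, i], cube.intensities[:, :, j], mask
            )
            if np.isnan(r) or r < cfg.min_corr:
                continue
            candidates.append(
                IonPair(
                    mono_channel=i,
                    iso_channel=j,
                    mono_mz=float(mz[i]),
                    iso_mz=float(mz[j]),
                    delta_mz=float(mz[j] - mz[i]),
                    spatial_corr=r,
                    intensity_ratio=float(ratio),
                )
            )

    # best iso per mono: highest correlation, then closest spacing
    best: dict[int, IonPair] = {}
    for p in candidates:
        cur = best.get(p.mono_channel)
        if cur is None:
            best[p.mono_channel] = p
            continue
        key = (p.spatial_corr, -abs(p.delta_mz - cfg.isotope_spacing))
        cur_key = (cur.spatial_corr, -abs(cur.delta_mz - cfg.isotope_spacing))
        if key > cur_key:
            best[p.mono_channel] = p

    accepted: list[IonPair] = []
    used_as_iso: set[int] = set()
    used_as_mono: set[int] = set()
    for i in sorted(best, key=lambda k: mz[k]):  # ascending mono m/z
        p = best[i]
        if p.mono_channel in used_as_iso or p.iso_channel in used_as_mono:
            continue
        if p.iso_channel in used_as_iso:
            continue
        accepted.append(p)
        used_as_mono.add(p.mono_channel)
        used_as_iso.add(p.iso_channel)
    return accepted


def build_training_set(
    cube: MSIDataCube, pairs: list[IonPair]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialise the training set: one (iso input, mono target) image pair each.

    Both images are max-normalised to [0, 1]; N = len(result) is the pair
    count the mean-absolute-error loss averages over.
    """
    H = cube.n_channels
    out = []
    for p in pairs:
        for ch in (p.mono_channel, p.iso_channel):
            if not 0 <= ch < H:
                raise ValueError(f"pair references channel {ch} outside cube with H={H}")
        iso = cube.intensities[:, :, p.iso_channel].copy()
        mono = cube.intensities[:, :, p.mono_channel].copy()
        for img in (iso, mono):
            m = img.max()
            if m > 0:
                img /= m
        out.append((iso, mono))
    return out


def pairs_to_table(pairs: list[IonPair]) -> pd.DataFrame:
    """Pair list as a DataFrame for reporting / CSV export."""
    return pd.DataFrame(
        [
            {
                "mono_mz": p.mono_mz,
                "iso_mz": p.iso_mz,
                "delta_mz": p.delta_mz,
                "corr": p.spatial_corr,
                "ratio": p.intensity_ratio,
                "mono_channel": p.mono_channel,
                "iso_channel": p.iso_channel,
            }
            for p in pairs
        ],
        columns=["mono_mz", "iso_mz", "delta_mz", "corr", "ratio", "mono_channel", "iso_channel"],
    )
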