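"""MSI datacube container and I/O.

A mass spectrometry imaging (MSI) experiment yields one mass spectrum per
pixel; reorganised by m/z channel this is a three-dimensional array
``(X, Y, H)`` — two spatial axes and ``H`` m/z bins — where each slice
``[:, :, k]`` is the *ion image* of the k-th m/z channel.  This module
defines the in-memory containers (:class:`MSIDataCube`, :class:`IonImage`)
and reads/writes them from imzML (via pyimzML) or a plain ``.npz``
container.

Conventions
-----------
* pixel indices are 0-based, ``x`` = column (horizontal), ``y`` = row
  (vertical); ``intensities[x, y, k]`` follows the ``(X, Y, H)`` layout.
* missing / unacquired measurements are stored as 0; ``pixel_mask`` is
  ``True`` for acquired (tissue) pixels, and downstream evaluation only
  considers mask-true pixels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MSIDataCube",
    "IonImage",
    "load_cube",
    "write_cube",
    "get_ion_image",
    "bin_peaks_ppm",
]


class CubeFormatError(ValueError):
    """Raised when a file does not conform to the expected cube format."""


@dataclass
class IonImage:
    """A single m/z channel of a datacube.

    Attributes
    ----------
    pixels : ndarray, shape (X, Y)
        Nonnegative intensities; zeros encode missing values.
    mz : float
        m/z value of the channel, in Thomson.
    channel_index : int
        Index of this channel in the parent cube.
    """

    pixels: np.ndarray
    mz: float
    channel_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"ion image must be 2-D, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("ion image intensities must be nonnegative")


@dataclass
class MSIDataCube:
    """An MSI datacube ``M`` of shape ``(X, Y, H)`` with its m/z axis.

    Attributes
    ----------
    intensities : ndarray, shape (X, Y, H)
        Nonnegative intensities (arbitrary units before normalisation).
    mz_axis : ndarray, shape (H,)
        Strictly increasing m/z values (Th), one per channel.
    pixel_mask : ndarray of bool, shape (X, Y)
        True where a pixel was acquired / lies on tissue.
    meta : dict
        Free-form provenance (source path, pixel size, ionisation mode, ...).
    """

    intensities: np.ndarray
    mz_axis: np.ndarray
    pixel_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"intensities must be 3-D (X, Y, H), got {self.intensities.shape}")
        X, Y, H = self.intensities.shape
        if X < 1 or Y < 1 or H < 1:
            raise ValueError("cube must be at least 1x1x1")
        if self.mz_axis.shape != (H,):
            raise ValueError(
                f"mz_axis length {self.mz_axis.shape} does not match H={H}"
            )
        if H > 1 and not np.all(np.diff(self.mz_axis) > 0):
            raise ValueError("mz_axis must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative (missing values are 0)")
        if self.pixel_mask is None:
            self.pixel_mask = np.ones((X, Y), dtype=bool)
        else:
            self.pixel_mask = np.asarray(self.pixel_mask, dtype=bool)
            if self.pixel_mask.shape != (X, Y):
                raise ValueError("pixel_mask shape must match (X, Y)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    def copy(self) -> "MSIDataCube":
        return MSIDataCube(
            intensities=self.intensities.copy(),
            mz_axis=self.mz_axis.copy(),
            pixel_mask=self.pixel_mask.copy(),
            meta=dict(self.meta),
        )


def get_ion_image(cube: MSIDataCube, channel: int) -> IonImage:
    """Extract one channel as an independent :class:`IonImage`.

    The returned image owns its pixel array: mutating it never corrupts the
    parent cube.
    """
    H = cube.n_channels
    if not 0 <= channel < H:
        raise IndexError(f"channel {channel} out of range [0, {H})")
    return IonImage(
        pixels=cube.intensities[:, :, channel].copy(),
        mz=float(cube.mz_axis[channel]),
        channel_index=channel,
    )


# ---------------------------------------------------------------------------
# npz_matrix container
# ---------------------------------------------------------------------------

def _write_npz(cube: MSIDataCube, path: str) -> None:
    np.savez_compressed(
        path,
        intensities=cube.intensities,
        mz=cube.mz_axis,
        mask=cube.pixel_mask,
        meta=np.asarray(json.dumps(cube.meta, default=str)),
    )


def _load_npz(path: str) -> MSIDataCube:
    with np.load(path, allow_pickle=False) as f:
        try:
            intensities = f["intensities"]
            mz = f["mz"]
        except KeyError as e:
            raise CubeFormatError(f"{path}: missing array {e} (not an npz_matrix cube)")
        mask = f["mask"] if "mask" in f else None
        meta = json.loads(str(f["meta"])) if "meta" in f else {}
    return MSIDataCube(intensities=intensities, mz_axis=mz, pixel_mask=mask, meta=meta)


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def bin_peaks_ppm(
    mz_lists: list[np.ndarray],
    intensity_lists: list[np.ndarray],
    tol_ppm: float = 10.0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Merge centroided peak lists onto a common m/z axis.

    Greedy single-pass binning of the pooled, sorted peaks: a peak within
    ``tol_ppm`` of the running (intensity-weighted) bin centre joins the
    current bin, otherwise it opens a new one.  Used to put processed-mode
    imzML spectra (per-pixel peak lists) onto the common axis a datacube
    requires.

    Returns
    -------
    axis : ndarray
        Bin centres, strictly increasing.
    binned : list of ndarray
        Per-spectrum intensity vectors on ``axis`` (co-eluting peaks in one
        spectrum and bin are summed).
    """
    all_mz = []
    all_int = []
    all_spec = []
    for s, (mzs, ints) in enumerate(zip(mz_lists, intensity_lists)):
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        all_mz.append(mzs)
        all_int.append(ints)
        all_spec.append(np.full(mzs.shape, s, dtype=int))
    if not all_mz or sum(len(a) for a in all_mz) == 0:
        raise CubeFormatError("no peaks found in any spectrum")
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_int)
    spec = np.concatenate(all_spec)
    order = np.argsort(mz, kind="stable")
    mz, inten, spec = mz[order], inten[order], spec[order]

    bin_id = np.empty(len(mz), dtype=int)
    centers: list[float] = []
    center = mz[0]
    weight = max(inten[0], np.finfo(float).tiny)
    current = 0
    bin_id[0] = 0
    for i in range(1, len(mz)):
        if mz[i] - center <= tol_ppm * 1e-6 * center:
            w = max(inten[i], np.finfo(float).tiny)
            center = (center * weight + mz[i] * w) / (weight + w)
            weight += w
        else:
            centers.append(center)
            current += 1
            center = mz[i]
            weight = max(inten[i], np.finfo(float).tiny)
        bin_id[i] = current
    centers.append(center)
    axis = np.asarray(centers)

    binned = []
    n_bins = len(axis)
    for s in range(len(mz_lists)):
        sel = spec == s
        v = np.zeros(n_bins)
        np.add.at(v, bin_id[sel], inten[sel])
        binned.append(v)
    return axis, binned


def _load_imzml(path: str, bin_tol_ppm: float = 10.0) -> MSIDataCube:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(path)
    coords = np.asarray(parser.coordinates)  # (n, 3) 1-based x, y, z
    xs = coords[:, 0] - coords[:, 0].min()
    ys = coords[:, 1] - coords[:, 1].min()
    X = int(xs.max()) + 1
    Y = int(ys.max()) + 1
    n = len(parser.coordinates)
    mz_lists, int_lists = [], []
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        mz_lists.append(np.asarray(mzs, dtype=float))
        int_lists.append(np.asarray(ints, dtype=float))

    lengths = {len(m) for m in mz_lists}
    continuous = len(lengths) == 1 and all(
        np.array_equal(mz_lists[0], m) for m in mz_lists[1:]
    )
    if continuous:
        axis = mz_lists[0]
        spectra = int_lists
    else:
        axis, spectra = bin_peaks_ppm(mz_lists, int_lists, tol_ppm=bin_tol_ppm)

    H = len(axis)
    intensities = np.zeros((X, Y, H))
    mask = np.zeros((X, Y), dtype=bool)
    for i in range(n):
        x, y = int(xs[i]), int(ys[i])
        intensities[x, y, :] = np.clip(spectra[i], 0.0, None)
        mask[x, y] = True
    meta = {"source": os.path.basename(path), "imzml_mode": "continuous" if continuous else "processed"}
    return MSIDataCube(intensities=intensities, mz_axis=axis, pixel_mask=mask, meta=meta)


def _write_imzml(cube: MSIDataCube, path: str) -> None:
    from pyimzml.ImzMLWriter import ImzMLWriter

    X, Y, _ = cube.shape
    with ImzMLWriter(path, mode="continuous", intensity_dtype=np.float64) as w:
        for x in range(X):
            for y in range(Y):
                if cube.pixel_mask[x, y]:
                    # imzML coordinates are 1-based
                    w.addSpectrum(cube.mz_axis, cube.intensities[x, y, :], (x + 1, y + 1, 1))


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    lower = str(path).lower()
    if lower.endswith(".imzml"):
        return "imzml"
    return "npz_matrix"


def load_cube(path: str, format: str | None = None, bin_tol_ppm: float = 10.0) -> MSIDataCube:
    """Load a datacube from disk.

    Parameters
    ----------
    path : str
        File to read.
    format : {"imzml", "npz_matrix"}, optional
        Inferred from the extension when omitted.
    bin_tol_ppm : float
        Tolerance for merging processed-mode imzML peaks onto a common axis.
    """
    if not os.path.exists(path):
        raise IOError(f"cube file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "imzml":
        return _load_imzml(path, bin_tol_ppm=bin_tol_ppm)
    if fmt == "npz_matrix":
        return _load_npz(path)
    raise ValueError(f"unknown cube format: {fmt!r}")


def write_cube(cube: MSIDataCube, path: str, format: str | None = None) -> None:
    """Write a datacube; ``load_cube`` round-trips it."""
    fmt = _infer_format(path, format)
    out = cube.copy()
    # mask-false pixels are by convention unacquired: store them as zeros
    out.intensities[~out.pixel_mask, :] = 0.0
    if fmt == "imzml":
        _write_imzml(out, path)
    elif fmt == "npz_matrix":
        _write_npz(out, path)
    else:
        raise ValueError(f"unknown cube format: {fmt!r}")
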