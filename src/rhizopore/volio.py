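"""Volume I/O and grayscale preprocessing.

A :class:`GrayVolume` is the unit every pipeline stage consumes: a 3-D scalar
grid of integer gray values with a physical voxel edge length in mm.  The
first array axis is the slice (depth) axis; coordinates are voxel-centered
and 0-based.

Preprocessing mirrors the standard micro-CT workflow: crop to an interior
cuboid away from the column wall, percentile-based contrast stretch with
reduction to 8-bit, and denoising to stabilise automatic histogram
thresholding.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.restoration import denoise_nl_means


class FormatError(ValueError):
    """Raised for malformed volume inputs (inconsistent slices, bad dtype)."""


@dataclass
class GrayVolume:
    """3-D grayscale image with voxel size metadata.

    Parameters
    ----------
    voxels
        3-D integer array, slice axis first.
    voxel_size
        Voxel edge length in mm (isotropic).
    bit_depth
        8 or 16.
    provenance
        Free-text log of processing steps applied so far.
    """

    voxels: np.ndarray
    voxel_size: float
    bit_depth: int = 8
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.voxels.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy_with(self, voxels: np.ndarray, note: str | None = None, **kw) -> "GrayVolume":
        out = replace(self, voxels=voxels, provenance=list(self.provenance), **kw)
        if note:
            out.log(note)
        return out


def read_volume(path: str | Path, voxel_size_mm: float) -> GrayVolume:
    """Read a multi-page TIFF or a directory of numbered TIFF slices.

    Slices in a directory are assembled in natural (numeric-aware
    lexicographic) order.
    """
    if voxel_size_mm is None or not voxel_size_mm > 0:
        raise ValueError("voxel size (mm) is required and must be positive")
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=_natural_key,
        )
        if not files:
            raise FormatError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice shapes: {sorted(shapes)}")
        arr = np.stack(slices, axis=0)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected 3-D data, got shape {arr.shape}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    vol = GrayVolume(arr, voxel_size_mm, bit_depth=bit_depth)
    vol.log(f"read {path.name}: shape={arr.shape} dtype={arr.dtype}")
    return vol


def write_volume(vol: GrayVolume, path: str | Path) -> Path:
    """Write as a multi-page TIFF with the voxel size in the resolution tags
    and the provenance log in a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px_per_cm = 10.0 / vol.voxel_size  # pixels per cm
    tifffile.imwrite(
        path,
        vol.voxels,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "voxel_size_mm": vol.voxel_size,
                "bit_depth": vol.bit_depth,
                "shape": list(vol.shape),
                "provenance": vol.provenance,
            },
            indent=2,
        )
    )
    return path


def crop_interior(vol: GrayVolume, margin_voxels: tuple[int, int, int] | int) -> GrayVolume:
    """Crop ``margin_voxels`` from both sides of each axis.

    Emulates cutting the reconstructed scan to an interior cuboid to avoid
    artifacts near the column wall.  A margin of 0 on an axis leaves it
    untouched.
    """
    if np.isscalar(margin_voxels):
        margin_voxels = (int(margin_voxels),) * 3
    margins = tuple(int(m) for m in margin_voxels)
    for ax, m in enumerate(margins):
        if m < 0 or 2 * m >= vol.shape[ax]:
            raise ValueError(
                f"margin {m} too large for axis {ax} of length {vol.shape[ax]}"
            )
    sl = tuple(slice(m, n - m) for m, n in zip(margins, vol.shape))
    return vol.copy_with(vol.voxels[sl], note=f"crop_interior margins={margins}")


def contrast_stretch_8bit(vol: GrayVolume, saturation_fraction: float = 0.0035) -> GrayVolume:
    """Linear contrast stretch to 8-bit with tail saturation.

    The lower/upper mapping bounds are the ``s/2`` and ``1 - s/2`` quantiles
    of the gray histogram with ``s = saturation_fraction``, so a total
    fraction ``s`` of voxels is saturated to 0/255 (split between the two
    tails).  The default 0.0035 follows the 0.35 "saturated pixels"
    percentage convention of the common enhance-contrast tool.
    """
    if not 0 <= saturation_fraction < 1:
        raise ValueError("saturation_fraction must be in [0, 1)")
    data = vol.voxels.astype(np.float64)
    lo = np.quantile(data, saturation_fraction / 2)
    hi = np.quantile(data, 1 - saturation_fraction / 2)
    if hi <= lo:
        warnings.warn("constant volume: mapping to mid-gray 128")
        out = np.full(vol.shape, 128, dtype=np.uint8)
    else:
        out = np.clip((data - lo) / (hi - lo) * 255.0, 0, 255)
        out = np.rint(out).astype(np.uint8)
    return vol.copy_with(
        out,
        note=f"contrast_stretch_8bit saturation_fraction={saturation_fraction} "
        f"(interpreted as fraction of voxels saturated, split between tails); "
        f"bounds=({lo:.2f}, {hi:.2f})",
        bit_depth=8,
    )


_DENOISERS = ("patch_mean", "box", "gaussian", "median")


def denoise(vol: GrayVolume, method: str = "patch_mean", strength: float = 1.0) -> GrayVolume:
    """Denoise an 8-bit volume.

    Methods
    -------
    patch_mean
        Patch-based (non-local) means: each voxel is replaced by a weighted
        mean of voxels with similar patch neighbourhoods; edge-preserving.
        ``strength`` scales the filtering parameter h (h = 6 * strength gray
        levels, tuned for noise SDs near 8).
    box
        Plain local mean over a cube of half-width ``round(strength)``.
    gaussian
        Gaussian smoothing with sigma = ``strength`` voxels.
    median
        Median over a cube of half-width ``round(strength)``; edge-preserving.

    ``strength = 0`` is the identity for every method.
    """
    if method not in _DENOISERS:
        raise ValueError(f"unknown denoise method {method!r}; choose from {_DENOISERS}")
    if vol.bit_depth != 8:
        raise ValueError("denoise expects an 8-bit volume; run contrast_stretch_8bit first")
    if strength <= 0:
        return vol.copy_with(vol.voxels.copy(), note=f"denoise {method} strength=0 (identity)")
    data = vol.voxels
    if method == "patch_mean":
        out = denoise_nl_means(
            data.astype(np.float32),
            patch_size=3,
            patch_distance=3,
            h=6.0 * strength,
            fast_mode=True,
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    elif method == "box":
        size = 2 * int(round(strength)) + 1
        out = ndi.uniform_filter(data.astype(np.float32), size=size)
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    elif method == "gaussian":
        out = ndi.gaussian_filter(data.astype(np.float32), sigma=strength)
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    else:  # median
        size = 2 * int(round(strength)) + 1
        out = ndi.median_filter(data, size=size)
    return vol.copy_with(out, note=f"denoise method={method} strength={strength}")


def _natural_key(p: Path):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]
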