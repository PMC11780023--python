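"""Volume/mask containers, NIfTI I/O, and the fixed preprocessing chain.

The preprocessing order is fixed: intensity normalisation to 0-255,
histogram equalisation, isotropic resampling (1 mm default), and per-VOI
gray-level discretisation with a fixed bin width (5 by default).
Normalisation and equalisation are applied to whole volumes so that image
and mask geometry stay aligned; discretisation happens per lesion VOI.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = [
    "Volume",
    "Mask",
    "DiscretizedVOI",
    "read_nifti_volume",
    "read_nifti_mask",
    "write_nifti",
    "normalize_0_255",
    "hist_equalize",
    "resample_isotropic",
    "discretize",
    "preprocess_volume",
]


@dataclasses.dataclass(frozen=True)
class Volume:
    """A 3-D intensity grid with voxel spacing and physical origin (mm)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got {data.ndim}-D")
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume contains non-finite values")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing_mm, self.origin_mm)


@dataclasses.dataclass(frozen=True)
class Mask:
    """A binary lesion segmentation on the same grid as its Volume."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        data = (data != 0).astype(np.uint8)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"Mask data must be 3-D, got {data.ndim}-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "Mask":
        return Mask(data, self.spacing_mm, self.origin_mm)


@dataclasses.dataclass(frozen=True)
class DiscretizedVOI:
    """Integer gray-level grid: 0 outside the mask, levels 1..n_levels inside."""

    levels: np.ndarray
    n_levels: int
    bin_width: float
    intensity_min: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "levels", levels)
        inside = levels[levels > 0]
        if inside.size == 0:
            raise ValueError("DiscretizedVOI has no in-mask voxels")
        if int(inside.max()) != self.n_levels:
            raise ValueError("max level must equal n_levels")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_nifti_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data, spacing, origin)


def read_nifti_mask(path: str | Path) -> Mask:
    """Read a mask; any nonzero voxel becomes 1."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Mask(data, spacing, origin)


def write_nifti(obj: Volume | Mask, path: str | Path) -> None:
    dtype = np.uint8 if isinstance(obj, Mask) else np.float64
    img = nib.Nifti1Image(obj.data.astype(dtype), _affine(obj.spacing_mm, obj.origin_mm))
    img.header.set_zooms(obj.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing


def normalize_0_255(vol: Volume) -> Volume:
    """Linear rescale so min -> 0 and max -> 255.

    A constant volume has no range and maps to all zeros.
    """
    lo = float(vol.data.min())
    hi = float(vol.data.max())
    if hi == lo:
        return vol.with_data(np.zeros_like(vol.data))
    out = (vol.data - lo) * (255.0 / (hi - lo))
    return vol.with_data(np.clip(out, 0.0, 255.0))  # guard float round-off


def hist_equalize(vol: Volume, n_bins: int = 256) -> Volume:
    """Classical CDF-mapping histogram equalisation on the 0-255 range.

    The transform is a monotone non-decreasing function of intensity; the
    output stays within [0, 255].
    """
    out = exposure.equalize_hist(vol.data, nbins=n_bins) * 255.0
    return vol.with_data(np.clip(out, 0.0, 255.0))


def _target_dims(shape, spacing, target) -> tuple[int, int, int]:
    dims = tuple(
        int(round(d * s / t)) for d, s, t in zip(shape, spacing, target)
    )
    if any(d < 1 for d in dims):
        raise ValueError(
            f"resampling {shape} at {spacing} mm to {target} mm yields empty grid {dims}"
        )
    return dims


def resample_isotropic(
    vol: Volume | Mask,
    target_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    interpolation: str = "linear",
) -> Volume | Mask:
    """Resample to the target spacing; dims = round(dim * spacing / target).

    Images use linear interpolation, masks nearest-neighbour (stays binary).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if any(t <= 0 for t in target_mm):
        raise ValueError("target spacing must be positive")
    new_dims = _target_dims(vol.shape, vol.spacing_mm, target_mm)
    if new_dims == tuple(vol.shape):
        out = vol.data.copy()
    else:
        zoom = [n / o for n, o in zip(new_dims, vol.shape)]
        order = 1 if interpolation == "linear" else 0
        out = ndimage.zoom(
            vol.data.astype(np.float64), zoom, order=order, mode="nearest",
            grid_mode=True, prefilter=False,
        )
        assert out.shape == new_dims
    cls = Mask if isinstance(vol, Mask) else Volume
    return cls(out, tuple(float(t) for t in target_mm), vol.origin_mm)


def discretize(vol: Volume, mask: Mask, bin_width: float = 5.0) -> DiscretizedVOI:
    """Fixed-bin-width gray-level discretisation inside the mask.

    level(x) = floor((x - min_in_mask) / bin_width) + 1; level 0 outside.
    Invariant under adding a constant to the whole VOI.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    vals = vol.data[m]
    lo = float(vals.min())
    levels = np.zeros(vol.shape, dtype=np.int64)
    levels[m] = np.floor((vol.data[m] - lo) / bin_width).astype(np.int64) + 1
    return DiscretizedVOI(
        levels, int(levels.max()), float(bin_width), lo, vol.spacing_mm
    )


def preprocess_volume(
    vol: Volume,
    mask: Mask | None = None,
    target_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 256,
) -> tuple[Volume, Mask | None]:
    """Full chain: normalise to 0-255, equalise, resample isotropically.

    Returns the preprocessed volume and (if given) the mask resampled with
    nearest-neighbour onto the same grid.
    """
    out = hist_equalize(normalize_0_255(vol), n_bins=n_bins)
    out = resample_isotropic(out, target_mm, "linear")
    rmask = None
    if mask is not None:
        rmask = resample_isotropic(mask, target_mm, "nearest")
        if rmask.shape != out.shape:
            raise ValueError("mask and volume disagree after resampling")
    return out, rmask
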