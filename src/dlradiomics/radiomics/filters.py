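"""Derived-image filters for radiomics extraction.

The default image-type set is: original, the 8 one-level wavelet sub-bands,
Laplacian-of-Gaussian at sigma 2.0/3.0/4.0/5.0 mm, and the intensity
transforms square, squareroot, logarithm, exponential, gradient magnitude
and per-slice 2-D local binary patterns — 19 image types in total.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

from ..io_preproc import Volume

__all__ = ["FilterSpec", "apply_filter", "default_filters", "WAVELET_SUBBANDS"]

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_KINDS = (
    "original",
    "wavelet",
    "log",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
    "gradient",
    "lbp2d",
)


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """One filter family and its parameters."""

    kind: str
    sigma_mm: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)  # LoG only
    wavelet: str = "haar"  # wavelet only
    lbp_points: int = 8
    lbp_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "log" and any(s <= 0 for s in self.sigma_mm):
            raise ValueError("LoG sigmas must be positive")


def default_filters() -> tuple[FilterSpec, ...]:
    return (
        FilterSpec("original"),
        FilterSpec("wavelet"),
        FilterSpec("log"),
        FilterSpec("square"),
        FilterSpec("squareroot"),
        FilterSpec("logarithm"),
        FilterSpec("exponential"),
        FilterSpec("gradient"),
        FilterSpec("lbp2d"),
    )


def _wavelet_bands(data: np.ndarray, wavelet: str) -> list[tuple[str, np.ndarray]]:
    coeffs = pywt.dwtn(data, wavelet)
    out = []
    for band in WAVELET_SUBBANDS:
        key = "".join("a" if c == "L" else "d" for c in band)
        single = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(single, wavelet)
        rec = rec[tuple(slice(0, n) for n in data.shape)]
        out.append((f"wavelet-{band}", rec))
    return out


def _lbp2d(data: np.ndarray, points: int, radius: float) -> np.ndarray:
    out = np.empty_like(data)
    for k in range(data.shape[2]):
        out[:, :, k] = local_binary_pattern(data[:, :, k], points, radius, "uniform")
    return out


def apply_filter(vol: Volume, spec: FilterSpec) -> list[tuple[str, Volume]]:
    """Apply one filter family; returns labelled derived volumes."""
    data = vol.data
    spacing = np.asarray(vol.spacing_mm)
    if spec.kind == "original":
        return [("original", vol)]

    if spec.kind == "wavelet":
        return [(lab, vol.with_data(d)) for lab, d in _wavelet_bands(data, spec.wavelet)]

    if spec.kind == "log":
        out = []
        # centre first: the truncated kernel leaks a ~1e-4 fraction of any
        # constant offset, so remove the mean the filter should annihilate
        centered = data - data.mean()
        for sigma in spec.sigma_mm:
            if sigma < min(spacing) / 2.0:
                warnings.warn(
                    f"LoG sigma {sigma} mm is below half the voxel spacing",
                    stacklevel=2,
                )
            filtered = ndimage.gaussian_laplace(centered, sigma=sigma / spacing)
            out.append((f"log-sigma-{sigma:g}-mm", vol.with_data(filtered)))
        return out

    if spec.kind == "gradient":
        grads = np.gradient(data, *spacing)
        mag = np.sqrt(sum(g * g for g in grads))
        return [("gradient", vol.with_data(mag))]

    if spec.kind == "lbp2d":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # skimage warns on float input
            return [("lbp-2D", vol.with_data(_lbp2d(data, spec.lbp_points, spec.lbp_radius)))]

    absmax = float(np.abs(data).max())
    if spec.kind == "square":
        out = data**2 / absmax if absmax > 0 else np.zeros_like(data)
        return [("square", vol.with_data(out))]
    if spec.kind == "squareroot":
        out = np.sign(data) * np.sqrt(absmax * np.abs(data))
        return [("squareroot", vol.with_data(out))]
    if spec.kind == "logarithm":
        scale = absmax / np.log1p(absmax) if absmax > 0 else 1.0
        out = np.sign(data) * np.log1p(np.abs(data)) * scale
        return [("logarithm", vol.with_data(out))]
    if spec.kind == "exponential":
        c = np.log(absmax) / absmax if absmax > 1 else 1.0
        return [("exponential", vol.with_data(np.exp(c * data)))]
    raise AssertionError(spec.kind)
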