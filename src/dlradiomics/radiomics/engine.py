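"""Radiomics extraction engine: 1781 named features per phase per case.

Layout of the default configuration: 14 shape features on the original
mask, plus 93 intensity/texture features (18 first-order, 24 GLCM, 16
GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) on each of 19 image types (original +
18 derived), i.e. 14 + 19 x 93 = 1781.

Extraction crops to the mask bounding box (with padding to give the
convolutional filters context), which makes texture features invariant
under translation of the lesion within the grid.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ..io_preproc import Mask, Volume, discretize
from .filters import FilterSpec, apply_filter, default_filters, WAVELET_SUBBANDS
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .matrices import (
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
)
from .shape import SHAPE_NAMES, shape_features
from .texture_features import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["RadiomicsConfig", "feature_names", "extract_features", "extract_table"]


@dataclasses.dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction parameters; the defaults emit exactly 1781 features."""

    bin_width: float = 5.0
    glcm_distance: int = 1
    gldm_alpha: int = 0
    filters: tuple[FilterSpec, ...] = dataclasses.field(default_factory=default_filters)
    crop_padding: int = 10

    def image_labels(self) -> list[str]:
        labels = []
        for spec in self.filters:
            if spec.kind == "original":
                labels.append("original")
            elif spec.kind == "wavelet":
                labels.extend(f"wavelet-{b}" for b in WAVELET_SUBBANDS)
            elif spec.kind == "log":
                labels.extend(f"log-sigma-{s:g}-mm" for s in spec.sigma_mm)
            elif spec.kind == "lbp2d":
                labels.append("lbp-2D")
            else:
                labels.append(spec.kind)
        return labels

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "glcm_distance": self.glcm_distance,
            "gldm_alpha": self.gldm_alpha,
            "filters": [dataclasses.asdict(f) for f in self.filters],
            "crop_padding": self.crop_padding,
        }


def feature_names(config: RadiomicsConfig | None = None) -> list[str]:
    """Deterministic ordered feature-name list for a configuration."""
    config = config or RadiomicsConfig()
    names = [f"original_shape_{n}" for n in SHAPE_NAMES]
    families = (
        ("firstorder", FIRSTORDER_NAMES),
        ("glcm", GLCM_NAMES),
        ("glrlm", GLRLM_NAMES),
        ("glszm", GLSZM_NAMES),
        ("gldm", GLDM_NAMES),
        ("ngtdm", NGTDM_NAMES),
    )
    for label in config.image_labels():
        for fam, fam_names in families:
            names.extend(f"{label}_{fam}_{n}" for n in fam_names)
    return names


def _bbox_slices(mask: np.ndarray, padding: int, shape) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - padding, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + padding, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _texture_block(
    vol: Volume, mask_data: np.ndarray, label: str, config: RadiomicsConfig
) -> dict[str, float]:
    voxel_volume = float(np.prod(vol.spacing_mm))
    vals = vol.data[mask_data]
    out = {}
    fo = firstorder_features(vals, voxel_volume, config.bin_width)
    out.update({f"{label}_firstorder_{k}": v for k, v in fo.items()})

    voi = discretize(vol, Mask(mask_data, vol.spacing_mm), config.bin_width)
    # texture matrices only see in-mask voxels: crop to the tight mask bbox
    idx = np.argwhere(mask_data)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    tight = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    voi = dataclasses.replace(voi, levels=voi.levels[tight])
    n_vox = voi.n_voxels
    glcm = glcm_features(compute_glcm(voi, distance=config.glcm_distance))
    out.update({f"{label}_glcm_{k}": v for k, v in glcm.items()})
    glrlm = glrlm_features(compute_glrlm(voi), n_vox)
    out.update({f"{label}_glrlm_{k}": v for k, v in glrlm.items()})
    glszm = glszm_features(compute_glszm(voi), n_vox)
    out.update({f"{label}_glszm_{k}": v for k, v in glszm.items()})
    gldm = gldm_features(compute_gldm(voi, alpha=config.gldm_alpha))
    out.update({f"{label}_gldm_{k}": v for k, v in gldm.items()})
    ngtdm = ngtdm_features(compute_ngtdm(voi))
    out.update({f"{label}_ngtdm_{k}": v for k, v in ngtdm.items()})
    return out


def extract_features(
    vol: Volume, mask: Mask, config: RadiomicsConfig | None = None
) -> pd.Series:
    """Extract the full named feature vector for one volume/mask pair.

    The volume is expected to be preprocessed (normalised, equalised,
    isotropically resampled) with the mask on the same grid.
    """
    config = config or RadiomicsConfig()
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")

    sl = _bbox_slices(mask.data.astype(bool), config.crop_padding, vol.shape)
    cvol = Volume(vol.data[sl], vol.spacing_mm)
    cmask = mask.data[sl].astype(bool)

    out: dict[str, float] = {}
    shp = shape_features(cmask, vol.spacing_mm)
    out.update({f"original_shape_{k}": v for k, v in shp.items()})

    for spec in config.filters:
        for label, derived in apply_filter(cvol, spec):
            out.update(_texture_block(derived, cmask, label, config))

    series = pd.Series(out, dtype=np.float64)
    return series.reindex(feature_names(config))


def extract_table(
    cases: list,
    config: RadiomicsConfig | None = None,
    phases: tuple[str, ...] = ("AP", "PP"),
    preprocess: bool = True,
    mask_attr: str = "mask",
) -> pd.DataFrame:
    """Per-case feature table: one row per case, columns phase-prefixed.

    ``cases`` are CaseRecord-like objects with ap_volume/pp_volume and a
    mask attribute (``mask_attr`` selects reader variants for ICC runs).
    Cases whose mask empties after preprocessing are skipped with a log row.
    """
    from ..io_preproc import preprocess_volume  # local import, avoids cycle

    config = config or RadiomicsConfig()
    rows = {}
    for rec in cases:
        row = {}
        skipped = False
        for phase in phases:
            vol = rec.ap_volume if phase == "AP" else rec.pp_volume
            mask = getattr(rec, mask_attr)
            if mask is None:
                raise ValueError(f"case {rec.case_id} lacks mask {mask_attr!r}")
            if preprocess:
                vol, mask = preprocess_volume(vol, mask)
            if mask.n_voxels == 0:
                warnings.warn(
                    f"case {rec.case_id}: mask empty after resampling; case skipped",
                    stacklevel=2,
                )
                skipped = True
                break
            feats = extract_features(vol, mask, config)
            row.update({f"{phase}_{k}": v for k, v in feats.items()})
        if not skipped:
            rows[rec.case_id] = row
    if not rows:
        raise ValueError("no case produced features (all masks empty)")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "case_id"
    return table


def write_table(table: pd.DataFrame, path: str | Path, config: RadiomicsConfig) -> None:
    """CSV feature table with a JSON sidecar recording the configuration."""
    path = Path(path)
    table.to_csv(path)
    sidecar = path.with_suffix(".config.json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2))
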