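"""Max-ROI axial slice selection and 2-D tumor crops.

The axial slice with the largest tumor cross-section (ties: lowest index)
is selected together with its -2, -1, +1, +2 neighbours; each of the five
slices is cropped to the minimum bounding rectangle of the tumor in that
slice.  If an offset slice carries no tumor, the nearest tumor-bearing
slice in that direction is substituted (with a warning), so every case
always yields exactly five crops per phase.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .io_preproc import Mask, Volume

__all__ = ["SliceStack", "select_max_roi", "extract_stack", "export_stacks"]

OFFSETS = (-2, -1, 0, 1, 2)


@dataclasses.dataclass(frozen=True)
class SliceStack:
    """Five cropped 2-D tumor images for one case-phase."""

    case_id: str
    phase: str
    offsets: tuple[int, ...]
    slice_indices: tuple[int, ...]
    images: tuple[np.ndarray, ...]
    crop_boxes: tuple[tuple[int, int, int, int], ...]  # half-open (r0,r1,c0,c1)

    def __post_init__(self) -> None:
        if len(self.images) != 5:
            raise ValueError("a SliceStack holds exactly 5 images")


def select_max_roi(mask: Mask) -> int:
    """Index of the axial (third-axis) slice with the largest tumor area."""
    areas = mask.data.sum(axis=(0, 1))
    if areas.sum() == 0:
        raise ValueError("mask is empty")
    return int(np.argmax(areas))  # argmax returns the lowest index on ties


def _nearest_tumor_slice(areas: np.ndarray, target: int, center: int) -> int:
    """Nearest tumor-bearing slice moving from target back toward center."""
    step = 1 if target < center else -1
    k = target
    while k != center:
        if 0 <= k < areas.size and areas[k] > 0:
            return k
        k += step
    return center


def extract_stack(vol: Volume, mask: Mask, case_id: str = "case", phase: str = "AP") -> SliceStack:
    """Crop the Max-ROI slice and its four neighbours to the tumor bounding box."""
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    areas = mask.data.sum(axis=(0, 1))
    center = select_max_roi(mask)
    indices, images, boxes = [], [], []
    for off in OFFSETS:
        k = center + off
        if k < 0 or k >= areas.size or areas[k] == 0:
            sub = _nearest_tumor_slice(areas, max(0, min(k, areas.size - 1)), center)
            warnings.warn(
                f"{case_id}/{phase}: slice {k} (offset {off:+d}) has no tumor; "
                f"substituting slice {sub}",
                stacklevel=2,
            )
            k = sub
        sl_mask = mask.data[:, :, k]
        rows = np.flatnonzero(sl_mask.any(axis=1))
        cols = np.flatnonzero(sl_mask.any(axis=0))
        box = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
        crop = vol.data[box[0] : box[1], box[2] : box[3], k].copy()
        indices.append(k)
        images.append(crop)
        boxes.append(box)
    return SliceStack(
        case_id=case_id,
        phase=phase,
        offsets=OFFSETS,
        slice_indices=tuple(indices),
        images=tuple(images),
        crop_boxes=tuple(boxes),
    )


def export_stacks(stacks: list[SliceStack], out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs plus a manifest CSV; returns its path.

    Images are assumed to be on the preprocessed 0-255 scale.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in stacks:
        for off, k, img in zip(st.offsets, st.slice_indices, st.images):
            name = f"{st.case_id}_{st.phase}_{off:+d}.png"
            arr = np.clip(np.round(img), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / name)
            rows.append(
                {
                    "case_id": st.case_id,
                    "phase": st.phase,
                    "offset": off,
                    "slice_index": k,
                    "file": name,
                }
            )
    manifest = out / "slices_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
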