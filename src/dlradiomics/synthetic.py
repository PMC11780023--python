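"""Synthetic dual-phase liver-lesion phantom cohorts.

The phantom plants exactly the class-discriminating axes that distinguish
the three lesion types in dual-phase contrast-enhanced MRI:

* margin irregularity (smooth angular perturbation of a spherical lesion),
* presence of a hyperintense capsule rim,
* arterial-phase (AP) and portal-venous-phase (PP) enhancement offsets,
* internal texture (a correlated Gaussian random field with class-specific
  correlation length and amplitude),

on top of a homogeneous background organ with additive acquisition noise.
Two-reader delineation variability is emulated by smooth random
perturbations of the lesion mask, which feeds the ICC reproducibility
filter downstream.

Setting every per-class parameter equal across the three classes defines
the *null* phantom: labels carry no image information, and any downstream
classifier should perform at chance.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preproc import Mask, Volume, write_nifti

__all__ = [
    "PhantomSpec",
    "CaseRecord",
    "generate_case",
    "generate_cohort",
    "perturb_mask",
    "write_cohort",
]

CLASS_NAMES = ("HCC", "DPHCC", "ICC")  # labels 0, 1, 2

_BACKGROUND_MEAN = 100.0
_CAPSULE_OFFSET = 30.0


def _triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return tuple(float(v) for v in arr)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a phantom cohort.

    Per-class parameters are 3-vectors ordered (HCC, DPHCC, ICC).  The
    defaults are the documented strong-effect conditions: HCC-like lesions
    are capsulated, smooth-margined, arterially hyperenhancing with PP
    washout; DPHCC-like lesions lack a capsule and have irregular margins;
    ICC-like lesions show progressive PP enhancement and coarser internal
    texture.
    """

    n_cases: int = 30
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    balanced: bool = True
    grid_shape: tuple[int, int, int] = (40, 40, 32)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_mm: tuple[float, float] = (6.0, 10.0)
    margin_irregularity: tuple[float, float, float] = (0.3, 1.5, 0.8)
    capsule_prob: tuple[float, float, float] = (0.8, 0.1, 0.2)
    enhancement_ap: tuple[float, float, float] = (45.0, 30.0, 10.0)
    enhancement_pp: tuple[float, float, float] = (-10.0, 5.0, 20.0)
    texture_corr_len_mm: tuple[float, float, float] = (2.0, 3.5, 5.0)
    texture_sd: tuple[float, float, float] = (6.0, 10.0, 14.0)
    noise_sd: float = 5.0
    reader_jitter_mm: float = 1.0
    center_jitter_mm: float = 2.0
    external_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "class_probs",
            "margin_irregularity",
            "capsule_prob",
            "enhancement_ap",
            "enhancement_pp",
            "texture_corr_len_mm",
            "texture_sd",
        ):
            object.__setattr__(self, name, _triple(getattr(self, name)))
        object.__setattr__(self, "grid_shape", tuple(int(v) for v in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(v) for v in self.voxel_spacing_mm)
        )
        object.__setattr__(
            self, "lesion_radius_mm", tuple(float(v) for v in self.lesion_radius_mm)
        )
        p = np.asarray(self.class_probs)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("class_probs must be non-negative and sum to 1")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if self.noise_sd < 0 or self.reader_jitter_mm < 0:
            raise ValueError("noise_sd and reader_jitter_mm must be non-negative")
        if min(self.margin_irregularity) < 0:
            raise ValueError("margin_irregularity must be non-negative")
        self._check_fits()

    def _check_fits(self) -> None:
        half_extent = min(
            d * s / 2.0 for d, s in zip(self.grid_shape, self.voxel_spacing_mm)
        )
        needed = (
            self.lesion_radius_mm[1]
            + max(self.margin_irregularity)
            + max(self.voxel_spacing_mm)  # capsule shell + voxelisation
            + self.center_jitter_mm
        )
        if needed >= half_extent:
            raise ValueError(
                f"grid too small: lesion needs {needed:.1f} mm half-extent, "
                f"grid provides {half_extent:.1f} mm"
            )

    @classmethod
    def strong_effect(cls, n_cases: int = 300, seed: int = 0, **kw) -> "PhantomSpec":
        """The documented strong-effect conditions (the constructor defaults)."""
        return cls(n_cases=n_cases, seed=seed, **kw)

    @classmethod
    def null(cls, n_cases: int = 300, seed: int = 0, **kw) -> "PhantomSpec":
        """All per-class parameters equal: no class signal in the images."""
        return cls(
            n_cases=n_cases,
            seed=seed,
            margin_irregularity=(0.8, 0.8, 0.8),
            capsule_prob=(0.3, 0.3, 0.3),
            enhancement_ap=(30.0, 30.0, 30.0),
            enhancement_pp=(5.0, 5.0, 5.0),
            texture_corr_len_mm=(3.0, 3.0, 3.0),
            texture_sd=(10.0, 10.0, 10.0),
            **kw,
        )

    @property
    def is_null(self) -> bool:
        return all(
            len(set(getattr(self, f))) == 1
            for f in (
                "margin_irregularity",
                "capsule_prob",
                "enhancement_ap",
                "enhancement_pp",
                "texture_corr_len_mm",
                "texture_sd",
            )
        )


@dataclasses.dataclass
class CaseRecord:
    """One phantom case: dual-phase volumes sharing a single lesion mask."""

    case_id: str
    cohort_tag: str  # "train_pool" or "external"
    label: int  # 0=HCC, 1=DPHCC, 2=ICC
    ap_volume: Volume
    pp_volume: Volume
    mask: Mask
    reader2_mask: Mask | None = None
    reader1_repeat_mask: Mask | None = None


# ---------------------------------------------------------------------------
# mask perturbation (two-reader simulation)


def _smooth_field(shape, spacing, corr_len_mm, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with ~corr_len_mm correlation."""
    sigma = [max(corr_len_mm / s, 0.5) for s in spacing]
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = field.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (field - field.mean()) / sd


def _signed_distance(mask_data: np.ndarray, spacing) -> np.ndarray:
    """Positive outside the mask, negative inside (mm)."""
    inside = mask_data.astype(bool)
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    return d_out - d_in


def perturb_mask(mask: Mask, jitter_mm: float, rng: np.random.Generator) -> Mask:
    """Shift the mask boundary by a smooth random offset field.

    The offset is bounded by ``jitter_mm``; zero jitter returns an identical
    mask.  If a draw empties the mask the amplitude is halved and the draw
    retried, up to 5 attempts.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    if jitter_mm == 0:
        return mask.with_data(mask.data.copy())
    phi = _signed_distance(mask.data, mask.spacing_mm)
    amp = float(jitter_mm)
    for _ in range(5):
        g = _smooth_field(mask.shape, mask.spacing_mm, 4.0, rng)
        peak = np.abs(g).max()
        if peak > 0:
            g = g * (amp / peak)  # bounded by amp
        new = phi <= g
        if new.any():
            return mask.with_data(new)
        amp *= 0.5
    raise ValueError("mask perturbation emptied the mask after 5 damped attempts")


# ---------------------------------------------------------------------------
# single-case generation


def _lesion_mask(spec: PhantomSpec, label: int, center_mm, radius_mm, rng) -> np.ndarray:
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_mm
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    delta = [c - m for c, m in zip(coords, center_mm)]
    dist = np.sqrt(sum(d * d for d in delta))
    amp = spec.margin_irregularity[label]
    if amp == 0:
        return dist <= radius_mm
    # smooth angular perturbation: sample a smooth 3-D field on the sphere of
    # radius radius_mm around the centre, i.e. at point c + r*unit(x - c)
    field = _smooth_field(shape, spacing, 6.0, rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = [np.where(dist > 0, d / dist, 0.0) for d in delta]
    pts = [
        (m + radius_mm * u) / s for m, u, s in zip(center_mm, unit, spacing)
    ]
    f = ndimage.map_coordinates(field, np.stack(pts), order=1, mode="nearest")
    sd = f.std()
    if sd > 1e-12:
        f = (f - f.mean()) / sd
    return dist <= radius_mm + amp * f


def generate_case(
    label: int, spec: PhantomSpec, rng: np.random.Generator, case_id: str = "case",
    cohort_tag: str = "train_pool",
) -> CaseRecord:
    """Generate one dual-phase phantom case of the given class."""
    if label not in (0, 1, 2):
        raise ValueError(f"label must be 0, 1 or 2, got {label}")
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_mm
    extent = [n * s for n, s in zip(shape, spacing)]
    j = spec.center_jitter_mm
    center_mm = [e / 2.0 + rng.uniform(-j, j) for e in extent]
    radius_mm = rng.uniform(*spec.lesion_radius_mm)

    lesion = _lesion_mask(spec, label, center_mm, radius_mm, rng)
    if not lesion.any():
        raise ValueError("lesion mask empty; grid too small for the lesion radius")

    interior = ndimage.binary_erosion(lesion)
    shell = lesion & ~interior
    has_capsule = rng.uniform() < spec.capsule_prob[label]

    corr = spec.texture_corr_len_mm[label]
    tex_sd = spec.texture_sd[label]
    volumes = []
    for enh in (spec.enhancement_ap[label], spec.enhancement_pp[label]):
        img = np.full(shape, _BACKGROUND_MEAN, dtype=np.float64)
        if tex_sd > 0:
            img[lesion] += tex_sd * _smooth_field(shape, spacing, corr, rng)[lesion]
        img[lesion] += enh
        if has_capsule:
            img[shell] += _CAPSULE_OFFSET
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, shape)
        volumes.append(Volume(img, spacing))

    mask = Mask(lesion, spacing)
    jitter = spec.reader_jitter_mm
    reader2 = perturb_mask(mask, jitter, rng)
    # intra-reader re-delineation is typically tighter than inter-reader
    repeat = perturb_mask(mask, 0.5 * jitter, rng)
    return CaseRecord(
        case_id=case_id,
        cohort_tag=cohort_tag,
        label=label,
        ap_volume=volumes[0],
        pp_volume=volumes[1],
        mask=mask,
        reader2_mask=reader2,
        reader1_repeat_mask=repeat,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _apportion_balanced(n: int, probs) -> np.ndarray:
    quotas = np.asarray(probs) * n
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for idx in np.argsort(-rem)[: n - counts.sum()]:
        counts[idx] += 1
    labels = np.repeat(np.arange(3), counts)
    return labels


def generate_cohort(spec: PhantomSpec) -> list[CaseRecord]:
    """Generate the full phantom cohort; a pure function of (spec, seed)."""
    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 915]))
    if spec.balanced:
        labels = _apportion_balanced(spec.n_cases, spec.class_probs)
    else:
        labels = master.choice(3, size=spec.n_cases, p=spec.class_probs)
    labels = np.array(labels)
    master.shuffle(labels)

    n_external = int(round(spec.external_frac * spec.n_cases))
    tags = ["train_pool"] * (spec.n_cases - n_external) + ["external"] * n_external

    records = []
    for i, (label, tag) in enumerate(zip(labels, tags)):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7, i]))
        records.append(
            generate_case(int(label), spec, rng, case_id=f"case_{i:04d}", cohort_tag=tag)
        )
    return records


def write_cohort(records: list[CaseRecord], out_dir: str | Path) -> Path:
    """Write per-case NIfTI volumes/masks and a manifest CSV; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = {
            "ap_path": out / f"{rec.case_id}_AP.nii.gz",
            "pp_path": out / f"{rec.case_id}_PP.nii.gz",
            "mask_path": out / f"{rec.case_id}_mask.nii.gz",
        }
        write_nifti(rec.ap_volume, paths["ap_path"])
        write_nifti(rec.pp_volume, paths["pp_path"])
        write_nifti(rec.mask, paths["mask_path"])
        row = {"case_id": rec.case_id, "cohort_tag": rec.cohort_tag, "label": rec.label}
        row.update({k: str(v) for k, v in paths.items()})
        for attr, key in (
            ("reader2_mask", "reader2_mask_path"),
            ("reader1_repeat_mask", "reader1_repeat_mask_path"),
        ):
            m = getattr(rec, attr)
            if m is not None:
                p = out / f"{rec.case_id}_{key.replace('_path', '')}.nii.gz"
                write_nifti(m, p)
                row[key] = str(p)
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
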