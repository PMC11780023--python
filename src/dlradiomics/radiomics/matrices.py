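"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All builders operate on an integer level grid: 0 marks out-of-mask voxels,
in-mask voxels carry levels 1..n_levels.  Directional matrices (GLCM,
GLRLM) are computed per 3-D direction over the 13 unique offsets; feature
values are averaged over directions downstream.  Zone, dependence and
gray-tone-difference matrices use full 26-connectivity.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools

import numpy as np
from scipy import ndimage

__all__ = [
    "TextureMatrix",
    "UNIQUE_DIRECTIONS_3D",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "compute_gldm",
    "compute_ngtdm",
]

# the 13 unique 3-D directions (first non-zero component positive)
UNIQUE_DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)
assert len(UNIQUE_DIRECTIONS_3D) == 13

_ALL_NEIGHBORS_3D = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)  # 26


@dataclasses.dataclass(frozen=True)
class TextureMatrix:
    """One texture matrix plus its per-direction stack where applicable.

    ``values`` is the direction-averaged (GLCM/GLRLM) or single (GLSZM/
    GLDM/NGTDM) matrix.  ``per_direction`` holds the stack the feature
    formulas are averaged over; it is None for non-directional kinds.
    """

    kind: str
    values: np.ndarray
    per_direction: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)


def _levels_of(voi) -> tuple[np.ndarray, int]:
    """Accept a DiscretizedVOI or a raw integer grid."""
    if hasattr(voi, "levels"):
        lv = np.asarray(voi.levels, dtype=np.int64)
        ng = int(voi.n_levels)
    else:
        lv = np.asarray(voi, dtype=np.int64)
        ng = int(lv.max())
    if ng < 1 or not (lv > 0).any():
        raise ValueError("empty mask: no in-mask voxels")
    return lv, ng


def _shift_slices(shape, off):
    """Slices (src, dst) so that src aligns with dst displaced by ``off``."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_one(lv, ng, off, symmetric):
    src, dst = _shift_slices(lv.shape, off)
    a = lv[src]
    b = lv[dst]
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return np.zeros((ng, ng))
    pairs = (a[ok] - 1) * ng + (b[ok] - 1)
    mat = np.bincount(pairs, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    if symmetric:
        mat = mat + mat.T
    return mat


def compute_glcm(
    voi,
    distance: int = 1,
    symmetric: bool = True,
    directions=None,
) -> TextureMatrix:
    """Co-occurrence of level pairs at the given distance, per direction.

    Each per-direction matrix is symmetrised and normalised to sum 1
    (directions with no valid pair yield an all-zero matrix and are
    excluded from the stack).
    """
    lv, ng = _levels_of(voi)
    dirs = UNIQUE_DIRECTIONS_3D if directions is None else tuple(map(tuple, directions))
    stack = []
    for d in dirs:
        off = tuple(int(c) * int(distance) for c in d)
        mat = _glcm_one(lv, ng, off, symmetric)
        tot = mat.sum()
        # a direction with no valid pair keeps an all-zero slot so the
        # stack stays aligned with ``dirs``
        stack.append(mat / tot if tot > 0 else mat)
    stack = np.stack(stack)
    return TextureMatrix(
        "glcm",
        stack.mean(axis=0),
        per_direction=stack,
        meta={"distance": distance, "symmetric": symmetric, "directions": dirs},
    )


# ---------------------------------------------------------------------------
# GLRLM


def _glrlm_one(lv, ng, d):
    """Run-length counts R[level-1, length-1] along direction d."""
    shape = lv.shape
    src, dst = _shift_slices(shape, d)
    # a voxel starts a run if in-mask and predecessor (pos - d) differs
    prev = np.zeros(shape, dtype=np.int64)
    prev[dst] = lv[src]
    starts = (lv > 0) & (lv != prev)
    coords = np.argwhere(starts)
    if coords.size == 0:
        return np.zeros((ng, 1))
    levels = lv[starts]
    # order of argwhere and levels agree (C order)
    lengths = np.ones(len(coords), dtype=np.int64)
    active = np.arange(len(coords))
    cur = coords.copy()
    dd = np.asarray(d)
    dims = np.asarray(shape)
    while active.size:
        nxt = cur[active] + dd
        inb = np.all((nxt >= 0) & (nxt < dims), axis=1)
        keep = active[inb]
        nxt = nxt[inb]
        same = lv[tuple(nxt.T)] == levels[keep]
        keep = keep[same]
        nxt = nxt[same]
        lengths[keep] += 1
        cur[keep] = nxt
        active = keep
    max_len = int(lengths.max())
    flat = (levels - 1) * max_len + (lengths - 1)
    return (
        np.bincount(flat, minlength=ng * max_len)
        .reshape(ng, max_len)
        .astype(np.float64)
    )


@functools.lru_cache(maxsize=16)
def _run_plan(shape: tuple[int, int, int]):
    """Per-direction (sort order, new-line flags) for run scanning.

    Sorting all grid positions by (line identity, position along the line)
    makes every lattice line contiguous, so maximal runs reduce to change
    detection on the sorted level sequence.  Depends only on the grid
    shape, hence cached.
    """
    idx = np.indices(shape).reshape(3, -1)
    plans = []
    for d in UNIQUE_DIRECTIONS_3D:
        dd = np.asarray(d)[:, None]
        t = (idx * dd).sum(axis=0)
        # line identity invariant along the direction: s*pos - t*d
        s = int((dd * dd).sum())
        line = idx * s - t[None, :] * dd
        line = line - line.min(axis=1, keepdims=True)
        dims = line.max(axis=1) + 1
        key = (line[0] * dims[1] + line[1]) * dims[2] + line[2]
        order = np.lexsort((t, key))
        key_s = key[order]
        newline = np.empty(key_s.size, dtype=bool)
        newline[0] = True
        newline[1:] = key_s[1:] != key_s[:-1]
        plans.append((order, newline))
    return plans


def _glrlm_one_planned(lv, ng, order, newline):
    v = lv.ravel()[order]
    start = newline.copy()
    start[1:] |= v[1:] != v[:-1]
    starts_idx = np.flatnonzero(start)
    lengths = np.diff(np.append(starts_idx, v.size))
    levels = v[starts_idx]
    keep = levels > 0
    levels = levels[keep]
    lengths = lengths[keep]
    if levels.size == 0:
        return np.zeros((ng, 1))
    max_len = int(lengths.max())
    flat = (levels - 1) * max_len + (lengths - 1)
    return (
        np.bincount(flat, minlength=ng * max_len)
        .reshape(ng, max_len)
        .astype(np.float64)
    )


def compute_glrlm(voi, directions=None) -> TextureMatrix:
    """Maximal-run counts R(i, j) per direction; runs partition the mask."""
    lv, ng = _levels_of(voi)
    dirs = UNIQUE_DIRECTIONS_3D if directions is None else tuple(map(tuple, directions))
    if directions is None:
        plans = _run_plan(lv.shape)
        mats = [_glrlm_one_planned(lv, ng, o, nl) for o, nl in plans]
    else:
        mats = [_glrlm_one(lv, ng, d) for d in dirs]
    max_len = max(m.shape[1] for m in mats)
    stack = np.stack(
        [np.pad(m, ((0, 0), (0, max_len - m.shape[1]))) for m in mats]
    )
    return TextureMatrix(
        "glrlm", stack.mean(axis=0), per_direction=stack, meta={"directions": dirs}
    )


# ---------------------------------------------------------------------------
# GLSZM


def compute_glszm(voi) -> TextureMatrix:
    """Counts of 26-connected equal-level zones by level and size."""
    lv, ng = _levels_of(voi)
    structure = np.ones((3, 3, 3), dtype=int)
    zones = []  # (level, size)
    for level in range(1, ng + 1):
        sel = lv == level
        if not sel.any():
            continue
        lab, nlab = ndimage.label(sel, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    return TextureMatrix("glszm", mat)


# ---------------------------------------------------------------------------
# GLDM


def _neighbor_pair_counts(lv, alpha):
    """Per-voxel count of in-mask 26-neighbours with |level diff| <= alpha."""
    dep = np.zeros(lv.shape, dtype=np.int64)
    inmask = lv > 0
    for d in UNIQUE_DIRECTIONS_3D:
        src, dst = _shift_slices(lv.shape, d)
        a = lv[src]
        b = lv[dst]
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        # symmetric: the pair contributes to both endpoints
        dep[src] += ok
        dep[dst] += ok
    dep[~inmask] = 0
    return dep


def compute_gldm(voi, alpha: int = 0) -> TextureMatrix:
    """Dependence counts D(i, d): voxels of level i with d dependent neighbours.

    The dependence of a voxel is the number of in-mask 26-neighbours whose
    level differs by at most ``alpha``; columns are indexed from d = 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    lv, ng = _levels_of(voi)
    dep = _neighbor_pair_counts(lv, alpha)
    inm = lv > 0
    levels = lv[inm] - 1
    deps = dep[inm]
    max_dep = int(deps.max())
    flat = levels * (max_dep + 1) + deps
    mat = (
        np.bincount(flat, minlength=ng * (max_dep + 1))
        .reshape(ng, max_dep + 1)
        .astype(np.float64)
    )
    return TextureMatrix("gldm", mat, meta={"alpha": alpha})


# ---------------------------------------------------------------------------
# NGTDM


def compute_ngtdm(voi) -> TextureMatrix:
    """Per-level (n_i, p_i, s_i): occurrence and summed absolute difference
    from the mean level of in-mask 26-neighbours.

    Voxels without any in-mask neighbour are excluded.  ``values`` has one
    row per level: columns (n_i, p_i, s_i).
    """
    lv, ng = _levels_of(voi)
    nsum = np.zeros(lv.shape)
    ncnt = np.zeros(lv.shape, dtype=np.int64)
    inm = lv > 0
    for d in UNIQUE_DIRECTIONS_3D:
        src, dst = _shift_slices(lv.shape, d)
        a = lv[src]
        b = lv[dst]
        ok = (a > 0) & (b > 0)
        nsum[src] += np.where(ok, b, 0)
        ncnt[src] += ok
        nsum[dst] += np.where(ok, a, 0)
        ncnt[dst] += ok
    valid = inm & (ncnt > 0)
    n_valid = int(valid.sum())
    mat = np.zeros((ng, 3))
    if n_valid:
        mean_ngb = nsum[valid] / ncnt[valid]
        diff = np.abs(lv[valid] - mean_ngb)
        levels = lv[valid] - 1
        n_i = np.bincount(levels, minlength=ng).astype(np.float64)
        s_i = np.bincount(levels, weights=diff, minlength=ng)
        mat[:, 0] = n_i
        mat[:, 1] = n_i / n_valid
        mat[:, 2] = s_i
    return TextureMatrix("ngtdm", mat, meta={"n_valid": n_valid})
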