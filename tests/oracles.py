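"""Independent brute-force oracles for the texture-matrix builders.

These enumerate pairs, runs, zones and neighbourhoods with plain Python
loops; they deliberately share no code with the package implementation.
"""

import itertools

import numpy as np

ALL_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


def _inb(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def brute_glcm(lv, ng, offset, symmetric=True):
    mat = np.zeros((ng, ng))
    for pos in np.ndindex(lv.shape):
        a = lv[pos]
        if a == 0:
            continue
        q = tuple(p + o for p, o in zip(pos, offset))
        if _inb(q, lv.shape) and lv[q] > 0:
            mat[a - 1, lv[q] - 1] += 1
    if symmetric:
        mat = mat + mat.T
    return mat


def brute_glrlm(lv, ng, direction):
    """Counts of maximal runs per (level, length) along one direction."""
    runs = {}
    shape = lv.shape
    for pos in np.ndindex(shape):
        a = lv[pos]
        if a == 0:
            continue
        prev = tuple(p - d for p, d in zip(pos, direction))
        if _inb(prev, shape) and lv[prev] == a:
            continue  # not a run start
        length = 1
        cur = pos
        while True:
            nxt = tuple(p + d for p, d in zip(cur, direction))
            if _inb(nxt, shape) and lv[nxt] == a:
                length += 1
                cur = nxt
            else:
                break
        runs[(a, length)] = runs.get((a, length), 0) + 1
    max_len = max((ln for _, ln in runs), default=1)
    mat = np.zeros((ng, max_len))
    for (a, ln), c in runs.items():
        mat[a - 1, ln - 1] += c
    return mat


def brute_glszm(lv, ng):
    """Zone sizes by flood fill over 26-connected equal-level components."""
    seen = np.zeros(lv.shape, dtype=bool)
    zones = []
    for pos in np.ndindex(lv.shape):
        if lv[pos] == 0 or seen[pos]:
            continue
        level = lv[pos]
        stack = [pos]
        seen[pos] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in ALL_26:
                q = tuple(p + o for p, o in zip(cur, d))
                if _inb(q, lv.shape) and not seen[q] and lv[q] == level:
                    seen[q] = True
                    stack.append(q)
        zones.append((level, size))
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    return mat


def brute_gldm(lv, ng, alpha=0):
    counts = {}
    for pos in np.ndindex(lv.shape):
        a = lv[pos]
        if a == 0:
            continue
        dep = 0
        for d in ALL_26:
            q = tuple(p + o for p, o in zip(pos, d))
            if _inb(q, lv.shape) and lv[q] > 0 and abs(int(lv[q]) - int(a)) <= alpha:
                dep += 1
        counts[(a, dep)] = counts.get((a, dep), 0) + 1
    max_dep = max(d for _, d in counts)
    mat = np.zeros((ng, max_dep + 1))
    for (a, d), c in counts.items():
        mat[a - 1, d] += c
    return mat


def brute_ngtdm(lv, ng):
    """Rows (n_i, p_i, s_i); voxels without in-mask neighbours excluded."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    total = 0
    for pos in np.ndindex(lv.shape):
        a = lv[pos]
        if a == 0:
            continue
        ngb = [
            lv[tuple(p + o for p, o in zip(pos, d))]
            for d in ALL_26
            if _inb(tuple(p + o for p, o in zip(pos, d)), lv.shape)
            and lv[tuple(p + o for p, o in zip(pos, d))] > 0
        ]
        if not ngb:
            continue
        total += 1
        n[a - 1] += 1
        s[a - 1] += abs(a - np.mean(ngb))
    mat = np.zeros((ng, 3))
    mat[:, 0] = n
    if total:
        mat[:, 1] = n / total
    mat[:, 2] = s
    return mat
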