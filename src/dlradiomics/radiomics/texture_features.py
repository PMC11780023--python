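"""Feature formulas on the five texture-matrix families.

Counts per family: GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5 (75
texture features per image type).  Directional families (GLCM, GLRLM)
compute features per direction and average them.  Formulas that divide by
zero on degenerate (e.g. single-level) VOIs return 0.
"""

from __future__ import annotations

import functools

import numpy as np

from .matrices import TextureMatrix

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_EPS = np.finfo(np.float64).eps


GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


@functools.lru_cache(maxsize=64)
def _sum_diff_aggregators(ng: int) -> tuple[np.ndarray, np.ndarray]:
    """One-hot matrices mapping a flattened GLCM onto its i+j and |i-j|
    marginals (cached per level count)."""
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    agg_sum = np.zeros((ng * ng, 2 * ng - 1))
    agg_sum[np.arange(ng * ng), (ii + jj).ravel() - 2] = 1.0
    agg_diff = np.zeros((ng * ng, ng))
    agg_diff[np.arange(ng * ng), np.abs(ii - jj).ravel()] = 1.0
    return agg_sum, agg_diff


def _plogp(p: np.ndarray, axis) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -term.sum(axis=axis)


def _glcm_features_stack(stack: np.ndarray) -> dict[str, float]:
    """All 24 GLCM features, vectorised over the direction axis and averaged."""
    p = np.asarray(stack, dtype=np.float64)  # (D, Ng, Ng), each sums to 1
    nd, ng, _ = p.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii = i[:, None]
    jj = i[None, :]

    px = p.sum(axis=2)  # (D, Ng)
    py = p.sum(axis=1)
    mux = (px * i).sum(axis=1)  # (D,)
    muy = (py * i).sum(axis=1)
    sigx = np.sqrt(((i - mux[:, None]) ** 2 * px).sum(axis=1))
    sigy = np.sqrt(((i - muy[:, None]) ** 2 * py).sum(axis=1))

    flat = p.reshape(nd, -1)
    agg_sum, agg_diff = _sum_diff_aggregators(ng)
    p_sum = flat @ agg_sum  # (D, 2Ng-1) marginal over i+j
    p_diff = flat @ agg_diff  # (D, Ng) marginal over |i-j|
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(0, ng, dtype=np.float64)

    autocorr = ((ii * jj) * p).sum(axis=(1, 2))
    contrast = (((ii - jj) ** 2) * p).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(
            (sigx > 0) & (sigy > 0),
            (autocorr - mux * muy) / np.where(sigx * sigy > 0, sigx * sigy, 1.0),
            0.0,
        )

    da = (k_diff * p_diff).sum(axis=1)
    dvar = (((k_diff[None, :] - da[:, None]) ** 2) * p_diff).sum(axis=1)
    dent = _plogp(p_diff, axis=1)

    hxy = _plogp(flat, axis=1)
    hx = _plogp(px, axis=1)
    hy = _plogp(py, axis=1)
    pxy = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = -(np.where(p > 0, p, 0.0) * log_pxy).sum(axis=(1, 2))
    hxy2 = -(pxy * log_pxy).sum(axis=(1, 2))
    denom = np.maximum(hx, hy)
    imc1 = np.where(denom > 0, (hxy - hxy1) / np.where(denom > 0, denom, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    dm = np.abs(ii - jj)
    off = dm > 0
    if off.any():
        inv_var = (p[:, off] / (dm[off] ** 2)).sum(axis=1)
    else:
        inv_var = np.zeros(nd)

    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(px[:, :, None] > 0, p / np.where(px[:, :, None] > 0, px[:, :, None], 1.0), 0.0)
            b = np.where(py[:, :, None] > 0, p / np.where(py[:, :, None] > 0, py[:, :, None], 1.0), 0.0)
        # Q_d = A_d @ B_d^T with B[j,k] = p(j,k)/py(k)
        q = a @ np.transpose(b, (0, 2, 1))
        eig = np.sort(np.real(np.linalg.eigvals(q)), axis=1)
        mcc = np.sqrt(np.clip(eig[:, -2], 0.0, None))
    else:
        mcc = np.ones(nd)

    cen = ii + jj - (mux + muy)[:, None, None]
    feats = {
        "Autocorrelation": autocorr,
        "ClusterProminence": (cen**4 * p).sum(axis=(1, 2)),
        "ClusterShade": (cen**3 * p).sum(axis=(1, 2)),
        "ClusterTendency": (cen**2 * p).sum(axis=(1, 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": dent,
        "DifferenceVariance": dvar,
        "Id": (p / (1.0 + dm)).sum(axis=(1, 2)),
        "Idm": (p / (1.0 + dm**2)).sum(axis=(1, 2)),
        "Idmn": (p / (1.0 + dm**2 / ng**2)).sum(axis=(1, 2)),
        "Idn": (p / (1.0 + dm / ng)).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mux,
        "JointEnergy": (p**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": p.max(axis=(1, 2)),
        "SumAverage": (k_sum * p_sum).sum(axis=1),
        "SumEntropy": _plogp(p_sum, axis=1),
        "SumSquares": (((ii - mux[:, None, None]) ** 2) * p).sum(axis=(1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in feats.items()}


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    stack = tm.per_direction if tm.per_direction is not None else tm.values[None]
    nonempty = stack[stack.sum(axis=(1, 2)) > 0]
    if len(nonempty) == 0:  # no co-occurring pair in any direction
        return {k: 0.0 for k in GLCM_NAMES}
    return _glcm_features_stack(nonempty)


# ---------------------------------------------------------------------------
# run-length / size-zone / dependence share the same algebra on a count
# matrix M(i, j) with gray level i and a size-like index j


def _ij_stats(m: np.ndarray, j_values: np.ndarray, reduce: bool = True):
    """Shared emphasis/non-uniformity algebra on count matrices M(i, j).

    ``m`` may be a single matrix (Ng, Nj) or a direction stack (D, Ng, Nj);
    results are per-direction arrays averaged at the end when ``reduce``.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim == 2:
        m = m[None]
    ns = m.sum(axis=(1, 2))  # (D,)
    if (ns == 0).all():
        return {}
    safe_ns = np.where(ns > 0, ns, 1.0)
    i = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    j = j_values.astype(np.float64)
    ii = i[None, :, None]
    jj = j[None, None, :]
    p = m / safe_ns[:, None, None]
    mu_i = (ii * p).sum(axis=(1, 2))
    mu_j = (jj * p).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        pl = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    out = {
        "small": (m / jj**2).sum(axis=(1, 2)) / safe_ns,
        "large": (m * jj**2).sum(axis=(1, 2)) / safe_ns,
        "low": (m / ii**2).sum(axis=(1, 2)) / safe_ns,
        "high": (m * ii**2).sum(axis=(1, 2)) / safe_ns,
        "small_low": (m / (ii**2 * jj**2)).sum(axis=(1, 2)) / safe_ns,
        "small_high": (m * ii**2 / jj**2).sum(axis=(1, 2)) / safe_ns,
        "large_low": (m * jj**2 / ii**2).sum(axis=(1, 2)) / safe_ns,
        "large_high": (m * ii**2 * jj**2).sum(axis=(1, 2)) / safe_ns,
        "gln": (m.sum(axis=2) ** 2).sum(axis=1) / safe_ns,
        "glnn": (m.sum(axis=2) ** 2).sum(axis=1) / safe_ns**2,
        "jn": (m.sum(axis=1) ** 2).sum(axis=1) / safe_ns,
        "jnn": (m.sum(axis=1) ** 2).sum(axis=1) / safe_ns**2,
        "gl_var": ((ii - mu_i[:, None, None]) ** 2 * p).sum(axis=(1, 2)),
        "j_var": ((jj - mu_j[:, None, None]) ** 2 * p).sum(axis=(1, 2)),
        "entropy": -pl.sum(axis=(1, 2)),
        "n_total": ns,
    }
    if reduce:
        return {k: float(np.mean(v)) for k, v in out.items()}
    return out


GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def glrlm_features(tm: TextureMatrix, n_voxels: int) -> dict[str, float]:
    stack = tm.per_direction if tm.per_direction is not None else tm.values[None]
    s = _ij_stats(stack, np.arange(1, stack.shape[-1] + 1))
    if not s:
        return {k: 0.0 for k in GLRLM_NAMES}
    return {
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "GrayLevelVariance": s["gl_var"],
        "HighGrayLevelRunEmphasis": s["high"],
        "LongRunEmphasis": s["large"],
        "LongRunHighGrayLevelEmphasis": s["large_high"],
        "LongRunLowGrayLevelEmphasis": s["large_low"],
        "LowGrayLevelRunEmphasis": s["low"],
        "RunEntropy": s["entropy"],
        "RunLengthNonUniformity": s["jn"],
        "RunLengthNonUniformityNormalized": s["jnn"],
        "RunPercentage": s["n_total"] / n_voxels,
        "RunVariance": s["j_var"],
        "ShortRunEmphasis": s["small"],
        "ShortRunHighGrayLevelEmphasis": s["small_high"],
        "ShortRunLowGrayLevelEmphasis": s["small_low"],
    }


GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)


def glszm_features(tm: TextureMatrix, n_voxels: int) -> dict[str, float]:
    m = tm.values
    s = _ij_stats(m, np.arange(1, m.shape[1] + 1))
    if not s:
        return {k: 0.0 for k in GLSZM_NAMES}
    return {
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "GrayLevelVariance": s["gl_var"],
        "HighGrayLevelZoneEmphasis": s["high"],
        "LargeAreaEmphasis": s["large"],
        "LargeAreaHighGrayLevelEmphasis": s["large_high"],
        "LargeAreaLowGrayLevelEmphasis": s["large_low"],
        "LowGrayLevelZoneEmphasis": s["low"],
        "SizeZoneNonUniformity": s["jn"],
        "SizeZoneNonUniformityNormalized": s["jnn"],
        "SmallAreaEmphasis": s["small"],
        "SmallAreaHighGrayLevelEmphasis": s["small_high"],
        "SmallAreaLowGrayLevelEmphasis": s["small_low"],
        "ZoneEntropy": s["entropy"],
        "ZonePercentage": s["n_total"] / n_voxels,
        "ZoneVariance": s["j_var"],
    }


GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def gldm_features(tm: TextureMatrix) -> dict[str, float]:
    # columns are dependence counts d = 0..dmax; the formulas use the
    # dependence size j = d + 1 so small-dependence emphases stay finite
    m = tm.values
    s = _ij_stats(m, np.arange(1, m.shape[1] + 1))
    if not s:
        return {k: 0.0 for k in GLDM_NAMES}
    return {
        "DependenceEntropy": s["entropy"],
        "DependenceNonUniformity": s["jn"],
        "DependenceNonUniformityNormalized": s["jnn"],
        "DependenceVariance": s["j_var"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelVariance": s["gl_var"],
        "HighGrayLevelEmphasis": s["high"],
        "LargeDependenceEmphasis": s["large"],
        "LargeDependenceHighGrayLevelEmphasis": s["large_high"],
        "LargeDependenceLowGrayLevelEmphasis": s["large_low"],
        "LowGrayLevelEmphasis": s["low"],
        "SmallDependenceEmphasis": s["small"],
        "SmallDependenceHighGrayLevelEmphasis": s["small_high"],
        "SmallDependenceLowGrayLevelEmphasis": s["small_low"],
    }


NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    n_i = tm.values[:, 0]
    p_i = tm.values[:, 1]
    s_i = tm.values[:, 2]
    nvc = tm.meta.get("n_valid", int(n_i.sum()))
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p_i) + 1, dtype=np.float64)

    if nvc == 0 or ngp == 0:
        return {k: 0.0 for k in NGTDM_NAMES}

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        ip, jp = np.meshgrid(i[present], i[present], indexing="ij")
        pp_i, pp_j = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        contrast = float(
            (pp_i * pp_j * (ip - jp) ** 2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvc)
        )
        denom_busy = float(np.abs(ip * pp_i - jp * pp_j).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        ss_i, ss_j = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(
            (
                np.abs(ip - jp)
                * (pp_i * ss_i + pp_j * ss_j)
                / (pp_i + pp_j)
            ).sum()
            / nvc
        )
        s_total = float(s_i.sum())
        strength = (
            float(((pp_i + pp_j) * (ip - jp) ** 2).sum()) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
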