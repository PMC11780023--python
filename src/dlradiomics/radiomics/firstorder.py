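"""First-order intensity statistics (18 features, IBSI-style definitions).

Entropy and Uniformity are computed on the fixed-bin-width discretised
histogram; all other statistics use the continuous in-mask intensities.
Moments are population moments (ddof = 0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray, voxel_volume_mm3: float, bin_width: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty value set")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    # discretised histogram for Entropy / Uniformity
    levels = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(levels).astype(np.float64)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p * p).sum())

    if sd > 1e-12 * max(1.0, abs(mean)):  # guard float-noise "variance"
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)  # not excess
    else:
        skew = 0.0
        kurt = 0.0

    energy = float((x * x).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x * x).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
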