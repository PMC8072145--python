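"""First-order (intensity histogram) features on raw in-ROI intensities."""

from __future__ import annotations

import numpy as np

from .base import ROIMask, VoxelGrid, discretize

__all__ = ["firstorder_features", "FIRSTORDER_FEATURES"]

FIRSTORDER_FEATURES = [
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
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]


def firstorder_features(
    grid: VoxelGrid, roi: ROIMask, bin_width: float = 25.0
) -> dict[str, float]:
    """The 19 first-order statistics.

    All moments use the raw (undiscretized) intensities; only Entropy and
    Uniformity use the fixed-bin-width histogram. Kurtosis is the
    non-excess (Pearson) form; Skewness/Kurtosis of a constant ROI are
    undefined and returned as NaN.
    """
    x = grid.intensities[roi.mask].astype(float)
    n = x.size
    voxel_volume = float(np.prod(grid.spacing))
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    q = discretize(grid, roi, bin_width)
    p_hist = np.bincount(q.roi_levels())[1:].astype(float)
    p_hist = p_hist[p_hist > 0] / n

    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = np.nan
        kurt = np.nan

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": float(-(p_hist * np.log2(p_hist)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else np.nan
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p_hist**2).sum()),
    }
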