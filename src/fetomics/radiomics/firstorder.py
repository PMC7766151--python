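"""The 18 first-order intensity statistics.

Energy is computed without an intensity shift (an SUV of zero is physically
meaningful), Entropy and Uniformity are computed on the discretized
histogram, and percentiles use numpy's linear interpolation.  Skewness and
kurtosis use the population (biased) moment estimators; kurtosis is not
excess-corrected.  On a constant VOI the variance-normalised moments are
undefined and reported as 0.
"""

from __future__ import annotations

import numpy as np

from .binning import BinningSpec, discretize

__all__ = ["first_order_features", "FIRST_ORDER_NAMES"]

FIRST_ORDER_NAMES = (
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


def first_order_features(
    values: np.ndarray,
    mask: np.ndarray,
    binning: BinningSpec | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    v = np.asarray(values, dtype=float)[mask]
    n = v.size
    voxel_volume = float(np.prod(spacing))

    levels, _ = discretize(values, mask, binning)
    counts = np.bincount(levels[mask])
    p = counts[counts > 0] / n

    mean = float(v.mean())
    var = float(v.var())  # population variance
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    centered = v - mean
    if var > 0:
        m2 = var
        skew = float((centered**3).mean() / m2**1.5)
        kurt = float((centered**4).mean() / m2**2)
    else:
        skew = 0.0
        kurt = 0.0

    energy = float((v**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(np.median(v)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
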