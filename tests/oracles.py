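"""Independent brute-force oracles for the texture matrices and features.

Everything here is written as naive enumeration (explicit loops, flood fill,
line group-by) so it shares no code path with the package's vectorised
implementations; features are computed from the brute matrices with plain
Python sums following the same documented conventions.
"""

from __future__ import annotations

import math
from itertools import groupby, product

import numpy as np

NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inb(idx, shape) -> bool:
    return all(0 <= c < s for c, s in zip(idx, shape))


def _add(a, b):
    return tuple(x + y for x, y in zip(a, b))


def _sub(a, b):
    return tuple(x - y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# matrices


def brute_glcm(levels, mask, offset, n_levels):
    P = np.zeros((n_levels, n_levels))
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        j = _add(idx, offset)
        if _inb(j, levels.shape) and mask[j]:
            P[levels[idx] - 1, levels[j] - 1] += 1
            P[levels[j] - 1, levels[idx] - 1] += 1
    return P


def brute_glrlm(levels, mask, direction, n_levels):
    shape = levels.shape
    runs = []
    for start in np.ndindex(shape):
        if _inb(_sub(start, direction), shape):
            continue  # not the first voxel of this line
        seq = []
        pos = start
        while _inb(pos, shape):
            seq.append(int(levels[pos]) if mask[pos] else 0)
            pos = _add(pos, direction)
        for val, grp in groupby(seq):
            if val != 0:
                runs.append((val, len(list(grp))))
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((n_levels, max_len))
    for val, length in runs:
        P[val - 1, length - 1] += 1
    return P


def brute_glszm(levels, mask, n_levels):
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    for idx in np.ndindex(shape):
        if not mask[idx] or visited[idx]:
            continue
        level = int(levels[idx])
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for off in NEIGHBORS_26:
                q = _add(p, off)
                if (
                    _inb(q, shape)
                    and mask[q]
                    and not visited[q]
                    and int(levels[q]) == level
                ):
                    visited[q] = True
                    stack.append(q)
        zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((n_levels, max_size))
    for level, size in zones:
        P[level - 1, size - 1] += 1
    return P


def brute_gldm(levels, mask, n_levels):
    deps = []
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        count = 0
        for off in NEIGHBORS_26:
            q = _add(idx, off)
            if _inb(q, levels.shape) and mask[q] and levels[q] == levels[idx]:
                count += 1
        deps.append((int(levels[idx]), count + 1))
    max_dep = max(d for _, d in deps)
    P = np.zeros((n_levels, max_dep))
    for level, dep in deps:
        P[level - 1, dep - 1] += 1
    return P


def brute_ngtdm(levels, mask, n_levels):
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    nvp = 0
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        neigh = [
            int(levels[_add(idx, off)])
            for off in NEIGHBORS_26
            if _inb(_add(idx, off), levels.shape) and mask[_add(idx, off)]
        ]
        if not neigh:
            continue
        nvp += 1
        lv = int(levels[idx])
        n_i[lv - 1] += 1
        s_i[lv - 1] += abs(lv - sum(neigh) / len(neigh))
    return n_i, s_i, nvp


# ---------------------------------------------------------------------------
# feature formulary (plain Python sums on the brute matrices)


def _ent(values) -> float:
    return -sum(v * math.log2(v) for v in values if v > 0)


def oracle_glcm_features(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    Ng = P.shape[0]
    p = {(i + 1, j + 1): P[i, j] / total for i in range(Ng) for j in range(Ng)}
    px = {i: sum(p[i, j] for j in range(1, Ng + 1)) for i in range(1, Ng + 1)}
    py = {j: sum(p[i, j] for i in range(1, Ng + 1)) for j in range(1, Ng + 1)}
    ux = sum(i * px[i] for i in px)
    uy = sum(j * py[j] for j in py)
    sx = math.sqrt(sum((i - ux) ** 2 * px[i] for i in px))
    sy = math.sqrt(sum((j - uy) ** 2 * py[j] for j in py))
    p_sum = {}
    p_diff = {}
    for (i, j), v in p.items():
        p_sum[i + j] = p_sum.get(i + j, 0.0) + v
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + v
    da = sum(k * v for k, v in p_diff.items())
    autocorr = sum(i * j * v for (i, j), v in p.items())
    hxy = _ent(p.values())
    hx = _ent(px.values())
    hy = _ent(py.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in px
        for j in py
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    support = [i for i in px if px[i] > 0]
    if len(support) <= 1:
        mcc = 1.0
    else:
        Q = np.array(
            [
                [
                    sum(p[i, k] * p[j, k] / (px[i] * py[k]) for k in support)
                    for j in support
                ]
                for i in support
            ]
        )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(min(max(eig[1], 0.0), 1.0))
    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": sum((i + j - ux - uy) ** 4 * v for (i, j), v in p.items()),
        "ClusterShade": sum((i + j - ux - uy) ** 3 * v for (i, j), v in p.items()),
        "ClusterTendency": sum((i + j - ux - uy) ** 2 * v for (i, j), v in p.items()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlation": 1.0 if sx * sy == 0 else (autocorr - ux * uy) / (sx * sy),
        "DifferenceAverage": da,
        "DifferenceEntropy": _ent(p_diff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "Idm": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "Idmn": sum(v / (1 + (i - j) ** 2 / Ng**2) for (i, j), v in p.items()),
        "Idn": sum(v / (1 + abs(i - j) / Ng) for (i, j), v in p.items()),
        "Imc1": 0.0 if denom == 0 else (hxy - hxy1) / denom,
        "Imc2": math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0))),
        "InverseVariance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "JointAverage": ux,
        "JointEnergy": sum(v**2 for v in p.values()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": _ent(p_sum.values()),
        "SumSquares": sum((i - ux) ** 2 * v for (i, j), v in p.items()),
    }


def oracle_run_zone_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Generic run/zone formulary keyed by neutral names."""
    N = P.sum()
    Ng, Ns = P.shape
    pg = [P[i, :].sum() / N for i in range(Ng)]
    ps = [P[:, s].sum() / N for s in range(Ns)]
    mu_g = sum((i + 1) * pg[i] for i in range(Ng))
    mu_s = sum((s + 1) * ps[s] for s in range(Ns))
    cells = [
        (i + 1, s + 1, P[i, s]) for i in range(Ng) for s in range(Ns) if P[i, s] > 0
    ]
    return {
        "gln": sum(P[i, :].sum() ** 2 for i in range(Ng)) / N,
        "glnn": sum(P[i, :].sum() ** 2 for i in range(Ng)) / N**2,
        "glv": sum((i + 1 - mu_g) ** 2 * pg[i] for i in range(Ng)),
        "high": sum(c * i**2 for i, s, c in cells) / N,
        "long": sum(c * s**2 for i, s, c in cells) / N,
        "long_high": sum(c * i**2 * s**2 for i, s, c in cells) / N,
        "long_low": sum(c * s**2 / i**2 for i, s, c in cells) / N,
        "low": sum(c / i**2 for i, s, c in cells) / N,
        "entropy": _ent([c / N for _, _, c in cells]),
        "sn": sum(P[:, s].sum() ** 2 for s in range(Ns)) / N,
        "snn": sum(P[:, s].sum() ** 2 for s in range(Ns)) / N**2,
        "pct": N / n_voxels,
        "sv": sum((s + 1 - mu_s) ** 2 * ps[s] for s in range(Ns)),
        "short": sum(c / s**2 for i, s, c in cells) / N,
        "short_high": sum(c * i**2 / s**2 for i, s, c in cells) / N,
        "short_low": sum(c / (i**2 * s**2) for i, s, c in cells) / N,
    }


RUN_KEY_MAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelRunEmphasis": "high",
    "LongRunEmphasis": "long",
    "LongRunHighGrayLevelEmphasis": "long_high",
    "LongRunLowGrayLevelEmphasis": "long_low",
    "LowGrayLevelRunEmphasis": "low",
    "RunEntropy": "entropy",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "pct",
    "RunVariance": "sv",
    "ShortRunEmphasis": "short",
    "ShortRunHighGrayLevelEmphasis": "short_high",
    "ShortRunLowGrayLevelEmphasis": "short_low",
}
ZONE_KEY_MAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelZoneEmphasis": "high",
    "LargeAreaEmphasis": "long",
    "LargeAreaHighGrayLevelEmphasis": "long_high",
    "LargeAreaLowGrayLevelEmphasis": "long_low",
    "LowGrayLevelZoneEmphasis": "low",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "SmallAreaEmphasis": "short",
    "SmallAreaHighGrayLevelEmphasis": "short_high",
    "SmallAreaLowGrayLevelEmphasis": "short_low",
    "ZoneEntropy": "entropy",
    "ZonePercentage": "pct",
    "ZoneVariance": "sv",
}


def oracle_gldm_features(P: np.ndarray) -> dict[str, float]:
    N = P.sum()
    Ng, Nd = P.shape
    pg = [P[i, :].sum() / N for i in range(Ng)]
    pd = [P[:, j].sum() / N for j in range(Nd)]
    mu_g = sum((i + 1) * pg[i] for i in range(Ng))
    mu_d = sum((j + 1) * pd[j] for j in range(Nd))
    cells = [
        (i + 1, j + 1, P[i, j]) for i in range(Ng) for j in range(Nd) if P[i, j] > 0
    ]
    return {
        "DependenceEntropy": _ent([c / N for _, _, c in cells]),
        "DependenceNonUniformity": sum(P[:, j].sum() ** 2 for j in range(Nd)) / N,
        "DependenceNonUniformityNormalized": sum(P[:, j].sum() ** 2 for j in range(Nd)) / N**2,
        "DependenceVariance": sum((j + 1 - mu_d) ** 2 * pd[j] for j in range(Nd)),
        "GrayLevelNonUniformity": sum(P[i, :].sum() ** 2 for i in range(Ng)) / N,
        "GrayLevelVariance": sum((i + 1 - mu_g) ** 2 * pg[i] for i in range(Ng)),
        "HighGrayLevelEmphasis": sum(c * i**2 for i, j, c in cells) / N,
        "LargeDependenceEmphasis": sum(c * j**2 for i, j, c in cells) / N,
        "LargeDependenceHighGrayLevelEmphasis": sum(c * i**2 * j**2 for i, j, c in cells) / N,
        "LargeDependenceLowGrayLevelEmphasis": sum(c * j**2 / i**2 for i, j, c in cells) / N,
        "LowGrayLevelEmphasis": sum(c / i**2 for i, j, c in cells) / N,
        "SmallDependenceEmphasis": sum(c / j**2 for i, j, c in cells) / N,
        "SmallDependenceHighGrayLevelEmphasis": sum(c * i**2 / j**2 for i, j, c in cells) / N,
        "SmallDependenceLowGrayLevelEmphasis": sum(c / (i**2 * j**2) for i, j, c in cells) / N,
    }


def oracle_ngtdm_features(n_i, s_i, nvp) -> dict[str, float]:
    if nvp == 0:
        return {"Busyness": 0.0, "Coarseness": 1e6, "Complexity": 0.0,
                "Contrast": 0.0, "Strength": 0.0}
    levels = [i + 1 for i in range(len(n_i)) if n_i[i] > 0]
    p = {i: n_i[i - 1] / nvp for i in levels}
    s = {i: s_i[i - 1] for i in levels}
    ngp = len(levels)
    coars_den = sum(p[i] * s[i] for i in levels)
    if ngp <= 1:
        contrast = 0.0
    else:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
            / (ngp * (ngp - 1))
            * sum(s.values())
            / nvp
        )
    busy_den = sum(abs(i * p[i] - j * p[j]) for i in levels for j in levels)
    complexity = (
        sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in levels
            for j in levels
        )
        / nvp
    )
    s_sum = sum(s.values())
    strength = (
        0.0
        if s_sum == 0
        else sum((p[i] + p[j]) * (i - j) ** 2 for i in levels for j in levels) / s_sum
    )
    return {
        "Busyness": 0.0 if busy_den == 0 else coars_den / busy_den,
        "Coarseness": 1e6 if coars_den == 0 else 1.0 / coars_den,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
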