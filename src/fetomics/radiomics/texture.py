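"""Gray-level texture matrices and their features, computed in 3D.

Conventions (fixed so that every value is reproducible and oracle-testable):

* GLCM: symmetric, distance 1, one matrix per each of the 13 unique 3D
  direction pairs; features are computed per direction and averaged.
* GLRLM: runs of equal gray level along the same 13 directions; features
  averaged over directions.
* GLSZM: zones are 26-connected components of equal gray level (one matrix).
* NGTDM: 26-neighborhood mean differences; voxels with no in-mask neighbor
  are excluded from the valid count.
* GLDM: a neighbor is "dependent" when its gray level equals the center's
  (alpha = 0); the dependence index of a voxel is 1 + its number of
  dependent 26-neighbors.

Degenerate matrices (single gray level, single voxel) produce the documented
limit values rather than NaNs.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

from .binning import BinningSpec, discretize

__all__ = [
    "texture_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "TEXTURE_FAMILIES",
]

#: the 13 unique direction pairs of the 26-neighborhood
OFFSETS_13 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
OFFSETS_26 = tuple(d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0))
_CONN26 = np.ones((3, 3, 3), dtype=bool)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

_LOG_EPS = 0.0  # entropies sum over strictly positive entries only


def _crop(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM


def _pair_slices(shape, d):
    src, dst = [], []
    for n, dd in zip(shape, d):
        if dd >= 0:
            src.append(slice(0, n - dd))
            dst.append(slice(dd, n))
        else:
            src.append(slice(-dd, n))
            dst.append(slice(0, n + dd))
    return tuple(src), tuple(dst)


def glcm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Un-normalised symmetric co-occurrence counts, one per direction."""
    lv, mk = _crop(levels, mask)
    out = []
    for d in OFFSETS_13:
        src, dst = _pair_slices(lv.shape, d)
        both = mk[src] & mk[dst]
        if not both.any():
            continue
        i = lv[src][both] - 1
        j = lv[dst][both] - 1
        P = np.zeros((n_levels, n_levels))
        np.add.at(P, (i, j), 1.0)
        out.append(P + P.T)
    return out


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    p = P / P.sum()
    Ng = p.shape[0]
    lv = np.arange(1, Ng + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((lv * px).sum())
    uy = float((lv * py).sum())
    sx = float(np.sqrt((((lv - ux) ** 2) * px).sum()))
    sy = float(np.sqrt((((lv - uy) ** 2) * py).sum()))
    ii, jj = np.meshgrid(lv, lv, indexing="ij")

    sum_idx = np.rint(ii + jj).astype(int).ravel()
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * Ng + 1)
    diff_idx = np.rint(np.abs(ii - jj)).astype(int).ravel()
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=Ng)
    k_sum = np.arange(p_sum.size, dtype=float)
    k_diff = np.arange(p_diff.size, dtype=float)

    autocorr = float((p * ii * jj).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    corr = 1.0 if sx * sy == 0 else float((autocorr - ux * uy) / (sx * sy))
    da = float((k_diff * p_diff).sum())

    hxy = _entropy(p)
    hx = _entropy(px)
    hy = _entropy(py)
    nz = p > 0
    pxy = np.outer(px, py)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    denom = max(hx, hy)
    imc1 = 0.0 if denom == 0 else float((hxy - hxy1) / denom)
    imc2 = float(np.sqrt(1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))

    support = px > 0
    if support.sum() <= 1:
        mcc = 1.0
    else:
        ps = p[np.ix_(support, support)]
        pxs = px[support]
        A = ps / pxs[:, None]          # p(i,k)/px(i)
        D = ps / pxs[None, :]          # p(j,k)/py(k); py == px by symmetry
        Q = A @ D.T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(np.clip(eig[1], 0.0, 1.0)))

    off_diag = np.abs(ii - jj) > 0
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float((p * (ii + jj - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - ux - uy) ** 2).sum()),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / Ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((((ii - ux) ** 2) * p).sum()),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    mats = glcm_matrices(levels, mask, n_levels)
    if not mats:  # single voxel: degenerate self co-occurrence
        lv = int(levels[mask][0])
        P = np.zeros((n_levels, n_levels))
        P[lv - 1, lv - 1] = 1.0
        mats = [P]
    per_dir = [_glcm_features_one(P) for P in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Run-length count matrices (Ng x max_run), one per direction."""
    lv, mk = _crop(levels, mask)
    padded = np.pad(np.where(mk, lv, 0), 1)  # 0 border: never matches a level
    coords = np.argwhere(mk) + 1
    max_run = max(lv.shape)
    out = []
    for d in OFFSETS_13:
        dv = np.array(d)
        cur = padded[tuple(coords.T)]
        prev = padded[tuple((coords - dv).T)]
        starts = coords[prev != cur]
        P = np.zeros((n_levels, max_run))
        for pos in starts:
            level = padded[tuple(pos)]
            length = 1
            nxt = pos + dv
            while padded[tuple(nxt)] == level:
                length += 1
                nxt = nxt + dv
            P[level - 1, length - 1] += 1.0
        out.append(P)
    return out


def _run_zone_features(P: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared formulary for run-length (kind='run') and size-zone (kind='zone')."""
    N = P.sum()
    p = P / N
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((np.arange(1, P.shape[0] + 1) * pg).sum())
    mu_s = float((np.arange(1, P.shape[1] + 1) * ps).sum())
    feats = {
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / N),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / N**2),
        "GrayLevelVariance": float(((np.arange(1, P.shape[0] + 1) - mu_g) ** 2 * pg).sum()),
        "short": float((P / s**2).sum() / N),
        "long": float((P * s**2).sum() / N),
        "low": float((P / i**2).sum() / N),
        "high": float((P * i**2).sum() / N),
        "short_low": float((P / (i**2 * s**2)).sum() / N),
        "short_high": float((P * i**2 / s**2).sum() / N),
        "long_low": float((P * s**2 / i**2).sum() / N),
        "long_high": float((P * i**2 * s**2).sum() / N),
        "size_nonuniformity": float((P.sum(axis=0) ** 2).sum() / N),
        "size_nonuniformity_norm": float((P.sum(axis=0) ** 2).sum() / N**2),
        "percentage": float(N / n_voxels),
        "size_variance": float(((np.arange(1, P.shape[1] + 1) - mu_s) ** 2 * ps).sum()),
        "entropy": _entropy(p),
    }
    if kind == "run":
        return {
            "GrayLevelNonUniformity": feats["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": feats["GrayLevelNonUniformityNormalized"],
            "GrayLevelVariance": feats["GrayLevelVariance"],
            "HighGrayLevelRunEmphasis": feats["high"],
            "LongRunEmphasis": feats["long"],
            "LongRunHighGrayLevelEmphasis": feats["long_high"],
            "LongRunLowGrayLevelEmphasis": feats["long_low"],
            "LowGrayLevelRunEmphasis": feats["low"],
            "RunEntropy": feats["entropy"],
            "RunLengthNonUniformity": feats["size_nonuniformity"],
            "RunLengthNonUniformityNormalized": feats["size_nonuniformity_norm"],
            "RunPercentage": feats["percentage"],
            "RunVariance": feats["size_variance"],
            "ShortRunEmphasis": feats["short"],
            "ShortRunHighGrayLevelEmphasis": feats["short_high"],
            "ShortRunLowGrayLevelEmphasis": feats["short_low"],
        }
    return {
        "GrayLevelNonUniformity": feats["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": feats["GrayLevelNonUniformityNormalized"],
        "GrayLevelVariance": feats["GrayLevelVariance"],
        "HighGrayLevelZoneEmphasis": feats["high"],
        "LargeAreaEmphasis": feats["long"],
        "LargeAreaHighGrayLevelEmphasis": feats["long_high"],
        "LargeAreaLowGrayLevelEmphasis": feats["long_low"],
        "LowGrayLevelZoneEmphasis": feats["low"],
        "SizeZoneNonUniformity": feats["size_nonuniformity"],
        "SizeZoneNonUniformityNormalized": feats["size_nonuniformity_norm"],
        "SmallAreaEmphasis": feats["short"],
        "SmallAreaHighGrayLevelEmphasis": feats["short_high"],
        "SmallAreaLowGrayLevelEmphasis": feats["short_low"],
        "ZoneEntropy": feats["entropy"],
        "ZonePercentage": feats["percentage"],
        "ZoneVariance": feats["size_variance"],
    }


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    n_vox = int(mask.sum())
    per_dir = [
        _run_zone_features(P, n_vox, kind="run")
        for P in glrlm_matrices(levels, mask, n_levels)
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    lv, mk = _crop(levels, mask)
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for level in np.unique(lv[mk]):
        lab, n = ndimage.label((lv == level) & mk, structure=_CONN26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zone_sizes[int(level)] = sizes.tolist()
            max_size = max(max_size, int(sizes.max()))
    P = np.zeros((n_levels, max_size))
    for level, sizes in zone_sizes.items():
        for s in sizes:
            P[level - 1, s - 1] += 1.0
    return P


def glszm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    P = glszm_matrix(levels, mask, n_levels)
    return _run_zone_features(P, int(mask.sum()), kind="zone")


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """(n_i, s_i) per gray level and the valid-voxel count N_vp."""
    lv, mk = _crop(levels, mask)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.correlate(np.where(mk, lv, 0).astype(float), kernel, mode="constant")
    neigh_cnt = ndimage.correlate(mk.astype(float), kernel, mode="constant")
    valid = mk & (neigh_cnt > 0)
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    lv_valid = lv[valid]
    diffs = np.abs(lv_valid - neigh_sum[valid] / neigh_cnt[valid])
    np.add.at(n_i, lv_valid - 1, 1.0)
    np.add.at(s_i, lv_valid - 1, diffs)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    n_i, s_i, nvp = ngtdm_table(levels, mask, n_levels)
    if nvp == 0:
        return {"Busyness": 0.0, "Coarseness": 1e6, "Complexity": 0.0,
                "Contrast": 0.0, "Strength": 0.0}
    p_i = n_i / nvp
    present = p_i > 0
    lv = np.arange(1, n_levels + 1, dtype=float)
    ngp = int(present.sum())

    coars_den = float((p_i * s_i).sum())
    coarseness = 1e6 if coars_den == 0 else 1.0 / coars_den

    if ngp <= 1:
        contrast = 0.0
    else:
        pi = p_i[present]
        li = lv[present]
        pairs = (pi[:, None] * pi[None, :] * (li[:, None] - li[None, :]) ** 2).sum()
        contrast = float(pairs / (ngp * (ngp - 1)) * s_i.sum() / nvp)

    pi = p_i[present]
    li = lv[present]
    si = s_i[present]
    busy_den = float(np.abs(li[:, None] * pi[:, None] - li[None, :] * pi[None, :]).sum())
    busyness = 0.0 if busy_den == 0 else float((p_i * s_i).sum() / busy_den)

    with np.errstate(divide="ignore", invalid="ignore"):
        numer = np.abs(li[:, None] - li[None, :]) * (
            (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
            / (pi[:, None] + pi[None, :])
        )
    complexity = float(numer.sum() / nvp)

    s_sum = float(si.sum())
    if s_sum == 0:
        strength = 0.0
    else:
        strength = float(
            ((pi[:, None] + pi[None, :]) * (li[:, None] - li[None, :]) ** 2).sum() / s_sum
        )
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    lv, mk = _crop(levels, mask)
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in OFFSETS_26:
        src, dst = _pair_slices(lv.shape, d)
        same = mk[src] & mk[dst] & (lv[src] == lv[dst])
        dep[src] += same
    j = dep[mk] + 1  # dependence index counts the center voxel
    i = lv[mk]
    P = np.zeros((n_levels, 27))
    np.add.at(P, (i - 1, j - 1), 1.0)
    return P[:, : int(j.max())]


def gldm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    P = gldm_matrix(levels, mask, n_levels)
    Nz = P.sum()
    p = P / Nz
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_g = float((np.arange(1, P.shape[0] + 1) * pg).sum())
    mu_d = float((np.arange(1, P.shape[1] + 1) * pd).sum())
    return {
        "DependenceEntropy": _entropy(p),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / Nz**2),
        "DependenceVariance": float(((np.arange(1, P.shape[1] + 1) - mu_d) ** 2 * pd).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Nz),
        "GrayLevelVariance": float(((np.arange(1, P.shape[0] + 1) - mu_g) ** 2 * pg).sum()),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / Nz),
        "LargeDependenceEmphasis": float((P * j**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / Nz),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / Nz),
        "SmallDependenceEmphasis": float((P / j**2).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / Nz),
    }


# ---------------------------------------------------------------------------
# dispatcher

_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}
FAMILY_NAMES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}


def texture_features(
    values: np.ndarray,
    mask: np.ndarray,
    binning: BinningSpec | None = None,
    family: str = "glcm",
) -> dict[str, float]:
    """Texture features of one family on a (possibly filtered) image."""
    family = family.lower()
    if family not in _FAMILY_FUNCS:
        raise ValueError(f"unknown texture family {family!r}")
    mask = np.asarray(mask, dtype=bool)
    levels, n_levels = discretize(values, mask, binning)
    return _FAMILY_FUNCS[family](levels, mask, n_levels)
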