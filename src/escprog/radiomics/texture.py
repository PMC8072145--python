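"""Texture-matrix feature classes on a discretized ROI.

All matrices are built on the quantized gray levels (1..Ng) of in-mask
voxels. Conventions: 26-connectivity for zones (GLSZM), dependencies (GLDM)
and neighborhoods (NGTDM); co-occurrence and run-length statistics computed
per direction over the 13 unique 3D offsets and averaged; out-of-mask voxels
break runs and never pair. Undefined features (e.g. co-occurrence statistics
on a single-voxel ROI) are returned as NaN, never silently zeroed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .base import QuantizedROI, UNIQUE_DIRECTIONS

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "GLDM_FEATURES",
    "NGTDM_FEATURES",
]

_EPS = np.finfo(float).eps


def _offset_slices(shape, offset):
    """Aligned slice pair (sl_a, sl_b) so A[sl_a] and A[sl_b] differ by offset."""
    sl_a, sl_b = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


# ---------------------------------------------------------------------------
# GLCM

GLCM_FEATURES = [
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
]


def glcm_matrix(q: QuantizedROI, offset, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (in-mask pairs only)."""
    ng = q.ng
    d = tuple(int(o) * distance for o in offset)
    sl_a, sl_b = _offset_slices(q.levels.shape, d)
    valid = q.mask[sl_a] & q.mask[sl_b]
    i = q.levels[sl_a][valid] - 1
    j = q.levels[sl_b][valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    return counts + counts.T  # symmetric


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())            # == mu_x == mu_y by symmetry
    sig2 = float((px * (i - mu) ** 2).sum())
    sig = np.sqrt(sig2)

    # diagonal / cross-diagonal marginals
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    nz = p[p > 0]
    hxy = float(-(nz * np.log2(nz)).sum())
    px_py = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-(p * np.log2(px_py + _EPS)).sum())
        hxy2 = float(-(px_py * np.log2(px_py + _EPS)).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())

    da = float((p_diff * k_diff).sum())
    feats = {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": (
            float(((p * ii * jj).sum() - mu * mu) / (sig * sig)) if sig > 0 else np.nan
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float((hxy - hxy1) / max(hx, _EPS)) if hx > 0 else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float((p[ii != jj] / (ii - jj)[ii != jj] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float((p * (ii - mu) ** 2).sum()),
    }
    if ng == 1:
        feats["MCC"] = 1.0
    else:
        keep = px > 0
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        B = pk / pxk[None, :]
        Q = (pk @ B.T) / pxk[:, None]
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        feats["MCC"] = float(np.sqrt(max(0.0, ev[1]))) if len(ev) > 1 else 1.0
    return feats


def glcm_features(q: QuantizedROI, distance: int = 1) -> dict[str, float]:
    """24 co-occurrence features averaged over the 13 unique 3D directions."""
    per_dir = []
    for off in UNIQUE_DIRECTIONS:
        counts = glcm_matrix(q, off, distance)
        total = counts.sum()
        if total == 0:
            continue  # no valid pair along this direction
        per_dir.append(_glcm_features_single(counts / total))
    if not per_dir:
        return {name: np.nan for name in GLCM_FEATURES}
    out = {}
    for name in GLCM_FEATURES:
        vals = np.array([f[name] for f in per_dir])
        finite = vals[np.isfinite(vals)]
        out[name] = float(finite.mean()) if finite.size else np.nan
    return out


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_FEATURES = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def glrlm_matrix(q: QuantizedROI, offset) -> np.ndarray:
    """Run-length counts P(level, run_length) along one direction.

    A run is a maximal string of consecutive in-mask voxels of equal level
    along the direction; out-of-mask voxels break runs.
    """
    shape = q.levels.shape
    d = np.asarray(offset)
    sl_a, sl_b = _offset_slices(shape, offset)

    # run starts: in-mask voxels whose predecessor along -offset is absent
    pred_same = np.zeros(shape, dtype=bool)
    pred_same[sl_b] = q.mask[sl_a] & q.mask[sl_b] & (q.levels[sl_a] == q.levels[sl_b])
    start = q.mask & ~pred_same

    pos = np.argwhere(start)
    lev = q.levels[start]
    n_runs = len(pos)
    lengths = np.ones(n_runs, dtype=np.int64)
    active = np.arange(n_runs)
    cur = pos.copy()
    while active.size:
        nxt = cur[active] + d
        inside = np.all((nxt >= 0) & (nxt < np.asarray(shape)), axis=1)
        ok = np.zeros(active.size, dtype=bool)
        idx_in = nxt[inside]
        if idx_in.size:
            cont = q.mask[tuple(idx_in.T)] & (
                q.levels[tuple(idx_in.T)] == lev[active[inside]]
            )
            ok[inside] = cont
        surviving = active[ok]
        lengths[surviving] += 1
        cur[surviving] = cur[surviving] + d
        active = surviving

    max_len = int(lengths.max()) if n_runs else 1
    mat = np.zeros((q.ng, max_len), dtype=float)
    np.add.at(mat, (lev - 1, lengths - 1), 1.0)
    return mat


def _rlm_style_features(P: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared feature family for run-length / size-zone matrices (levels x sizes)."""
    nr = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = P.sum(axis=1)  # per gray level
    pr = P.sum(axis=0)  # per run length / zone size
    p = P / nr
    mu_i = (p.sum(axis=1) * i).sum()
    mu_j = (p.sum(axis=0) * j).sum()
    nz = p[p > 0]
    if prefix == "Run":
        short, long_, unit, gl = "ShortRun", "LongRun", "RunLength", "Run"
        pct, var_name, ent_name = "RunPercentage", "RunVariance", "RunEntropy"
    else:
        short, long_, unit, gl = "SmallArea", "LargeArea", "SizeZone", "Zone"
        pct, var_name, ent_name = "ZonePercentage", "ZoneVariance", "ZoneEntropy"
    return {
        f"{short}Emphasis": float((P / jj**2).sum() / nr),
        f"{long_}Emphasis": float((P * jj**2).sum() / nr),
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        f"{unit}NonUniformity": float((pr**2).sum() / nr),
        f"{unit}NonUniformityNormalized": float((pr**2).sum() / nr**2),
        pct: float(nr / n_voxels),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        var_name: float((p * (jj - mu_j) ** 2).sum()),
        ent_name: float(-(nz * np.log2(nz)).sum()),
        f"LowGrayLevel{gl}Emphasis": float((P / ii**2).sum() / nr),
        f"HighGrayLevel{gl}Emphasis": float((P * ii**2).sum() / nr),
        f"{short}LowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum() / nr),
        f"{short}HighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum() / nr),
        f"{long_}LowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum() / nr),
        f"{long_}HighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum() / nr),
    }


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    """16 run-length features averaged over the 13 unique 3D directions."""
    n_voxels = int(q.mask.sum())
    per_dir = []
    for off in UNIQUE_DIRECTIONS:
        P = glrlm_matrix(q, off)
        per_dir.append(_rlm_style_features(P, n_voxels, prefix="Run"))
    return {
        name: float(np.nanmean([f[name] for f in per_dir])) for name in GLRLM_FEATURES
    }


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_FEATURES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Zone counts P(level, size): 26-connected equal-level components."""
    structure = np.ones((3, 3, 3), dtype=int)
    rows: list[tuple[int, int]] = []
    for g in range(1, q.ng + 1):
        lab, n_lab = ndimage.label(q.levels == g, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        rows.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in rows)
    mat = np.zeros((q.ng, max_size), dtype=float)
    for g, s in rows:
        mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    """The 16 size-zone features (zones = 26-connected equal-level components)."""
    P = glszm_matrix(q)
    feats = _rlm_style_features(P, int(q.mask.sum()), prefix="Zone")
    return {name: feats[name] for name in GLSZM_FEATURES}


# ---------------------------------------------------------------------------
# GLDM

GLDM_FEATURES = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]


def gldm_matrix(q: QuantizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts P(level, j): j = 1 + number of 26-neighbors within
    gray-level tolerance ``alpha`` (the center voxel counts itself)."""
    dep = np.zeros(q.levels.shape, dtype=np.int64)
    for off in UNIQUE_DIRECTIONS:
        sl_a, sl_b = _offset_slices(q.levels.shape, off)
        ok = (
            q.mask[sl_a]
            & q.mask[sl_b]
            & (np.abs(q.levels[sl_a] - q.levels[sl_b]) <= alpha)
        )
        dep[sl_a] += ok
        dep[sl_b] += ok
    j = dep[q.mask] + 1
    lev = q.levels[q.mask]
    mat = np.zeros((q.ng, int(j.max())), dtype=float)
    np.add.at(mat, (lev - 1, j - 1), 1.0)
    return mat


def gldm_features(q: QuantizedROI, alpha: int = 0) -> dict[str, float]:
    """The 14 gray-level dependence features."""
    P = gldm_matrix(q, alpha)
    nz_total = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    p = P / nz_total
    mu_i = (p.sum(axis=1) * i).sum()
    mu_j = (p.sum(axis=0) * j).sum()
    nz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((P / jj**2).sum() / nz_total),
        "LargeDependenceEmphasis": float((P * jj**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz_total),
        "DependenceNonUniformity": float((pd_**2).sum() / nz_total),
        "DependenceNonUniformityNormalized": float((pd_**2).sum() / nz_total**2),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(nz * np.log2(nz)).sum()),
        "LowGrayLevelEmphasis": float((P / ii**2).sum() / nz_total),
        "HighGrayLevelEmphasis": float((P * ii**2).sum() / nz_total),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (P / (ii**2 * jj**2)).sum() / nz_total
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (P * ii**2 / jj**2).sum() / nz_total
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (P * jj**2 / ii**2).sum() / nz_total
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (P * ii**2 * jj**2).sum() / nz_total
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM

NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def ngtdm_table(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i): counts, probabilities and summed absolute
    differences from the 26-neighborhood mean, over voxels with >= 1 in-mask
    neighbor."""
    shape = q.levels.shape
    nb_sum = np.zeros(shape, dtype=float)
    nb_cnt = np.zeros(shape, dtype=np.int64)
    for off in UNIQUE_DIRECTIONS:
        sl_a, sl_b = _offset_slices(shape, off)
        mb = q.mask[sl_b]
        ma = q.mask[sl_a]
        nb_sum[sl_a] += q.levels[sl_b] * mb
        nb_cnt[sl_a] += mb
        nb_sum[sl_b] += q.levels[sl_a] * ma
        nb_cnt[sl_b] += ma
    valid = q.mask & (nb_cnt > 0)
    lev = q.levels[valid]
    diff = np.abs(lev - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(lev - 1, minlength=q.ng).astype(float)
    s_i = np.zeros(q.ng)
    np.add.at(s_i, lev - 1, diff)
    p_i = n_i / n_i.sum() if n_i.sum() > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features."""
    n_i, p_i, s_i = ngtdm_table(q)
    nvp = n_i.sum()
    if nvp == 0:
        return {name: np.nan for name in NGTDM_FEATURES}
    i = np.arange(1, q.ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p_i[present], s_i[present]

    coarse_den = float((pp * sp).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di**2).sum()) / (ngp * (ngp - 1)) * float(sp.sum()) / nvp
        v = ip * pp
        busy_den = float(np.abs(v[:, None] - v[None, :]).sum())
        busyness = float((pp * sp).sum()) / busy_den if busy_den > 0 else 0.0
        num = np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / (
            pp[:, None] + pp[None, :]
        )
        complexity = float(num.sum()) / nvp
        strength_num = float(((pp[:, None] + pp[None, :]) * di**2).sum())
        s_total = float(sp.sum())
        strength = strength_num / s_total if s_total > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
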