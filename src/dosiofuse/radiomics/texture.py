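"""Gray-level texture matrices and their features — 136 values.

Six matrix families over the discretized ROI:

* GLCM — symmetric co-occurrence at Chebyshev distance 1 over the 13 unique
  3D directions; 25 features under two aggregations (per-direction matrices
  averaged, and directions merged into one matrix) = 50.
* GLRLM — run-length matrices over the same 13 directions; 16 features x
  {averaged, merged} = 32.
* GLSZM — size-zone matrix over 26-connected constant-level zones = 16.
* GLDZM — distance-zone matrix; a zone's distance is the minimum city-block
  distance of its voxels to the ROI edge = 16.
* NGTDM — neighborhood gray-tone difference over 26-neighborhoods = 5.
* NGLDM — neighboring gray-level dependence, coarseness parameter alpha=0 at
  Chebyshev distance 1 = 17.

Feature values follow the standard reference definitions; blocks whose ROI
cannot form a single valid pair/zone emit NaN (documented degenerate rule).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

from .quantize import QuantizedROI

__all__ = [
    "DIRECTIONS_3D",
    "glcm_matrix", "glcm_features",
    "glrlm_matrix", "glrlm_features",
    "glszm_matrix", "glszm_features",
    "gldzm_matrix", "gldzm_features",
    "ngtdm_features", "ngldm_matrix", "ngldm_features",
    "GLCM_FEATURES", "GLRLM_FEATURES", "GLSZM_FEATURES", "GLDZM_FEATURES",
    "NGTDM_FEATURES", "NGLDM_FEATURES",
]

# 13 unique direction vectors (k, j, i): half of the 26 neighbors, modulo sign
DIRECTIONS_3D = [
    d for d in product((0, 1, -1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
]
assert len(DIRECTIONS_3D) == 13


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (and its negative)."""
    lv = q.levels
    ng = q.n_levels
    dk, dj, di = direction
    src = _shift_pairs(lv, (dk, dj, di))
    mat = np.zeros((ng, ng))
    if src is None:
        return mat
    a, b = src
    np.add.at(mat, (a - 1, b - 1), 1)
    np.add.at(mat, (b - 1, a - 1), 1)
    return mat


def _shift_pairs(lv: np.ndarray, d: tuple[int, int, int]):
    """Return aligned in-mask level pairs (a, b) for offset d, or None."""
    sl_a, sl_b = [], []
    for dim, off in zip(lv.shape, d):
        if off >= 0:
            sl_a.append(slice(0, dim - off))
            sl_b.append(slice(off, dim))
        else:
            sl_a.append(slice(-off, dim))
            sl_b.append(slice(0, dim + off))
    a = lv[tuple(sl_a)]
    b = lv[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    return a[valid], b[valid]


GLCM_FEATURES = [
    "joint_max", "joint_avg", "joint_var", "joint_entr",
    "diff_avg", "diff_var", "diff_entr",
    "sum_avg", "sum_var", "sum_entr",
    "energy", "contrast", "dissimilarity",
    "inv_diff", "inv_diff_norm", "inv_diff_mom", "inv_diff_mom_norm",
    "inv_var", "corr", "auto_corr",
    "clust_tend", "clust_shade", "clust_prom",
    "info_corr_1", "info_corr_2",
]


def _glcm_features_from_matrix(mat: np.ndarray) -> dict[str, float]:
    ng = mat.shape[0]
    total = mat.sum()
    if total == 0:
        return {k: float("nan") for k in GLCM_FEATURES}
    p = mat / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # row marginal (symmetric)
    mu = float((ii * p).sum())
    out: dict[str, float] = {}
    out["joint_max"] = float(p.max())
    out["joint_avg"] = mu
    out["joint_var"] = float(((ii - mu) ** 2 * p).sum())
    nz = p[p > 0]
    out["joint_entr"] = float(-(nz * np.log2(nz)).sum())

    k_diff = np.arange(ng)
    p_minus = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    da = float((k_diff * p_minus).sum())
    out["diff_avg"] = da
    out["diff_var"] = float(((k_diff - da) ** 2 * p_minus).sum())
    nzm = p_minus[p_minus > 0]
    out["diff_entr"] = float(-(nzm * np.log2(nzm)).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    p_plus = np.array([p[ii + jj == k].sum() for k in k_sum])
    sa = float((k_sum * p_plus).sum())
    out["sum_avg"] = sa
    out["sum_var"] = float(((k_sum - sa) ** 2 * p_plus).sum())
    nzp = p_plus[p_plus > 0]
    out["sum_entr"] = float(-(nzp * np.log2(nzp)).sum())

    out["energy"] = float((p**2).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    out["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["inv_diff"] = float((p / (1 + np.abs(ii - jj))).sum())
    out["inv_diff_norm"] = float((p / (1 + np.abs(ii - jj) / ng)).sum())
    out["inv_diff_mom"] = float((p / (1 + (ii - jj) ** 2)).sum())
    out["inv_diff_mom_norm"] = float((p / (1 + (ii - jj) ** 2 / ng**2)).sum())
    off = ii != jj
    with np.errstate(divide="ignore"):
        out["inv_var"] = float((p[off] / (ii - jj)[off] ** 2).sum())
    sigma2 = float(((i - mu) ** 2 * pi).sum())
    if sigma2 > 0:
        out["corr"] = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
    else:
        out["corr"] = float("nan")
    out["auto_corr"] = float((ii * jj * p).sum())
    out["clust_tend"] = float(((ii + jj - 2 * mu) ** 2 * p).sum())
    out["clust_shade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    out["clust_prom"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())

    nz_pi = pi[pi > 0]
    hx = float(-(nz_pi * np.log2(nz_pi)).sum())
    pij_prod = np.outer(pi, pi)
    valid = (p > 0) & (pij_prod > 0)
    hxy1 = float(-(p[valid] * np.log2(pij_prod[valid])).sum())
    vp = pij_prod[pij_prod > 0]
    hxy2 = float(-(vp * np.log2(vp)).sum())
    out["info_corr_1"] = (out["joint_entr"] - hxy1) / hx if hx > 0 else float("nan")
    arg = 1 - np.exp(-2 * (hxy2 - out["joint_entr"]))
    out["info_corr_2"] = float(np.sqrt(max(arg, 0.0)))
    return out


def glcm_features(q: QuantizedROI) -> dict[str, float]:
    """25 GLCM features under averaged and merged direction aggregations."""
    mats = [glcm_matrix(q, d) for d in DIRECTIONS_3D]
    valid = [m for m in mats if m.sum() > 0]
    out: dict[str, float] = {}
    if not valid:
        for agg in ("avg", "mrg"):
            for name in GLCM_FEATURES:
                out[f"glcm_{name}_{agg}"] = float("nan")
        return out
    per_dir = [_glcm_features_from_matrix(m) for m in valid]
    for name in GLCM_FEATURES:
        vals = [f[name] for f in per_dir]
        finite = [v for v in vals if np.isfinite(v)]
        out[f"glcm_{name}_avg"] = float(np.mean(finite)) if finite else float("nan")
    merged = _glcm_features_from_matrix(np.sum(valid, axis=0))
    for name in GLCM_FEATURES:
        out[f"glcm_{name}_mrg"] = merged[name]
    return out


# ---------------------------------------------------------------------------
# Shared skeleton for run-length / size-zone / distance-zone features
# ---------------------------------------------------------------------------

def _rl_zone_features(mat: np.ndarray, n_vox: float, prefix: str,
                      small: str, large: str, col: str) -> dict[str, float]:
    """16 features shared by GLRLM/GLSZM/GLDZM (emphasis, non-uniformity,
    percentage, variances, entropy); naming differs per family."""
    names = _names_for(prefix, small, large, col)
    total = mat.sum()
    if total == 0:
        return {n: float("nan") for n in names}
    ng, nmax = mat.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nmax + 1)
    ri = mat.sum(axis=1)
    cj = mat.sum(axis=0)
    p = mat / total
    ii, jj = np.meshgrid(i, j, indexing="ij")
    out = {}
    out[names[0]] = float((cj / j**2).sum() / total)            # small emphasis
    out[names[1]] = float((cj * j**2).sum() / total)            # large emphasis
    out[names[2]] = float((ri / i**2).sum() / total)            # low gray
    out[names[3]] = float((ri * i**2).sum() / total)            # high gray
    out[names[4]] = float((mat / (ii**2 * jj**2)).sum() / total)
    out[names[5]] = float((mat * ii**2 / jj**2).sum() / total)
    out[names[6]] = float((mat * jj**2 / ii**2).sum() / total)
    out[names[7]] = float((mat * ii**2 * jj**2).sum() / total)
    out[names[8]] = float((ri**2).sum() / total)                # glnu
    out[names[9]] = float((ri**2).sum() / total**2)             # glnu normalized
    out[names[10]] = float((cj**2).sum() / total)               # col non-uniformity
    out[names[11]] = float((cj**2).sum() / total**2)
    out[names[12]] = float(total / n_vox)                       # percentage
    mu_i = float((ii * p).sum())
    out[names[13]] = float(((ii - mu_i) ** 2 * p).sum())        # gray-level variance
    mu_j = float((jj * p).sum())
    out[names[14]] = float(((jj - mu_j) ** 2 * p).sum())        # col variance
    nz = p[p > 0]
    out[names[15]] = float(-(nz * np.log2(nz)).sum())           # entropy
    return out


def _names_for(prefix: str, small: str, large: str, col: str) -> list[str]:
    return [
        f"{prefix}_{small}", f"{prefix}_{large}",
        f"{prefix}_lgle", f"{prefix}_hgle",
        f"{prefix}_{small}_lgle", f"{prefix}_{small}_hgle",
        f"{prefix}_{large}_lgle", f"{prefix}_{large}_hgle",
        f"{prefix}_glnu", f"{prefix}_glnu_norm",
        f"{prefix}_{col}nu", f"{prefix}_{col}nu_norm",
        f"{prefix}_{col}_perc", f"{prefix}_gl_var", f"{prefix}_{col}_var",
        f"{prefix}_{col}_entr",
    ]


GLRLM_FEATURES = _names_for("glrlm", "sre", "lre", "rl")
GLSZM_FEATURES = _names_for("glszm", "sze", "lze", "zs")
GLDZM_FEATURES = _names_for("gldzm", "sde", "lde", "zd")


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(q: QuantizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts along one direction; out-of-mask voxels break runs."""
    lv = q.levels
    ng = q.n_levels
    longest = int(np.ceil(np.sqrt(sum(s**2 for s in lv.shape)))) + 1
    mat = np.zeros((ng, longest))
    for line in _grid_lines(lv.shape, direction):
        vals = lv[tuple(line.T)]
        run_level, run_len = 0, 0
        for v in list(vals) + [0]:
            if v == run_level:
                run_len += 1
            else:
                if run_level > 0 and run_len > 0:
                    mat[run_level - 1, run_len - 1] += 1
                run_level, run_len = v, 1
    # trim trailing all-zero columns to the longest observed run
    nz = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : nz[-1] + 1] if nz.size else mat[:, :1]


def _grid_lines(shape: tuple[int, int, int], d: tuple[int, int, int]):
    """Enumerate all maximal lattice lines with step d; yields index arrays."""
    d = np.asarray(d)
    starts = []
    nz, ny, nx = shape
    all_idx = np.stack(np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    prev = all_idx - d
    outside = (
        (prev[:, 0] < 0) | (prev[:, 0] >= nz)
        | (prev[:, 1] < 0) | (prev[:, 1] >= ny)
        | (prev[:, 2] < 0) | (prev[:, 2] >= nx)
    )
    for start in all_idx[outside]:
        line = []
        pos = start.copy()
        while (0 <= pos[0] < nz) and (0 <= pos[1] < ny) and (0 <= pos[2] < nx):
            line.append(pos.copy())
            pos += d
        yield np.asarray(line)


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    """16 run-length features under averaged and merged aggregations."""
    n_vox = int((q.levels > 0).sum())
    mats = [glrlm_matrix(q, d) for d in DIRECTIONS_3D]
    per_dir = [
        _rl_zone_feats_padded(m, n_vox, "glrlm", "sre", "lre", "rl") for m in mats
    ]
    out: dict[str, float] = {}
    names = _names_for("glrlm", "sre", "lre", "rl")
    for name in names:
        out[f"{name}_avg"] = float(np.nanmean([f[name] for f in per_dir]))
    nmax = max(m.shape[1] for m in mats)
    merged = np.zeros((q.n_levels, nmax))
    for m in mats:
        merged[:, : m.shape[1]] += m
    mf = _rl_zone_feats_padded(merged, n_vox * len(DIRECTIONS_3D), "glrlm", "sre", "lre", "rl")
    for name in names:
        out[f"{name}_mrg"] = mf[name]
    return out


def _rl_zone_feats_padded(mat, n_vox, prefix, small, large, col):
    return _rl_zone_features(mat, n_vox, prefix, small, large, col)


# ---------------------------------------------------------------------------
# GLSZM / GLDZM
# ---------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=int)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone counts: 26-connected constant-level zones by size."""
    lv = q.levels
    ng = q.n_levels
    zones: list[tuple[int, int]] = []
    for level in range(1, ng + 1):
        labeled, n_zones = ndimage.label(lv == level, structure=_CONN26)
        if n_zones:
            sizes = np.bincount(labeled.ravel())[1:]
            zones += [(level, int(s)) for s in sizes]
    if not zones:
        return np.zeros((ng, 1))
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    return mat


def gldzm_matrix(q: QuantizedROI) -> np.ndarray:
    """Distance-zone counts: zone distance = min city-block distance of the
    zone's voxels to the ROI morphological edge (edge voxels have distance 1)."""
    lv = q.levels
    ng = q.n_levels
    mask = lv > 0
    # pad so the array boundary counts as ROI edge (border voxels = 1)
    dist = ndimage.distance_transform_cdt(np.pad(mask, 1), metric="taxicab")
    dist = dist[1:-1, 1:-1, 1:-1]
    zones: list[tuple[int, int]] = []
    for level in range(1, ng + 1):
        labeled, n_zones = ndimage.label(lv == level, structure=_CONN26)
        for z in range(1, n_zones + 1):
            zones.append((level, int(dist[labeled == z].min())))
    if not zones:
        return np.zeros((ng, 1))
    max_d = max(d for _, d in zones)
    mat = np.zeros((ng, max_d))
    for level, d in zones:
        mat[level - 1, d - 1] += 1
    return mat


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    n_vox = int((q.levels > 0).sum())
    return _rl_zone_feats_padded(glszm_matrix(q), n_vox, "glszm", "sze", "lze", "zs")


def gldzm_features(q: QuantizedROI) -> dict[str, float]:
    n_vox = int((q.levels > 0).sum())
    return _rl_zone_feats_padded(gldzm_matrix(q), n_vox, "gldzm", "sde", "lde", "zd")


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_FEATURES = [
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
]

_COARSENESS_CAP = 1e6


def _neighbor_sums(lv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of in-mask 26-neighbor levels per voxel."""
    mask = (lv > 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    s = ndimage.convolve(lv.astype(float) * mask, kernel, mode="constant", cval=0.0)
    c = ndimage.convolve(mask, kernel, mode="constant", cval=0.0)
    return s, c


def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    lv = q.levels
    ng = q.n_levels
    mask = lv > 0
    n_vox = int(mask.sum())
    nbr_sum, nbr_cnt = _neighbor_sums(lv)
    has_nbr = mask & (nbr_cnt > 0)
    s_i = np.zeros(ng)
    n_i = np.zeros(ng)
    for level in range(1, ng + 1):
        sel = (lv == level) & mask
        n_i[level - 1] = sel.sum()
        sel_n = sel & has_nbr
        if sel_n.any():
            avg = nbr_sum[sel_n] / nbr_cnt[sel_n]
            s_i[level - 1] = np.abs(level - avg).sum()
    p_i = n_i / n_vox
    i = np.arange(1, ng + 1)
    present = p_i > 0
    ngp = int(present.sum())
    out: dict[str, float] = {}
    denom = float((p_i * s_i).sum())
    out["ngtdm_coarseness"] = min(1.0 / denom, _COARSENESS_CAP) if denom > 0 else _COARSENESS_CAP
    if ngp > 1:
        pi_p, i_p = p_i[present], i[present]
        pp = np.outer(pi_p, pi_p)
        didj2 = (i_p[:, None] - i_p[None, :]) ** 2
        out["ngtdm_contrast"] = float(
            (pp * didj2).sum() / (ngp * (ngp - 1)) * s_i.sum() / n_vox
        )
        num_b = float((p_i * s_i).sum())
        den_b = float(np.abs(i_p[:, None] * pi_p[:, None] - i_p[None, :] * pi_p[None, :]).sum())
        out["ngtdm_busyness"] = num_b / den_b if den_b > 0 else 0.0
        si_p = s_i[present]
        combo = (np.abs(i_p[:, None] - i_p[None, :])
                 * (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
                 / (pi_p[:, None] + pi_p[None, :]))
        out["ngtdm_complexity"] = float(combo.sum() / n_vox)
        s_total = float(s_i.sum())
        strength_num = float(((pi_p[:, None] + pi_p[None, :]) * didj2).sum())
        out["ngtdm_strength"] = strength_num / s_total if s_total > 0 else 0.0
    else:
        out["ngtdm_contrast"] = 0.0
        out["ngtdm_busyness"] = 0.0
        out["ngtdm_complexity"] = 0.0
        out["ngtdm_strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

NGLDM_FEATURES = [
    "ngldm_lde", "ngldm_hde", "ngldm_lgce", "ngldm_hgce",
    "ngldm_ldlge", "ngldm_ldhge", "ngldm_hdlge", "ngldm_hdhge",
    "ngldm_glnu", "ngldm_glnu_norm", "ngldm_dcnu", "ngldm_dcnu_norm",
    "ngldm_dc_perc", "ngldm_gl_var", "ngldm_dc_var", "ngldm_dc_entr",
    "ngldm_dc_energy",
]


def ngldm_matrix(q: QuantizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts: per voxel, number of 26-neighbors within alpha
    gray levels; matrix rows = level, cols = dependence count + 1."""
    lv = q.levels
    ng = q.n_levels
    mask = lv > 0
    dep = np.zeros(lv.shape, dtype=int)
    for d in DIRECTIONS_3D:
        for sign in (1, -1):
            off = tuple(sign * c for c in d)
            pairs = _shift_view(lv, off)
            if pairs is None:
                continue
            a_view, b_view, region_a = pairs
            ok = (a_view > 0) & (b_view > 0) & (np.abs(a_view - b_view) <= alpha)
            dep_region = np.zeros_like(a_view)
            dep_region[ok] = 1
            dep[region_a] += dep_region
    max_dep = int(dep[mask].max()) if mask.any() else 0
    mat = np.zeros((ng, max_dep + 1))
    np.add.at(mat, (lv[mask] - 1, dep[mask]), 1)
    return mat


def _shift_view(lv: np.ndarray, d: tuple[int, int, int]):
    sl_a, sl_b = [], []
    for dim, off in zip(lv.shape, d):
        if off >= 0:
            sl_a.append(slice(0, dim - off))
            sl_b.append(slice(off, dim))
        else:
            sl_a.append(slice(-off, dim))
            sl_b.append(slice(0, dim + off))
    a = lv[tuple(sl_a)]
    if a.size == 0:
        return None
    return a, lv[tuple(sl_b)], tuple(sl_a)


def ngldm_features(q: QuantizedROI, alpha: int = 0) -> dict[str, float]:
    """17 neighboring gray-level dependence features."""
    mat = ngldm_matrix(q, alpha=alpha)
    n_vox = int((q.levels > 0).sum())
    names16 = _names_for("ngldm", "lde", "hde", "dc")
    feats = _rl_zone_feats_padded(mat, n_vox, "ngldm", "lde", "hde", "dc")
    # remap the skeleton's generic names onto the NGLDM roster
    mapping = dict(zip(names16, NGLDM_FEATURES[:16]))
    out = {mapping[k]: v for k, v in feats.items()}
    total = mat.sum()
    p = mat / total if total > 0 else mat
    out["ngldm_dc_energy"] = float((p**2).sum()) if total > 0 else float("nan")
    return out
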