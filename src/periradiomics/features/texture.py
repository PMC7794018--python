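"""Texture matrices and their features: GLCM, GLRLM, GLSZM, NGTDM.

All families operate on gray levels discretized to 32 equal-width bins
within the ROI (bins are ROI-relative, so texture is invariant to a global
HU shift).  GLCM and GLRLM are computed in 3D at offset distance 1 voxel
over the 13 unique directions of the 26-neighbourhood, with feature-level
averaging across directions; GLSZM zones use 26-connectivity; NGTDM uses
the 26-neighbourhood mean gray-tone difference.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..datatypes import DegenerateTextureError
from .manifest import GLCM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES

__all__ = [
    "DIRECTIONS_3D",
    "discretize",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "texture_features",
    "NGTDM_COARSENESS_SENTINEL",
]

#: The 13 unique 3D directions (one representative per +/- offset pair).
DIRECTIONS_3D = tuple(
    (a, b, c)
    for a in (0, 1)
    for b in ((-1, 0, 1) if a else (0, 1))
    for c in ((-1, 0, 1) if (a or b) else (1,))
)
assert len(DIRECTIONS_3D) == 13

DEFAULT_N_BINS = 32

#: Documented sentinel for NGTDM coarseness when its denominator is 0
#: (perfectly flat ROI); keeps the feature finite and deterministic.
NGTDM_COARSENESS_SENTINEL = 1e6


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-width discretization of in-ROI intensities to levels 1..n_bins.

    Returns an integer grid that is 0 outside the ROI.  A constant ROI maps
    to level 1 everywhere.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    mask = mask.astype(bool)
    if not mask.any():
        raise DegenerateTextureError("cannot discretize an empty ROI")
    levels = np.zeros(values.shape, dtype=np.int32)
    v = values[mask]
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        levels[mask] = 1
        return levels
    width = (vmax - vmin) / n_bins
    lev = np.floor((v - vmin) / width).astype(np.int32) + 1
    levels[mask] = np.minimum(lev, n_bins)
    return levels


def _shifted(arr: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """arr evaluated at x+d, zero-filled at the border."""
    out = np.zeros_like(arr)
    src = tuple(slice(max(di, 0), arr.shape[a] + min(di, 0)) for a, di in enumerate(d))
    dst = tuple(slice(max(-di, 0), arr.shape[a] + min(-di, 0)) for a, di in enumerate(d))
    out[dst] = arr[src]
    return out


# --------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, direction: tuple[int, int, int], distance: int = 1) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one direction.

    ``levels`` is 0 outside the ROI; only pairs with both voxels in-ROI
    count.  Returns an L x L matrix summing to 1, or all-zeros if the
    direction has no pairs.
    """
    d = tuple(int(distance) * di for di in direction)
    nb = _shifted(levels, d)
    valid = (levels > 0) & (nb > 0)
    L = int(levels.max())
    if not valid.any():
        return np.zeros((L, L))
    a = levels[valid] - 1
    b = nb[valid] - 1
    counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(np.float64)
    counts = counts + counts.T  # symmetrize
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 22 GLCM features of one normalized symmetric matrix."""
    L = P.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    # symmetric matrix: x and y marginals coincide
    diff = np.abs(ii - jj)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=L)[:L]
    k_diff = np.arange(L)
    p_sum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * L + 1)[2 : 2 * L + 1]
    k_sum = np.arange(2, 2 * L + 1)

    nz = P > 0
    ent = float(-(P[nz] * np.log2(P[nz])).sum())
    pd_nz = p_diff[p_diff > 0]
    ps_nz = p_sum[p_sum > 0]
    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())

    pxpy = np.outer(px, px)
    both = nz & (pxpy > 0)
    hxy1 = float(-(P[both] * np.log2(pxpy[both])).sum())
    pp = pxpy[pxpy > 0]
    hxy2 = float(-(pp * np.log2(pp)).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    imc1 = (ent - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))

    corr_num = float((ii * jj * P).sum()) - mu_x * mu_x
    correlation = corr_num / sig_x ** 2 if sig_x > 0 else 1.0

    offdiag = diff > 0
    out = {
        "autocorrelation": float((ii * jj * P).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu_x) ** 4 * P).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu_x) ** 3 * P).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu_x) ** 2 * P).sum()),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": correlation,
        "difference_entropy": float(-(pd_nz * np.log2(pd_nz)).sum()),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "dissimilarity": da,
        "energy": float((P ** 2).sum()),
        "entropy": ent,
        "homogeneity": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((P / (1.0 + ((ii - jj) / L) ** 2)).sum()),
        "inverse_difference": float((P / (1.0 + diff)).sum()),
        "idn": float((P / (1.0 + diff / L)).sum()),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": float((P[offdiag] / diff[offdiag] ** 2).sum()),
        "maximum_probability": float(P.max()),
        "sum_average": sa,
        "sum_entropy": float(-(ps_nz * np.log2(ps_nz)).sum()),
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
    }
    assert set(out) == set(GLCM_NAMES)
    return out


# --------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix for one direction: entry (i, j) counts maximal runs
    of j+1 collinear in-ROI voxels of level i+1.  Shape L x R_max."""
    L = int(levels.max())
    in_roi = levels > 0
    nxt_same = in_roi & (_shifted(levels, direction) == levels)
    neg = tuple(-di for di in direction)
    prev_same = in_roi & (_shifted(levels, neg) == levels)
    starts = in_roi & ~prev_same
    coords = np.argwhere(starts)
    gl = levels[starts]  # argwhere and boolean indexing share C order
    n = len(coords)
    lengths = np.ones(n, dtype=np.int64)
    cur = coords.copy()
    active = np.arange(n)
    dvec = np.asarray(direction)
    while active.size:
        cont = nxt_same[tuple(cur[active].T)]
        active = active[cont]
        cur[active] += dvec
        lengths[active] += 1
    if n == 0:
        return np.zeros((L, 1))
    rmax = int(lengths.max())
    mat = np.zeros((L, rmax), dtype=np.float64)
    np.add.at(mat, (gl - 1, lengths - 1), 1.0)
    return mat


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 13 GLRLM features of one run matrix (levels x run lengths)."""
    nr = R.sum()
    if nr == 0:
        raise DegenerateTextureError("glrlm: no runs in this direction")
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = R / nr
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    ri = R.sum(axis=1)
    rj = R.sum(axis=0)
    out = {
        "short_run_emphasis": float((R / jj ** 2).sum() / nr),
        "long_run_emphasis": float((R * jj ** 2).sum() / nr),
        "gray_level_nonuniformity": float((ri ** 2).sum() / nr),
        "run_length_nonuniformity": float((rj ** 2).sum() / nr),
        "run_percentage": float(nr / n_voxels),
        "low_gray_level_run_emphasis": float((R / ii ** 2).sum() / nr),
        "high_gray_level_run_emphasis": float((R * ii ** 2).sum() / nr),
        "short_run_low_gray_level_emphasis": float((R / (ii ** 2 * jj ** 2)).sum() / nr),
        "short_run_high_gray_level_emphasis": float((R * ii ** 2 / jj ** 2).sum() / nr),
        "long_run_low_gray_level_emphasis": float((R * jj ** 2 / ii ** 2).sum() / nr),
        "long_run_high_gray_level_emphasis": float((R * ii ** 2 * jj ** 2).sum() / nr),
        "gray_level_variance": float(((ii - mu_i) ** 2 * p).sum()),
        "run_length_variance": float(((jj - mu_j) ** 2 * p).sum()),
    }
    assert set(out) == set(GLRLM_NAMES)
    return out


# --------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray) -> np.ndarray:
    """Size-zone matrix: entry (i, j) counts 26-connected zones of level i+1
    with j+1 voxels."""
    L = int(levels.max())
    zone_counts: list[tuple[int, np.ndarray]] = []
    zmax = 1
    for lev in range(1, L + 1):
        labeled, n = ndimage.label(levels == lev, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zone_counts.append((lev, sizes))
        zmax = max(zmax, int(sizes.max()))
    mat = np.zeros((L, zmax), dtype=np.float64)
    for lev, sizes in zone_counts:
        np.add.at(mat, (lev - 1, sizes - 1), 1.0)
    return mat


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = Z.sum()
    if nz == 0:
        raise DegenerateTextureError("glszm: no zones")
    i = np.arange(1, Z.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, Z.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    zi = Z.sum(axis=1)
    zj = Z.sum(axis=0)
    out = {
        "small_area_emphasis": float((Z / jj ** 2).sum() / nz),
        "large_area_emphasis": float((Z * jj ** 2).sum() / nz),
        "gray_level_nonuniformity": float((zi ** 2).sum() / nz),
        "size_zone_nonuniformity": float((zj ** 2).sum() / nz),
        "zone_percentage": float(nz / n_voxels),
    }
    assert set(out) == set(GLSZM_NAMES)
    return out


# --------------------------------------------------------------------------
# NGTDM

def ngtdm_table(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) of the neighbourhood gray-tone difference matrix.

    For every in-ROI voxel with at least one in-ROI 26-neighbour, s_i
    accumulates |i - mean level of its in-ROI neighbours|.  Returns
    (counts, s, n_valid_voxels).
    """
    in_roi = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.correlate(np.where(in_roi, levels, 0).astype(np.float64), kernel,
                                  mode="constant", cval=0.0)
    neigh_cnt = ndimage.correlate(in_roi.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = in_roi & (neigh_cnt > 0)
    if not valid.any():
        raise DegenerateTextureError("ngtdm: no voxel has an in-ROI neighbour")
    L = int(levels.max())
    lev = levels[valid].astype(np.float64)
    diff = np.abs(lev - neigh_sum[valid] / neigh_cnt[valid])
    n_i = np.bincount(levels[valid] - 1, minlength=L).astype(np.float64)
    s_i = np.bincount(levels[valid] - 1, weights=diff, minlength=L)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray, n_valid: int) -> dict[str, float]:
    p = n_i / n_valid
    present = p > 0
    i = np.arange(1, len(p) + 1, dtype=np.float64)
    ngp = int(present.sum())
    pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
    li, lj = np.meshgrid(i[present], i[present], indexing="ij")
    si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")

    denom_coarse = float((p * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else NGTDM_COARSENESS_SENTINEL
    if ngp > 1:
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ngp * (ngp - 1))) * float(s_i.sum() / n_valid)
        busy_den = float(np.abs(li * pi - lj * pj).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_valid)
        strength = float(((pi + pj) * (li - lj) ** 2).sum() / s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    out = {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
    assert set(out) == set(NGTDM_NAMES)
    return out


# --------------------------------------------------------------------------
# per-variant driver

def texture_features(values: np.ndarray, mask: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> dict[str, dict[str, float]]:
    """All 45 texture features (22 GLCM + 13 GLRLM + 5 GLSZM + 5 NGTDM) of
    one image variant restricted to ``mask``.  GLCM/GLRLM are averaged over
    the 13 directions at the feature level; directions with no voxel pairs
    are skipped."""
    mask = np.asarray(mask, dtype=bool)
    if mask.any():  # crop to the ROI bounding box; texture only sees in-ROI voxels
        bbox = tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in np.nonzero(mask))
        values, mask = values[bbox], mask[bbox]
    levels = discretize(values, mask, n_bins)
    n_vox = int((levels > 0).sum())

    glcm_acc: list[dict[str, float]] = []
    glrlm_acc: list[dict[str, float]] = []
    for d in DIRECTIONS_3D:
        P = glcm_matrix(levels, d)
        if P.sum() > 0:
            glcm_acc.append(glcm_features(P))
        R = glrlm_matrix(levels, d)
        if R.sum() > 0:
            glrlm_acc.append(glrlm_features(R, n_vox))
    if not glcm_acc:
        raise DegenerateTextureError("glcm: no co-occurring voxel pairs in any direction")

    def _avg(dicts: list[dict[str, float]], names) -> dict[str, float]:
        return {k: float(np.mean([d[k] for d in dicts])) for k in names}

    return {
        "glcm": _avg(glcm_acc, GLCM_NAMES),
        "glrlm": _avg(glrlm_acc, GLRLM_NAMES),
        "glszm": glszm_features(glszm_matrix(levels), n_vox),
        "ngtdm": ngtdm_features(*ngtdm_table(levels)),
    }
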