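"""Grey-level texture-matrix features.

All matrices are built in 3D on the discretised grey-level volume (integer
levels >= 1 inside the intensity mask, 0 outside).  Conventions:

* GLCM — distance 1 (Chebyshev), symmetric; one matrix per each of the 13
  unique 26-neighbourhood directions, features averaged over directions.
* GLRLM — runs along the same 13 directions, features averaged.
* GLSZM — zones are 26-connected components of equal grey level; one matrix.
* GLDZM — zone distance is the minimum (city-block) distance of any zone
  voxel to the edge of the *morphological* mask, with edge voxels at
  distance 1; one matrix.
* NGTDM / NGLDM — 26-connected neighbourhood at Chebyshev distance 1; the
  NGLDM coarseness parameter α = 0 (neighbours count as dependent when their
  level is exactly equal) and the dependence-count column index is the
  dependent-neighbour count + 1.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "run_length_matrix",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngtdm_features",
    "ngldm_features",
]

DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and ((dy > 0) or (dy == 0 and dz > 0)))
)
# 13 unique antipodal-pair representatives of the 26-neighbourhood.
assert len(DIRECTIONS_13) == 13

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _pair_views(vol: np.ndarray, d: tuple[int, int, int]):
    """Aligned views (a, b) with b displaced by d relative to a."""
    sl_a, sl_b = [], []
    for axis, step in enumerate(d):
        n = vol.shape[axis]
        if step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        elif step == -1:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    return vol[tuple(sl_a)], vol[tuple(sl_b)]


def glcm_matrix(levels: np.ndarray, n_levels: int, d: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction."""
    a, b = _pair_views(levels, d)
    valid = (a > 0) & (b > 0)
    av, bv = a[valid], b[valid]
    m = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(m, (av - 1, bv - 1), 1.0)
    return m + m.T


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # symmetric: row marginal == column marginal
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())

    diff = np.abs(ii - jj)
    ssum = ii + jj
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[ssum == k].sum() for k in k_sum])

    nz = p[p > 0]
    out: dict[str, float] = {}
    out["joint_max"] = float(p.max())
    out["joint_average"] = float((ii * p).sum())
    out["joint_variance"] = float((((ii - out["joint_average"]) ** 2) * p).sum())
    out["joint_entropy"] = float(-(nz * np.log2(nz)).sum())
    da = float((k_diff * p_diff).sum())
    out["difference_average"] = da
    out["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    out["difference_entropy"] = float(-(nzd * np.log2(nzd)).sum())
    sa = float((k_sum * p_sum).sum())
    out["sum_average"] = sa
    out["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    out["sum_entropy"] = float(-(nzs * np.log2(nzs)).sum())
    out["angular_second_moment"] = float((p**2).sum())
    out["contrast"] = float((diff**2 * p).sum())
    out["dissimilarity"] = float((diff * p).sum())
    out["inverse_difference"] = float((p / (1.0 + diff)).sum())
    out["inverse_difference_normalised"] = float((p / (1.0 + diff / ng)).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + diff**2)).sum())
    out["inverse_difference_moment_normalised"] = float((p / (1.0 + (diff / ng) ** 2)).sum())
    off = diff > 0
    out["inverse_variance"] = float((p[off] / diff[off] ** 2).sum()) if off.any() else 0.0
    if var > 0:
        out["correlation"] = float(((ii - mu) * (jj - mu) * p).sum()) / var
    else:
        out["correlation"] = 1.0  # single grey level: perfectly correlated limit
    out["autocorrelation"] = float((ii * jj * p).sum())
    ct = (ii + jj - 2 * mu)
    out["cluster_tendency"] = float((ct**2 * p).sum())
    out["cluster_shade"] = float((ct**3 * p).sum())
    out["cluster_prominence"] = float((ct**4 * p).sum())

    hxy = out["joint_entropy"]
    pp = np.outer(pi, pi)
    with np.errstate(divide="ignore"):
        log_pp = np.where(pp > 0, np.log2(np.where(pp > 0, pp, 1.0)), 0.0)
    hxy1 = float(-(p * log_pp).sum())
    hxy2 = float(-(pp * log_pp).sum())
    hx = float(-(pi[pi > 0] * np.log2(pi[pi > 0])).sum())
    out["info_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy))
    out["info_correlation_2"] = math.sqrt(arg) if arg > 0 else 0.0
    return out


def glcm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLCM features averaged over the 13 directions (feature-wise)."""
    per_dir: list[dict[str, float]] = []
    for d in DIRECTIONS_13:
        m = glcm_matrix(levels, n_levels, d)
        s = m.sum()
        if s == 0:
            continue
        per_dir.append(_glcm_features_single(m / s))
    if not per_dir:
        raise ValueError("no co-occurrence pairs (ROI too small)")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# Run-length
# ---------------------------------------------------------------------------

def run_length_matrix(levels: np.ndarray, n_levels: int, d: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix r[i-1, l-1] for one direction.

    Runs are maximal sequences of voxels with equal non-zero level stepping by
    d; voxels outside the mask (level 0) break runs.  Vectorised by sorting
    in-mask voxels on (line id, position along the line).
    """
    coords = np.argwhere(levels > 0)
    if len(coords) == 0:
        return np.zeros((n_levels, 1), dtype=float)
    vals = levels[coords[:, 0], coords[:, 1], coords[:, 2]]
    dv = np.asarray(d)
    axis = int(np.nonzero(dv)[0][0])
    t = coords[:, axis] * dv[axis]
    line = coords - t[:, None] * dv
    # Encode line id into a single integer for sorting.  Line components lie
    # in [-max_n, 2*max_n] so use a base wide enough to avoid collisions.
    max_n = int(max(levels.shape))
    base = 4 * max_n + 4
    off = max_n + 1
    enc = ((line[:, 0] + off) * base + (line[:, 1] + off)) * base + (line[:, 2] + off)
    order = np.lexsort((t, enc))
    enc_s, t_s, v_s = enc[order], t[order], vals[order]
    # New run starts where the line changes, the step is non-adjacent, or the
    # level changes.
    new_run = np.ones(len(order), dtype=bool)
    if len(order) > 1:
        new_run[1:] = (
            (enc_s[1:] != enc_s[:-1]) | (t_s[1:] != t_s[:-1] + 1) | (v_s[1:] != v_s[:-1])
        )
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(order)))
    run_vals = v_s[starts]
    max_len = int(lengths.max())
    m = np.zeros((n_levels, max_len), dtype=float)
    np.add.at(m, (run_vals - 1, lengths - 1), 1.0)
    return m


def _series_features(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 shared features of run/zone/distance/dependence matrices.

    ``m[i-1, j-1]`` counts grey level i against the series quantity j (run
    length, zone size, zone distance or dependence count).  Returned under
    generic keys; families rename them.
    """
    ns = m.sum()
    if ns == 0:
        raise ValueError("empty matrix")
    ng, nj = m.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    gi = m.sum(axis=1)
    rj = m.sum(axis=0)
    p = m / ns
    mu_i = float((i * gi).sum() / ns)
    mu_j = float((j * rj).sum() / ns)
    nz = p[p > 0]
    out = {
        "sje": float((rj / j**2).sum() / ns),
        "lje": float((rj * j**2).sum() / ns),
        "lge": float((gi / i**2).sum() / ns),
        "hge": float((gi * i**2).sum() / ns),
        "sjlge": float((m / np.outer(i**2, j**2)).sum() / ns),
        "sjhge": float((m * np.outer(i**2, 1.0 / j**2)).sum() / ns),
        "ljlge": float((m * np.outer(1.0 / i**2, j**2)).sum() / ns),
        "ljhge": float((m * np.outer(i**2, j**2)).sum() / ns),
        "glnu": float((gi**2).sum() / ns),
        "glnun": float((gi**2).sum() / ns**2),
        "jnu": float((rj**2).sum() / ns),
        "jnun": float((rj**2).sum() / ns**2),
        "percentage": float(ns / n_voxels),
        "glvar": float((((i - mu_i)[:, None]) ** 2 * p).sum()),
        "jvar": float((((j - mu_j)[None, :]) ** 2 * p).sum()),
        "jentropy": float(-(nz * np.log2(nz)).sum()),
        "jenergy": float((nz**2).sum()),
    }
    return out


_RLM_RENAME = {
    "sje": "short_run_emphasis", "lje": "long_run_emphasis",
    "lge": "low_grey_level_run_emphasis", "hge": "high_grey_level_run_emphasis",
    "sjlge": "short_run_low_grey_level_emphasis",
    "sjhge": "short_run_high_grey_level_emphasis",
    "ljlge": "long_run_low_grey_level_emphasis",
    "ljhge": "long_run_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnun": "grey_level_non_uniformity_normalised",
    "jnu": "run_length_non_uniformity", "jnun": "run_length_non_uniformity_normalised",
    "percentage": "run_percentage", "glvar": "grey_level_variance",
    "jvar": "run_length_variance", "jentropy": "run_entropy",
}

_SZM_RENAME = {
    "sje": "small_zone_emphasis", "lje": "large_zone_emphasis",
    "lge": "low_grey_level_zone_emphasis", "hge": "high_grey_level_zone_emphasis",
    "sjlge": "small_zone_low_grey_level_emphasis",
    "sjhge": "small_zone_high_grey_level_emphasis",
    "ljlge": "large_zone_low_grey_level_emphasis",
    "ljhge": "large_zone_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnun": "grey_level_non_uniformity_normalised",
    "jnu": "zone_size_non_uniformity", "jnun": "zone_size_non_uniformity_normalised",
    "percentage": "zone_percentage", "glvar": "grey_level_variance",
    "jvar": "zone_size_variance", "jentropy": "zone_size_entropy",
}

_DZM_RENAME = {
    "sje": "small_distance_emphasis", "lje": "large_distance_emphasis",
    "lge": "low_grey_level_zone_emphasis", "hge": "high_grey_level_zone_emphasis",
    "sjlge": "small_distance_low_grey_level_emphasis",
    "sjhge": "small_distance_high_grey_level_emphasis",
    "ljlge": "large_distance_low_grey_level_emphasis",
    "ljhge": "large_distance_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnun": "grey_level_non_uniformity_normalised",
    "jnu": "zone_distance_non_uniformity", "jnun": "zone_distance_non_uniformity_normalised",
    "percentage": "zone_percentage", "glvar": "grey_level_variance",
    "jvar": "zone_distance_variance", "jentropy": "zone_distance_entropy",
}

_NGLDM_RENAME = {
    "sje": "low_dependence_emphasis", "lje": "high_dependence_emphasis",
    "lge": "low_grey_level_count_emphasis", "hge": "high_grey_level_count_emphasis",
    "sjlge": "low_dependence_low_grey_level_emphasis",
    "sjhge": "low_dependence_high_grey_level_emphasis",
    "ljlge": "high_dependence_low_grey_level_emphasis",
    "ljhge": "high_dependence_high_grey_level_emphasis",
    "glnu": "grey_level_non_uniformity", "glnun": "grey_level_non_uniformity_normalised",
    "jnu": "dependence_count_non_uniformity",
    "jnun": "dependence_count_non_uniformity_normalised",
    "percentage": "dependence_count_percentage", "glvar": "grey_level_variance",
    "jvar": "dependence_count_variance", "jentropy": "dependence_count_entropy",
    "jenergy": "dependence_count_energy",
}


def _rename(raw: dict[str, float], table: dict[str, str]) -> dict[str, float]:
    return {table[k]: v for k, v in raw.items() if k in table}


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLRLM features averaged over the 13 directions (feature-wise)."""
    nv = int((levels > 0).sum())
    per_dir = []
    for d in DIRECTIONS_13:
        m = run_length_matrix(levels, n_levels, d)
        if m.sum() == 0:
            continue
        per_dir.append(_rename(_series_features(m, nv), _RLM_RENAME))
    if not per_dir:
        raise ValueError("no runs (empty mask)")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _zones(levels: np.ndarray, n_levels: int):
    """Yield (grey level, zone-voxel indices) for 26-connected zones."""
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, nlab = ndimage.label(binary, structure=_STRUCT_26)
        objs = ndimage.find_objects(lab)
        for z in range(1, nlab + 1):
            sl = objs[z - 1]
            where = np.argwhere(lab[sl] == z) + np.array([s.start for s in sl])
            yield g, where


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    nv = int((levels > 0).sum())
    entries = [(g, len(w)) for g, w in _zones(levels, n_levels)]
    if not entries:
        raise ValueError("no zones (empty mask)")
    max_size = max(s for _, s in entries)
    m = np.zeros((n_levels, max_size), dtype=float)
    for g, s in entries:
        m[g - 1, s - 1] += 1.0
    return _rename(_series_features(m, nv), _SZM_RENAME)


def gldzm_features(
    levels: np.ndarray, n_levels: int, morph_mask: np.ndarray
) -> dict[str, float]:
    """Grey-level distance-zone features.

    ``morph_mask`` is the morphological mask on the same crop; the distance
    map counts city-block steps to outside the mask, with mask-border voxels
    (and voxels on the padded array edge) at distance 1.
    """
    nv = int((levels > 0).sum())
    dmap = ndimage.distance_transform_cdt(
        np.pad(morph_mask, 1), metric="taxicab"
    )[1:-1, 1:-1, 1:-1]
    entries = []
    for g, where in _zones(levels, n_levels):
        dz = int(dmap[where[:, 0], where[:, 1], where[:, 2]].min())
        entries.append((g, max(dz, 1)))
    if not entries:
        raise ValueError("no zones (empty mask)")
    max_d = max(d for _, d in entries)
    m = np.zeros((n_levels, max_d), dtype=float)
    for g, d in entries:
        m[g - 1, d - 1] += 1.0
    return _rename(_series_features(m, nv), _DZM_RENAME)


# ---------------------------------------------------------------------------
# Neighbourhood families
# ---------------------------------------------------------------------------

_KERNEL_26 = np.ones((3, 3, 3), dtype=float)
_KERNEL_26[1, 1, 1] = 0.0


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Neighbourhood grey tone difference features (26-neighbourhood)."""
    mask = levels > 0
    lv = levels.astype(float) * mask
    nb_sum = ndimage.convolve(lv, _KERNEL_26, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(float), _KERNEL_26, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no voxel has in-mask neighbours")
    a = nb_sum[valid] / nb_cnt[valid]
    g = levels[valid]
    n = g.size
    s = np.zeros(n_levels + 1)
    np.add.at(s, g, np.abs(g - a))
    cnt = np.bincount(g, minlength=n_levels + 1).astype(float)
    p = cnt / n
    i = np.arange(n_levels + 1, dtype=float)
    present = p > 0
    ngp = int(present[1:].sum())

    out: dict[str, float] = {}
    denom = float((p * s).sum())
    out["coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        pi, pj = np.meshgrid(p[1:], p[1:], indexing="ij")
        ii, jj = np.meshgrid(i[1:], i[1:], indexing="ij")
        out["contrast"] = (
            float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1))
        ) * (float(s.sum()) / n)
    else:
        out["contrast"] = 0.0
    ipi = i * p
    num_b = float((p * s).sum())
    den_b = float(np.abs(ipi[present][:, None] - ipi[present][None, :]).sum())
    out["busyness"] = num_b / den_b if den_b > 0 else 0.0
    if ngp >= 1:
        idx = np.flatnonzero(present)
        pi = p[idx][:, None]
        pj = p[idx][None, :]
        si = s[idx][:, None]
        sj = s[idx][None, :]
        ii = i[idx][:, None]
        jj = i[idx][None, :]
        out["complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()
        ) / n
        ssum = float(s.sum())
        out["strength"] = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / ssum if ssum > 0 else 0.0
        )
    return out


def ngldm_features(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    """Neighbouring grey level dependence features.

    A neighbour is dependent when its level differs from the centre by at
    most ``alpha`` (default 0).  The matrix column is the dependence count
    plus one, so columns are 1-based like run lengths.
    """
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _pair_views(levels, d)
        am, bm = _pair_views(mask, d)
        hit = am & bm & (np.abs(a.astype(int) - b.astype(int)) <= alpha)
        da, db = _pair_views(dep, d)
        da += hit
        db += hit
    j = dep[mask] + 1
    g = levels[mask]
    m = np.zeros((n_levels, 27 + 1), dtype=float)
    np.add.at(m, (g - 1, j - 1), 1.0)
    m = m[:, : int(j.max())]
    return _rename(_series_features(m, int(mask.sum())), _NGLDM_RENAME)
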