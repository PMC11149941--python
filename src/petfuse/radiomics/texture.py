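"""3D texture features from the six matrix families: 136 in total.

Breakdown: GLCM 25 x {direction-averaged, direction-merged},
GLRLM 16 x {averaged, merged}, GLSZM 16, GLDZM 16, NGTDM 5, NGLDM 17.

Degenerate single-level ROIs follow fixed conventions (entropy 0,
correlation 0); no feature is ever non-finite. For the NGLDM the matrix
column index is the raw number of dependent neighbors (0 for an isolated
voxel); feature weights use the dependence count k = j + 1 so that
inverse-square weights stay defined.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI
from .matrices import (
    DIRECTIONS_13,
    TextureMatrix,
    glcm_matrix,
    gldzm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_matrix,
)

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngtdm_features",
    "ngldm_features",
    "texture_features",
    "N_TEXTURE",
]

N_TEXTURE = 136
_EPS = 1e-30


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM (25)


_GLCM_NAMES = (
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_normalised", "inverse_difference_moment",
    "inverse_difference_moment_normalised", "inverse_variance", "correlation",
    "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "information_correlation_1", "information_correlation_2",
)


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total <= 0:
        # ROI with no voxel pairs (e.g. a single voxel): degenerate convention
        return {name: 0.0 for name in _GLCM_NAMES}
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None] * np.ones((1, ng))
    j = i.T

    px = p.sum(axis=1)
    mu = float((i * p).sum())  # == joint average of either margin (symmetric)
    mux = float((np.arange(1, ng + 1) * px).sum())
    sigx = float(np.sqrt(((np.arange(1, ng + 1) - mux) ** 2 * px).sum()))

    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in k_diff])
    da = float((k_diff * p_diff).sum())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(i + j) == k].sum() for k in k_sum])
    sa = float((k_sum * p_sum).sum())

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    corr = 0.0
    if sigx > 0:
        corr = float(((i - mux) * (j - mux) * p).sum()) / sigx**2

    off = np.abs(i - j) > 0
    f = {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": float(((i - mu) ** 2 * p).sum()),
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": _entropy2(p_diff),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": _entropy2(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(i - j))).sum()),
        "inverse_difference_normalised": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (i - j) ** 2)).sum()),
        "inverse_difference_moment_normalised": float((p / (1.0 + (i - j) ** 2 / ng**2)).sum()),
        "inverse_variance": float((p[off] / (i - j)[off] ** 2).sum()),
        "correlation": corr,
        "autocorrelation": float((i * j * p).sum()),
        "cluster_tendency": float(((i + j - 2 * mux) ** 2 * p).sum()),
        "cluster_shade": float(((i + j - 2 * mux) ** 3 * p).sum()),
        "cluster_prominence": float(((i + j - 2 * mux) ** 4 * p).sum()),
        "information_correlation_1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "information_correlation_2": float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0))),
    }
    return f


# ---------------------------------------------------------------------------
# run/zone/distance family: shared 16-feature template


def _rlm_style_features(
    mat: np.ndarray, n_voxels: int, names: tuple[str, ...], runs_denominator: int
) -> dict[str, float]:
    ns = mat.sum()
    if ns <= 0:
        return {name: 0.0 for name in names}
    p = mat / ns
    ng, nr = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    jv = np.arange(1, nr + 1)[None, :]
    ri = mat.sum(axis=1)  # per gray level
    rj = mat.sum(axis=0)  # per second index
    mu_i = float((i * p).sum())
    mu_j = float((jv * p).sum())
    vals = [
        float((p / jv**2).sum()),
        float((p * jv**2).sum()),
        float((p / i**2).sum()),
        float((p * i**2).sum()),
        float((p / (i**2 * jv**2)).sum()),
        float((p * i**2 / jv**2).sum()),
        float((p * jv**2 / i**2).sum()),
        float((p * i**2 * jv**2).sum()),
        float((ri**2).sum() / ns),
        float((ri**2).sum() / ns**2),
        float((rj**2).sum() / ns),
        float((rj**2).sum() / ns**2),
        float(ns / max(n_voxels * runs_denominator, 1)),
        float(((i - mu_i) ** 2 * p).sum()),
        float(((jv - mu_j) ** 2 * p).sum()),
        _entropy2(p.ravel()),
    ]
    return dict(zip(names, vals))


_GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_nonuniformity",
    "grey_level_nonuniformity_normalised",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalised",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
)

_GLSZM_NAMES = tuple(
    n.replace("run_length", "zone_size").replace("run", "zone") for n in _GLRLM_NAMES
)
_GLDZM_NAMES = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis",
    "grey_level_nonuniformity",
    "grey_level_nonuniformity_normalised",
    "zone_distance_nonuniformity",
    "zone_distance_nonuniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_distance_variance",
    "zone_distance_entropy",
)


def glrlm_features(mat: np.ndarray, n_voxels: int, n_directions: int = 1) -> dict[str, float]:
    return _rlm_style_features(mat, n_voxels, _GLRLM_NAMES, n_directions)


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rlm_style_features(mat, n_voxels, _GLSZM_NAMES, 1)


def gldzm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rlm_style_features(mat, n_voxels, _GLDZM_NAMES, 1)


# ---------------------------------------------------------------------------
# NGTDM (5)


def ngtdm_features(mat: np.ndarray) -> dict[str, float]:
    n_i = mat[:, 0]
    s_i = mat[:, 1]
    n = n_i.sum()
    if n <= 0:
        # no voxel has an in-mask neighbor: degenerate convention
        return {"coarseness": 0.0, "contrast": 0.0, "busyness": 0.0, "complexity": 0.0, "strength": 0.0}
    p_i = n_i / n
    present = p_i > 0
    ngp = int(present.sum())
    levels = np.arange(1, mat.shape[0] + 1, dtype=np.float64)

    coarse_den = float((p_i * s_i).sum())
    coarseness = min(1.0 / coarse_den, 1e6) if coarse_den > 0 else 1e6

    contrast = 0.0
    busyness = 0.0
    complexity = 0.0
    strength = 0.0
    if ngp > 1:
        ii = levels[present][:, None]
        jj = levels[present][None, :]
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * float(s_i.sum()) / n
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / n
        s_sum = float(s_i.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# NGLDM (17)


def ngldm_features(mat: np.ndarray) -> dict[str, float]:
    ns = mat.sum()
    if ns <= 0:
        raise ValueError("empty dependence matrix")
    p = mat / ns
    ng, nd = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    k = np.arange(1, nd + 1)[None, :]  # dependence count = neighbors + 1
    si = mat.sum(axis=1)
    sj = mat.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_k = float((k * p).sum())
    return {
        "low_dependence_emphasis": float((p / k**2).sum()),
        "high_dependence_emphasis": float((p * k**2).sum()),
        "low_grey_level_count_emphasis": float((p / i**2).sum()),
        "high_grey_level_count_emphasis": float((p * i**2).sum()),
        "low_dependence_low_grey_level_emphasis": float((p / (i**2 * k**2)).sum()),
        "low_dependence_high_grey_level_emphasis": float((p * i**2 / k**2).sum()),
        "high_dependence_low_grey_level_emphasis": float((p * k**2 / i**2).sum()),
        "high_dependence_high_grey_level_emphasis": float((p * i**2 * k**2).sum()),
        "grey_level_nonuniformity": float((si**2).sum() / ns),
        "grey_level_nonuniformity_normalised": float((si**2).sum() / ns**2),
        "dependence_count_nonuniformity": float((sj**2).sum() / ns),
        "dependence_count_nonuniformity_normalised": float((sj**2).sum() / ns**2),
        "dependence_count_percentage": 1.0,  # all voxels have a defined neighborhood
        "grey_level_variance": float(((i - mu_i) ** 2 * p).sum()),
        "dependence_count_variance": float(((k - mu_k) ** 2 * p).sum()),
        "dependence_count_entropy": _entropy2(p.ravel()),
        "dependence_count_energy": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# assembly


def _pad_to(mat: np.ndarray, ncols: int) -> np.ndarray:
    if mat.shape[1] >= ncols:
        return mat
    out = np.zeros((mat.shape[0], ncols))
    out[:, : mat.shape[1]] = mat
    return out


def texture_features(disc: DiscretizedROI, delta: int = 1, alpha: int = 0) -> dict[str, float]:
    """All 136 texture features with stable names and ordering."""
    nv = disc.n_voxels
    out: dict[str, float] = {}

    # GLCM: averaged over the 13 directions, and merged
    per_dir = []
    merged = None
    for d in DIRECTIONS_13:
        c = glcm_matrix(disc, d, delta).matrix
        per_dir.append(glcm_features(c))
        merged = c if merged is None else merged + c
    for name in per_dir[0]:
        out[f"glcm_{name}_avg"] = float(np.mean([f[name] for f in per_dir]))
    for name, val in glcm_features(merged).items():
        out[f"glcm_{name}_mrg"] = val

    # GLRLM: averaged and merged
    per_dir = []
    rl_merged = None
    ncols = 0
    mats = []
    for d in DIRECTIONS_13:
        m = glrlm_matrix(disc, d).matrix
        mats.append(m)
        ncols = max(ncols, m.shape[1])
    for m in mats:
        per_dir.append(glrlm_features(m, nv, 1))
        mp = _pad_to(m, ncols)
        rl_merged = mp if rl_merged is None else rl_merged + mp
    for name in per_dir[0]:
        out[f"glrlm_{name}_avg"] = float(np.mean([f[name] for f in per_dir]))
    for name, val in glrlm_features(rl_merged, nv, len(DIRECTIONS_13)).items():
        out[f"glrlm_{name}_mrg"] = val

    for name, val in glszm_features(glszm_matrix(disc).matrix, nv).items():
        out[f"glszm_{name}"] = val
    for name, val in gldzm_features(gldzm_matrix(disc).matrix, nv).items():
        out[f"gldzm_{name}"] = val
    for name, val in ngtdm_features(ngtdm_matrix(disc).matrix).items():
        out[f"ngtdm_{name}"] = val
    for name, val in ngldm_features(ngldm_matrix(disc, alpha=alpha, delta=delta).matrix).items():
        out[f"ngldm_{name}"] = val

    assert len(out) == N_TEXTURE, f"expected {N_TEXTURE} texture features, got {len(out)}"
    return out
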