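"""The six 3D texture-matrix builders.

All builders operate on a :class:`DiscretizedROI` (levels 1..Ng inside the
mask, 0 outside) and return a :class:`TextureMatrix` of raw counts:

- GLCM: symmetric gray-level co-occurrence counts at Chebyshev distance
  delta along one of the 13 unique 3D directions.
- GLRLM: gray-level run lengths along a direction.
- GLSZM: gray-level zone sizes, zones being 26-connected components of
  equal gray level.
- GLDZM: gray level x zone distance, the distance of a zone being the
  minimum over its voxels of the city-block distance to the ROI edge
  (border voxels have distance 1; the array boundary counts as edge).
- NGLDM: gray level x dependence count; a neighbor with level j is
  dependent on a center with level i when ``|i - j| <= alpha``; the count
  column is the raw number of dependent neighbors in the 26-neighborhood
  (0 for an isolated voxel). Entries sum to the number of in-mask voxels.
- NGTDM: per gray level i, the count ``n_i`` of contributing voxels and
  the summed absolute difference ``s_i`` between i and the mean level of
  each voxel's in-mask 26-neighbors; stored as an (Ng, 2) matrix with
  columns (n_i, s_i).

Vectorized with array shifts; an exhaustive nested-loop enumeration of the
same definitions lives in the test suite as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "TextureMatrix",
    "DIRECTIONS_13",
    "NEIGHBORS_26",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldzm_matrix",
    "ngldm_matrix",
    "ngtdm_matrix",
]

# 13 unique 3D directions: one of each antiparallel pair of the 26 neighbors
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

NEIGHBORS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class TextureMatrix:
    """A non-negative count matrix indexed by gray level and a second index."""

    family: str
    matrix: np.ndarray
    params: dict = field(default_factory=dict)


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = arr[v + offset], with ``fill`` where v+offset leaves the grid."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for ax, o in enumerate(offset):
        n = arr.shape[ax]
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glcm_matrix(disc: DiscretizedROI, direction: tuple[int, int, int], delta: int = 1) -> TextureMatrix:
    """Symmetric co-occurrence counts at ``delta`` steps along ``direction``."""
    if tuple(direction) not in DIRECTIONS_13 and tuple(-d for d in direction) not in DIRECTIONS_13:
        raise ValueError(f"invalid 3D direction {direction}; expected a unit 26-neighbor offset")
    ng = disc.n_levels
    offset = tuple(int(d) * delta for d in direction)
    a = disc.levels
    b = _shift(disc.levels, offset)
    valid = (a > 0) & (b > 0)
    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T  # symmetrize: count each pair in both orders
    return TextureMatrix("GLCM", counts, {"direction": tuple(direction), "delta": delta})


def glrlm_matrix(disc: DiscretizedROI, direction: tuple[int, int, int]) -> TextureMatrix:
    """Run-length counts along ``direction``; columns are run lengths 1..L."""
    if tuple(direction) not in DIRECTIONS_13 and tuple(-d for d in direction) not in DIRECTIONS_13:
        raise ValueError(f"invalid 3D direction {direction}; expected a unit 26-neighbor offset")
    lev = disc.levels
    d = tuple(int(x) for x in direction)
    back = tuple(-x for x in d)
    prev = _shift(lev, back)
    starts = (lev > 0) & (prev != lev)

    max_len = int(np.ceil(np.sqrt(sum((s * abs(o)) ** 2 for s, o in zip(lev.shape, d))))) + 1
    # run length per start voxel: keep stepping while the level repeats
    run_len = np.zeros(lev.shape, dtype=np.int64)
    active = starts.copy()
    k = 0
    while active.any() and k < max_len:
        run_len[active] += 1
        k += 1
        ahead = _shift(lev, tuple(x * k for x in d))
        active = active & (ahead == lev) & (lev > 0)

    ng = disc.n_levels
    lmax = int(run_len.max()) if run_len.any() else 1
    mat = np.zeros((ng, lmax), dtype=np.float64)
    sel = starts & (run_len > 0)
    np.add.at(mat, (lev[sel] - 1, run_len[sel] - 1), 1.0)
    return TextureMatrix("GLRLM", mat, {"direction": d})


def _zone_labels(disc: DiscretizedROI):
    """Yield (gray_level, zone_voxel_index_arrays) for every 26-connected zone."""
    for g in range(1, disc.n_levels + 1):
        comp = disc.levels == g
        if not comp.any():
            continue
        labels, n = ndimage.label(comp, structure=_STRUCT_26)
        if n == 0:
            continue
        yield g, labels, n


def glszm_matrix(disc: DiscretizedROI) -> TextureMatrix:
    """Zone-size counts: 26-connected equal-level zones, columns sizes 1..S."""
    ng = disc.n_levels
    entries: list[tuple[int, int]] = []
    smax = 1
    for g, labels, n in _zone_labels(disc):
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            entries.append((g, int(s)))
            smax = max(smax, int(s))
    mat = np.zeros((ng, smax), dtype=np.float64)
    for g, s in entries:
        mat[g - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", mat, {"connectivity": 26})


def roi_distance_map(mask: np.ndarray) -> np.ndarray:
    """City-block distance of each in-mask voxel to the ROI edge (border = 1)."""
    padded = np.pad(mask, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[1:-1, 1:-1, 1:-1]


def gldzm_matrix(disc: DiscretizedROI) -> TextureMatrix:
    """Gray level x zone distance counts (minimum city-block edge distance)."""
    ng = disc.n_levels
    dist = roi_distance_map(disc.mask)
    entries: list[tuple[int, int]] = []
    dmax = 1
    for g, labels, n in _zone_labels(disc):
        mins = ndimage.minimum(dist, labels, index=np.arange(1, n + 1))
        for d in np.atleast_1d(mins):
            entries.append((g, int(d)))
            dmax = max(dmax, int(d))
    mat = np.zeros((ng, dmax), dtype=np.float64)
    for g, d in entries:
        mat[g - 1, d - 1] += 1.0
    return TextureMatrix("GLDZM", mat, {"connectivity": 26, "distance": "city-block"})


def ngldm_matrix(disc: DiscretizedROI, alpha: int = 0, delta: int = 1) -> TextureMatrix:
    """Gray level x dependence count; entries sum to the in-mask voxel count."""
    if delta != 1:
        raise ValueError("only the Chebyshev distance-1 (26-voxel) neighborhood is supported")
    lev = disc.levels
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in NEIGHBORS_26:
        nb = _shift(lev, off)
        dep += ((nb > 0) & (np.abs(nb - lev) <= alpha)).astype(np.int64)
    ng = disc.n_levels
    mat = np.zeros((ng, len(NEIGHBORS_26) + 1), dtype=np.float64)
    sel = disc.mask
    np.add.at(mat, (lev[sel] - 1, dep[sel]), 1.0)
    return TextureMatrix("NGLDM", mat, {"alpha": alpha, "delta": delta})


def ngtdm_matrix(disc: DiscretizedROI) -> TextureMatrix:
    """Counts n_i and summed neighborhood-difference s_i per gray level.

    Every in-mask voxel with at least one in-mask 26-neighbor contributes
    ``|i - A|`` to its level's s_i, where A is the mean level of its in-mask
    neighbors.
    """
    lev = disc.levels.astype(np.float64)
    nsum = np.zeros(lev.shape)
    ncnt = np.zeros(lev.shape)
    for off in NEIGHBORS_26:
        nb = _shift(disc.levels, off)
        nsum += nb
        ncnt += nb > 0
    valid = disc.mask & (ncnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.where(valid, np.abs(lev - nsum / np.maximum(ncnt, 1)), 0.0)
    ng = disc.n_levels
    mat = np.zeros((ng, 2), dtype=np.float64)
    idx = disc.levels[valid] - 1
    np.add.at(mat[:, 0], idx, 1.0)
    np.add.at(mat[:, 1], idx, diff[valid])
    return TextureMatrix("NGTDM", mat, {"delta": 1})
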