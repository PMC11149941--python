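"""Independent brute-force oracles for the test suite.

Deliberately naive nested-loop enumerations of the texture-matrix
definitions, a closed-form scalar GLM, dense-kernel convolution and
trilinear interpolation. These never share code with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def bf_glcm(levels: np.ndarray, direction, delta: int = 1) -> np.ndarray:
    ng = int(levels.max())
    out = np.zeros((ng, ng))
    off = tuple(d * delta for d in direction)
    for v in np.ndindex(levels.shape):
        i = levels[v]
        if i == 0:
            continue
        w = tuple(v[a] + off[a] for a in range(3))
        if _in(levels.shape, w) and levels[w] > 0:
            j = levels[w]
            out[i - 1, j - 1] += 1
            out[j - 1, i - 1] += 1
    return out


def bf_glrlm(levels: np.ndarray, direction) -> np.ndarray:
    ng = int(levels.max())
    runs = []
    d = tuple(direction)
    for v in np.ndindex(levels.shape):
        g = levels[v]
        if g == 0:
            continue
        prev = tuple(v[a] - d[a] for a in range(3))
        if _in(levels.shape, prev) and levels[prev] == g:
            continue  # not a run start
        length = 1
        w = tuple(v[a] + d[a] for a in range(3))
        while _in(levels.shape, w) and levels[w] == g:
            length += 1
            w = tuple(w[a] + d[a] for a in range(3))
        runs.append((g, length))
    lmax = max((l for _, l in runs), default=1)
    out = np.zeros((ng, lmax))
    for g, l in runs:
        out[g - 1, l - 1] += 1
    return out


def _zones(levels: np.ndarray):
    """26-connected equal-level zones as lists of voxel tuples."""
    seen = np.zeros(levels.shape, dtype=bool)
    for v in np.ndindex(levels.shape):
        if levels[v] == 0 or seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        zone = []
        while stack:
            u = stack.pop()
            zone.append(u)
            for off in NEIGHBORS_26:
                w = tuple(u[a] + off[a] for a in range(3))
                if _in(levels.shape, w) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        yield g, zone


def bf_glszm(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    zones = list(_zones(levels))
    smax = max((len(z) for _, z in zones), default=1)
    out = np.zeros((ng, smax))
    for g, z in zones:
        out[g - 1, len(z) - 1] += 1
    return out


def _bf_distance(mask: np.ndarray) -> np.ndarray:
    """City-block distance to the nearest background voxel (grid edge counts)."""
    shape = mask.shape
    bg = [v for v in np.ndindex(shape) if not mask[v]]
    dist = np.zeros(shape, dtype=int)
    for v in np.ndindex(shape):
        if not mask[v]:
            continue
        d_edge = min(min(v[a] + 1, shape[a] - v[a]) for a in range(3))
        d_bg = min((sum(abs(v[a] - b[a]) for a in range(3)) for b in bg), default=d_edge)
        dist[v] = min(d_edge, d_bg)
    return dist


def bf_gldzm(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    dist = _bf_distance(levels > 0)
    entries = [(g, min(dist[v] for v in z)) for g, z in _zones(levels)]
    dmax = max((d for _, d in entries), default=1)
    out = np.zeros((ng, dmax))
    for g, d in entries:
        out[g - 1, d - 1] += 1
    return out


def bf_ngldm(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    ng = int(levels.max())
    out = np.zeros((ng, 27))
    for v in np.ndindex(levels.shape):
        i = levels[v]
        if i == 0:
            continue
        dep = 0
        for off in NEIGHBORS_26:
            w = tuple(v[a] + off[a] for a in range(3))
            if _in(levels.shape, w) and levels[w] > 0 and abs(int(levels[w]) - int(i)) <= alpha:
                dep += 1
        out[i - 1, dep] += 1
    return out


def bf_ngtdm(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    out = np.zeros((ng, 2))
    for v in np.ndindex(levels.shape):
        i = levels[v]
        if i == 0:
            continue
        nb = []
        for off in NEIGHBORS_26:
            w = tuple(v[a] + off[a] for a in range(3))
            if _in(levels.shape, w) and levels[w] > 0:
                nb.append(levels[w])
        if nb:
            out[i - 1, 0] += 1
            out[i - 1, 1] += abs(i - float(np.mean(nb)))
    return out


def glm_t_group(y: np.ndarray, group: np.ndarray, age: np.ndarray | None = None) -> tuple[float, int]:
    """Closed-form least squares t for the group column (normal equations)."""
    cols = [np.ones_like(y, dtype=float), group.astype(float)]
    if age is not None and np.ptp(age) > 0:
        cols.append(age - age.mean())
    x = np.column_stack(cols)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    df = y.size - x.shape[1]
    resid = y - x @ beta
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * xtx_inv[1, 1])
    return (float(beta[1] / se) if se > 0 else 0.0), df


def dense_gaussian_convolve(data: np.ndarray, sigma_vox: float, truncate: float = 4.0) -> np.ndarray:
    """Direct dense-kernel 3D Gaussian convolution with zero padding."""
    r = int(truncate * sigma_vox + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-(ax**2) / (2.0 * sigma_vox**2))
    k1 /= k1.sum()
    kern = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    out = np.zeros_like(data, dtype=float)
    padded = np.pad(data, r)
    for v in np.ndindex(data.shape):
        block = padded[v[0] : v[0] + 2 * r + 1, v[1] : v[1] + 2 * r + 1, v[2] : v[2] + 2 * r + 1]
        out[v] = (block * kern).sum()
    return out


def trilinear(data: np.ndarray, point: tuple[float, float, float]) -> float:
    """Hand-rolled trilinear interpolation with zero outside the domain."""
    base = [int(np.floor(c)) for c in point]
    frac = [c - b for c, b in zip(point, base)]
    acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                v = (base[0] + dx, base[1] + dy, base[2] + dz)
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                val = data[v] if _in(data.shape, v) else 0.0
                acc += w * val
    return acc
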