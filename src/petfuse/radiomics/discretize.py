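"""Fixed-bin-number gray-level discretization of an ROI.

Equal-width bins over the in-mask [min, max] range, half-open
``[edge_k, edge_{k+1})`` with the top bin closed, so the minimum maps to
level 1 and the maximum to level Ng. A constant ROI maps every voxel to
level 1 (zero-range convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import Volume

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray  # int array, 0 outside mask
    n_levels: int
    mask: np.ndarray
    bin_edges: np.ndarray  # Ng+1 edges over the in-mask intensity range

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(volume: Volume, mask: np.ndarray | None = None, n_bins: int = 32) -> DiscretizedROI:
    """Discretize in-mask intensities into ``n_bins`` gray levels."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if mask is None:
        mask = volume.brain_mask
    if mask is None:
        raise ValueError("no mask supplied and volume has no brain_mask")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    if not mask.any():
        raise ValueError("empty mask: nothing to discretize")

    vals = volume.data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        lv = np.floor((volume.data[mask] - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)  # the top bin is closed
        levels[mask] = lv
    return DiscretizedROI(levels=levels, n_levels=n_bins, mask=mask, bin_edges=edges)
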