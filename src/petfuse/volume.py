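"""3D scalar volume container with voxel spacing and grid-to-world affine.

The unit of all image processing in this package. Thin wrapper around a
numpy array plus the NIfTI-1 metadata needed to round-trip through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "load_volume", "save_volume", "threshold_brain_mask"]


@dataclass
class Volume:
    """A 3D scalar grid of uptake values.

    Parameters
    ----------
    data : (nx, ny, nz) float array
        Voxel values (arbitrary uptake units; after global-mean scaling the
        in-brain mean is 1).
    spacing_mm : 3-tuple of float
        Voxel edge lengths in mm, strictly positive.
    affine : (4, 4) array, optional
        Grid-to-world transform. Defaults to a diagonal affine built from
        ``spacing_mm``.
    brain_mask : bool array, optional
        Same shape as ``data``; True inside the brain.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None
    brain_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape:
                raise ValueError(
                    f"brain_mask shape {self.brain_mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        """A deep copy, optionally with replaced voxel data on the same grid."""
        return Volume(
            data=np.array(self.data if data is None else data),
            spacing_mm=self.spacing_mm,
            affine=self.affine.copy(),
            brain_mask=None if self.brain_mask is None else self.brain_mask.copy(),
        )


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, spacing_mm=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))


def save_volume(volume: Volume, path: str | Path, dtype=np.float32) -> Path:
    """Write a :class:`Volume` as NIfTI-1 (.nii or .nii.gz by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(dtype), volume.affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def threshold_brain_mask(volume: Volume, fraction_of_max: float = 0.10) -> np.ndarray:
    """Threshold-based brain mask: voxels above ``fraction_of_max``·max.

    The default 10%-of-max rule is the package's stand-in for an anatomical
    brain mask when none is supplied.
    """
    if not 0 <= fraction_of_max < 1:
        raise ValueError("fraction_of_max must be in [0, 1)")
    vmax = float(volume.data.max())
    if vmax <= 0:
        raise ValueError("volume has no positive voxels; cannot derive a brain mask")
    return volume.data > fraction_of_max * vmax
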