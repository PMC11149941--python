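"""Template-grid resampling, global-mean scaling and Gaussian smoothing.

The standard single-subject FDG-PET preparation: bring the scan onto the
79×95×69 / 2 mm template grid, divide by the mean activity within the brain,
and smooth with an isotropic 3D Gaussian (8 mm FWHM by default). Nonlinear
warping to a template is the business of external registration tools; here
an affine/trilinear resampling stands in, and phantom volumes are generated
natively on-grid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume, threshold_brain_mask

__all__ = [
    "resample_to_template_grid",
    "scale_to_global_mean",
    "gaussian_smooth",
    "preprocess_volume",
    "TEMPLATE_SHAPE",
    "TEMPLATE_SPACING_MM",
    "fwhm_to_sigma",
]

TEMPLATE_SHAPE = (79, 95, 69)
TEMPLATE_SPACING_MM = (2.0, 2.0, 2.0)

# FWHM = 2 sqrt(2 ln 2) sigma
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum (mm)."""
    return fwhm_mm / _FWHM_PER_SIGMA


def resample_to_template_grid(
    volume: Volume,
    target_shape: tuple[int, int, int] = TEMPLATE_SHAPE,
    target_spacing_mm: tuple[float, float, float] = TEMPLATE_SPACING_MM,
) -> Volume:
    """Trilinear resampling onto a fixed target grid.

    The world position of output voxel ``i`` along an axis is
    ``i * target_spacing``; source coordinates are reached through the
    inverse of the source grid-to-world affine (axis-aligned affines only —
    an affine stand-in for full registration). Voxels mapping outside the
    source domain are 0. If the volume is already on the target grid it is
    returned unchanged (copy).
    """
    target_shape = tuple(int(t) for t in target_shape)
    target_spacing_mm = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target_spacing_mm):
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm}")
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")

    if volume.shape == target_shape and tuple(volume.spacing_mm) == target_spacing_mm:
        out = volume.copy()
        return out

    # output index -> world mm -> source index (diagonal affine assumption)
    scale = [t / s for t, s in zip(target_spacing_mm, volume.spacing_mm)]
    coords = np.indices(target_shape, dtype=np.float64)
    for a in range(3):
        coords[a] *= scale[a]
    data = ndimage.map_coordinates(
        volume.data, coords.reshape(3, -1), order=1, mode="constant", cval=0.0
    ).reshape(target_shape)
    return Volume(data=data, spacing_mm=target_spacing_mm)


def scale_to_global_mean(volume: Volume, mask: np.ndarray | None = None) -> Volume:
    """Divide by the mean activity within the brain mask.

    After scaling the in-mask mean is exactly 1. The mask defaults to the
    volume's own ``brain_mask`` or, failing that, a 10%-of-max threshold
    mask. Degenerate scans (empty mask, non-positive mean) raise.
    """
    if mask is None:
        mask = volume.brain_mask if volume.brain_mask is not None else threshold_brain_mask(volume)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    if not mask.any():
        raise ValueError("empty brain mask: cannot scale to global mean")
    mean = float(volume.data[mask].mean())
    if mean <= 0:
        raise ValueError(f"non-positive in-mask mean ({mean}): degenerate scan")
    out = volume.copy(data=volume.data / mean)
    out.brain_mask = mask
    return out


def gaussian_smooth(volume: Volume, fwhm_mm: float = 8.0) -> Volume:
    """Separable isotropic 3D Gaussian smoothing, FWHM in mm.

    Per-axis sigma in voxels is ``fwhm / (2 sqrt(2 ln 2)) / spacing``.
    Boundary handling is zero-padding (the brain-in-air setting); the kernel
    is truncated at 4 sigma. ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in volume.spacing_mm]
    data = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="constant", truncate=4.0)
    out = volume.copy(data=data)
    return out


def preprocess_volume(
    volume: Volume,
    fwhm_mm: float = 8.0,
    target_shape: tuple[int, int, int] | None = None,
    target_spacing_mm: tuple[float, float, float] | None = None,
    mask: np.ndarray | None = None,
) -> Volume:
    """Full preparation chain: resample → scale to global mean → smooth.

    When ``target_shape`` is None the volume is assumed to be on the template
    grid already (the phantom case) and resampling is skipped.
    """
    if target_shape is not None:
        volume = resample_to_template_grid(
            volume, target_shape, target_spacing_mm or TEMPLATE_SPACING_MM
        )
        mask = None  # the original-grid mask no longer applies
    scaled = scale_to_global_mean(volume, mask)
    out = gaussian_smooth(scaled, fwhm_mm)
    out.brain_mask = scaled.brain_mask
    return out
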