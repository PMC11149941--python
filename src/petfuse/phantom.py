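"""Synthetic template-space FDG-PET phantom cohorts.

Generates smooth "brain-like" control volumes on the 79×95×69 / 2 mm
template grid, and "demented" volumes in which named ellipsoidal or box
regions have uptake multiplied by a hypometabolism factor before noise is
added. The generator makes every downstream stage (preprocessing, voxel
statistics, radiomics, classification) testable without any real scan.

The baseline pattern is a superposition of a large ellipsoidal brain mask
with a cortical-ribbon-like shell of higher uptake, blurred to the
configured smoothness. Noise is additive Gaussian, clipped at zero, which
is the simplest model producing positive PET-like values. Anatomy, PET
physics and partial-volume effects are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume, save_volume

__all__ = [
    "PhantomConfig",
    "Region",
    "SubjectRecord",
    "default_region_spec",
    "generate_control_volume",
    "generate_demented_volume",
    "generate_cohort",
]

MANIFEST_COLUMNS = ["id", "path", "age", "sex", "label", "subtype", "mmse"]


@dataclass(frozen=True)
class Region:
    """A named lesion region: ellipsoid or box around ``center`` (voxel units)."""

    name: str
    center: tuple[int, int, int]
    radii: tuple[float, float, float]
    shape: str = "ellipsoid"  # or "box"

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=np.float64)
        d = [(idx[a] - self.center[a]) / max(self.radii[a], 1e-9) for a in range(3)]
        if self.shape == "box":
            return (np.abs(d[0]) <= 1) & (np.abs(d[1]) <= 1) & (np.abs(d[2]) <= 1)
        if self.shape == "ellipsoid":
            return d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= 1.0
        raise ValueError(f"unknown region shape {self.shape!r}")


def default_region_spec(grid_shape: tuple[int, int, int]) -> list[Region]:
    """Dementia-pattern stand-ins scaled to the grid.

    Subtypes are modelled purely as different region sets: e.g. a
    frontotemporal pattern is the frontal plus temporal regions. The
    classifier only needs control-vs-demented separation, so anatomical
    fidelity is not attempted.
    """
    nx, ny, nz = grid_shape

    def c(fx, fy, fz):
        return (int(round(fx * (nx - 1))), int(round(fy * (ny - 1))), int(round(fz * (nz - 1))))

    def r(fx, fy, fz):
        return (max(1.5, fx * nx), max(1.5, fy * ny), max(1.5, fz * nz))

    return [
        Region("frontal", c(0.50, 0.78, 0.55), r(0.14, 0.09, 0.10)),
        Region("temporal_left", c(0.22, 0.45, 0.40), r(0.08, 0.12, 0.08)),
        Region("temporal_right", c(0.78, 0.45, 0.40), r(0.08, 0.12, 0.08)),
        Region("parietal", c(0.50, 0.30, 0.72), r(0.12, 0.10, 0.09)),
        Region("occipital", c(0.50, 0.12, 0.52), r(0.10, 0.07, 0.09)),
        Region("posterior_cingulate", c(0.50, 0.35, 0.58), r(0.07, 0.07, 0.07), "box"),
    ]


# region sets standing in for dementia subtypes
SUBTYPE_REGIONS: dict[str, tuple[str, ...]] = {
    "AD": ("parietal", "posterior_cingulate", "temporal_left"),
    "FT": ("frontal", "temporal_left", "temporal_right"),
    "DLB": ("occipital", "parietal"),
    "MCI": ("temporal_left",),
    "CB": ("frontal", "parietal"),
}


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort generator.

    ``grid_shape``/``voxel_size_mm`` default to the 79×95×69 / 2 mm template
    grid. ``hypometabolism_factor`` multiplies in-region uptake and must lie
    strictly in (0, 1): dementia reduces uptake, never increases it.
    """

    grid_shape: tuple[int, int, int] = (79, 95, 69)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    baseline_uptake: float = 100.0
    noise_sd: float = 5.0
    smoothness_mm: float = 6.0
    hypometabolism_factor: float = 0.75
    region_spec: list[Region] = field(default_factory=list)
    age_range_control: tuple[int, int] = (23, 84)
    age_range_demented: tuple[int, int] = (56, 88)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if self.baseline_uptake <= 0:
            raise ValueError("baseline_uptake must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.smoothness_mm < 0:
            raise ValueError("smoothness_mm must be non-negative")
        if not 0.0 < self.hypometabolism_factor < 1.0:
            raise ValueError(
                "hypometabolism_factor must be strictly between 0 and 1 "
                f"(a reduction), got {self.hypometabolism_factor}"
            )
        if not self.region_spec:
            self.region_spec = default_region_spec(self.grid_shape)

    def region(self, name: str) -> Region:
        for reg in self.region_spec:
            if reg.name == name:
                return reg
        available = ", ".join(r.name for r in self.region_spec)
        raise KeyError(f"unknown region {name!r}; available regions: {available}")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["region_spec"] = [dataclasses.asdict(r) for r in self.region_spec]
        Path(path).write_text(json.dumps(payload, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomConfig":
        payload = json.loads(Path(path).read_text())
        regions = [
            Region(r["name"], tuple(r["center"]), tuple(r["radii"]), r.get("shape", "ellipsoid"))
            for r in payload.pop("region_spec", [])
        ]
        payload = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
        return cls(region_spec=regions, **payload)


@dataclass
class SubjectRecord:
    """One cohort subject: volume reference plus covariates and label."""

    id: str
    path: str
    age: int
    sex: str
    label: str
    subtype: str | None = None
    mmse: int | None = None
    volume: Volume | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.label not in ("control", "demented"):
            raise ValueError(f"label must be 'control' or 'demented', got {self.label!r}")
        if self.mmse is not None and not 0 <= int(self.mmse) <= 30:
            raise ValueError(f"mmse must be in [0, 30], got {self.mmse}")


def _baseline_pattern(config: PhantomConfig) -> np.ndarray:
    """Deterministic smooth brain-like uptake pattern (no noise).

    Large ellipsoid at ~baseline uptake with a brighter cortical-ribbon
    shell, blurred by ``smoothness_mm``; gives texture matrices
    non-degenerate structure.
    """
    shape = config.grid_shape
    idx = np.indices(shape, dtype=np.float64)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.42 * s for s in shape]
    rho = np.sqrt(sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)))
    brain = rho <= 1.0
    # gray-matter-like ribbon: outer 25% of the ellipsoid radius runs hotter
    ribbon = (rho > 0.72) & brain
    pattern = np.where(brain, 0.75 * config.baseline_uptake, 0.0)
    pattern[ribbon] = 1.25 * config.baseline_uptake
    # mild deterministic low-frequency modulation so no two axes are equivalent
    mod = 1.0 + 0.05 * np.sin(2.0 * np.pi * idx[0] / shape[0]) * np.cos(
        2.0 * np.pi * idx[1] / shape[1]
    )
    pattern *= mod
    if config.smoothness_mm > 0:
        sigma_vox = [
            config.smoothness_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
            for v in config.voxel_size_mm
        ]
        pattern = ndimage.gaussian_filter(pattern, sigma=sigma_vox, mode="constant")
    return pattern


def _brain_mask_from_pattern(pattern: np.ndarray) -> np.ndarray:
    return pattern > 0.10 * pattern.max()


def _assemble(config: PhantomConfig, pattern: np.ndarray, seed: int) -> Volume:
    rng = np.random.default_rng(seed)
    data = pattern.copy()
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=pattern.shape)
        np.clip(data, 0.0, None, out=data)
    return Volume(
        data=data,
        spacing_mm=config.voxel_size_mm,
        brain_mask=_brain_mask_from_pattern(pattern),
    )


def generate_control_volume(config: PhantomConfig, seed: int) -> Volume:
    """A healthy-control phantom: baseline pattern plus clipped Gaussian noise.

    Deterministic given ``seed``; with ``noise_sd=0`` the output is exactly
    the deterministic baseline pattern.
    """
    return _assemble(config, _baseline_pattern(config), seed)


def generate_demented_volume(
    config: PhantomConfig, regions: list[str] | tuple[str, ...], seed: int
) -> Volume:
    """A demented phantom: control pattern with named regions scaled down.

    Identical to :func:`generate_control_volume` at the same seed except that
    voxels inside the named regions are multiplied by
    ``config.hypometabolism_factor`` before noise is added.
    """
    pattern = _baseline_pattern(config)
    lesion = np.zeros(config.grid_shape, dtype=bool)
    for name in regions:
        lesion |= config.region(name).mask(config.grid_shape)
    pattern = np.where(lesion, pattern * config.hypometabolism_factor, pattern)
    return _assemble(config, pattern, seed)


def _cohort_seed(seed: int, i: int) -> int:
    # distinct per-subject streams, stable across cohort sizes
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))


def generate_cohort(
    config: PhantomConfig,
    n_control: int,
    n_demented: int,
    out_dir: str | Path,
    seed: int,
) -> pd.DataFrame:
    """Write a cohort of NIfTI phantoms and return its CSV manifest.

    One ``.nii.gz`` per subject plus ``manifest.csv`` with columns
    ``id,path,age,sex,label,subtype,mmse``. Ages are drawn uniformly from the
    configured control/demented ranges; demented subjects cycle through the
    subtype region sets. Fully deterministic given ``seed``.
    """
    if n_control < 0 or n_demented < 0:
        raise ValueError("cohort sizes must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    subtypes = list(SUBTYPE_REGIONS)
    rows = []
    for i in range(n_control + n_demented):
        is_control = i < n_control
        sid = f"{'hc' if is_control else 'pt'}{i:03d}"
        sub_seed = _cohort_seed(seed, i)
        if is_control:
            vol = generate_control_volume(config, sub_seed)
            lo, hi = config.age_range_control
            subtype, mmse = "", ""
        else:
            subtype = subtypes[(i - n_control) % len(subtypes)]
            vol = generate_demented_volume(config, SUBTYPE_REGIONS[subtype], sub_seed)
            lo, hi = config.age_range_demented
            mmse = int(rng.integers(5, 27))
        age = int(rng.integers(lo, hi + 1))
        sex = "M" if rng.random() < 0.5 else "F"
        path = out_dir / f"{sid}.nii.gz"
        save_volume(vol, path)
        rows.append(
            {
                "id": sid,
                "path": str(path),
                "age": age,
                "sex": sex,
                "label": "control" if is_control else "demented",
                "subtype": subtype,
                "mmse": mmse,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
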