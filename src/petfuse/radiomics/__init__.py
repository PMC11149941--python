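"""Whole-brain radiomics: 32-level discretization, 79 first-order and 136
3D texture features (215 total) in reference-nomenclature naming.

The whole preprocessed brain volume is the region of interest; the paper's
four highlighted features are ``stat_maximum``, ``stat_interquartile_range``,
``ngldm_dependence_count_nonuniformity`` (DN) and
``ngldm_low_dependence_low_grey_level_emphasis`` (SDLGLE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..volume import Volume, threshold_brain_mask
from .discretize import DiscretizedROI, discretize
from .firstorder import N_FIRST_ORDER, first_order_features
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
from .texture import N_TEXTURE, texture_features

__all__ = [
    "RadiomicsConfig",
    "FeatureVector",
    "extract_all",
    "extract_cohort",
    "discretize",
    "DiscretizedROI",
    "first_order_features",
    "texture_features",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldzm_matrix",
    "ngldm_matrix",
    "ngtdm_matrix",
    "TextureMatrix",
    "DIRECTIONS_13",
    "N_FIRST_ORDER",
    "N_TEXTURE",
    "N_TOTAL",
]

N_TOTAL = N_FIRST_ORDER + N_TEXTURE  # 215


@dataclass
class RadiomicsConfig:
    """Extraction parameters: 32 bins, Chebyshev distance 1, alpha 0."""

    n_bins: int = 32
    delta: int = 1
    alpha: int = 0
    connectivity: int = 26
    aggregations: tuple[str, ...] = ("averaged", "merged")


@dataclass
class FeatureVector:
    """Ordered named feature values with extraction provenance."""

    values: dict[str, float]
    provenance: dict = field(default_factory=dict)

    @property
    def feature_count(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)

    def to_csv(self, path: str | Path, subject_id: str = "subject") -> None:
        df = pd.DataFrame([self.values], index=[subject_id])
        df.index.name = "id"
        df.to_csv(path)


def extract_all(
    volume: Volume,
    mask: np.ndarray | None = None,
    config: RadiomicsConfig | None = None,
) -> FeatureVector:
    """The full 215-feature whole-brain signature of one volume.

    Ordering is stable across runs: first-order block (morphology, local
    intensity, statistics, histogram, intensity-volume histogram), then the
    texture block (GLCM avg/merged, GLRLM avg/merged, GLSZM, GLDZM, NGTDM,
    NGLDM). All values are finite, including on pathological ROIs.
    """
    config = config or RadiomicsConfig()
    if mask is None:
        mask = volume.brain_mask if volume.brain_mask is not None else threshold_brain_mask(volume)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to extract")

    disc = discretize(volume, mask, config.n_bins)
    fo, fo_prov = first_order_features(volume, mask, disc)
    tex = texture_features(disc, delta=config.delta, alpha=config.alpha)
    values = {**fo, **tex}
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite features: {bad}")
    prov = {
        "n_bins": config.n_bins,
        "delta": config.delta,
        "alpha": config.alpha,
        "connectivity": config.connectivity,
        "aggregations": list(config.aggregations),
        **fo_prov,
    }
    return FeatureVector(values=values, provenance=prov)


def extract_cohort(
    manifest: pd.DataFrame,
    config: RadiomicsConfig | None = None,
    loader=None,
) -> pd.DataFrame:
    """Feature table for a cohort manifest (columns id, path, label, ...).

    ``loader`` maps a path to a :class:`Volume`; defaults to NIfTI loading.
    Returns one row per subject, 215 feature columns plus ``label``.
    """
    from ..volume import load_volume

    loader = loader or load_volume
    rows = {}
    for _, rec in manifest.iterrows():
        vol = loader(rec["path"])
        rows[rec["id"]] = extract_all(vol, config=config).values
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "id"
    table["label"] = manifest.set_index("id").loc[table.index, "label"]
    return table
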