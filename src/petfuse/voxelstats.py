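"""Single-subject voxel-wise GLM t-maps with cluster extent thresholding.

One individual scan is compared with a healthy-control group by fitting, at
every voxel, the linear model

    y = b0 + b1 * group + b2 * age

over the N controls plus the subject (group = 1 for the subject, 0 for
controls), and reporting t = b1_hat / se(b1_hat). A negative t marks the
subject as hypometabolic relative to controls. The map is thresholded at an
uncorrected p (default 0.01, hypometabolic tail) and supra-threshold
connected components smaller than a minimum extent (strictly "more than"
``min_size`` voxels, default 100) are discarded. No random-field correction
is applied — the emulated clinical pipeline uses only the uncorrected
threshold plus the extent rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import Volume

__all__ = ["TMap", "ClusterSet", "single_subject_tmap", "threshold_and_cluster"]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class TMap:
    """Per-voxel t-scores with their degrees of freedom."""

    t: np.ndarray
    df: int
    n_controls: int
    covariates_used: list[str] = field(default_factory=list)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"degrees of freedom must be >= 1, got {self.df}")


@dataclass
class ClusterSet:
    """Labelled supra-threshold connected components with sizes and peaks."""

    label_map: np.ndarray
    clusters: list[dict]
    p_threshold: float
    min_size: int
    connectivity: int
    t_critical: float
    tail: str

    def to_table(self) -> pd.DataFrame:
        cols = ["id", "size_voxels", "peak_t", "x", "y", "z"]
        rows = [
            {
                "id": c["id"],
                "size_voxels": c["size_voxels"],
                "peak_t": c["peak_t"],
                "x": c["peak_coordinate"][0],
                "y": c["peak_coordinate"][1],
                "z": c["peak_coordinate"][2],
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows, columns=cols)

    def save_table(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False)


def single_subject_tmap(
    subject: Volume,
    controls: list[Volume],
    subject_age: float,
    control_ages: list[float],
    mask: np.ndarray | None = None,
) -> TMap:
    """Voxel-wise t-map of one subject against a control group, age-adjusted.

    The age column is dropped automatically when it has zero variance across
    the N+1 scans (its inclusion would make the design singular), in which
    case the degrees of freedom increase by one. Voxels with zero residual
    variance get t = 0, as do voxels outside the analysis mask.
    """
    if len(controls) < 3:
        raise ValueError(f"need at least 3 control volumes, got {len(controls)}")
    if len(control_ages) != len(controls):
        raise ValueError("control_ages must match controls in length")
    shape = subject.shape
    for v in controls:
        if v.shape != shape:
            raise ValueError(f"grid mismatch: control shape {v.shape} != subject shape {shape}")

    n = len(controls) + 1
    y = np.empty((n, int(np.prod(shape))), dtype=np.float64)
    for i, v in enumerate(controls):
        y[i] = v.data.ravel()
    y[-1] = subject.data.ravel()

    ages = np.array([*control_ages, subject_age], dtype=np.float64)
    group = np.zeros(n)
    group[-1] = 1.0
    covariates = ["age"]
    if np.ptp(ages) == 0:
        covariates = []
        X = np.column_stack([np.ones(n), group])
    else:
        X = np.column_stack([np.ones(n), group, ages - ages.mean()])

    p = X.shape[1]
    df = n - p
    if df < 1:
        raise ValueError(f"fewer scans ({n}) than needed for {p} design columns")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y  # (p, n_vox)
    resid = y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    # voxels whose residual variance is zero to machine precision get t = 0
    scale = (y**2).mean(axis=0)
    zero_var = sigma2 <= 1e-20 * np.maximum(scale, np.finfo(float).tiny)
    var_b1 = sigma2 * xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((var_b1 > 0) & ~zero_var, beta[1] / np.sqrt(np.maximum(var_b1, 1e-300)), 0.0)
    t = t.reshape(shape)

    if mask is None and subject.brain_mask is not None:
        mask = subject.brain_mask
    if mask is not None:
        t = np.where(np.asarray(mask, dtype=bool), t, 0.0)

    return TMap(
        t=t,
        df=df,
        n_controls=len(controls),
        covariates_used=covariates,
        spacing_mm=subject.spacing_mm,
    )


def threshold_and_cluster(
    tmap: TMap,
    p_threshold: float = 0.01,
    min_size: int = 100,
    tail: str = "hypo",
    connectivity: int = 18,
) -> ClusterSet:
    """Threshold a t-map and keep clusters strictly larger than ``min_size``.

    ``p_threshold`` is converted to a one-tailed t critical value with the
    map's degrees of freedom. For ``tail='hypo'`` voxels with
    ``t < -t_crit`` survive (subject below controls under the stated sign
    convention); for ``'hyper'``, ``t > t_crit``. Components are labelled at
    the chosen connectivity (6, 18 or 26; 18 is the convention of the
    emulated tool) and those with ``size <= min_size`` are discarded.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    if tail not in ("hypo", "hyper"):
        raise ValueError(f"tail must be 'hypo' or 'hyper', got {tail!r}")

    t_crit = float(stats.t.isf(p_threshold, tmap.df))
    supra = tmap.t < -t_crit if tail == "hypo" else tmap.t > t_crit

    labels, n_raw = ndimage.label(supra, structure=_CONNECTIVITY_STRUCTS[connectivity])
    clusters = []
    out_labels = np.zeros_like(labels)
    next_id = 0
    if n_raw:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_raw + 1))
        for raw_id, size in enumerate(sizes, start=1):
            if size <= min_size:
                continue
            next_id += 1
            comp = labels == raw_id
            out_labels[comp] = next_id
            tvals = np.where(comp, tmap.t, 0.0)
            flat_peak = np.abs(tvals).argmax()
            peak = np.unravel_index(flat_peak, tmap.t.shape)
            clusters.append(
                {
                    "id": next_id,
                    "size_voxels": int(size),
                    "peak_t": float(tmap.t[peak]),
                    "peak_coordinate": tuple(int(c) for c in peak),
                }
            )
    return ClusterSet(
        label_map=out_labels,
        clusters=clusters,
        p_threshold=p_threshold,
        min_size=min_size,
        connectivity=connectivity,
        t_critical=t_crit,
        tail=tail,
    )
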