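"""MRMR feature ranking, top-fraction retention and Pearson de-correlation.

The selection chain the classifiers are fed from:

1. greedy minimum-redundancy maximum-relevance (MRMR) ranking — the first
   feature maximizes mutual information (MI) with the class label; each next
   feature maximizes ``MI(f; label) - mean_g MI(f; g)`` over the already
   ranked features g (the MI-difference criterion; an MI-quotient variant is
   available);
2. retention of the top fraction of the ranking (10% of 215 features = 21);
3. a greedy walk down the retained ranking keeping a feature only when its
   absolute Pearson correlation with every already-kept feature is below a
   threshold (default 0.30).

MI is estimated by a plug-in estimate after per-feature equal-frequency
discretization into ``B = clamp(floor(n_rows / 5), 2, 8)`` bins — pinned so
that rankings are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "mutual_information",
    "discretize_feature",
    "mrmr_rank",
    "select_top_fraction",
    "correlation_filter",
    "select_features",
]


@dataclass
class SelectionResult:
    """Full provenance of a selection run."""

    ranking: list[str]
    scores: dict[str, float]
    relevance: dict[str, float]
    top_fraction_kept: float
    retained_after_mrmr: list[str]
    pairwise_r: pd.DataFrame
    final_features: list[str]
    r_threshold: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ranking": self.ranking,
            "scores": self.scores,
            "relevance": self.relevance,
            "top_fraction_kept": self.top_fraction_kept,
            "retained_after_mrmr": self.retained_after_mrmr,
            "pairwise_r": self.pairwise_r.to_dict(),
            "final_features": self.final_features,
            "r_threshold": self.r_threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def discretize_feature(x: np.ndarray, n_rows: int | None = None) -> np.ndarray:
    """Equal-frequency binning with B = clamp(floor(n/5), 2, 8) bins."""
    x = np.asarray(x, dtype=np.float64)
    n = n_rows or x.size
    b = int(max(2, min(8, n // 5)))
    if np.ptp(x) == 0:
        return np.zeros(x.size, dtype=np.int64)
    edges = np.quantile(x, np.linspace(0, 1, b + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) between two discrete label arrays."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())


def _validate_table(table: pd.DataFrame, labels: np.ndarray) -> None:
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for selection")
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per class for selection")


def mrmr_rank(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series | None = None,
    criterion: str = "difference",
) -> tuple[list[str], dict[str, float], dict[str, float]]:
    """Greedy MRMR ranking of all feature columns.

    ``table`` may carry the class labels in a ``label`` column, or they can
    be passed separately. Returns ``(ranking, scores, relevance)``. Ties in
    greedy scores break by (score, then original column order). Constant
    columns get MI 0 with everything.
    """
    if criterion not in ("difference", "quotient"):
        raise ValueError("criterion must be 'difference' or 'quotient'")
    if labels is None:
        if "label" not in table.columns:
            raise ValueError("no labels: pass them or include a 'label' column")
        labels = table["label"].to_numpy()
        table = table.drop(columns=["label"])
    labels = np.asarray(labels)
    _validate_table(table, labels)

    cols = list(table.columns)
    n = len(table)
    disc = {c: discretize_feature(table[c].to_numpy(), n) for c in cols}
    constant = {c: np.ptp(table[c].to_numpy()) == 0 for c in cols}
    relevance = {
        c: 0.0 if constant[c] else mutual_information(disc[c], labels) for c in cols
    }
    if all(constant.values()):
        raise ValueError("all feature columns are constant; nothing to rank")

    mi_cache: dict[tuple[str, str], float] = {}

    def mi_ff(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = (
                0.0 if constant[a] or constant[b] else mutual_information(disc[a], disc[b])
            )
        return mi_cache[key]

    ranking: list[str] = []
    scores: dict[str, float] = {}
    remaining = list(cols)
    while remaining:
        best_c, best_s = None, -np.inf
        for c in remaining:  # column order is the tie-break
            if ranking:
                red = float(np.mean([mi_ff(c, g) for g in ranking]))
                s = relevance[c] - red if criterion == "difference" else relevance[c] / (red + 1e-12)
            else:
                s = relevance[c]
            if s > best_s:
                best_c, best_s = c, s
        ranking.append(best_c)
        scores[best_c] = float(best_s)
        remaining.remove(best_c)
    return ranking, scores, relevance


def select_top_fraction(ranking: list[str], fraction: float = 0.10) -> list[str]:
    """First ``floor(fraction * n)`` features of the ranking, at least 1."""
    if not ranking:
        raise ValueError("empty ranking")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = max(1, int(np.floor(fraction * len(ranking))))
    return list(ranking[:k])


def correlation_filter(
    table: pd.DataFrame, retained: list[str], r_threshold: float = 0.30
) -> list[str]:
    """Greedy de-correlation in ranking order at |r| < ``r_threshold``.

    A zero-variance feature has its correlations defined as 0 (it cannot
    block others) but is itself dropped.
    """
    if not retained:
        raise ValueError("retained feature list is empty")
    kept: list[str] = []
    for c in retained:
        x = table[c].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0 or np.std(x) == 0:
            continue
        ok = True
        for k in kept:
            r = float(np.corrcoef(x, table[k].to_numpy(dtype=np.float64))[0, 1])
            if abs(r) >= r_threshold:
                ok = False
                break
        if ok:
            kept.append(c)
    if not kept and retained:
        # every retained feature constant — mirror the first-feature guarantee
        kept = [retained[0]]
    return kept


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series | None = None,
    fraction: float = 0.10,
    r_threshold: float = 0.30,
    criterion: str = "difference",
) -> SelectionResult:
    """Full chain: MRMR rank → top fraction → correlation filter."""
    if labels is None and "label" in table.columns:
        labels = table["label"].to_numpy()
        table = table.drop(columns=["label"])
    ranking, scores, relevance = mrmr_rank(table, labels, criterion)
    retained = select_top_fraction(ranking, fraction)
    final = correlation_filter(table, retained, r_threshold)
    pairwise = table[final].corr() if len(final) > 1 else pd.DataFrame(
        np.ones((len(final), len(final))), index=final, columns=final
    )
    return SelectionResult(
        ranking=ranking,
        scores=scores,
        relevance=relevance,
        top_fraction_kept=fraction,
        retained_after_mrmr=retained,
        pairwise_r=pairwise,
        final_features=final,
        r_threshold=r_threshold,
    )
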