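"""Confusion metrics, per-subject score tables and paired-t model comparison.

Demented is the positive class. Sensitivity = TP/(TP+FN) and specificity =
TN/(TN+FP), reported on the 0-100 percent scale, as are the per-subject
class-posterior scores. Model score vectors are compared per class with a
two-sided paired Student t-test; all-zero differences are reported as a
degenerate flag rather than a number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .models import PredictionRecord

__all__ = ["EvaluationReport", "confusion_metrics", "paired_score_test", "build_report"]


@dataclass
class EvaluationReport:
    per_subject: pd.DataFrame  # id, label, <model> score columns (percent)
    metrics: dict  # model -> {sensitivity, specificity, accuracy} (percent or None)
    summary: pd.DataFrame  # per model per class mean/SD of scores
    comparisons: pd.DataFrame  # model_a, model_b, class, t, p / degenerate
    omitted_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_subject": self.per_subject.to_dict(orient="records"),
            "metrics": self.metrics,
            "summary": self.summary.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "omitted_ids": self.omitted_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.per_subject.to_csv(path, index=False)


def confusion_metrics(
    predictions: list[PredictionRecord], labels: dict[str, str] | list[str]
) -> dict:
    """Sensitivity, specificity and accuracy (percent), demented positive.

    A metric whose class is absent is reported as None (missing), never 0.
    """
    if isinstance(labels, dict):
        truth = [labels[p.subject_id] for p in predictions]
    else:
        truth = list(labels)
    if len(truth) != len(predictions):
        raise ValueError("labels must match predictions in length")
    if not predictions:
        raise ValueError("no predictions")
    tp = sum(1 for p, t in zip(predictions, truth) if t == "demented" and p.predicted_label == "demented")
    fn = sum(1 for p, t in zip(predictions, truth) if t == "demented" and p.predicted_label == "control")
    tn = sum(1 for p, t in zip(predictions, truth) if t == "control" and p.predicted_label == "control")
    fp = sum(1 for p, t in zip(predictions, truth) if t == "control" and p.predicted_label == "demented")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    acc = 100.0 * (tp + tn) / len(predictions)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def paired_score_test(scores_a, scores_b) -> dict:
    """Two-sided paired Student t on per-subject score differences.

    Returns {"t", "p", "df", "degenerate"}; when every difference is zero
    (or its variance is), the result is flagged degenerate and t/p are None.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1D and equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return {"t": None, "p": None, "df": a.size - 1, "degenerate": True}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": a.size - 1, "degenerate": False}


def build_report(
    test_manifest: pd.DataFrame,
    model_predictions: dict[str, list[PredictionRecord]],
    omit_ids: list[str] | None = None,
) -> EvaluationReport:
    """Per-subject score table, per-class mean/SD and pairwise comparisons.

    ``model_predictions`` maps model name → predictions for the manifest's
    subjects. Scores are the demented-class posterior for demented subjects
    and the control-class posterior for controls ("likelihood of the true
    class"), on the percent scale. ``omit_ids`` recomputes summary/
    comparisons without the listed subjects (a supported report option).
    """
    ids = list(test_manifest["id"])
    labels = dict(zip(test_manifest["id"], test_manifest["label"]))
    for name, preds in model_predictions.items():
        missing = set(ids) - {p.subject_id for p in preds}
        if missing:
            raise ValueError(f"model {name!r} is missing predictions for: {sorted(missing)}")

    by_model = {
        name: {p.subject_id: p for p in preds} for name, preds in model_predictions.items()
    }
    rows = []
    for sid in ids:
        row = {"id": sid, "label": labels[sid]}
        for name in model_predictions:
            p = by_model[name][sid]
            score = p.score_demented if labels[sid] == "demented" else p.score_control
            row[name] = 100.0 * score
        rows.append(row)
    per_subject = pd.DataFrame(rows)

    metrics = {
        name: confusion_metrics([by_model[name][sid] for sid in ids], [labels[sid] for sid in ids])
        for name in model_predictions
    }

    omit_ids = omit_ids or []
    kept = per_subject[~per_subject["id"].isin(omit_ids)]

    summary_rows = []
    for name in model_predictions:
        for cls in ("demented", "control"):
            vals = kept.loc[kept["label"] == cls, name].to_numpy()
            if vals.size:
                summary_rows.append(
                    {
                        "model": name,
                        "class": cls,
                        "mean_score": float(vals.mean()),
                        "sd_score": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "n": int(vals.size),
                    }
                )
    summary = pd.DataFrame(summary_rows)

    comp_rows = []
    names = list(model_predictions)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            for cls in ("demented", "control"):
                sub = kept[kept["label"] == cls]
                if len(sub) < 2:
                    continue
                res = paired_score_test(sub[names[i]].to_numpy(), sub[names[j]].to_numpy())
                comp_rows.append(
                    {
                        "model_a": names[i],
                        "model_b": names[j],
                        "class": cls,
                        "t_statistic": res["t"],
                        "p_value": res["p"],
                        "degenerate": res["degenerate"],
                    }
                )
    comparisons = pd.DataFrame(comp_rows)
    return EvaluationReport(
        per_subject=per_subject,
        metrics=metrics,
        summary=summary,
        comparisons=comparisons,
        omitted_ids=list(omit_ids),
    )
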