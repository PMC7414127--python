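"""Per-task AUROC/AUPR evaluation and model-vs-model comparison.

AUROC is the rank-based (Mann-Whitney) area under the ROC curve; AUPR is
the average-precision formulation of the area under the precision-recall
curve (step interpolation, not trapezoidal).  Both delegate to
scikit-learn; a task is *undefined* for AUROC when its labels are
single-class and for AUPR when it has no positives, and undefined tasks
are excluded from macro averages and dropped pairwise from comparisons.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; ties contribute 1/2.

    Returns NaN (undefined) when labels are single-class.
    """
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if labels.min() == labels.max():
        return float("nan")
    return float(roc_auc_score(labels, scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision).

    Returns NaN (undefined) when there are no positives.
    """
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if labels.sum() == 0:
        return float("nan")
    return float(average_precision_score(labels, scores))


def evaluate_scores(scores: np.ndarray, y: np.ndarray,
                    task_names: Sequence[str] | None = None
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-task metrics table and macro averages from a score matrix.

    Parameters
    ----------
    scores : (n, T) predicted probabilities
    y : (n, T) binary labels
    task_names : optional task roster (defaults to task0..task{T-1})

    Returns
    -------
    per_task : DataFrame with columns task, n_pos, n_neg, auroc, aupr
        (NaN where undefined).
    macro : {"auroc": ..., "aupr": ..., "n_defined_auroc": ...,
        "n_defined_aupr": ...} — means over tasks where the metric is
        defined.
    """
    scores, y = np.asarray(scores), np.asarray(y)
    if scores.shape != y.shape:
        raise ValueError("scores and labels shape mismatch")
    T = scores.shape[1]
    names = list(task_names) if task_names is not None else [
        f"task{j}" for j in range(T)]
    rows = []
    for j in range(T):
        lab = y[:, j]
        rows.append({
            "task": names[j],
            "n_pos": int(lab.sum()),
            "n_neg": int(len(lab) - lab.sum()),
            "auroc": auroc(scores[:, j], lab),
            "aupr": aupr(scores[:, j], lab),
        })
    per_task = pd.DataFrame(rows)
    macro = {
        "auroc": float(per_task["auroc"].mean()),
        "aupr": float(per_task["aupr"].mean()),
        "n_defined_auroc": int(per_task["auroc"].notna().sum()),
        "n_defined_aupr": int(per_task["aupr"].notna().sum()),
    }
    return per_task, macro


def evaluate_model(model, X: np.ndarray, y: np.ndarray,
                   task_names: Sequence[str] | None = None
                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Evaluate a fitted classifier on a held-out split (per-task + macro)."""
    if len(X) == 0:
        raise ValueError("empty evaluation split")
    return evaluate_scores(model.predict_proba(X), y, task_names)


def percent_better(n_better: int, n_total: int) -> float:
    """100 * n_better / n_total, rounded to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_better / n_total, 2)


def compare_models(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                   metric: str = "auroc"
                   ) -> tuple[dict[str, float], pd.DataFrame]:
    """Count tasks where model A strictly beats model B on a metric.

    Tasks undefined (NaN) in either table are dropped pairwise; ties count
    as not-better.  Returns ``{"n_better", "n_total", "percent"}`` and the
    scatter-plot table (per task: x = B's score, y = A's score).
    """
    if list(metrics_a["task"]) != list(metrics_b["task"]):
        raise ValueError("task rosters differ between models")
    a = metrics_a[metric].to_numpy(dtype=float)
    b = metrics_b[metric].to_numpy(dtype=float)
    defined = ~(np.isnan(a) | np.isnan(b))
    n_total = int(defined.sum())
    n_better = int((a[defined] > b[defined]).sum())
    scatter = pd.DataFrame({
        "task": metrics_a["task"][defined].to_numpy(),
        "x_model_b": b[defined],
        "y_model_a": a[defined],
    })
    summary = {"n_better": n_better, "n_total": n_total,
               "percent": percent_better(n_better, n_total)}
    return summary, scatter
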