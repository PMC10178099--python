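"""Forecast and risk-level evaluation metrics.

Indicator forecasts are scored per (province, indicator) with RMSE and MAE;
because carcinogenic risks live on a 1e-6..1e-4 scale, TCR residual metrics
are multiplied by 1e5 before reporting so all three indicators share one
order of magnitude.  Risk-level predictions are scored with one-vs-rest
precision, recall and F1 per level (as percentages) plus the full confusion
matrix.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .indicators import INDICATOR_NAMES

logger = logging.getLogger(__name__)

TCR_REPORT_SCALE = 1e5


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error."""
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("rmse requires equal, nonzero-length inputs")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error."""
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("mae requires equal, nonzero-length inputs")
    return float(np.mean(np.abs(y_true - y_pred)))


def scaled_indicator_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-(province, indicator) RMSE and MAE with TCR metrics scaled by 1e5.

    ``predictions`` columns: province, week, indicator, y_true, y_pred.
    """
    present = set(predictions["indicator"].unique())
    missing = set(INDICATOR_NAMES) - present
    if missing:
        raise ValueError(f"predictions lack indicator series {sorted(missing)}")
    rows = []
    for (province, indicator), group in predictions.groupby(["province", "indicator"]):
        factor = TCR_REPORT_SCALE if indicator == "tcr" else 1.0
        rows.append(
            {
                "province": province,
                "indicator": indicator,
                "rmse": factor * rmse(group["y_true"], group["y_pred"]),
                "mae": factor * mae(group["y_true"], group["y_pred"]),
            }
        )
    return pd.DataFrame(rows).sort_values(["province", "indicator"], ignore_index=True)


def level_metrics(
    true_levels: Sequence[str], predicted_levels: Sequence[str], labels: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-vs-rest precision/recall/F1 per level (percent) and the confusion matrix.

    ``labels`` fixes the level order (low risk first).  A level with zero
    predicted positives is reported with precision 0 and a warning.
    """
    true_arr = np.asarray(list(true_levels), dtype=object)
    pred_arr = np.asarray(list(predicted_levels), dtype=object)
    if true_arr.shape != pred_arr.shape:
        raise ValueError("true and predicted level sequences differ in length")
    unknown = (set(true_arr) | set(pred_arr)) - set(labels)
    if unknown:
        raise ValueError(f"unknown level labels {sorted(unknown)}")
    for label in labels:
        if (pred_arr == label).sum() == 0:
            logger.warning("level %r has zero predicted positives; precision reported as 0", label)
    precision, recall, f1, support = precision_recall_fscore_support(
        true_arr, pred_arr, labels=list(labels), zero_division=0
    )
    table = pd.DataFrame(
        {
            "level": list(labels),
            "precision_pct": 100.0 * precision,
            "recall_pct": 100.0 * recall,
            "f1_pct": 100.0 * f1,
            "support": support,
        }
    )
    confusion = pd.DataFrame(
        _sk_confusion(true_arr, pred_arr, labels=list(labels)),
        index=pd.Index(list(labels), name="true"),
        columns=pd.Index(list(labels), name="predicted"),
    )
    return table, confusion


__all__ = [
    "TCR_REPORT_SCALE",
    "level_metrics",
    "mae",
    "rmse",
    "scaled_indicator_metrics",
]
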