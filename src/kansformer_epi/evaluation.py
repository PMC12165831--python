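"""Evaluation: ranking metrics, repeated-run comparison, feature importance.

AUROC is the rank (Mann-Whitney) statistic; AUPR the step-interpolated area
under the precision-recall curve -- the conservative choice for the heavily
imbalanced EPI pair tables, where negatives outnumber positives up to 20:1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm


def _check_scored(y_true: np.ndarray, scores: np.ndarray,
                  need_negative: bool = True) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("y_true and scores differ in length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if y.sum() == 0:
        raise ValueError("metric needs at least one positive")
    if need_negative and y.sum() == len(y):
        raise ValueError("metric needs at least one negative")
    return y, s


def auroc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (midrank tie handling)."""
    y, s = _check_scored(y_true, scores)
    return float(skm.roc_auc_score(y, s))


def aupr(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the step-interpolated precision-recall curve."""
    y, s = _check_scored(y_true, scores, need_negative=False)
    return float(skm.average_precision_score(y, s))


def roc_curve_table(y_true, scores) -> pd.DataFrame:
    y, s = _check_scored(y_true, scores)
    fpr, tpr, _ = skm.roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def pr_curve_table(y_true, scores) -> pd.DataFrame:
    y, s = _check_scored(y_true, scores, need_negative=False)
    precision, recall, _ = skm.precision_recall_curve(y, s)
    return pd.DataFrame({"recall": recall[::-1], "precision": precision[::-1]})


@dataclass(frozen=True)
class RunComparison:
    metric: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool
    welch: bool


def compare_runs(a: Sequence[float], b: Sequence[float], alpha: float = 0.05,
                 metric: str = "auroc", welch: bool = True) -> RunComparison:
    """Two-sample t-test between repeated-run metric values of two models.

    Welch's unequal-variance form by default; ``welch=False`` selects the
    pooled-variance Student form.  Two degenerate constant groups with equal
    means report t=0, p=1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 runs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("metric values must be finite")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return RunComparison(metric=metric, mean_a=float(a.mean()),
                         mean_b=float(b.mean()), t_statistic=float(t),
                         p_value=float(p), alpha=alpha,
                         significant=bool(p < alpha), welch=welch)


def window_feature_importance(
        X: np.ndarray, labels: Sequence[int],
        e_bins: Sequence[int], p_bins: Sequence[int],
        channels: Sequence[str],
        estimator=None, neighborhood: int = 2,
        seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Importance of each (anchor-relative window, signal feature) cell.

    Flattens the windows ``e-neighborhood .. e+neighborhood`` and
    ``p-neighborhood .. p+neighborhood`` of every pair (signal channels only;
    the distance channel, if present, is dropped) into tabular columns, fits
    an importance-yielding classifier (random forest by default), and returns
    a long table of per-cell importances plus the per-feature average over
    the selected windows.
    """
    X = np.asarray(X)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature importance needs both classes")
    feat_idx = [i for i, c in enumerate(channels) if c != "distance"]
    feat_names = [channels[i] for i in feat_idx]
    n, bins, _ = X.shape
    offsets = list(range(-neighborhood, neighborhood + 1))
    col_names: list[tuple[str, str]] = []
    cols = []
    for anchor, bins_arr in (("e", np.asarray(e_bins)), ("p", np.asarray(p_bins))):
        for off in offsets:
            idx = np.clip(bins_arr + off, 0, bins - 1)
            tag = anchor if off == 0 else f"{anchor}{off:+d}"
            for ci, cname in zip(feat_idx, feat_names):
                cols.append(X[np.arange(n), idx, ci])
                col_names.append((tag, cname))
    table = np.column_stack(cols)
    if estimator is None:
        from sklearn.ensemble import RandomForestClassifier
        estimator = RandomForestClassifier(n_estimators=200, random_state=seed)
    estimator.fit(table, y)
    importances = np.asarray(estimator.feature_importances_)
    out = pd.DataFrame({"window": [w for w, _ in col_names],
                        "feature": [f for _, f in col_names],
                        "importance": importances})
    per_feature = out.groupby("feature", sort=False)["importance"].mean()
    return out, per_feature
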