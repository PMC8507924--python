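"""Repeated leave-one-out cross-validation and the six-metric panel.

Each LOOCV fold holds out one subject and, on the remaining n-1 only, refits
the preprocessing (median imputation + z-scoring), optionally the RF-RFE
feature selection, and the gradient-boosting classifier — the leakage-safe
default.  The ``paper_faithful`` switch instead performs feature selection
once on the full cohort before the folds, which reproduces the common (and
optimistic) shortcut of selecting features outside cross-validation; a
leakage warning is logged when it is used.

The metric panel: accuracy, precision, recall, F1 (positive class =
short-term survival, the clinically urgent class; macro averages alongside),
the Mann-Whitney AUC (ties count 1/2) and the Matthews correlation
coefficient.  Trial-to-trial variation of repeated LOOCV comes from
reseeding the stochastic components (RFE forests, boosting subsampling); the
folds themselves are deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .learners import fit_gboost, rf_rfe, tune_hyperparameters
from .radiomics import FeatureTable

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc", "mcc")


class EvaluationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    mcc: float
    precision_macro: float
    recall_macro: float
    f1_macro: float

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0",
                      stacklevel=3)
        return 0.0
    return num / den


def auc_mann_whitney(y_true: Sequence[int],
                     y_prob: Sequence[float]) -> float:
    """AUC as the Mann-Whitney pair statistic, ties counted 1/2."""
    y = np.asarray(y_true)
    p = np.asarray(y_prob, dtype=np.float64)
    pos = p[y == 1]
    neg = p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    return precision, recall, f1


def confusion_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                      y_prob: Optional[Sequence[float]] = None) -> Metrics:
    """The full metric panel from labels, hard predictions and (for AUC)
    held-out probabilities.  Positive class is 1."""
    y = np.asarray(y_true).astype(np.int64)
    yp = np.asarray(y_pred).astype(np.int64)
    if y.shape != yp.shape:
        raise EvaluationError("y_true and y_pred lengths differ")
    tp = int(np.sum((y == 1) & (yp == 1)))
    tn = int(np.sum((y == 0) & (yp == 0)))
    fp = int(np.sum((y == 0) & (yp == 1)))
    fn = int(np.sum((y == 1) & (yp == 0)))
    n = len(y)
    accuracy = _safe_div(tp + tn, n, "accuracy")
    precision, recall, f1 = _prf(tp, fp, fn)
    prec0, rec0, f10 = _prf(tn, fn, fp)   # the negative class, mirrored
    single_class = len(np.unique(y)) < 2
    if single_class:
        warnings.warn("single-class y_true: AUC and MCC undefined",
                      stacklevel=2)
        auc = np.nan
        mcc = np.nan
    else:
        denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
        auc = (auc_mann_whitney(y, y_prob)
               if y_prob is not None else np.nan)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   f1=f1, auc=auc, mcc=float(mcc),
                   precision_macro=(precision + prec0) / 2,
                   recall_macro=(recall + rec0) / 2,
                   f1_macro=(f1 + f10) / 2)


def roc_points(y_true: Sequence[int],
               y_prob: Sequence[float]) -> np.ndarray:
    """ROC polyline (FPR, TPR) from thresholds swept over the unique
    probabilities in descending order; starts at (0,0), ends at (1,1), and
    its trapezoidal area equals the Mann-Whitney AUC."""
    y = np.asarray(y_true).astype(np.int64)
    p = np.asarray(y_prob, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both classes")
    pts = [(0.0, 0.0)]
    for thr in np.unique(p)[::-1]:
        sel = p >= thr
        tpr = float((y[sel] == 1).sum()) / n_pos
        fpr = float((y[sel] == 0).sum()) / n_neg
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.asarray(pts)


@dataclass
class EvalConfig:
    """Classification pipeline settings for one LOOCV run."""

    use_rfe: bool = True
    n_select: int = 60
    rfe_step_fraction: float = 0.1
    rfe_trees: int = 200
    rfe_mtry: Optional[int] = None
    n_estimators: int = 100
    learning_rate: float = 0.1
    max_depth: int = 2
    subsample: float = 1.0
    min_leaf: int = 1
    tune: bool = False
    tune_grid: Optional[List[Dict]] = None
    inner_folds: int = 5
    paper_faithful: bool = False
    threshold: float = 0.5
    positive_class: str = "short"

    def as_dict(self) -> Dict[str, object]:
        return asdict(self)


def _fold_preprocess(train: pd.DataFrame,
                     test: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute and z-score with statistics from the training fold."""
    med = train.median().fillna(0.0)
    tr = train.fillna(med)
    te = test.fillna(med)
    mean = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (tr - mean) / sd, (te - mean) / sd


def loocv_run(table: FeatureTable, config: EvalConfig,
              trial_seed: int = 0) -> pd.DataFrame:
    """One leave-one-out pass: per-subject held-out probability and class."""
    raw = table.raw
    y = table.y01(config.positive_class)
    n = len(raw)
    if n < 2:
        raise EvaluationError("LOOCV needs at least 2 subjects")
    if len(np.unique(y)) < 2:
        raise EvaluationError("LOOCV needs both classes")
    rng = np.random.default_rng(trial_seed)
    preselected: Optional[List[str]] = None
    if config.use_rfe and config.paper_faithful:
        logger.warning(
            "paper-faithful mode: feature selection on the full cohort "
            "before cross-validation leaks test information")
        full_std, _ = _fold_preprocess(raw, raw)
        preselected = rf_rfe(
            full_std, y, n_select=config.n_select,
            step_fraction=config.rfe_step_fraction,
            n_trees=config.rfe_trees, mtry=config.rfe_mtry,
            seed=int(rng.integers(0, 2 ** 31 - 1))).selected
    rows = []
    for i in range(n):
        fold_rng = np.random.default_rng([trial_seed, i])
        train_raw = raw.drop(raw.index[i])
        test_raw = raw.iloc[[i]]
        y_train = np.delete(y, i)
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %d: single-class training data; "
                           "predicting the majority class", i)
            majority = int(round(float(y_train.mean())))
            rows.append({"subject_id": raw.index[i], "y_true": int(y[i]),
                         "y_prob": float(y_train.mean()),
                         "y_pred": majority})
            continue
        train_std, test_std = _fold_preprocess(train_raw, test_raw)
        if config.use_rfe:
            if preselected is not None:
                cols = preselected
            else:
                cols = rf_rfe(
                    train_std, y_train, n_select=config.n_select,
                    step_fraction=config.rfe_step_fraction,
                    n_trees=config.rfe_trees, mtry=config.rfe_mtry,
                    seed=int(fold_rng.integers(0, 2 ** 31 - 1))).selected
            train_std = train_std[cols]
            test_std = test_std[cols]
        params = {"n_estimators": config.n_estimators,
                  "learning_rate": config.learning_rate,
                  "max_depth": config.max_depth,
                  "subsample": config.subsample}
        if config.tune:
            params = tune_hyperparameters(
                train_std, y_train, grid=config.tune_grid,
                inner_folds=config.inner_folds,
                seed=int(fold_rng.integers(0, 2 ** 31 - 1)))
        model = fit_gboost(train_std, y_train, min_leaf=config.min_leaf,
                           seed=int(fold_rng.integers(0, 2 ** 31 - 1)),
                           **params)
        prob = float(model.predict_proba(test_std)[0])
        rows.append({"subject_id": raw.index[i], "y_true": int(y[i]),
                     "y_prob": prob,
                     "y_pred": int(prob >= config.threshold)})
    return pd.DataFrame(rows)


@dataclass
class CVReport:
    """Repeated-LOOCV outcome: per-trial predictions, the metric panel per
    trial, their mean/SD, and the pooled ROC of the first trial."""

    predictions: List[pd.DataFrame]
    trial_metrics: pd.DataFrame
    mean_metrics: Dict[str, float]
    sd_metrics: Dict[str, float]
    roc: np.ndarray
    config: Dict[str, object]
    base_seed: int

    @property
    def per_trial_accuracy(self) -> np.ndarray:
        return self.trial_metrics["accuracy"].to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "base_seed": self.base_seed,
            "config": self.config,
            "n_trials": len(self.predictions),
            "trial_metrics": self.trial_metrics.to_dict(orient="records"),
            "mean_metrics": self.mean_metrics,
            "sd_metrics": self.sd_metrics,
            "roc_points": self.roc.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def save_roc_csv(self, path) -> None:
        pd.DataFrame(self.roc, columns=["fpr", "tpr"]).to_csv(
            path, index=False, float_format="%.10g")

    def save_accuracy_csv(self, path) -> None:
        pd.DataFrame({"trial": np.arange(1, len(self.predictions) + 1),
                      "accuracy": self.per_trial_accuracy}).to_csv(
            path, index=False, float_format="%.10g")

    def plot_roc(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4.2, 4))
        ax.plot(self.roc[:, 0], self.roc[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"held-out ROC (AUC={self.mean_metrics['auc']:.3f})")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def plot_trial_accuracies(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        acc = self.per_trial_accuracy
        fig, ax = plt.subplots(figsize=(5.5, 3.2))
        ax.plot(np.arange(1, len(acc) + 1), acc, marker="o", ms=3)
        ax.axhline(acc.mean(), color="firebrick", lw=0.8,
                   label=f"mean {acc.mean():.3f}")
        ax.set_xlabel("LOOCV trial")
        ax.set_ylabel("held-out accuracy")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def repeated_trials(table: FeatureTable, config: EvalConfig,
                    n_trials: int = 50, base_seed: int = 0) -> CVReport:
    """Repeat LOOCV ``n_trials`` times with per-trial derived seeds."""
    if n_trials < 1:
        raise EvaluationError("n_trials must be >= 1")
    trial_seeds = np.random.default_rng(base_seed).integers(
        0, 2 ** 31 - 1, size=n_trials)
    predictions: List[pd.DataFrame] = []
    metric_rows = []
    for t, ts in enumerate(trial_seeds):
        preds = loocv_run(table, config, trial_seed=int(ts))
        predictions.append(preds)
        m = confusion_metrics(preds["y_true"], preds["y_pred"],
                              preds["y_prob"])
        row = {"trial": t + 1}
        row.update(m.as_dict())
        metric_rows.append(row)
    trial_metrics = pd.DataFrame(metric_rows)
    panel = trial_metrics.drop(columns="trial")
    mean_metrics = {k: float(v) for k, v in panel.mean().items()}
    sd_metrics = {k: float(v) for k, v in panel.std(ddof=1).items()} \
        if n_trials > 1 else {k: 0.0 for k in panel.columns}
    first = predictions[0]
    roc = roc_points(first["y_true"], first["y_prob"])
    return CVReport(predictions=predictions, trial_metrics=trial_metrics,
                    mean_metrics=mean_metrics, sd_metrics=sd_metrics,
                    roc=roc, config=config.as_dict(), base_seed=base_seed)
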