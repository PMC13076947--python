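"""Cross-validation protocol and evaluation metrics.

Regression: MSE, RMSE, Pearson correlation; a t-based 95% confidence interval
summarizes per-fold MSEs.  Classification treats the predicted continuous
score through the same published synergy cut as the ground-truth labels, so
AUC/AUPR/ACC/F1/Cohen's kappa are a deterministic view of the regression
output (positive = synergistic).

Folds are stratified on the 3-class interaction label so rare synergistic
pairs are spread evenly: records are grouped by class, shuffled with the
seed, and dealt round-robin; strata smaller than k are merged into the
largest stratum with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import (accuracy_score, average_precision_score,
                             cohen_kappa_score, f1_score, roc_auc_score)


@dataclass
class FoldAssignment:
    k: int
    assignment: np.ndarray  # record index -> fold id
    key: str
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(len(self.assignment))
        return idx[self.assignment != fold], idx[self.assignment == fold]


def stratified_kfold(strata, k: int = 10, seed: int = 0,
                     key: str = "interaction class") -> FoldAssignment:
    """Stratified k-fold assignment: shuffle within each stratum, deal
    round-robin.  Fold sizes within a stratum differ by at most one."""
    strata = np.asarray(strata)
    n = len(strata)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} records")
    groups: dict = {}
    for idx, s in enumerate(strata):
        groups.setdefault(s, []).append(idx)
    # merge strata too small to spread over k folds into the largest stratum
    sizes = {s: len(v) for s, v in groups.items()}
    largest = max(sizes, key=lambda s: sizes[s])
    merged = []
    for s in list(groups):
        if s != largest and len(groups[s]) < k:
            warnings.warn(
                f"stratum {s!r} has {len(groups[s])} < k={k} records; "
                f"merged into stratum {largest!r}")
            merged.extend(groups.pop(s))
    if merged:
        groups[largest].extend(merged)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    start = 0  # rotate the dealing origin between strata to balance folds
    for s in sorted(groups, key=str):
        idx = np.array(groups[s])
        rng.shuffle(idx)
        for pos, record in enumerate(idx):
            assignment[record] = (start + pos) % k
        start = (start + len(idx)) % k
    return FoldAssignment(k, assignment, key, seed)


@dataclass
class RegressionMetrics:
    mse: float
    rmse: float
    pcc: float  # NaN when undefined (constant input)
    pcc_defined: bool = True

    def as_dict(self) -> dict:
        return {"mse": self.mse, "rmse": self.rmse, "pcc": self.pcc}


def regression_metrics(y, y_hat) -> RegressionMetrics:
    """MSE, RMSE and Pearson correlation between truth and prediction."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError(f"length mismatch or empty: {y.shape} vs {y_hat.shape}")
    mse = float(np.mean((y - y_hat) ** 2))
    rmse = float(np.sqrt(mse))
    if np.std(y) == 0 or np.std(y_hat) == 0:
        warnings.warn("Pearson correlation undefined for constant input")
        return RegressionMetrics(mse, rmse, float("nan"), pcc_defined=False)
    pcc = float(scipy.stats.pearsonr(y, y_hat).statistic)
    return RegressionMetrics(mse, rmse, pcc)


def mse_confidence_interval(per_fold_mse, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the mean of per-fold MSEs:
    mean +/- t_{(1+level)/2, k-1} * sd / sqrt(k)."""
    vals = np.asarray(per_fold_mse, dtype=float)
    k = vals.size
    if k < 2:
        raise ValueError("confidence interval requires at least 2 folds")
    mean = float(vals.mean())
    half = float(scipy.stats.t.ppf((1 + level) / 2, k - 1)
                 * vals.std(ddof=1) / np.sqrt(k))
    return mean - half, mean + half


@dataclass
class ClassificationMetrics:
    auc: float
    aupr: float
    acc: float
    f1: float
    kappa: float
    rank_defined: bool = True  # AUC/AUPR defined (both classes present)

    def as_dict(self) -> dict:
        return {"auc": self.auc, "aupr": self.aupr, "acc": self.acc,
                "f1": self.f1, "kappa": self.kappa}


def classification_metrics(labels, scores, threshold: float) -> ClassificationMetrics:
    """Binary classification view of continuous predictions.

    ``labels`` are binary ground truth (1 = synergistic); ``scores`` are
    predicted continuous synergy values.  AUC uses the rank (Mann-Whitney)
    formulation with midrank tie correction; AUPR is precision-recall step
    integration; ACC/F1/kappa binarize the scores at ``threshold`` (the same
    published synergy cut used to label the ground truth).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size == 0:
        raise ValueError("labels/scores length mismatch or empty")
    preds = (scores >= threshold).astype(int)
    acc = float(accuracy_score(labels, preds))
    f1 = float(f1_score(labels, preds, zero_division=0))
    kappa = float(cohen_kappa_score(labels, preds))
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC/AUPR undefined with a single class present")
        return ClassificationMetrics(float("nan"), float("nan"), acc, f1, kappa,
                                     rank_defined=False)
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    return ClassificationMetrics(auc, aupr, acc, f1, kappa)


@dataclass
class MetricReport:
    """Per-fold and aggregate metrics of one cross-validated run."""

    per_fold: list[dict] = field(default_factory=list)

    def add_fold(self, fold: int, reg: RegressionMetrics,
                 clf: ClassificationMetrics | None = None) -> None:
        row = {"fold": fold, **reg.as_dict()}
        if clf is not None:
            row.update(clf.as_dict())
        self.per_fold.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold).set_index("fold")

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
        lo, hi = mse_confidence_interval(df["mse"].to_numpy())
        out.attrs["mse_ci95"] = (lo, hi)
        return out

    def mse_ci95(self) -> tuple[float, float]:
        return mse_confidence_interval(self.to_frame()["mse"].to_numpy())
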