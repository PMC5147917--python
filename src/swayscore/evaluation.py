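"""Evaluation protocol: stratified split, ROC/AUC, per-descriptor report.

The protocol mirrors a single stratified 70/30 train-test split: the forest
is fit on the training subjects and its scores are judged by the ROC curve
and AUC on the held-out subjects.  Alongside, every descriptor gets a
univariate report: class means/stds, the two-tailed Wilcoxon rank-sum
p-value, and the AUC of a soft-margin linear 1-D SVM trained on the same
split.  The positive class is "non-faller" throughout, consistent with the
score direction (100 = high quality balance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .forest import ForestConfig, RankingForestModel, fit_forest

__all__ = ["SplitConfig", "ROCResult", "stratified_split", "roc_auc",
           "wilcoxon_ranksum", "univariate_auc", "descriptor_report",
           "DescriptorReport"]


@dataclass(frozen=True)
class SplitConfig:
    """Stratified train/test split: per-class fractions are preserved."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split(labels, cfg: SplitConfig = SplitConfig()):
    """Split indices per class with a seeded shuffle.

    Per class, ``round(train_fraction * n_class)`` records go to train,
    adjusted so both sets keep at least one record of each class.  Returns
    sorted (train_idx, test_idx).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 records")
        perm = rng.permutation(idx)
        n_train = int(round(cfg.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and area; fpr/tpr run from (0, 0) to (1, 1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC by threshold sweep; trapezoidal AUC.

    ``labels`` are truthy for the positive class (non-faller).  The AUC
    equals the Mann-Whitney pair statistic with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group ties: cumulative counts at each distinct threshold
    distinct = np.nonzero(np.diff(s))[0]
    last = np.concatenate([distinct, [len(s) - 1]])
    cum_pos = np.cumsum(y)[last]
    cum_neg = (last + 1) - cum_pos
    tpr = np.concatenate([[0.0], cum_pos / n_pos])
    fpr = np.concatenate([[0.0], cum_neg / n_neg])
    thresholds = np.concatenate([[np.inf], s[last]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def wilcoxon_ranksum(a, b, method: str = "auto") -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``method="auto"`` uses exact enumeration when both groups have at most
    10 tie-free observations, otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def univariate_auc(values, labels, train_idx, test_idx, C: float = 1.0) -> float:
    """Test AUC of a soft-margin linear 1-D SVM on a single descriptor.

    The SVM is fit on the training rows of the feature; the AUC of its signed
    decision values on the test rows is returned as-is (no reorientation, so
    values below 0.5 are possible).  A constant training feature yields 0.5
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    x_tr = values[train_idx]
    if np.ptp(x_tr) == 0.0:
        warnings.warn("constant feature; univariate AUC defaults to 0.5")
        return 0.5
    svm = SVC(kernel="linear", C=C)
    svm.fit(x_tr.reshape(-1, 1), labels[train_idx])
    decision = svm.decision_function(values[test_idx].reshape(-1, 1))
    return roc_auc(decision, labels[test_idx]).auc


@dataclass
class DescriptorReport:
    """Per-descriptor class statistics plus the forest AUC row.

    ``table`` has one row per descriptor (class means/stds on the full
    cohort, univariate SVM AUC on the split, Wilcoxon two-tailed p) and a
    final forest row carrying only the held-out AUC.
    """

    table: pd.DataFrame
    roc: ROCResult
    model: RankingForestModel
    n_train: int
    n_test: int

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.3g}")


def descriptor_report(features, is_faller, split_cfg: SplitConfig = SplitConfig(),
                      forest_cfg: ForestConfig = ForestConfig(),
                      feature_names=FEATURE_NAMES) -> DescriptorReport:
    """Run the full evaluation protocol on a feature matrix.

    ``features`` is (n, 5); ``is_faller`` truthy for fallers.  Class means
    and stds are computed on the full cohort; univariate and forest AUCs on
    the stratified split.
    """
    X = np.asarray(features, dtype=float)
    fall = np.asarray(is_faller).astype(bool)
    y_pos = ~fall  # positive class: non-faller
    train_idx, test_idx = stratified_split(fall, split_cfg)

    model = fit_forest(X[train_idx], y_pos[train_idx], forest_cfg,
                       feature_names=feature_names)
    roc = roc_auc(model.score(X[test_idx]), y_pos[test_idx])

    rows = []
    for j, name in enumerate(feature_names):
        col = X[:, j]
        rows.append({
            "descriptor": name,
            "faller_mean": col[fall].mean(),
            "faller_std": col[fall].std(ddof=1),
            "nonfaller_mean": col[~fall].mean(),
            "nonfaller_std": col[~fall].std(ddof=1),
            "auc": univariate_auc(col, y_pos, train_idx, test_idx),
            "p_wilcoxon": wilcoxon_ranksum(col[fall], col[~fall]),
        })
    rows.append({"descriptor": "ranking_forest",
                 "faller_mean": np.nan, "faller_std": np.nan,
                 "nonfaller_mean": np.nan, "nonfaller_std": np.nan,
                 "auc": roc.auc, "p_wilcoxon": np.nan})
    table = pd.DataFrame(rows).set_index("descriptor")
    return DescriptorReport(table=table, roc=roc, model=model,
                            n_train=len(train_idx), n_test=len(test_idx))
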