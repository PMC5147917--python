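"""Model/Results facade over the scoring pipeline.

`BalanceScoreModel` holds a cohort's descriptor matrix and fall labels;
`fit()` runs the stratified split, fits the ranking forest on the training
subjects and evaluates the full protocol, returning a
`BalanceScoreResults` with the fitted forest, feature importances, the ROC
curve and the per-descriptor report, plus a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (DescriptorReport, SplitConfig, descriptor_report,
                         roc_auc)
from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .forest import ForestConfig, RankingForestModel

__all__ = ["BalanceScoreModel", "BalanceScoreResults"]


class BalanceScoreModel:
    """Fall-risk scoring model for a cohort of descriptor vectors.

    Parameters
    ----------
    features : (n, 5) array-like
        One row per subject, columns in :data:`FEATURE_NAMES` order.
    is_faller : (n,) boolean array-like
        Fall label per subject (True = faller).
    """

    def __init__(self, features, is_faller, feature_names=FEATURE_NAMES,
                 subject_ids=None,
                 forest_config: ForestConfig = ForestConfig(),
                 split_config: SplitConfig = SplitConfig()):
        self.features = np.asarray(features, dtype=float)
        self.is_faller = np.asarray(is_faller).astype(bool)
        if self.features.ndim != 2 or len(self.features) != len(self.is_faller):
            raise ValueError("features must be (n, d) with one label per row")
        self.feature_names = tuple(feature_names)
        self.subject_ids = (list(subject_ids) if subject_ids is not None
                            else [f"S{i}" for i in range(len(self.is_faller))])
        self.forest_config = forest_config
        self.split_config = split_config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       **kwargs) -> "BalanceScoreModel":
        """Build from a feature table (as written by the pipeline)."""
        labels = df[label_col]
        if labels.dtype == object:
            fall = labels.astype(str).str.strip().str.lower().isin(
                ("faller", "1", "true"))
        else:
            fall = labels.astype(bool)
        ids = df["subject_id"].tolist() if "subject_id" in df else None
        return cls(df[list(FEATURE_NAMES)].to_numpy(), fall.to_numpy(),
                   subject_ids=ids, **kwargs)

    @classmethod
    def from_subjects(cls, subjects,
                      feature_config: FeatureConfig = FeatureConfig(),
                      **kwargs) -> "BalanceScoreModel":
        """Extract descriptors from raw subject records, then build."""
        X = np.vstack([extract_features(s, feature_config).to_array()
                       for s in subjects])
        return cls(X, [s.is_faller for s in subjects],
                   subject_ids=[s.subject_id for s in subjects], **kwargs)

    def fit(self) -> "BalanceScoreResults":
        """Run split + forest fit + evaluation protocol."""
        report = descriptor_report(self.features, self.is_faller,
                                   self.split_config, self.forest_config,
                                   self.feature_names)
        return BalanceScoreResults(self, report)


@dataclass
class BalanceScoreResults:
    """Fitted forest plus the evaluation of one train/test split."""

    model: BalanceScoreModel
    report: DescriptorReport

    @property
    def forest(self) -> RankingForestModel:
        return self.report.model

    @property
    def auc(self) -> float:
        """Held-out AUC of the forest score (positive class: non-faller)."""
        return self.report.roc.auc

    @property
    def roc(self):
        return self.report.roc

    def score(self, features=None) -> np.ndarray:
        """Balance scores in [0, 100] for new (or the cohort's) subjects."""
        if features is None:
            features = self.model.features
        return self.forest.score(features)

    def importances(self) -> pd.DataFrame:
        mean, std = self.forest.feature_importances()
        return pd.DataFrame({"mean": mean, "std": std},
                            index=list(self.model.feature_names))

    def summary(self) -> str:
        """Human-readable account of the fit and the evaluation."""
        m = self.model
        lines = [
            "Balance ranking-forest score",
            "=" * 64,
            f"subjects: {len(m.is_faller)}  "
            f"(fallers {int(m.is_faller.sum())}, "
            f"non-fallers {int((~m.is_faller).sum())})",
            f"split: train {self.report.n_train} / test {self.report.n_test} "
            f"(fraction {m.split_config.train_fraction}, "
            f"seed {m.split_config.seed})",
            f"forest: {m.forest_config.n_trees} trees, "
            f"max depth {m.forest_config.max_depth}, "
            f"{m.forest_config.features_per_split}/5 features per split",
            f"held-out forest AUC: {self.auc:.3f}",
            "",
            "Per-descriptor report (class stats on full cohort; AUC on split)",
            "-" * 64,
            self.report.table.to_string(float_format=lambda v: f"{v:.3g}"),
            "",
            "Feature importances (mean +- std over trees)",
            "-" * 64,
            self.importances().to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the forest score on the held-out subjects."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr,
                label=f"ranking forest (AUC = {self.auc:.2f})")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title("Balance score ROC (positive class: non-faller)")
        ax.legend(loc="lower right")
        return ax
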