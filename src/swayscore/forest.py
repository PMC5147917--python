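"""Ranking forest: a bagged ensemble of cross-entropy scoring trees.

Each of the (default 50) trees is grown on a random subsample of the training
records, drawing a random subset of the descriptors at every node and picking
the (feature, threshold) split that minimises the size-weighted cross-entropy
of the children.  A leaf scores the fraction of non-fallers among the training
records it holds (Laplace-smoothed by default); the forest score of a subject
is 100 times the mean leaf score over the trees, so 100 reads as "high
quality balance" and 0 as maximal fall risk.

Everything is deterministic given (data, config, seed), and models round-trip
losslessly through versioned JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .features import FEATURE_NAMES

__all__ = ["ForestConfig", "TreeNode", "RankingTree", "RankingForestModel",
           "fit_tree", "fit_forest", "cross_entropy"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Hyper-parameters of the scoring forest.

    ``features_per_split=3`` keeps a majority of the five descriptors in play
    at each node while still decorrelating trees; subsampling is without
    replacement ("a randomly selected subset", not a bootstrap).
    """

    n_trees: int = 50
    max_depth: int = 5
    min_leaf: int = 5
    features_per_split: int = 3
    subsample_fraction: float = 0.8
    laplace: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.features_per_split:
            raise ValueError("features_per_split must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


def cross_entropy(n_pos: int, n_neg: int) -> float:
    """Binary cross-entropy (log-loss impurity) of a node, in nats."""
    n = n_pos + n_neg
    if n == 0 or n_pos == 0 or n_neg == 0:
        return 0.0
    p = n_pos / n
    return float(-(p * np.log(p) + (1.0 - p) * np.log(1.0 - p)))


@dataclass
class TreeNode:
    """A node of a scoring tree; a leaf iff ``feature is None``.

    ``score`` is the (possibly Laplace-smoothed) non-faller fraction of the
    training records reaching the node; it is populated for every node so the
    tree can be inspected, but only leaf scores enter the forest score.
    """

    n: int
    n_pos: int
    score: float
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "n_pos": self.n_pos, "score": self.score}
        if not self.is_leaf:
            d["feature"] = self.feature
            d["threshold"] = self.threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n=d["n"], n_pos=d["n_pos"], score=d["score"])
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _leaf_score(n_pos: int, n: int, laplace: bool) -> float:
    if laplace:
        return (n_pos + 0.5) / (n + 1.0)
    return n_pos / n


def _best_split(X: np.ndarray, y: np.ndarray, feat_idx: np.ndarray,
                min_leaf: int):
    """Exhaustive best (feature, threshold) among the drawn features.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values.  Ties in impurity break on the lowest feature index, then the
    smallest threshold (guaranteed by scan order and strict improvement).
    Returns (feature, threshold, gain_weighted) or None.
    """
    n = len(y)
    parent = cross_entropy(int(y.sum()), int(n - y.sum()))
    best = None
    best_impurity = np.inf
    for f in np.sort(feat_idx):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        cum_pos = np.cumsum(ys)
        total_pos = cum_pos[-1]
        # split after position i: left = first i+1 samples
        for i in range(n - 1):
            if xs[i + 1] <= xs[i]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            lp = int(cum_pos[i])
            rp = int(total_pos - lp)
            imp = (n_left * cross_entropy(lp, n_left - lp)
                   + n_right * cross_entropy(rp, n_right - rp)) / n
            if imp < best_impurity - 1e-15:
                best_impurity = imp
                best = (int(f), float((xs[i] + xs[i + 1]) / 2.0),
                        parent - imp)
    return best


def fit_tree(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
             cfg: ForestConfig) -> "RankingTree":
    """Grow one cross-entropy scoring tree on (X, y), y = 1 for non-faller."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot fit a tree on empty data")
    n_features = X.shape[1]
    importances = np.zeros(n_features)
    n_root = len(y)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        n = len(idx)
        n_pos = int(y[idx].sum())
        node = TreeNode(n=n, n_pos=n_pos,
                        score=_leaf_score(n_pos, n, cfg.laplace))
        pure = n_pos == 0 or n_pos == n
        if depth >= cfg.max_depth or pure or n < 2 * cfg.min_leaf:
            return node
        k = min(cfg.features_per_split, n_features)
        feats = rng.choice(n_features, size=k, replace=False)
        split = _best_split(X[idx], y[idx], feats, cfg.min_leaf)
        if split is None:
            return node
        f, thr, gain = split
        importances[f] += (n / n_root) * gain
        mask = X[idx, f] <= thr
        node.feature = f
        node.threshold = thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    root = grow(np.arange(len(y)), 0)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    else:  # stump: no split anywhere, attribute importance uniformly
        importances = np.full(n_features, 1.0 / n_features)
    return RankingTree(root=root, importances=importances)


@dataclass
class RankingTree:
    """One fitted scoring tree with its normalised importance vector."""

    root: TreeNode
    importances: np.ndarray

    def score_one(self, x: np.ndarray) -> float:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.score

    def to_dict(self) -> dict:
        return {"root": self.root.to_dict(),
                "importances": [float(v) for v in self.importances]}

    @classmethod
    def from_dict(cls, d: dict) -> "RankingTree":
        return cls(root=TreeNode.from_dict(d["root"]),
                   importances=np.asarray(d["importances"], dtype=float))


def fit_forest(X: np.ndarray, y: np.ndarray,
               cfg: ForestConfig = ForestConfig(),
               feature_names=FEATURE_NAMES) -> "RankingForestModel":
    """Fit the bagged scoring forest; deterministic given (X, y, cfg.seed)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit scoring forest on one class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    n_sub = max(2, int(round(cfg.subsample_fraction * n)))
    trees = []
    for _ in range(cfg.n_trees):
        idx = rng.choice(n, size=n_sub, replace=False)
        trees.append(fit_tree(X[idx], y[idx], rng, cfg))
    return RankingForestModel(trees=trees, config=cfg,
                              feature_names=tuple(feature_names))


@dataclass
class RankingForestModel:
    """A fitted ranking forest emitting balance scores in [0, 100]."""

    trees: list
    config: ForestConfig
    feature_names: tuple = FEATURE_NAMES

    def score(self, X) -> np.ndarray:
        """Balance score(s) in [0, 100]; higher = more non-faller-like."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("cannot score non-finite features")
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        leaf = np.array([[t.score_one(x) for t in self.trees] for x in X])
        return 100.0 * leaf.mean(axis=1)

    def faller_probability(self, X) -> np.ndarray:
        return 1.0 - self.score(X) / 100.0

    def feature_importances(self):
        """(mean, std) of the per-tree normalised importances.

        Means sum to 1; std is the sample standard deviation over trees.
        """
        mat = np.vstack([t.importances for t in self.trees])
        std = mat.std(axis=0, ddof=1) if len(self.trees) > 1 else np.zeros(mat.shape[1])
        return mat.mean(axis=0), std

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "config": asdict(self.config),
            "feature_names": list(self.feature_names),
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_dict(cls, d: dict) -> "RankingForestModel":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return cls(trees=[RankingTree.from_dict(t) for t in d["trees"]],
                   config=ForestConfig(**d["config"]),
                   feature_names=tuple(d["feature_names"]))

    @classmethod
    def load(cls, path) -> "RankingForestModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
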