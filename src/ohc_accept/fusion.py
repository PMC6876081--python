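"""Feature fusion and cross-validated gradient-boosting evaluation.

The acceptance classifier consumes h_i = (h_i_text, h_i_num): the
textual feature vector from the trained sentence encoder concatenated
with the encoded tabular attributes.  Evaluation follows the three-way
comparison protocol — textual features only, numerical features only,
and both — on identical stratified 5-fold splits, reporting each metric
as mean +- std over folds.

Answers to the same question share text and patient attributes, so by
default folds are grouped by question to avoid leakage across the
train/test boundary.  The boosted-tree backend is pluggable
("sklearn" gradient boosting by default; "xgboost"/"lightgbm" when
installed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .metrics import MetricsReport, evaluate

__all__ = [
    "ClassifierConfig",
    "ComparisonResult",
    "make_classifier",
    "fuse",
    "train_eval_cv",
    "compare_feature_sets",
    "render_table",
]

MODES = ("textual", "numerical", "all")


@dataclass
class ClassifierConfig:
    """Boosted-tree settings; defaults are the common 100/3/0.1 recipe."""

    backend: str = "sklearn"
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    n_folds: int = 5
    group_by_question: bool = True
    threshold: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def make_classifier(config: ClassifierConfig):
    """Instantiate the gradient-boosting backend."""
    kw = dict(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    )
    if config.backend == "sklearn":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(**kw)
    if config.backend == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(eval_metric="logloss", **kw)
    if config.backend == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(verbose=-1, **kw)
    raise ValueError(f"unknown classifier backend {config.backend!r}")


def fuse(
    features_text: np.ndarray | None,
    features_num: np.ndarray | None,
    labels: Sequence[int],
    mode: str = "all",
) -> tuple[np.ndarray, np.ndarray]:
    """Select and concatenate feature blocks (text first, then numeric)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    y = np.asarray(labels, dtype=np.int64)
    blocks = []
    if mode in ("textual", "all"):
        if features_text is None:
            raise ValueError(f"mode {mode!r} needs textual features")
        blocks.append(np.asarray(features_text, dtype=np.float64))
    if mode in ("numerical", "all"):
        if features_num is None:
            raise ValueError(f"mode {mode!r} needs numerical features")
        blocks.append(np.asarray(features_num, dtype=np.float64))
    for b in blocks:
        if b.shape[0] != y.shape[0]:
            raise ValueError("features and labels are misaligned")
    return np.hstack(blocks), y


@dataclass
class CVResult:
    """Per-fold metrics for one feature mode, plus mean +- std."""

    mode: str
    fold_reports: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    METRIC_NAMES = ("f1", "auc", "accuracy", "recall", "precision")

    def __post_init__(self) -> None:
        for name in self.METRIC_NAMES:
            vals = [getattr(r, name) for r in self.fold_reports]
            self.mean[name] = float(np.mean(vals))
            self.std[name] = float(np.std(vals))

    def fold_values(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.fold_reports]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": self.mean,
            "std": self.std,
        }


@dataclass
class ComparisonResult:
    """The three-way feature comparison on identical folds."""

    results: dict[str, CVResult]
    config: ClassifierConfig

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "modes": {m: r.to_dict() for m, r in self.results.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _fold_splits(y: np.ndarray, groups: np.ndarray | None, config: ClassifierConfig):
    if config.group_by_question and groups is not None:
        splitter = StratifiedGroupKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        return list(splitter.split(np.zeros_like(y), y, groups))
    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    return list(splitter.split(np.zeros_like(y), y))


def train_eval_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    groups: np.ndarray | None = None,
    mode: str = "all",
    splits=None,
) -> CVResult:
    """K-fold cross-validated training and evaluation of the classifier.

    Folds are stratified (and grouped by question when ``groups`` is
    given); each fold's held-out metrics come from
    :func:`ohc_accept.metrics.evaluate`.  Precomputed ``splits`` let the
    three-way comparison reuse identical folds.
    """
    config = config or ClassifierConfig()
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("cross-validation requires both classes")
    if splits is None:
        splits = _fold_splits(y, groups, config)
    reports: list[MetricsReport] = []
    for train_ix, test_ix in splits:
        if np.unique(y[test_ix]).size < 2:
            raise ValueError("a fold ended up with a single class; use stratified folds")
        clf = make_classifier(config)
        clf.fit(X[train_ix], y[train_ix])
        scores = clf.predict_proba(X[test_ix])[:, 1]
        reports.append(evaluate(scores, y[test_ix], threshold=config.threshold))
    return CVResult(mode=mode, fold_reports=reports)


def compare_feature_sets(
    features_text: np.ndarray,
    features_num: np.ndarray,
    labels: Sequence[int],
    config: ClassifierConfig | None = None,
    groups: np.ndarray | None = None,
) -> ComparisonResult:
    """Run the textual / numerical / all comparison on identical folds."""
    config = config or ClassifierConfig()
    y = np.asarray(labels, dtype=np.int64)
    splits = _fold_splits(y, groups, config)
    results = {}
    for mode in MODES:
        X, _ = fuse(features_text, features_num, y, mode=mode)
        results[mode] = train_eval_cv(X, y, config, mode=mode, splits=splits)
    return ComparisonResult(results=results, config=config)


def render_table(comparison: ComparisonResult) -> str:
    """Delimited-text table, one row per feature mode, "mean +-std" cells."""
    names = CVResult.METRIC_NAMES
    lines = ["\t".join(["features"] + [n.upper() if n == "auc" else n.capitalize() for n in names])]
    for mode in MODES:
        r = comparison.results[mode]
        cells = [f"{r.mean[n]:.3f} ±{r.std[n]:.3f}" for n in names]
        lines.append("\t".join([mode] + cells))
    return "\n".join(lines) + "\n"
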