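"""Feature selection, boosted-tree classification, and CV evaluation.

The boosting core is delegated to xgboost; this module owns its
configuration (tree count K, L2 penalty λ, leaf cap T, learning rate),
gain-based importance ranking with threshold pruning, and stratified
k-fold evaluation reporting sensitivity, specificity, and accuracy:

    SEN = TP/(TP+FN)·100%,  SPE = TN/(TN+FP)·100%,  ACC = (TP+TN)/N·100%.

Feature selection is refit inside each training fold by default so no
test-fold information leaks into the feature subset; a ``global_selection``
flag reproduces the riskier select-once-on-everything reading.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .features import COMPONENT_SEPARATOR, feature_domain, parse_feature_name

__all__ = [
    "ClassifierConfig",
    "ConfusionCounts",
    "EvaluationReport",
    "DEFAULT_IMPORTANCE_THRESHOLD",
    "fit_classifier",
    "predict",
    "importance_ranking",
    "select_features",
    "top_features",
    "confusion",
    "sen_spe_acc",
    "cross_validate",
]

DEFAULT_IMPORTANCE_THRESHOLD = 0.001
POSITIVE_CLASS = "seizure"


@dataclass(frozen=True)
class ClassifierConfig:
    """Boosted-tree hyperparameters.

    ``n_trees`` is the boosting-round count K, ``reg_lambda`` the L2
    penalty λ, ``max_leaves`` the per-tree leaf cap T (0 = governed by
    depth only).  Importance scores use total split gain, normalized.
    """

    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 6
    reg_lambda: float = 1.0
    max_leaves: int = 0
    seed: int = 0
    missing: str = "allow"  # allow | impute-median | error

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.max_leaves != 0 and self.max_leaves < 2:
            raise ValueError("max_leaves must be 0 (unlimited) or >= 2")
        if self.missing not in ("allow", "impute-median", "error"):
            raise ValueError(f"unknown missing policy {self.missing!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class FittedModel:
    """A trained booster plus the label vocabulary it was fitted with."""

    booster: XGBClassifier
    classes: list[str]
    feature_names: list[str]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        idx = self.booster.predict(x)
        return np.asarray(self.classes)[idx]


@dataclass
class EvaluationReport:
    """Per-fold and aggregate SEN/SPE/ACC percentages for a k-fold run."""

    k: int
    fold_metrics: pd.DataFrame  # columns SEN, SPE, ACC (NaN where undefined)
    per_class_sen_spe: dict[str, tuple[float, float]] = field(default_factory=dict)
    cv_seconds: float = 0.0
    n_samples: int = 0
    classes: list[str] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(self.fold_metrics[metric].mean())

    def std(self, metric: str) -> float:
        return float(self.fold_metrics[metric].std(ddof=0))

    def summary(self) -> dict[str, float]:
        out = {}
        for metric in ("SEN", "SPE", "ACC"):
            out[f"{metric}_mean"] = self.mean(metric)
            out[f"{metric}_sd"] = self.std(metric)
        return out

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "n_samples": self.n_samples,
            "classes": self.classes,
            "folds": self.fold_metrics.to_dict(orient="records"),
            "summary": self.summary(),
            "per_class_sen_spe": self.per_class_sen_spe,
            "cv_seconds": self.cv_seconds,
        }
        return json.dumps(payload, indent=2, default=float)

    def to_text(self) -> str:
        s = self.summary()

        def cell(metric: str) -> str:
            m, sd = s[f"{metric}_mean"], s[f"{metric}_sd"]
            return "-" if math.isnan(m) else f"{m:.2f} ± {sd:.2f}"

        lines = [
            f"{'SEN':>16} {'SPE':>16} {'ACC':>16} {'Time':>8}",
            f"{cell('SEN'):>16} {cell('SPE'):>16} {cell('ACC'):>16} "
            f"{self.cv_seconds:>7.1f}s",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fitting and importance
# ---------------------------------------------------------------------------


def _prepare_matrix(table: pd.DataFrame, cfg: ClassifierConfig) -> np.ndarray:
    x = table.to_numpy(dtype=float)
    finite = np.isfinite(x)
    if finite.all():
        return x
    if cfg.missing == "error":
        bad = table.columns[~finite.all(axis=0)].tolist()
        raise ValueError(f"non-finite values in features: {bad[:5]}")
    if cfg.missing == "impute-median":
        med = np.nanmedian(np.where(finite, x, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        return np.where(finite, x, med[None, :])
    return np.where(finite, x, np.nan)  # xgboost handles NaN natively


def fit_classifier(
    table: pd.DataFrame, labels, cfg: ClassifierConfig = ClassifierConfig()
) -> FittedModel:
    """Train a boosted-tree classifier; deterministic under a fixed seed."""
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    y = labels.map({c: i for i, c in enumerate(classes)}).to_numpy()
    x = _prepare_matrix(table, cfg)
    booster = XGBClassifier(
        n_estimators=cfg.n_trees,
        learning_rate=cfg.learning_rate,
        max_depth=cfg.max_depth,
        reg_lambda=cfg.reg_lambda,
        max_leaves=cfg.max_leaves,
        random_state=cfg.seed,
        tree_method="hist",
        n_jobs=1,
        objective="binary:logistic" if len(classes) == 2 else "multi:softprob",
        eval_metric="logloss",
        verbosity=0,
    )
    booster.fit(x, y)
    return FittedModel(booster, classes, list(table.columns))


def predict(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    return model.predict(table)


def importance_ranking(model: FittedModel) -> pd.Series:
    """Gain importances normalized to sum 1, descending.

    Features the booster never split on get score 0.
    """
    raw = model.booster.get_booster().get_score(importance_type="gain")
    scores = pd.Series(0.0, index=model.feature_names)
    for key, value in raw.items():
        # keys are feature names when fitted from a DataFrame, else f<idx>
        name = key if key in scores.index else model.feature_names[int(key[1:])]
        scores[name] = value
    total = scores.sum()
    if total > 0:
        scores = scores / total
    return scores.sort_values(ascending=False, kind="stable")


def select_features(
    ranking: pd.Series, threshold: float = DEFAULT_IMPORTANCE_THRESHOLD
) -> list[str]:
    """Names with importance ≥ threshold, in descending-score order."""
    kept = ranking[ranking >= threshold]
    if kept.empty:
        raise ValueError(
            f"no feature reaches importance {threshold}; lower the threshold "
            f"(max observed score is {float(ranking.max()):.3g})"
        )
    return list(kept.index)


def top_features(ranking: pd.Series, n: int) -> pd.DataFrame:
    """Top-n table of (name, score, component, domain); ties lexicographic."""
    if n > len(ranking):
        raise ValueError(f"asked for {n} features but only {len(ranking)} exist")
    frame = ranking.rename("score").rename_axis("name").reset_index()
    frame = frame.sort_values(["score", "name"], ascending=[False, True], kind="stable")
    frame = frame.head(n).reset_index(drop=True)
    parsed = frame["name"].map(parse_feature_name)
    frame["component"] = [c for c, _ in parsed]
    frame["domain"] = [feature_domain(f) for _, f in parsed]
    return frame


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion(labels, predictions, positive: str = POSITIVE_CLASS) -> ConfusionCounts:
    labels = np.asarray(list(labels))
    predictions = np.asarray(list(predictions))
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    unseen = set(np.unique(predictions)) - set(np.unique(labels))
    if unseen:
        raise ValueError(f"predictions contain unseen classes: {sorted(unseen)}")
    pos_true = labels == positive
    pos_pred = predictions == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_true & pos_pred)),
        FP=int(np.sum(~pos_true & pos_pred)),
        TN=int(np.sum(~pos_true & ~pos_pred)),
        FN=int(np.sum(pos_true & ~pos_pred)),
    )


def sen_spe_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy as percentages (NaN where undefined)."""
    sen = 100.0 * c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else math.nan
    spe = 100.0 * c.TN / (c.TN + c.FP) if c.TN + c.FP > 0 else math.nan
    acc = 100.0 * (c.TP + c.TN) / c.total if c.total > 0 else math.nan
    return sen, spe, acc


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _positive_class(classes: list[str]) -> str:
    return POSITIVE_CLASS if POSITIVE_CLASS in classes else classes[-1]


def cross_validate(
    table: pd.DataFrame,
    labels,
    cfg: ClassifierConfig = ClassifierConfig(),
    k: int = 10,
    seed: int = 0,
    selection_threshold: float | None = DEFAULT_IMPORTANCE_THRESHOLD,
    global_selection: bool = False,
) -> EvaluationReport:
    """Stratified k-fold evaluation with in-fold feature selection.

    Each training fold fits a ranking model, prunes features below
    ``selection_threshold`` (``None`` disables selection), refits on the
    surviving features, and scores the held-out fold.  For more than two
    classes, SEN/SPE are reported one-vs-rest per class and the headline
    fold metrics carry accuracy only.
    """
    labels = pd.Series(list(labels)).reset_index(drop=True)
    table = table.reset_index(drop=True)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("cross-validation needs >= 2 classes")
    smallest = labels.value_counts().min()
    if k > smallest:
        raise ValueError(f"k={k} exceeds the smallest class size {smallest}")
    binary = len(classes) == 2
    positive = _positive_class(classes)

    start = time.perf_counter()
    if global_selection and selection_threshold is not None:
        ranking = importance_ranking(fit_classifier(table, labels, cfg))
        table = table[select_features(ranking, selection_threshold)]

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    all_true: list[str] = []
    all_pred: list[str] = []
    for train_idx, test_idx in splitter.split(table, labels):
        train_x, train_y = table.iloc[train_idx], labels.iloc[train_idx]
        if selection_threshold is not None and not global_selection:
            ranking = importance_ranking(fit_classifier(train_x, train_y, cfg))
            kept = select_features(ranking, selection_threshold)
            train_x = train_x[kept]
        model = fit_classifier(train_x, train_y, cfg)
        pred = model.predict(table.iloc[test_idx])
        true = labels.iloc[test_idx].to_numpy()
        all_true.extend(true)
        all_pred.extend(pred)
        if binary:
            sen, spe, acc = sen_spe_acc(confusion(true, pred, positive))
        else:
            sen = spe = math.nan
            acc = 100.0 * float(np.mean(pred == true))
        rows.append({"SEN": sen, "SPE": spe, "ACC": acc})
    elapsed = time.perf_counter() - start

    per_class: dict[str, tuple[float, float]] = {}
    if not binary:
        for cls in classes:
            s, p, _ = sen_spe_acc(confusion(all_true, all_pred, cls))
            per_class[cls] = (s, p)
    return EvaluationReport(
        k=k,
        fold_metrics=pd.DataFrame(rows),
        per_class_sen_spe=per_class,
        cv_seconds=elapsed,
        n_samples=len(labels),
        classes=classes,
    )
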