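"""Statistical layer: importance ranking, correlations, 3-class prediction.

Mirrors the study's evaluation protocol on a LabeledDataset of (features,
rate class, rate constant): random-forest impurity importances over the 16
variables, a Pearson correlation map including log10 k, and three
classifiers (one-vs-rest logistic regression, RBF support vector machine,
decision tree) scored by split accuracy, stratified cross-validation, and
one-vs-rest ROC with per-class, micro- and macro-averaged AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import (
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
    train_test_split,
)
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "MODEL_SPECS",
    "LabeledDataset",
    "ImportanceRanking",
    "EvalReport",
    "assemble_dataset",
    "feature_importance",
    "pearson_correlations",
    "make_classifier",
    "train_and_evaluate",
    "cross_validated_metrics",
    "external_test",
]

MODEL_SPECS = ("logistic_regression", "svm", "decision_tree")

CLASSES = (0, 1, 2)


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix in fixed X1..X16 order with rate classes and constants."""

    frame: pd.DataFrame  # columns: sample_id, X1..X16, rate_class, k [, invader_len]

    def __post_init__(self) -> None:
        required = ["sample_id", *FEATURE_NAMES, "rate_class", "k"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if self.frame[list(FEATURE_NAMES)].isna().any().any():
            raise ValueError("dataset has missing feature values")
        bad = set(self.frame["rate_class"]) - set(CLASSES)
        if bad:
            raise ValueError(f"rate classes outside {{0,1,2}}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["rate_class"].to_numpy(int)

    @property
    def ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()


@dataclass(frozen=True)
class ImportanceRanking:
    """Normalized feature weights in descending order."""

    ranking: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.ranking])
        if np.any(weights < 0):
            raise ValueError("importance weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("importance weights must sum to 1")
        if np.any(np.diff(weights) > 1e-12):
            raise ValueError("importance ranking must be descending")

    @property
    def top_feature(self) -> str:
        return self.ranking[0][0]

    def as_dict(self) -> dict[str, float]:
        return dict(self.ranking)


@dataclass(frozen=True)
class EvalReport:
    """Evaluation of one classifier on one dataset split."""

    model_spec: str
    seed: int
    train_accuracy: float
    validation_accuracy: float
    cv_mean: float
    cv_sd: float
    cv_folds: int
    per_class_auc: dict[int, float]
    micro_auc: float
    macro_auc: float
    confusion: list[list[int]]
    split_frac: float

    def to_dict(self) -> dict:
        return {
            "model_spec": self.model_spec,
            "seed": self.seed,
            "train_accuracy": self.train_accuracy,
            "validation_accuracy": self.validation_accuracy,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "cv_folds": self.cv_folds,
            "per_class_auc": {str(c): v for c, v in self.per_class_auc.items()},
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
            "confusion": self.confusion,
            "split_frac": self.split_frac,
        }


def assemble_dataset(
    features: pd.DataFrame, rates: pd.DataFrame
) -> LabeledDataset:
    """Inner-join a feature table with rate fits on sample_id.

    ``rates`` needs columns sample_id, k, rate_class (invader_len carried
    through when present).  Duplicate or orphan ids are errors; row order is
    deterministic (sorted by id).
    """
    for name, df in (("features", features), ("rates", rates)):
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids in {name}: {dups[:5]}")
    orphans = set(features["sample_id"]) ^ set(rates["sample_id"])
    if orphans:
        raise ValueError(f"unmatched sample_ids: {sorted(orphans)[:5]}")
    keep = ["sample_id", "k", "rate_class"]
    if "invader_len" in rates.columns:
        keep.append("invader_len")
    merged = features.merge(rates[keep], on="sample_id", validate="one_to_one")
    merged = merged.sort_values("sample_id", kind="stable").reset_index(drop=True)
    return LabeledDataset(frame=merged)


def feature_importance(
    ds: LabeledDataset, n_trees: int = 500, seed: int = 0
) -> ImportanceRanking:
    """Impurity-based importances from a seeded random forest."""
    if np.unique(ds.y).size < 2:
        raise ValueError("feature importance needs at least 2 classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(ds.X, ds.y)
    weights = forest.feature_importances_
    weights = weights / weights.sum()
    order = np.argsort(-weights, kind="stable")
    return ImportanceRanking(
        ranking=tuple((FEATURE_NAMES[i], float(weights[i])) for i in order)
    )


def pearson_correlations(ds: LabeledDataset, include_k: bool = True) -> pd.DataFrame:
    """Pearson r between every pair of variables (optionally with log10 k).

    Zero-variance columns give undefined correlations, reported as NaN.
    """
    if len(ds) < 3:
        raise ValueError("correlation analysis needs at least 3 rows")
    mat = ds.frame[list(FEATURE_NAMES)].copy()
    if include_k:
        mat["log10_k"] = np.log10(ds.frame["k"].to_numpy(float))
    return mat.corr(method="pearson")


def make_classifier(model_spec: str, seed: int = 0):
    """Seeded classifier pipeline for one of the three model specs.

    Logistic regression and the SVM see standardized features; the decision
    tree sees raw features.  Logistic regression is wrapped one-vs-rest to
    match the ROC construction; the SVM uses an RBF kernel and contributes
    decision-function margins as class scores.
    """
    if model_spec == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    OneVsRestClassifier(
                        LogisticRegression(max_iter=5000, random_state=seed)
                    ),
                ),
            ]
        )
    if model_spec == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", random_state=seed)),
            ]
        )
    if model_spec == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown model spec {model_spec!r} (choose from {MODEL_SPECS})")


def _class_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    return model.decision_function(X)


def _auc_report(y_true: np.ndarray, scores: np.ndarray) -> tuple[dict, float, float]:
    y_bin = label_binarize(y_true, classes=list(CLASSES))
    per_class = {
        c: float(roc_auc_score(y_bin[:, c], scores[:, c])) for c in CLASSES
    }
    micro = float(roc_auc_score(y_bin.ravel(), scores.ravel()))
    macro = float(np.mean(list(per_class.values())))
    return per_class, micro, macro


def train_and_evaluate(
    ds: LabeledDataset,
    model_spec: str,
    split_frac: float = 0.8,
    cv_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified split + cross-validation + one-vs-rest ROC for one model.

    The split is stratified on the rate class; if a class is too small to
    stratify the split is reshuffled with consecutive seeds.  Cross-
    validation uses stratified folds sharing the same seed.  Fully
    reproducible from (dataset, seed).
    """
    X, y = ds.X, ds.y
    split_seed = seed
    for _ in range(10):
        try:
            X_tr, X_va, y_tr, y_va = train_test_split(
                X, y, train_size=split_frac, stratify=y, random_state=split_seed
            )
        except ValueError:
            split_seed += 1
            continue
        if set(np.unique(y_tr)) == set(np.unique(y)):
            break
        split_seed += 1
    else:
        raise ValueError("could not produce a stratified split with all classes")

    model = make_classifier(model_spec, seed)
    model.fit(X_tr, y_tr)
    train_acc = float(accuracy_score(y_tr, model.predict(X_tr)))
    val_acc = float(accuracy_score(y_va, model.predict(X_va)))
    per_class, micro, macro = _auc_report(y_va, _class_scores(model, X_va))
    confusion = confusion_matrix(y_va, model.predict(X_va), labels=list(CLASSES))

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(make_classifier(model_spec, seed), X, y, cv=cv)

    return EvalReport(
        model_spec=model_spec,
        seed=seed,
        train_accuracy=train_acc,
        validation_accuracy=val_acc,
        cv_mean=float(cv_scores.mean()),
        cv_sd=float(cv_scores.std()),
        cv_folds=cv_folds,
        per_class_auc=per_class,
        micro_auc=micro,
        macro_auc=macro,
        confusion=confusion.tolist(),
        split_frac=split_frac,
    )


def cross_validated_metrics(
    ds: LabeledDataset, model_spec: str, cv_folds: int = 5, seed: int = 0
) -> dict:
    """Pooled held-out metrics from stratified cross-validation.

    Every sample is scored exactly once by a model that never saw it; the
    pooled predictions give a single accuracy and one-vs-rest AUC set with
    far lower variance than a single small split.
    """
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    method = "decision_function" if model_spec == "svm" else "predict_proba"
    scores = cross_val_predict(
        make_classifier(model_spec, seed), ds.X, ds.y, cv=cv, method=method
    )
    preds = np.asarray(scores).argmax(axis=1)
    per_class, micro, macro = _auc_report(ds.y, np.asarray(scores))
    return {
        "accuracy": float(accuracy_score(ds.y, preds)),
        "per_class_auc": per_class,
        "micro_auc": micro,
        "macro_auc": macro,
    }


def external_test(
    ds_train: LabeledDataset,
    ds_test: LabeledDataset,
    model_specs: Sequence[str] = MODEL_SPECS,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fit on the full training data, predict the held-out test set once.

    Returns per-sample predictions and per-model accuracy.  Test rows whose
    invader length differs from the (single) training length are flagged
    ``out_of_domain`` — the feature construction assumes a fixed strand
    length, so such rows sit outside the training distribution.
    """
    if list(ds_train.frame.columns[:17]) != list(ds_test.frame.columns[:17]):
        raise ValueError("train and test datasets have different feature schemas")
    preds = pd.DataFrame({"sample_id": ds_test.ids, "true_class": ds_test.y})
    if "invader_len" in ds_train.frame and "invader_len" in ds_test.frame:
        train_lens = set(ds_train.frame["invader_len"])
        preds["out_of_domain"] = [
            ln not in train_lens for ln in ds_test.frame["invader_len"]
        ]
    accuracies = {}
    for spec in model_specs:
        model = make_classifier(spec, seed)
        model.fit(ds_train.X, ds_train.y)
        y_hat = model.predict(ds_test.X)
        preds[f"pred_{spec}"] = y_hat
        accuracies[spec] = float(accuracy_score(ds_test.y, y_hat))
    return preds, accuracies
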