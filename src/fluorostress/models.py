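"""Stress-stage classification harness.

Seven classifiers in three families — kernel SVMs (RBF, polynomial),
bagging ensembles (bagged trees, random forest), and boosting ensembles
(AdaBoost, gradient boosting, XGBoost-style) — trained on the feature
table with a single stratified 75/25 split and evaluated with per-class
precision/recall/F1 plus overall accuracy. Hyperparameters are the
underlying libraries' documented defaults, frozen in
``DEFAULT_HYPERPARAMS`` and echoed verbatim in every report. SVMs get
train-fitted z-scoring (kernels are scale-sensitive); tree ensembles
are scale-invariant and get none.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import CLASS_LABELS, LABEL_COLUMN
from .indices import INDEX_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_KINDS",
    "DEFAULT_HYPERPARAMS",
    "SELECTED_FEATURES",
    "SplitSpec",
    "ClassifierSpec",
    "EvalReport",
    "split",
    "train_eval",
    "benchmark",
    "benchmark_frame",
]

CLASSIFIER_KINDS = (
    "svm_rbf",
    "svm_poly",
    "bagged_tree",
    "random_forest",
    "adaboost",
    "gradient_boosting",
    "xg_boosting",
)

#: The four selective indicators: red-edge stress index, the two
#: chlorophyll-b indices, and the red-edge chlorophyll index.
SELECTED_FEATURES = ("rvsi", "psnd_b", "pssr_b", "ci_rededge")

#: Frozen defaults (the libraries' own documented defaults) echoed in
#: every report so a result is reproducible from the report alone.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "svm_rbf": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "svm_poly": {"kernel": "poly", "C": 1.0, "degree": 3, "gamma": "scale"},
    "bagged_tree": {"n_estimators": 10},
    "random_forest": {"n_estimators": 100, "criterion": "gini"},
    "adaboost": {"n_estimators": 50, "learning_rate": 1.0},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    # exact split enumeration: midpoint cuts behave better than histogram
    # quantization at this problem's tiny tabular size
    "xg_boosting": {"n_estimators": 100, "learning_rate": 0.3, "max_depth": 6,
                    "tree_method": "exact"},
}

try:  # optional dependency; histogram gradient boosting otherwise
    from xgboost import XGBClassifier

    _HAVE_XGBOOST = True
except ImportError:  # pragma: no cover
    _HAVE_XGBOOST = False
    logger.info("xgboost not installed; xg_boosting falls back to "
                "HistGradientBoostingClassifier")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: fraction, stratification flag, seed."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the seven classifier kinds plus its hyperparameters."""

    kind: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind '{self.kind}'")

    def resolved_hyperparameters(self) -> dict:
        return {**DEFAULT_HYPERPARAMS[self.kind], **self.hyperparameters}


@dataclass
class EvalReport:
    """Evaluation of one classifier on one split and feature subset."""

    classifier: str
    hyperparameters: dict
    features: tuple[str, ...]
    split: SplitSpec
    labels: tuple[str, ...]
    confusion: np.ndarray  # rows true, cols predicted
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    wall_time_s: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        d["split"] = asdict(self.split)
        return d


def split(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition; stratified by default
    and reproducible from the seed."""
    y = table[LABEL_COLUMN]
    if spec.stratified and (y.value_counts() < 2).any():
        raise ValueError("stratified split needs >= 2 samples per class")
    train, test = train_test_split(
        table,
        train_size=spec.train_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _build_estimator(cspec: ClassifierSpec):
    hp = cspec.resolved_hyperparameters()
    seed = cspec.seed
    if cspec.kind == "svm_rbf" or cspec.kind == "svm_poly":
        # one-vs-rest multiclass, z-scored inputs
        svc = SVC(random_state=seed, **hp)
        return make_pipeline(StandardScaler(), OneVsRestClassifier(svc))
    if cspec.kind == "bagged_tree":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
            **hp,
        )
    if cspec.kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if cspec.kind == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if cspec.kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if cspec.kind == "xg_boosting":
        if _HAVE_XGBOOST:
            return XGBClassifier(random_state=seed, verbosity=0, n_jobs=1, **hp)
        return HistGradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind '{cspec.kind}'")  # pragma: no cover


def _metrics_from_confusion(cm: np.ndarray) -> tuple[dict, dict, dict, float]:
    labels = list(CLASS_LABELS)
    precision, recall, f1 = {}, {}, {}
    for k, lab in enumerate(labels):
        tp = cm[k, k]
        pred = cm[:, k].sum()
        true = cm[k, :].sum()
        p = tp / pred if pred else 0.0
        r = tp / true if true else 0.0
        precision[lab] = float(p)
        recall[lab] = float(r)
        f1[lab] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    accuracy = float(np.trace(cm) / cm.sum())
    return precision, recall, f1, accuracy


def train_eval(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cspec: ClassifierSpec,
    features: tuple[str, ...] | list[str] | None = None,
    split_spec: SplitSpec | None = None,
) -> EvalReport:
    """Fit one classifier on the train table, evaluate on the test table.

    ``features`` restricts the columns used (default: all eight). Labels
    never seen in train raise; degenerate predictions (a class never
    predicted) are valid and score zero precision by convention.
    """
    features = tuple(INDEX_NAMES) if features is None else tuple(features)
    if not features:
        raise ValueError("feature subset must be non-empty")
    if set(train[LABEL_COLUMN].unique()) != set(CLASS_LABELS):
        raise ValueError("train table must contain all three classes")
    xtr = train[list(features)].to_numpy(dtype=float)
    xte = test[list(features)].to_numpy(dtype=float)
    # integer codes keep xgboost happy and fix the class order
    codes = {lab: k for k, lab in enumerate(CLASS_LABELS)}
    ytr = train[LABEL_COLUMN].map(codes).to_numpy(dtype=int)
    yte = test[LABEL_COLUMN].map(codes).to_numpy(dtype=int)

    est = _build_estimator(cspec)
    t0 = time.perf_counter()
    est.fit(xtr, ytr)
    pred = est.predict(xte)
    wall = time.perf_counter() - t0

    cm = _sk_confusion(yte, pred, labels=list(range(len(CLASS_LABELS))))
    precision, recall, f1, accuracy = _metrics_from_confusion(cm)
    return EvalReport(
        classifier=cspec.kind,
        hyperparameters=cspec.resolved_hyperparameters(),
        features=features,
        split=split_spec or SplitSpec(seed=cspec.seed),
        labels=tuple(CLASS_LABELS),
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        wall_time_s=wall,
    )


def benchmark(
    table: pd.DataFrame,
    feature_sets: dict[str, tuple[str, ...]] | None = None,
    seeds: tuple[int, ...] = (0,),
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    train_fraction: float = 0.75,
) -> list[EvalReport]:
    """One report per (classifier x feature set x seed).

    ``feature_sets`` defaults to ``{"all": all eight, "selected": the
    four selective indicators}``.
    """
    if feature_sets is None:
        feature_sets = {"all": tuple(INDEX_NAMES), "selected": SELECTED_FEATURES}
    reports = []
    for seed in seeds:
        sspec = SplitSpec(train_fraction=train_fraction, seed=seed)
        train, test = split(table, sspec)
        for set_name, feats in feature_sets.items():
            for kind in kinds:
                rep = train_eval(
                    train, test, ClassifierSpec(kind, seed=seed), feats, split_spec=sspec
                )
                rep.feature_set_name = set_name  # type: ignore[attr-defined]
                reports.append(rep)
    return reports


def benchmark_frame(reports: list[EvalReport]) -> pd.DataFrame:
    """Flatten reports into a results table mirroring the standard
    per-class precision/recall/F1 + overall-accuracy layout, with
    mean +/- sd of accuracy aggregated per (classifier, feature set).

    Wall times stay out of this table (they live on the reports) so the
    table is bit-reproducible under a fixed config.
    """
    rows = []
    for rep in reports:
        row = {
            "classifier": rep.classifier,
            "feature_set": getattr(rep, "feature_set_name", ",".join(rep.features)),
            "seed": rep.split.seed,
            "accuracy": rep.accuracy,
        }
        for lab in rep.labels:
            row[f"precision_{lab}"] = rep.precision[lab]
            row[f"recall_{lab}"] = rep.recall[lab]
            row[f"f1_{lab}"] = rep.f1[lab]
        rows.append(row)
    frame = pd.DataFrame(rows)
    agg = (
        frame.groupby(["classifier", "feature_set"])["accuracy"]
        .agg(["mean", "std"])
        .rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd"})
        .reset_index()
    )
    return frame.merge(agg, on=["classifier", "feature_set"])
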