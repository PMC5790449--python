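"""Specimen-type classification and chi-square attribute (merit) ranking.

Evaluation is stratified k-fold cross-validation of a random forest on
log10(x+1) normalized counts, deterministic for a fixed seed. The merit of a
feature is the chi-square statistic of the contingency table between its
equal-frequency expression bins and the specimen labels (no continuity
correction), which makes it invariant to strictly monotone transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .matrix import NormalizedMatrix


@dataclass
class ClassifierReport:
    accuracy: float
    confusion: pd.DataFrame  # rows = true label, columns = predicted
    n_misclassified: int
    scheme: str
    seed: int

    def check(self) -> None:
        total = self.confusion.to_numpy().sum()
        trace = np.trace(self.confusion.to_numpy())
        if total and abs(self.accuracy - trace / total) > 1e-12:
            raise AssertionError("accuracy inconsistent with confusion matrix")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_misclassified": int(self.n_misclassified),
            "scheme": self.scheme,
            "seed": self.seed,
            "labels": list(self.confusion.index),
            "confusion": self.confusion.to_numpy().tolist(),
        }


def _design(normalized: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(normalized, NormalizedMatrix):
        return normalized.log10p().T
    return np.log10(normalized + 1.0).T


def train_evaluate(
    normalized: NormalizedMatrix | pd.DataFrame,
    labels: Mapping[str, str] | pd.Series | None = None,
    seed: int = 0,
    folds: int = 10,
    n_trees: int = 500,
) -> ClassifierReport:
    """Stratified k-fold CV accuracy of a seeded random forest."""
    X = _design(normalized)
    if labels is None:
        if not isinstance(normalized, NormalizedMatrix):
            raise ValueError("labels are required with a bare data frame")
        labels = normalized.specimen_groups()
    y = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    y = y.reindex(X.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("need at least two classes")
    min_count = int(class_counts.min())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} samples; reducing folds from {folds}",
            RuntimeWarning,
            stacklevel=2,
        )
        folds = max(2, min_count)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, X.to_numpy(), y.to_numpy(), cv=cv)
    label_order = sorted(class_counts.index)
    confusion = pd.crosstab(
        pd.Categorical(y, categories=label_order),
        pd.Categorical(pred, categories=label_order),
        dropna=False,
    )
    confusion.index = label_order
    confusion.columns = label_order
    n_wrong = int((pred != y.to_numpy()).sum())
    report = ClassifierReport(
        accuracy=float((pred == y.to_numpy()).mean()),
        confusion=confusion,
        n_misclassified=n_wrong,
        scheme=f"stratified {folds}-fold cross-validation, {n_trees} trees",
        seed=seed,
    )
    report.check()
    return report


@dataclass(frozen=True)
class MeritRecord:
    feature: str
    merit: float
    rank: int


def chi_square_merit(
    normalized: NormalizedMatrix | pd.DataFrame,
    labels: Mapping[str, str] | pd.Series | None = None,
    bins: int = 10,
) -> list[MeritRecord]:
    """Chi-square statistic of binned expression vs class, per feature.

    Features are discretized into at most ``bins`` equal-frequency bins on
    log counts (degenerate bins merged by qcut); constant features get
    merit 0. Records are ranked by descending merit, ties broken by id.
    """
    X = _design(normalized)
    if labels is None:
        if not isinstance(normalized, NormalizedMatrix):
            raise ValueError("labels are required with a bare data frame")
        labels = normalized.specimen_groups()
    y = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    y = y.reindex(X.index)
    merits: list[tuple[float, str]] = []
    for feature in X.columns:
        x = X[feature]
        try:
            binned = pd.qcut(x, q=bins, duplicates="drop")
        except ValueError:
            merits.append((0.0, feature))
            continue
        if binned.nunique() < 2:
            merits.append((0.0, feature))
            continue
        table = pd.crosstab(binned, y)
        stat = stats.chi2_contingency(table.to_numpy(), correction=False)[0]
        merits.append((float(stat), feature))
    merits.sort(key=lambda t: (-t[0], t[1]))
    return [
        MeritRecord(feature=f, merit=m, rank=i + 1) for i, (m, f) in enumerate(merits)
    ]


def merit_frame(records: Sequence[MeritRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature": r.feature, "merit": r.merit, "rank": r.rank} for r in records],
        columns=["feature", "merit", "rank"],
    )
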