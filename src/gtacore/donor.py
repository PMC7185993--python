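"""Donor-sugar specificity prediction for GT-A domains.

The classifier is a multiclass gradient-boosted decision-tree ensemble
(GDBT) over the physicochemical feature matrix, with the published
hyperparameters as defaults, plus a capped random-forest baseline.  The
module is organised statsmodels-style: :class:`DonorSpecificityModel` is
built from a :class:`~gtacore.features.FeatureMatrix` and labels; ``fit()``
returns a :class:`DonorSpecificityResults` carrying the fitted ensemble,
ranked feature importances, confidence-scored predictions and a
``summary()`` table.

Each prediction carries a confidence category derived from the two largest
class probabilities p1 >= p2: *high* when p1 > 4 p2; otherwise *moderate*
when p1 - p2 > 2 * (1/6) (twice the six-class chance probability);
otherwise *low*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .features import DONOR_CLASSES, FeatureDescriptor, FeatureMatrix

CHANCE_PROBABILITY = 1.0 / len(DONOR_CLASSES)


@dataclass(frozen=True)
class GdbtConfig:
    """Gradient-boosting hyperparameters; defaults are the published values."""

    learning_rate: float = 0.1
    n_estimators: int = 1600
    min_samples_split: int = 25
    min_samples_leaf: int = 7
    max_depth: int = 4
    max_features: int = 18
    subsample: float = 0.75
    random_state: int = 10

    def to_sklearn(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(**asdict(self))


@dataclass
class DonorPrediction:
    """Per-sequence class probabilities with a confidence category."""

    sequence_id: str
    class_probabilities: np.ndarray
    predicted_class: str
    confidence: str


def confidence_category(
    probs: Sequence[float],
    rule: str = "difference",
    n_classes: int | None = None,
) -> str:
    """Confidence band of a class-probability vector.

    With p1 >= p2 the two largest probabilities: *high* iff ``p1 > 4 * p2``;
    else *moderate* iff ``p1 - p2 > 2 / n_classes`` (the default
    "difference" reading) or, under ``rule="absolute"``, iff
    ``p1 > 2 / n_classes``; else *low*.  Boundary cases are excluded from
    the higher band (``p1 == 4 p2`` is not high; ``p1 - p2 == 1/3`` is not
    moderate for six classes).
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    if rule not in ("difference", "absolute"):
        raise ValueError(f"unknown confidence rule {rule!r}")
    if n_classes is None:
        n_classes = len(p)
    top = np.sort(p)[::-1]
    p1, p2 = float(top[0]), float(top[1])
    if p1 > 4.0 * p2:
        return "high"
    threshold = 2.0 / n_classes
    moderate = (p1 - p2 > threshold) if rule == "difference" else (p1 > threshold)
    return "moderate" if moderate else "low"


@dataclass
class CrossValidationResult:
    accuracy: float
    fold_accuracies: list[float]
    confusion: pd.DataFrame
    per_class: pd.DataFrame
    n_folds: int


class DonorSpecificityModel:
    """Multiclass donor-specificity model over a labelled feature matrix.

    Parameters
    ----------
    features
        Encoded (and typically CFS-selected) feature matrix.
    labels
        Donor-class label per sequence; defaults to ``features.labels``.
    config
        GDBT hyperparameters (published defaults).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        labels: Sequence[str] | None = None,
        config: GdbtConfig | None = None,
    ) -> None:
        labels = list(labels) if labels is not None else features.labels
        if labels is None:
            raise ValueError("labels are required to build the model")
        if len(labels) != len(features.sequence_ids):
            raise ValueError("label vector length mismatch")
        if len(set(labels)) < 2:
            raise ValueError("need at least two donor classes to train")
        self.features = features
        self.labels = labels
        self.config = config or GdbtConfig()
        self.classes_: list[str] = sorted(set(labels))

    # -- fitting -----------------------------------------------------------

    def _make_estimator(self):
        est = self.config.to_sklearn()
        mf = est.max_features
        if isinstance(mf, int) and mf > self.features.n_features:
            est.set_params(max_features=self.features.n_features)
        return est

    def fit(self) -> "DonorSpecificityResults":
        est = self._make_estimator()
        est.fit(self.features.values, self.labels)
        return DonorSpecificityResults(self, est)

    def cross_validate(self, k: int = 10, seed: int = 0) -> CrossValidationResult:
        """Stratified k-fold CV accuracy with a pooled confusion matrix.

        If the smallest class has fewer than ``k`` members the fold count is
        reduced to that size with a warning.
        """
        y = np.asarray(self.labels)
        counts = pd.Series(y).value_counts()
        if counts.min() < k:
            warnings.warn(
                f"class {counts.idxmin()!r} has {counts.min()} members; "
                f"reducing folds from {k} to {counts.min()}"
            )
            k = int(counts.min())
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        y_true_all, y_pred_all, fold_acc = [], [], []
        for train_idx, test_idx in skf.split(self.features.values, y):
            est = self._make_estimator()
            est.fit(self.features.values[train_idx], y[train_idx])
            pred = est.predict(self.features.values[test_idx])
            fold_acc.append(float(np.mean(pred == y[test_idx])))
            y_true_all.extend(y[test_idx])
            y_pred_all.extend(pred)
        y_true_all = np.array(y_true_all)
        y_pred_all = np.array(y_pred_all)
        acc = float(np.mean(y_true_all == y_pred_all))
        cm = _sk_confusion(y_true_all, y_pred_all, labels=self.classes_)
        confusion = pd.DataFrame(cm, index=self.classes_, columns=self.classes_)
        with np.errstate(invalid="ignore", divide="ignore"):
            recall = np.diag(cm) / cm.sum(axis=1)
            precision = np.diag(cm) / np.maximum(cm.sum(axis=0), 1)
        per_class = pd.DataFrame(
            {"precision": precision, "recall": recall, "n": cm.sum(axis=1)},
            index=self.classes_,
        )
        return CrossValidationResult(acc, fold_acc, confusion, per_class, k)

    # -- baselines and per-donor models ------------------------------------

    def rf_baseline(
        self,
        n_trees: int = 300,
        max_terminal_nodes: int = 100,
        feature_subset: Sequence[FeatureDescriptor] | None = None,
        k: int = 10,
        seed: int = 0,
    ) -> tuple[RandomForestClassifier, float]:
        """Capped random forest with stratified k-fold CV accuracy.

        ``feature_subset`` restricts training to the given descriptors
        (e.g. features of donor-binding columns only); the tree count and
        terminal-node cap guard against unrestricted expansion.
        """
        if feature_subset is not None and len(feature_subset) == 0:
            raise ValueError("feature subset must not be empty")
        fm = self.features if feature_subset is None else self.features.subset(feature_subset)
        y = np.asarray(self.labels)
        k = min(k, int(pd.Series(y).value_counts().min()))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        correct = total = 0
        for train_idx, test_idx in skf.split(fm.values, y):
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_leaf_nodes=max_terminal_nodes, random_state=seed
            )
            rf.fit(fm.values[train_idx], y[train_idx])
            pred = rf.predict(fm.values[test_idx])
            correct += int(np.sum(pred == y[test_idx]))
            total += len(test_idx)
        final = RandomForestClassifier(
            n_estimators=n_trees, max_leaf_nodes=max_terminal_nodes, random_state=seed
        )
        final.fit(fm.values, y)
        return final, correct / total

    def per_donor_importance(self, donor_class: str) -> pd.DataFrame:
        """One-vs-rest GDBT importances for a single donor class.

        The class is relabelled against "everything else", a GDBT with the
        same configuration is fitted, and impurity importances are ranked
        (sum normalized to 1).
        """
        if donor_class not in self.classes_:
            raise ValueError(f"class {donor_class!r} absent from the labels")
        y_bin = [l if l == donor_class else "rest" for l in self.labels]
        est = self._make_estimator()
        est.fit(self.features.values, y_bin)
        return _importance_frame(est, self.features.descriptors)

    def importance_comparison(
        self, classes: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Join the full-model feature ranks with each one-vs-rest rank.

        Output columns: ``feature, column_id, property, full_rank,
        full_score`` plus ``<class>_rank`` / ``<class>_score`` per donor
        class.
        """
        full = self.fit().feature_importances()
        out = full.rename(columns={"rank": "full_rank", "importance": "full_score"})[
            ["feature", "column_id", "property", "full_rank", "full_score"]
        ].set_index("feature")
        for cls in classes or self.classes_:
            per = self.per_donor_importance(cls).set_index("feature")
            out[f"{cls}_rank"] = per["rank"]
            out[f"{cls}_score"] = per["importance"]
        return out.reset_index()


def _importance_frame(est, descriptors: list[FeatureDescriptor]) -> pd.DataFrame:
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    rows = []
    for rank, i in enumerate(order, start=1):
        band = "high" if rank <= 10 else ("moderate" if rank <= 20 else "")
        rows.append(
            {
                "feature": str(descriptors[i]),
                "column_id": descriptors[i].column_id,
                "property": descriptors[i].property,
                "importance": float(imp[i]),
                "rank": rank,
                "band": band,
            }
        )
    return pd.DataFrame(rows)


class DonorSpecificityResults:
    """Fitted donor-specificity model: predictions, importances, summary."""

    def __init__(self, model: DonorSpecificityModel, estimator) -> None:
        self.model = model
        self.estimator = estimator
        self.classes_ = list(estimator.classes_)

    def feature_importances(self) -> pd.DataFrame:
        """Impurity importances normalized to sum 1, ranked descending.

        Ranks 1-10 are flagged ``high`` and 11-20 ``moderate`` in the
        ``band`` column.
        """
        return _importance_frame(self.estimator, self.model.features.descriptors)

    def predict_with_confidence(
        self, features: FeatureMatrix, rule: str = "difference"
    ) -> list[DonorPrediction]:
        """Class probabilities, argmax class and confidence per sequence.

        The feature descriptors must match the training descriptors exactly
        (an error lists any missing features).  Exact probability ties
        resolve to the first class in training order and fall out as low
        confidence.
        """
        if features.descriptors != self.model.features.descriptors:
            missing = [
                str(d) for d in self.model.features.descriptors
                if d not in set(features.descriptors)
            ]
            raise ValueError(
                "feature descriptors do not match the training descriptors; "
                f"missing: {missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        probs = self.estimator.predict_proba(features.values)
        out = []
        for sid, p in zip(features.sequence_ids, probs):
            idx = int(np.argmax(p))
            out.append(
                DonorPrediction(
                    sequence_id=sid,
                    class_probabilities=p,
                    predicted_class=self.classes_[idx],
                    confidence=confidence_category(p, rule=rule, n_classes=len(DONOR_CLASSES)),
                )
            )
        return out

    def predictions_frame(
        self, features: FeatureMatrix, rule: str = "difference"
    ) -> pd.DataFrame:
        preds = self.predict_with_confidence(features, rule=rule)
        rows = []
        for p in preds:
            row = {
                "sequence_id": p.sequence_id,
                "predicted_class": p.predicted_class,
                "confidence": p.confidence,
            }
            row.update(
                {f"p_{c}": float(v) for c, v in zip(self.classes_, p.class_probabilities)}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        imp = self.feature_importances().head(10)
        lines = [
            "Donor-specificity GDBT model",
            "=" * 60,
            f"classes:          {', '.join(self.classes_)}",
            f"n sequences:      {len(self.model.features.sequence_ids)}",
            f"n features:       {self.model.features.n_features}",
            f"config:           {self.model.config}",
            "",
            "top 10 features (impurity importance):",
        ]
        for _, r in imp.iterrows():
            lines.append(f"  {r['rank']:>3}  {r['feature']:<20} {r['importance']:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional aliases mirroring the pipeline-style surface


def train_gdbt(
    X: FeatureMatrix, y: Sequence[str] | None = None, config: GdbtConfig | None = None
) -> DonorSpecificityResults:
    return DonorSpecificityModel(X, y, config).fit()


def cross_validate(
    X: FeatureMatrix,
    y: Sequence[str] | None = None,
    config: GdbtConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    return DonorSpecificityModel(X, y, config).cross_validate(k=k, seed=seed)


def rf_baseline(
    X: FeatureMatrix,
    y: Sequence[str] | None = None,
    n_trees: int = 300,
    max_terminal_nodes: int = 100,
    feature_subset: Sequence[FeatureDescriptor] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[RandomForestClassifier, float]:
    return DonorSpecificityModel(X, y).rf_baseline(
        n_trees=n_trees,
        max_terminal_nodes=max_terminal_nodes,
        feature_subset=feature_subset,
        k=k,
        seed=seed,
    )
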