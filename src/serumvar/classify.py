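"""Random-forest labelling of sex and female hormonal status.

Labels samples as male, postmenopausal female, OC user, or female with a
menstrual cycle (follicular and luteal phases merged) from serum analyte
concentrations and covariates.  Variable importance is the mean decrease in
Gini impurity; a reduced model restricted to the ten most important
variables offers a cheaper classifier for retrospective labelling of
studies that did not record hormonal status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .synthetic import CATEGORICAL_COVARIATES

CLASS_LABELS = ("male", "menstrual_cycle", "oc_user", "postmenopausal")


def merge_cycle_labels(groups: pd.Series) -> pd.Series:
    """Collapse the follicular and luteal phases into one cycling class."""
    return groups.replace({"follicular": "menstrual_cycle",
                           "luteal": "menstrual_cycle"})


@dataclass
class ClassifierReport:
    """Evaluation of a forest: confusion matrix, accuracies, importances."""

    confusion_matrix: pd.DataFrame       # true class x predicted class
    per_class_accuracy: dict             # %, per true class
    overall_accuracy: float              # %
    oob_error: float | None = None       # %, training only
    importance_ranking: list = field(default_factory=list)

    def __post_init__(self):
        cm = self.confusion_matrix.to_numpy()
        assert abs(
            100.0 * np.trace(cm) / cm.sum() - self.overall_accuracy
        ) < 1e-9
        imps = [v for _, v in self.importance_ranking]
        assert imps == sorted(imps, reverse=True)


@dataclass
class ForestModel:
    """A trained forest plus the feature encoding needed to apply it."""

    forest: RandomForestClassifier
    feature_columns: list[str]           # encoded (one-hot) column order
    variable_of_column: dict             # encoded column -> source variable
    classes: list[str]


def encode_features(features: pd.DataFrame,
                    reference_columns: list[str] | None = None,
                    ) -> tuple[pd.DataFrame, dict]:
    """One-hot encode categorical variables.

    Importance of a categorical variable is later reported as the sum over
    its indicator columns; the returned mapping records each encoded
    column's source variable.  ``reference_columns`` aligns a test-set
    encoding to the training layout (absent indicator levels become zero
    columns).
    """
    cat = [c for c in features.columns
           if c in CATEGORICAL_COVARIATES
           or features[c].dtype == object
           or isinstance(features[c].dtype, pd.CategoricalDtype)]
    encoded = pd.get_dummies(features, columns=cat, dtype=float)
    encoded = encoded.astype(float)
    if reference_columns is not None:
        missing = [c for c in reference_columns if c not in encoded.columns]
        for c in missing:
            encoded[c] = 0.0
        encoded = encoded[reference_columns]
    mapping = {}
    for col in encoded.columns:
        src = col
        for c in cat:
            if col.startswith(f"{c}_"):
                src = c
                break
        mapping[col] = src
    return encoded, mapping


def _report(cm: pd.DataFrame, oob_error: float | None,
            ranking: list) -> ClassifierReport:
    counts = cm.to_numpy()
    total = counts.sum()
    per_class = {}
    for i, cls in enumerate(cm.index):
        row = counts[i].sum()
        per_class[cls] = 100.0 * counts[i, i] / row if row else np.nan
    return ClassifierReport(
        confusion_matrix=cm,
        per_class_accuracy=per_class,
        overall_accuracy=100.0 * np.trace(counts) / total,
        oob_error=oob_error,
        importance_ranking=ranking,
    )


def train_classifier(features: pd.DataFrame, labels: pd.Series,
                     n_trees: int = 5000, seed: int = 0,
                     ) -> tuple[ForestModel, ClassifierReport]:
    """Train a random forest and report its out-of-bag performance.

    ``n_trees`` bootstrap trees with ``floor(sqrt(p))`` candidate features
    per split and unlimited depth.  The report's confusion matrix and
    accuracies are computed from out-of-bag votes, so they estimate
    performance on unseen data; importances are mean decreases in Gini
    impurity summed over each source variable's indicator columns.
    """
    labels = pd.Series(labels, index=features.index).astype(str)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if features.isna().any().any():
        raise ValueError("features contain missing values; impute first")
    X, mapping = encode_features(features)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        oob_score=True, random_state=seed, n_jobs=1,
    )
    forest.fit(X.to_numpy(), labels.to_numpy())
    model = ForestModel(
        forest=forest, feature_columns=list(X.columns),
        variable_of_column=mapping, classes=list(forest.classes_),
    )

    oob_pred = np.asarray(model.classes)[
        np.argmax(forest.oob_decision_function_, axis=1)
    ]
    cm = _confusion(labels.to_numpy(), oob_pred, model.classes)
    oob_error = 100.0 * (1.0 - forest.oob_score_)
    return model, _report(cm, oob_error, rank_importance(model, k=None))


def _confusion(y_true, y_pred, classes) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def rank_importance(model: ForestModel, k: int | None = 10) -> list:
    """Top-``k`` variables by mean decrease in Gini impurity.

    Indicator columns of a categorical variable pool their importance mass.
    Ties break lexicographically; ``k=None`` (or k beyond the variable
    count) returns all variables.
    """
    if not hasattr(model.forest, "feature_importances_"):
        raise ValueError("model is not trained")
    raw = model.forest.feature_importances_
    agg: dict[str, float] = {}
    for col, imp in zip(model.feature_columns, raw):
        src = model.variable_of_column[col]
        agg[src] = agg.get(src, 0.0) + float(imp)
    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if k is None else ranked[:k]


def predict(model: ForestModel, features: pd.DataFrame) -> pd.Series:
    X, _ = encode_features(features, reference_columns=model.feature_columns)
    pred = model.forest.predict(X.to_numpy())
    return pd.Series(pred, index=features.index, name="predicted")


def evaluate(model: ForestModel, features: pd.DataFrame,
             labels: pd.Series) -> ClassifierReport:
    """Confusion matrix and accuracies of a trained forest on labelled data."""
    if len(features) == 0:
        raise ValueError("empty evaluation set")
    labels = pd.Series(labels, index=features.index).astype(str)
    pred = predict(model, features)
    classes = sorted(set(model.classes) | set(labels.unique()))
    cm = _confusion(labels.to_numpy(), pred.to_numpy(), classes)
    return _report(cm, None, rank_importance(model, k=None))


def train_reduced_and_evaluate(top_variables: list[str],
                               train_features: pd.DataFrame,
                               train_labels: pd.Series,
                               test_features: pd.DataFrame,
                               test_labels: pd.Series,
                               n_trees: int = 5000, seed: int = 0,
                               ) -> tuple[ForestModel, ClassifierReport]:
    """Train on the top-ranked variables only and evaluate on held-out data."""
    for frame, name in ((train_features, "training"),
                        (test_features, "test")):
        absent = [v for v in top_variables if v not in frame.columns]
        if absent:
            raise ValueError(f"variables absent from the {name} set: {absent}")
    if len(test_features) == 0:
        raise ValueError("empty test set")
    model, _ = train_classifier(
        train_features[list(top_variables)], train_labels,
        n_trees=n_trees, seed=seed,
    )
    return model, evaluate(model, test_features[list(top_variables)],
                           test_labels)
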