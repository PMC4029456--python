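"""Classifier backends behind a model / results interface.

``EnhancerActivityModel`` is built from a labeled feature table and a
``ModelSpec`` naming one of three backends:

* ``rf``  — random forest, 30 trees by default; the score is the
  fraction of trees voting for the positive class.
* ``svm`` — RBF-kernel support vector machine on standardized
  features; the score is the signed decision value.
* ``bde`` — discrete Bayesian classifier with BDe-scored parent-set
  search (cardinality <= 3 by default); the score is the posterior
  probability of the positive class.

``fit()`` returns an ``EnhancerActivityResults`` carrying the fitted
state, the training feature names (prediction requires the same names
in the same order), and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bde import BDeClassifier
from .io import LabeledFeatureMatrix

__all__ = [
    "ModelSpec",
    "EnhancerActivityModel",
    "EnhancerActivityResults",
    "DECISION_THRESHOLDS",
    "train",
    "predict_scores",
]

#: Score threshold separating predicted-negative from predicted-positive,
#: per backend: vote fraction, signed margin, posterior probability.
DECISION_THRESHOLDS = {"rf": 0.5, "svm": 0.0, "bde": 0.5}


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "rf"
    n_estimators: int = 30
    svm_c: float = 1.0
    svm_gamma: str | float = "auto"  # "auto" = 1/p on standardized features
    max_parents: int = 3
    n_bins: int = 3
    equivalent_sample_size: float = 1.0
    bde_search_budget: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "svm", "bde"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, seed=seed)


class EnhancerActivityModel:
    """A classifier specification bound to training data."""

    def __init__(self, features: pd.DataFrame, labels: np.ndarray, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else ModelSpec()
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        if len(features) != len(self.labels):
            raise ValueError("feature rows != labels")
        if len(features) < 2:
            raise ValueError("need at least 2 training rows")
        classes = np.unique(self.labels)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                f"training data must contain both classes, got labels {classes}"
            )
        if features.isna().any().any():
            raise ValueError("missing values in training features")

    @classmethod
    def from_feature_matrix(
        cls,
        data: LabeledFeatureMatrix,
        feature_set: str | None = None,
        spec: ModelSpec | None = None,
    ) -> "EnhancerActivityModel":
        if feature_set is not None:
            data = data.select(feature_set)
        return cls(data.features, data.labels, spec)

    def fit(self) -> "EnhancerActivityResults":
        spec = self.spec
        X = self.features.to_numpy(dtype=float)
        y = self.labels
        if spec.kind == "rf":
            est = RandomForestClassifier(
                n_estimators=spec.n_estimators, random_state=spec.seed
            ).fit(X, y)
        elif spec.kind == "svm":
            est = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svc", SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_gamma)),
                ]
            ).fit(X, y)
        else:  # bde
            est = BDeClassifier(
                max_parents=spec.max_parents,
                n_bins=spec.n_bins,
                equivalent_sample_size=spec.equivalent_sample_size,
                search_budget=spec.bde_search_budget,
            ).fit(X, y, feature_names=list(self.features.columns))
        return EnhancerActivityResults(self, est)


class EnhancerActivityResults:
    """Fitted classifier state with prediction and summary methods."""

    def __init__(self, model: EnhancerActivityModel, estimator):
        self.model = model
        self.spec = model.spec
        self.feature_names = list(model.features.columns)
        self._estimator = estimator

    def _check_features(self, features: pd.DataFrame) -> np.ndarray:
        names = list(features.columns)
        if names != self.feature_names:
            raise ValueError(
                "feature columns do not match training (same names, same "
                f"order required); trained on {self.feature_names[:4]}..., "
                f"got {names[:4]}..."
            )
        return features.to_numpy(dtype=float)

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Per-region activity score; higher means more likely active."""
        X = self._check_features(features)
        kind = self.spec.kind
        if kind == "rf":
            return self._estimator.predict_proba(X)[:, 1]
        if kind == "svm":
            return self._estimator.decision_function(X)
        return self._estimator.predict_proba_positive(X)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        scores = self.predict_scores(features)
        return (scores > DECISION_THRESHOLDS[self.spec.kind]).astype(int)

    @property
    def training_error(self) -> float:
        pred = self.predict(self.model.features)
        return float(np.mean(pred != self.model.labels))

    def summary(self) -> str:
        lines = [
            "Enhancer activity classifier",
            "=" * 40,
            f"backend:          {self.spec.kind}",
            f"training regions: {len(self.model.labels)} "
            f"({int(self.model.labels.sum())} positive)",
            f"features:         {len(self.feature_names)}",
            f"training error:   {self.training_error:.4f}",
        ]
        if self.spec.kind == "rf":
            lines.append(f"trees:            {self.spec.n_estimators}")
        if self.spec.kind == "bde":
            parents = self._estimator.parent_names()
            lines.append(f"class parents:    {parents if parents else '(prior only)'}")
            lines.append(f"BDe log score:    {self._estimator.score_:.3f}")
        return "\n".join(lines)


def train(spec: ModelSpec, data: LabeledFeatureMatrix) -> EnhancerActivityResults:
    """Functional wrapper: fit a backend on a labeled feature matrix."""
    return EnhancerActivityModel(data.features, data.labels, spec).fit()


def predict_scores(results: EnhancerActivityResults, features: pd.DataFrame) -> np.ndarray:
    return results.predict_scores(features)
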