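"""Cross-validation (standard and reversed), AUC and error metrics,
and external validation against an independent region set.

The reversed scheme trains on a single fold and tests on the remaining
k-1 folds, probing how sensitive a classifier is to training-set size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .features import TrapParams, build_feature_matrix
from .io import Genome, GenomicRegion, LabeledFeatureMatrix, PWM, SignalTrack, overlaps
from .model import (
    DECISION_THRESHOLDS,
    EnhancerActivityModel,
    EnhancerActivityResults,
    ModelSpec,
)
from .sampling import remove_overlapping

__all__ = [
    "CVSpec",
    "CVResult",
    "make_folds",
    "roc_auc",
    "classification_error",
    "cross_validate",
    "external_validate",
]


@dataclass(frozen=True)
class CVSpec:
    k: int = 10
    reversed_scheme: bool = False
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class CVResult:
    fold_auc: list[float]
    fold_error: list[float]
    model_kind: str
    feature_tag: str
    reversed_scheme: bool = False
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        # empty when every test fold was single-class (e.g. leave-one-out)
        return float(np.mean(self.fold_auc)) if self.fold_auc else float("nan")

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def error_mean(self) -> float:
        return float(np.mean(self.fold_error))

    @property
    def error_sd(self) -> float:
        return float(np.std(self.fold_error, ddof=1)) if len(self.fold_error) > 1 else 0.0

    def summary(self) -> str:
        scheme = "reversed" if self.reversed_scheme else "standard"
        return (
            f"{self.feature_tag}/{self.model_kind} ({len(self.fold_auc)}-fold, {scheme}): "
            f"AUC {self.auc_mean:.3f} +/- {self.auc_sd:.3f}, "
            f"error {100 * self.error_mean:.1f} +/- {100 * self.error_sd:.1f}%"
        )


def make_folds(
    n: int,
    k: int,
    seed: int = 0,
    stratified: bool = False,
    labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Disjoint, exhaustive folds of near-equal size from a seeded shuffle."""
    if k > n:
        raise ValueError(f"k={k} folds > n={n} samples")
    rng = np.random.default_rng(seed)
    if stratified:
        if labels is None:
            raise ValueError("stratified folds need labels")
        labels = np.asarray(labels)
        folds: list[list[int]] = [[] for _ in range(k)]
        offset = 0
        for cls in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            for i, j in enumerate(idx):
                folds[(i + offset) % k].append(int(j))
            offset += len(idx)
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def classification_error(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> float:
    """Fraction of rows whose thresholded score disagrees with the label."""
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    return float(np.mean(pred != np.asarray(labels)))


def cross_validate(
    model_spec: ModelSpec, data: LabeledFeatureMatrix, cv: CVSpec | None = None
) -> CVResult:
    """k-fold CV; the reversed scheme swaps the train/test roles.

    Folds whose training part contains a single class are skipped with
    a warning and recorded in the result.
    """
    if cv is None:
        cv = CVSpec()
    y = data.labels
    folds = make_folds(data.n, cv.k, seed=cv.seed, stratified=cv.stratified, labels=y)
    all_idx = np.arange(data.n)
    threshold = DECISION_THRESHOLDS[model_spec.kind]

    fold_auc: list[float] = []
    fold_error: list[float] = []
    skipped: list[int] = []
    for i, fold in enumerate(folds):
        rest = np.setdiff1d(all_idx, fold)
        train_idx, test_idx = (fold, rest) if cv.reversed_scheme else (rest, fold)
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {i}: single-class training part, skipped", stacklevel=2)
            skipped.append(i)
            continue
        model = EnhancerActivityModel(
            data.features.iloc[train_idx], y_train, model_spec.with_seed(model_spec.seed + i)
        )
        results = model.fit()
        scores = results.predict_scores(data.features.iloc[test_idx])
        if len(np.unique(y[test_idx])) >= 2:
            fold_auc.append(roc_auc(scores, y[test_idx]))
        fold_error.append(classification_error(scores, y[test_idx], threshold))
    if not fold_error:
        raise RuntimeError("all folds skipped (single-class training parts)")
    return CVResult(
        fold_auc=fold_auc,
        fold_error=fold_error,
        model_kind=model_spec.kind,
        feature_tag=data.tag(),
        reversed_scheme=cv.reversed_scheme,
        skipped_folds=skipped,
    )


def external_validate(
    results: EnhancerActivityResults,
    validation_regions: Sequence[GenomicRegion],
    genome: Genome,
    tracks: Sequence[SignalTrack],
    pwms: Sequence[PWM],
    training_regions: Sequence[GenomicRegion] | None = None,
    params: TrapParams | None = None,
) -> dict[str, float]:
    """Score an independent labeled region set with a trained classifier.

    Features are rebuilt with the training-time parameters and column
    layout.  If ``training_regions`` is given, any validation region
    overlapping the training set raises — an optimistic-bias guard.
    """
    if training_regions is not None:
        survivors = remove_overlapping(validation_regions, training_regions)
        if len(survivors) != len(validation_regions):
            n_bad = len(validation_regions) - len(survivors)
            raise ValueError(
                f"{n_bad} validation region(s) overlap the training set; "
                "filter with remove_overlapping() first"
            )
    tag = _infer_feature_set(results.feature_names)
    data = build_feature_matrix(
        genome, tracks, pwms, list(validation_regions), feature_set=tag, params=params
    )
    features = data.features[results.feature_names]
    scores = results.predict_scores(features)
    threshold = DECISION_THRESHOLDS[results.spec.kind]
    return {
        "auc": roc_auc(scores, data.labels),
        "error": classification_error(scores, data.labels, threshold),
        "n": data.n,
    }


def _infer_feature_set(names: Sequence[str]) -> str:
    has_epi = any(n.startswith("EPI:") for n in names)
    has_mot = any(n.startswith("MOT:") for n in names)
    if has_epi and has_mot:
        return "ALL"
    return "EPI" if has_epi else "MOT"
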