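"""Shadow-feature importance, false-discovery estimation and ablation.

The importance procedure follows the shadow-feature (Boruta-style)
scheme: each iteration re-permutes a shadow copy of every feature,
fits a random forest, and records a "hit" for features whose
permutation importance exceeds the best shadow importance; a two-sided
binomial test on the hit count confirms or rejects features.  The data
is additionally extended with *contrast* variables — row-permuted
copies of real features that carry no label information by design —
and the whole run is repeated with fresh contrast realizations; the
mean number of confirmed contrasts per repetition estimates the
expected number of false discoveries among the real features.

Ablation protocols: single-mark removal, removal of the K most or
least important marks (K = 1..7), and iterative elimination of the 80%
least important motif features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .evaluation import CVResult, CVSpec, cross_validate
from .io import CONTRAST_PREFIX, EPI_PREFIX, MOT_PREFIX, LabeledFeatureMatrix
from .model import ModelSpec

__all__ = [
    "ImportanceSpec",
    "AblationSpec",
    "BorutaRun",
    "ImportanceReport",
    "AblationPoint",
    "add_contrast_variables",
    "boruta_run",
    "repeated_importance",
    "ablation_curve",
    "iterative_tf_elimination",
    "reduced_model_eval",
]


@dataclass(frozen=True)
class ImportanceSpec:
    n_repetitions: int = 30
    max_rf_iterations: int = 100
    alpha: float = 0.01
    n_contrast: int | None = None  # default: one per original feature
    n_estimators: int = 30
    holdout_fraction: float = 0.3  # validation split for permutation importance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_rf_iterations < 1:
            raise ValueError("max_rf_iterations must be >= 1")


@dataclass
class BorutaRun:
    """Outcome of one shadow-importance run over an (augmented) table."""

    decisions: dict[str, str]  # feature -> confirmed | rejected | tentative
    z_scores: dict[str, float]
    iterations: int


@dataclass
class ImportanceReport:
    """Aggregated importance over repeated contrast realizations."""

    feature_z: dict[str, float]
    decisions: dict[str, str]
    contrast_confirmations: list[int]
    n_contrast: int

    @property
    def expected_false_discoveries(self) -> float:
        """Mean number of contrast variables confirmed per repetition."""
        return float(np.mean(self.contrast_confirmations))

    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    def ranking(self) -> list[str]:
        """Feature names by decreasing mean Z-score."""
        return sorted(self.feature_z, key=lambda f: -self.feature_z[f])

    def summary(self) -> str:
        lines = [
            "Feature importance (shadow-feature procedure)",
            "=" * 52,
            f"{'feature':<28} {'mean Z':>8}  decision",
        ]
        for f in self.ranking():
            lines.append(f"{f:<28} {self.feature_z[f]:>8.2f}  {self.decisions[f]}")
        lines.append(
            f"expected false discoveries: {self.expected_false_discoveries:.3f} "
            f"(of {self.n_contrast} contrast variables, "
            f"{len(self.contrast_confirmations)} repetitions)"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class AblationSpec:
    mode: str = "single_mark"  # single_mark | top_k_marks | bottom_k_marks
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    cv_spec: CVSpec = field(default_factory=CVSpec)

    def __post_init__(self) -> None:
        if self.mode not in ("single_mark", "top_k_marks", "bottom_k_marks"):
            raise ValueError(f"unknown ablation mode {self.mode!r}")


@dataclass
class AblationPoint:
    removed: tuple[str, ...]
    cv_result: CVResult
    accuracy_loss: float  # error(ablated) - error(full)


# ---------------------------------------------------------------------------


def add_contrast_variables(
    data: LabeledFeatureMatrix, n_contrast: int, rng: np.random.Generator
) -> LabeledFeatureMatrix:
    """Extend the table with row-permuted copies of original features.

    Contrast variable i is an independently permuted copy of original
    feature ``i mod p`` (cycling over features preserves the marginal
    distributions); labels are untouched.
    """
    if n_contrast < 1:
        raise ValueError("n_contrast must be >= 1")
    src_names = data.feature_names
    p = len(src_names)
    cols = {}
    for i in range(n_contrast):
        src = src_names[i % p]
        perm = rng.permutation(data.n)
        cols[f"{CONTRAST_PREFIX}{i + 1:03d}:{src}"] = data.features[src].to_numpy()[perm]
    augmented = pd.concat([data.features, pd.DataFrame(cols, index=data.features.index)], axis=1)
    return LabeledFeatureMatrix(features=augmented, labels=data.labels.copy())


def _binom_two_sided(hits: np.ndarray, n: np.ndarray) -> np.ndarray:
    lo = binom.cdf(hits, n, 0.5)
    hi = binom.sf(hits - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def _permutation_importance(
    rf: RandomForestClassifier,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-decrease-accuracy-style importance on held-out rows.

    Uses the forest's probability of the true class (a soft accuracy)
    rather than the 0/1 vote, which keeps the measure continuous at
    small validation sizes; the drop after permuting one column is
    that column's importance.  All permuted copies are scored in a
    single stacked predict call.
    """
    n_val, p = X_val.shape
    baseline = rf.predict_proba(X_val)[np.arange(n_val), y_val].mean()
    stacked = np.repeat(X_val[None, :, :], p, axis=0)
    for j in range(p):
        stacked[j, :, j] = X_val[rng.permutation(n_val), j]
    proba = rf.predict_proba(stacked.reshape(p * n_val, p))[np.arange(p * n_val), np.tile(y_val, p)]
    return baseline - proba.reshape(p, n_val).mean(axis=1)


def boruta_run(
    data: LabeledFeatureMatrix, spec: ImportanceSpec, rng: np.random.Generator
) -> BorutaRun:
    """One shadow-importance run: iterate, test hit counts, decide.

    Every feature in ``data`` (including any contrast columns) gets a
    decision; shadows are internal, re-permuted each iteration.  A
    feature scores a hit when its importance exceeds the best shadow
    importance; accumulated hit counts are tested two-sided against
    Binomial(iterations, 1/2) at ``alpha``.  Rejected features are
    dropped from the design for later iterations; the run stops early
    once nothing is tentative.  The per-feature Z-score is
    (importance - mean shadow) / sd shadow averaged over the
    iterations in which the feature was active.
    """
    names = data.feature_names
    X = data.features.to_numpy(dtype=float)
    y = data.labels
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")

    hits = np.zeros(p, dtype=int)
    iters_active = np.zeros(p, dtype=int)
    z_sums = np.zeros(p)
    z_counts = np.zeros(p, dtype=int)
    status = np.array(["tentative"] * p, dtype=object)
    active = np.ones(p, dtype=bool)
    n_val = max(int(round(spec.holdout_fraction * n)), 10)

    it = 0
    for it in range(1, spec.max_rf_iterations + 1):
        idx = np.flatnonzero(active)
        Xa = X[:, idx]
        shadow = rng.permuted(Xa, axis=0)  # each column shuffled independently
        full = np.hstack([Xa, shadow])
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
            continue
        rf = RandomForestClassifier(
            n_estimators=spec.n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(full[train_idx], y[train_idx])
        imps = _permutation_importance(rf, full[val_idx], y[val_idx], rng)
        real, shad = imps[: len(idx)], imps[len(idx) :]
        if np.all(imps == 0):
            warnings.warn("degenerate forest importance (all zero)", stacklevel=2)
            continue
        iters_active[idx] += 1
        hits[idx] += real > shad.max()
        # Z needs a usable spread estimate: require a handful of shadows
        if len(shad) >= 5:
            sd = shad.std(ddof=1)
            if sd > 1e-12:
                z_sums[idx] += (real - shad.mean()) / sd
                z_counts[idx] += 1
        # decide still-tentative features on the accumulated hit counts
        tentative = status == "tentative"
        if tentative.any():
            tent_idx = np.flatnonzero(tentative)
            pvals = _binom_two_sided(hits[tent_idx], iters_active[tent_idx])
            for j in tent_idx[pvals < spec.alpha]:
                if hits[j] > iters_active[j] / 2:
                    status[j] = "confirmed"
                else:
                    status[j] = "rejected"
                    active[j] = False
        if not (status == "tentative").any():
            break

    z = np.where(z_counts > 0, z_sums / np.maximum(z_counts, 1), 0.0)
    return BorutaRun(
        decisions={f: s for f, s in zip(names, status)},
        z_scores={f: float(v) for f, v in zip(names, z)},
        iterations=it,
    )


def repeated_importance(
    data: LabeledFeatureMatrix, spec: ImportanceSpec | None = None
) -> ImportanceReport:
    """Shadow-importance runs over repeated contrast realizations.

    Final Z = mean over repetitions; decision = majority vote (ties
    stay tentative); expected false discoveries = mean number of
    confirmed contrast variables per repetition.
    """
    if spec is None:
        spec = ImportanceSpec()
    orig_names = data.feature_names
    n_contrast = spec.n_contrast if spec.n_contrast is not None else len(orig_names)
    rng = np.random.default_rng(spec.seed)

    z_acc = {f: [] for f in orig_names}
    votes = {f: {"confirmed": 0, "rejected": 0, "tentative": 0} for f in orig_names}
    contrast_confirmed: list[int] = []
    for _rep in range(spec.n_repetitions):
        augmented = add_contrast_variables(data, n_contrast, rng)
        run = boruta_run(augmented, spec, rng)
        n_cc = 0
        for f, decision in run.decisions.items():
            if f.startswith(CONTRAST_PREFIX):
                n_cc += decision == "confirmed"
            else:
                votes[f][decision] += 1
                z_acc[f].append(run.z_scores[f])
        contrast_confirmed.append(n_cc)

    decisions = {}
    for f, v in votes.items():
        top = max(v.values())
        winners = [d for d, c in v.items() if c == top]
        decisions[f] = winners[0] if len(winners) == 1 else "tentative"
    return ImportanceReport(
        feature_z={f: float(np.mean(zs)) if zs else 0.0 for f, zs in z_acc.items()},
        decisions=decisions,
        contrast_confirmations=contrast_confirmed,
        n_contrast=n_contrast,
    )


# ---------------------------------------------------------------------------
# Ablation


def ablation_curve(
    data: LabeledFeatureMatrix,
    spec: AblationSpec,
    ranking: Sequence[str],
) -> list[AblationPoint]:
    """Retrain and cross-validate after removing chromatin marks.

    ``ranking`` lists features by decreasing importance (e.g. from
    ``ImportanceReport.ranking()``); only its EPI entries are eligible
    for removal.  Accuracy loss is measured against the full model.
    """
    mark_ranking = [f for f in ranking if f.startswith(EPI_PREFIX)]
    if not mark_ranking:
        raise ValueError("ranking contains no chromatin-mark features")
    full = cross_validate(spec.model_spec, data, spec.cv_spec)

    removal_sets: list[tuple[str, ...]] = []
    if spec.mode == "single_mark":
        removal_sets = [(m,) for m in mark_ranking]
    else:
        for k in spec.k_range:
            if k > len(mark_ranking):
                raise ValueError(f"K={k} exceeds the {len(mark_ranking)}-mark panel")
            if spec.mode == "top_k_marks":
                removal_sets.append(tuple(mark_ranking[:k]))
            else:
                removal_sets.append(tuple(mark_ranking[-k:]))

    points = []
    for removed in removal_sets:
        ablated = data.drop_features(removed)
        res = cross_validate(spec.model_spec, ablated, spec.cv_spec)
        points.append(
            AblationPoint(
                removed=removed,
                cv_result=res,
                accuracy_loss=res.error_mean - full.error_mean,
            )
        )
    return points


def _elimination_step(count: int) -> int:
    """How many motif features the iterative protocol removes at once."""
    return max(int(0.8 * count), 1) if count >= 5 else 1


def iterative_tf_elimination(
    data: LabeledFeatureMatrix,
    importance_spec: ImportanceSpec | None = None,
    model_spec: ModelSpec | None = None,
    cv_spec: CVSpec | None = None,
) -> list[dict]:
    """Iteratively drop the 80% least important motif features.

    Each step re-ranks the surviving motif features (chromatin-mark
    columns, if present, are kept throughout), removes
    floor(0.8 * count) of the least important when count >= 5 and a
    single one otherwise, and records the cross-validated error.
    Stops when one motif feature remains.
    """
    if importance_spec is None:
        importance_spec = ImportanceSpec()
    if model_spec is None:
        model_spec = ModelSpec()
    if cv_spec is None:
        cv_spec = CVSpec()
    mot = [f for f in data.feature_names if f.startswith(MOT_PREFIX)]
    if not mot:
        raise ValueError("no motif features to eliminate")

    current = data
    trace: list[dict] = []
    step = 0
    while True:
        n_tf = sum(f.startswith(MOT_PREFIX) for f in current.feature_names)
        res = cross_validate(model_spec, current, cv_spec)
        trace.append(
            {
                "step": step,
                "n_tf": n_tf,
                "cv_error": res.error_mean,
                "cv_auc": res.auc_mean,
                "features": list(current.feature_names),
            }
        )
        if n_tf <= 1:
            break
        report = repeated_importance(current, replace(importance_spec, seed=importance_spec.seed + step))
        mot_ranked = [f for f in report.ranking() if f.startswith(MOT_PREFIX)]
        n_remove = _elimination_step(n_tf)
        current = current.drop_features(mot_ranked[-n_remove:])
        step += 1
    return trace


def reduced_model_eval(
    data: LabeledFeatureMatrix,
    feature_subset: Sequence[str],
    model_spec: ModelSpec | None = None,
    cv_spec: CVSpec | None = None,
) -> CVResult:
    """Cross-validate a hand-picked feature subset (e.g. one motif plus
    three marks)."""
    if model_spec is None:
        model_spec = ModelSpec()
    if cv_spec is None:
        cv_spec = CVSpec()
    return cross_validate(model_spec, data.subset_features(feature_subset), cv_spec)
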