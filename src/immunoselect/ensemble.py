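"""Recursive automatic ensemble feature selection.

The selection strategy runs eight classifier families (bagging,
gradient boosting, logistic regression, passive-aggressive, random
forest, ridge, SGD on a linear model, linear-kernel SVC) under repeated
stratified cross-validation, reads a per-feature relevance vector out of
every fitted model, aggregates the vectors into a single ensemble
ranking weighted by both mean importance and the frequency with which a
feature contributes at all, and then discards the bottom 20% of
features.  Iterating this from the full panel down to a single feature
yields a trace of feature-set size against global average accuracy; the
smallest set whose global average accuracy clears a cutoff (90% by
default) is the selected signature.

Using many families guards against the selection biases of any single
algorithm, which matters in small-cohort settings where one model's
idiosyncratic fit can dominate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .data_model import FeatureTable, ValidityError

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = (
    "bagging",
    "gradient_boosting",
    "logistic_regression",
    "passive_aggressive",
    "random_forest",
    "ridge",
    "sgd_linear",
    "linear_svc",
)


class ConfigError(ValueError):
    pass


class NoFurtherReduction(Exception):
    """Raised when a single remaining feature cannot be reduced further."""


@dataclass
class RFEConfig:
    """Knobs of the recursive ensemble selection."""

    classifier_families: tuple[str, ...] = CLASSIFIER_FAMILIES
    n_repeats: int = 10
    n_folds: int = 10
    reduction_fraction: float = 0.20
    accuracy_cutoff: float = 0.90
    base_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.classifier_families) - set(CLASSIFIER_FAMILIES)
        if unknown:
            raise ConfigError(f"unknown classifier families: {sorted(unknown)}")
        if not 0 < self.reduction_fraction < 1:
            raise ConfigError("reduction_fraction must lie in (0, 1)")
        if not 0 < self.accuracy_cutoff <= 1:
            raise ConfigError("accuracy_cutoff must lie in (0, 1]")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be at least 1")


def make_classifier(family: str, seed: int):
    """Instantiate one classifier family with its frozen hyperparameters.

    Hyperparameters are the scikit-learn library defaults.  The
    passive-aggressive family is built as SGD with the PA-I update
    (hinge loss, no penalty, ``learning_rate="pa1"``), which is the
    passive-aggressive algorithm in current scikit-learn.
    """
    if family == "bagging":
        return BaggingClassifier(random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if family == "passive_aggressive":
        return SGDClassifier(
            loss="hinge", penalty=None, learning_rate="pa1", eta0=1.0,
            random_state=seed,
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "ridge":
        return RidgeClassifier()
    if family == "sgd_linear":
        return SGDClassifier(random_state=seed)
    if family == "linear_svc":
        return LinearSVC(random_state=seed)
    raise ConfigError(f"unknown classifier family {family!r}")


def make_pipeline(family: str, seed: int) -> Pipeline:
    """Imputation + standardization + classifier, fitted per fold.

    Median imputation and scaling are fitted on the training portion of
    each fold only, so no information leaks from held-out samples.
    """
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", make_classifier(family, seed)),
        ]
    )


def extract_importance(model) -> np.ndarray:
    """Per-feature relevance of a fitted model, rescaled to sum 1.

    Linear families contribute absolute coefficients; tree ensembles
    their impurity-based importances; bagging the mean of its base
    estimators' importances.  An all-zero vector (a model that used no
    feature) passes through unchanged with a log note.
    """
    if isinstance(model, Pipeline):
        model = model.named_steps["clf"]
    if isinstance(model, BaggingClassifier):
        imp = np.mean(
            [est.feature_importances_ for est in model.estimators_], axis=0
        )
    elif hasattr(model, "coef_"):
        imp = np.abs(np.asarray(model.coef_)).sum(axis=0)
    elif hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise ConfigError(
            f"{type(model).__name__} exposes neither coefficients nor importances"
        )
    imp = np.asarray(imp, dtype=float)
    total = imp.sum()
    if total == 0:
        logger.debug("all-zero importance vector from %s", type(model).__name__)
        return imp
    return imp / total


@dataclass
class RunResult:
    """One (family, repeat) cross-validated run on a fixed feature set."""

    family: str
    repeat: int
    features: tuple[str, ...]
    fold_accuracies: np.ndarray
    importance: np.ndarray  # fold-averaged normalized importances


def effective_folds(labels: np.ndarray, n_folds: int) -> int:
    """Stratified CV cannot use more folds than the minority class size."""
    minority = int(np.bincount(labels).min())
    if minority < 2:
        raise ValidityError("stratified CV needs at least 2 samples per class")
    eff = min(n_folds, minority)
    if eff < n_folds:
        logger.info(
            "minority class has %d members; using %d folds instead of %d",
            minority, eff, n_folds,
        )
    return eff


def run_classifier_cv(
    table: FeatureTable,
    features: Sequence[str],
    family: str,
    repeat_seed: int,
    n_folds: int = 10,
) -> RunResult:
    """One repeat of stratified k-fold CV for one classifier family.

    Returns held-out accuracy per fold and the fold-averaged normalized
    importance vector over ``features``.
    """
    features = list(features)
    if not features:
        raise ValidityError("feature subset is empty")
    table.require_both_groups()
    X = table.data[features].to_numpy(dtype=float)
    y = table.labels()
    eff = effective_folds(y, n_folds)
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=repeat_seed)
    accs = np.empty(eff)
    imps = np.empty((eff, len(features)))
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValidityError(
                "a training fold contains a single class; use fewer folds"
            )
        pipe = make_pipeline(family, repeat_seed)
        pipe.fit(X[tr], y[tr])
        accs[k] = float(np.mean(pipe.predict(X[te]) == y[te]))
        imps[k] = extract_importance(pipe)
    return RunResult(
        family=family,
        repeat=repeat_seed,
        features=tuple(features),
        fold_accuracies=accs,
        importance=imps.mean(axis=0),
    )


@dataclass
class EnsembleRanking:
    """Aggregated per-feature relevance over many classifier runs.

    ``score = mean normalized importance x contribution frequency``,
    where the frequency is the fraction of runs in which the feature
    received any nonzero importance.  Ties break lexicographically by
    feature name so the ordering is total and deterministic.
    """

    features: tuple[str, ...]
    scores: np.ndarray
    frequencies: np.ndarray
    mean_importance: np.ndarray

    def ordered(self) -> list[str]:
        order = sorted(
            range(len(self.features)),
            key=lambda i: (-self.scores[i], self.features[i]),
        )
        return [self.features[i] for i in order]

    def top(self, k: int) -> list[str]:
        return self.ordered()[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.scores,
                "frequency": self.frequencies,
                "mean_importance": self.mean_importance,
            },
            index=pd.Index(self.features, name="feature"),
        ).sort_values("score", ascending=False, kind="stable")


def aggregate_rankings(runs: Sequence[RunResult]) -> EnsembleRanking:
    """Combine per-run importance vectors into one ensemble ranking."""
    if not runs:
        raise ValidityError("no runs to aggregate")
    features = runs[0].features
    for r in runs:
        if r.features != features:
            raise ValidityError(
                "runs disagree on the feature set; cannot aggregate"
            )
    imp = np.stack([r.importance for r in runs])  # runs x features
    freq = (imp > 0).mean(axis=0)
    mean_imp = imp.mean(axis=0)
    return EnsembleRanking(
        features=features,
        scores=mean_imp * freq,
        frequencies=freq,
        mean_importance=mean_imp,
    )


def reduce_features(
    ranking: EnsembleRanking, current: Sequence[str], fraction: float = 0.20
) -> list[str]:
    """Keep the top ``floor((1 - fraction) * n)`` features by score.

    The retained count is clamped to ``[1, n - 1]`` so every step
    strictly shrinks the set and never empties it.
    """
    current = list(current)
    n = len(current)
    if n <= 1:
        raise NoFurtherReduction("cannot reduce a single remaining feature")
    k = math.floor((1.0 - fraction) * n)
    k = max(1, min(k, n - 1))
    keep = [f for f in ranking.ordered() if f in set(current)][:k]
    return keep


@dataclass
class Iteration:
    """One elimination step: the feature set and its accuracy profile."""

    features: tuple[str, ...]
    per_family_accuracy: dict[str, float]
    global_accuracy: float
    ranking: EnsembleRanking


@dataclass
class RFETrace:
    """Ordered record of all elimination iterations (largest set first)."""

    iterations: list[Iteration] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.sizes()
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValidityError("iteration feature-set sizes must strictly decrease")

    def sizes(self) -> list[int]:
        return [len(it.features) for it in self.iterations]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            row = {"n_features": len(it.features)}
            row.update(it.per_family_accuracy)
            row["global_accuracy"] = it.global_accuracy
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "iterations": [
                {
                    "features": list(it.features),
                    "per_family_accuracy": {
                        k: it.per_family_accuracy[k]
                        for k in sorted(it.per_family_accuracy)
                    },
                    "global_accuracy": it.global_accuracy,
                }
                for it in self.iterations
            ]
        }


@dataclass
class SelectionResult:
    """The chosen signature and the accuracy at which it was chosen."""

    features: tuple[str, ...]
    n_features: int
    global_accuracy: float
    cutoff: float
    cutoff_met: bool
    trace: RFETrace


def _evaluate_feature_set(
    table: FeatureTable, features: Sequence[str], config: RFEConfig
) -> Iteration:
    runs = []
    for family in config.classifier_families:
        for r in range(config.n_repeats):
            runs.append(
                run_classifier_cv(
                    table, features, family, config.base_seed + r, config.n_folds
                )
            )
    ranking = aggregate_rankings(runs)
    per_family = {
        family: float(
            np.mean(
                np.concatenate(
                    [r.fold_accuracies for r in runs if r.family == family]
                )
            )
        )
        for family in config.classifier_families
    }
    global_acc = float(np.mean(np.concatenate([r.fold_accuracies for r in runs])))
    return Iteration(
        features=tuple(features),
        per_family_accuracy=per_family,
        global_accuracy=global_acc,
        ranking=ranking,
    )


def recursive_selection(table: FeatureTable, config: RFEConfig | None = None) -> RFETrace:
    """Run the full recursion from the complete panel down to one feature.

    Every iteration re-runs all families x repeats on the current set,
    re-aggregates the ranking, and drops the bottom fraction.  Repeat
    ``r`` always uses seed ``base_seed + r``, so iterations differ only
    in their feature set.
    """
    config = config or RFEConfig()
    features = list(table.feature_names)
    trace = RFETrace()
    while True:
        iteration = _evaluate_feature_set(table, features, config)
        trace.iterations.append(iteration)
        logger.info(
            "iteration with %d features: global accuracy %.3f",
            len(features), iteration.global_accuracy,
        )
        if len(features) == 1:
            break
        features = reduce_features(
            iteration.ranking, features, config.reduction_fraction
        )
    return trace


def select_optimal(trace: RFETrace, cutoff: float = 0.90) -> SelectionResult:
    """Smallest feature set whose global average accuracy meets the cutoff.

    If no iteration qualifies, the most accurate iteration is returned
    with ``cutoff_met=False``.
    """
    if not trace.iterations:
        raise ValidityError("empty trace")
    qualifying = [it for it in trace.iterations if it.global_accuracy >= cutoff]
    if qualifying:
        best = min(qualifying, key=lambda it: len(it.features))
        met = True
    else:
        best = max(trace.iterations, key=lambda it: it.global_accuracy)
        met = False
        logger.warning(
            "no iteration reached the %.0f%% accuracy cutoff; "
            "falling back to the most accurate set (%d features, %.3f)",
            100 * cutoff, len(best.features), best.global_accuracy,
        )
    return SelectionResult(
        features=best.features,
        n_features=len(best.features),
        global_accuracy=best.global_accuracy,
        cutoff=cutoff,
        cutoff_met=met,
        trace=trace,
    )
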