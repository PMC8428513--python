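"""Evaluation artifacts for a selected feature signature.

Given a signature chosen by the recursive ensemble, this module
produces the standard read-outs: pooled cross-validated ROC curves and
AUC per classifier family, a two-component PCA projection of the
z-scored signature, and the accuracy-versus-feature-count report of the
elimination trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .data_model import FeatureTable, ValidityError, zscore_normalize
from .ensemble import RFETrace, effective_folds, make_pipeline

__all__ = [
    "cross_validated_scores",
    "roc_auc",
    "pca_projection",
    "accuracy_curve_report",
    "ROCResult",
    "PCAProjection",
]


def cross_validated_scores(
    table: FeatureTable,
    features: Sequence[str],
    family: str,
    n_folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Pooled held-out decision scores, one per sample.

    A single seeded stratified CV pass; each sample is scored by the
    model from the fold that held it out, so no score comes from a model
    trained on that sample.  Families with a decision function
    contribute signed margins, probabilistic families the predicted
    probability of the treated class.
    """
    features = list(features)
    if not features:
        raise ValidityError("feature subset is empty")
    table.require_both_groups()
    X = table.data[features].to_numpy(dtype=float)
    y = table.labels()
    eff = effective_folds(y, n_folds)
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        pipe = make_pipeline(family, seed)
        pipe.fit(X[tr], y[tr])
        clf = pipe.named_steps["clf"]
        if hasattr(clf, "decision_function"):
            scores[te] = pipe.decision_function(X[te])
        else:
            scores[te] = pipe.predict_proba(X[te])[:, 1]
    return scores


@dataclass
class ROCResult:
    """ROC curve and rank-formula AUC for one score vector."""

    family: str
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def roc_auc(scores, labels, family: str = "") -> ROCResult:
    """ROC analysis of per-sample scores against binary group labels.

    The AUC uses the rank formula ``U / (n1 * n0)`` — the Mann-Whitney
    U-statistic of treated versus control scores with ties counted half
    — which equals the probability that a random treated sample scores
    above a random control sample.  The curve itself is a threshold
    sweep; it starts at (0, 0) and ends at (1, 1), both coordinates
    non-decreasing.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind not in "biu":
        labels = (labels == "antibiotic").astype(int)
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    if n1 == 0 or n0 == 0:
        raise ValidityError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)  # midranks: ties counted half
    u = float(ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        family=family, scores=scores, labels=labels,
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
    )


@dataclass
class PCAProjection:
    """First two principal components of the z-scored signature."""

    coordinates: pd.DataFrame  # samples x {PC1, PC2}
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x {PC1, PC2}


def pca_projection(table: FeatureTable, features: Sequence[str]) -> PCAProjection:
    """Project samples on the leading principal components.

    Operates on per-feature z-scores (correlation PCA) so that
    mixed-unit panels contribute on equal footing.  Component signs are
    fixed deterministically: the loading with the largest magnitude is
    made positive.
    """
    features = list(features)
    if len(features) < 2:
        raise ValidityError("PCA needs at least 2 features")
    if table.n_samples < 3:
        raise ValidityError("PCA needs at least 3 samples")
    z = zscore_normalize(table.subset(features))
    X = z.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        col_med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), col_med, X)
    n_comp = min(2, len(features), table.n_samples - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for i in range(n_comp):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            coords[:, i] *= -1
    names = [f"PC{i+1}" for i in range(n_comp)]
    return PCAProjection(
        coordinates=pd.DataFrame(coords, index=table.sample_ids, columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(comps.T, index=features, columns=names),
    )


def accuracy_curve_report(
    trace: RFETrace, outdir: str | Path, cutoff: float = 0.90
) -> dict:
    """Write the accuracy-vs-feature-count table and figure.

    The table holds one row per elimination iteration (feature count,
    per-family mean accuracy, global mean); the figure draws the global
    curve with a horizontal line at the accuracy cutoff.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = trace.to_frame()
    table_path = outdir / "accuracy_curve.tsv"
    with open(table_path, "w") as fh:
        fh.write(f"# accuracy cutoff: {cutoff}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame["n_features"], frame["global_accuracy"], "o-",
            label="global average")
    ax.axhline(cutoff, color="crimson", linestyle="--",
               label=f"cutoff {cutoff:.0%}")
    ax.set_xlabel("number of features")
    ax.set_ylabel("cross-validated accuracy")
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.legend(frameon=False)
    fig.suptitle("Recursive ensemble feature elimination")
    figure_path = outdir / "accuracy_curve.svg"
    fig.savefig(figure_path, metadata={"Description": f"accuracy cutoff={cutoff}"})
    plt.close(fig)
    return {"table": table_path, "figure": figure_path, "cutoff": cutoff}
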