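"""Model-object interface to the recursive ensemble selection.

Follows the model/results idiom of statistical modelling packages: a
:class:`RecursiveEnsembleSelector` is constructed from data (a
:class:`~immunoselect.data_model.FeatureTable` or a plain DataFrame via
:meth:`~RecursiveEnsembleSelector.from_dataframe`), its :meth:`fit`
runs the full recursion and returns an
:class:`EnsembleSelectionResults` object carrying the elimination
trace, the selected signature, per-family accuracies, and evaluation
methods (ROC, PCA, summary table, accuracy plot).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .data_model import FeatureTable
from .ensemble import (
    RFEConfig,
    RFETrace,
    SelectionResult,
    recursive_selection,
    select_optimal,
)


class RecursiveEnsembleSelector:
    """Recursive automatic ensemble feature selection on a labeled cohort.

    Parameters
    ----------
    table
        Labeled sample x feature table; both group levels must be
        present with at least 2 samples each.
    config
        Selection settings; defaults are 8 classifier families,
        10 repeats of (up to) 10-fold stratified CV, 20% elimination
        per step and a 90% global-accuracy cutoff.

    Examples
    --------
    >>> from immunoselect import CohortConfig, generate_cohort
    >>> table, truth = generate_cohort(CohortConfig(seed=3))
    >>> res = RecursiveEnsembleSelector(table).fit()   # doctest: +SKIP
    >>> res.selected_features_                         # doctest: +SKIP
    """

    def __init__(self, table: FeatureTable, config: RFEConfig | None = None):
        self.table = table
        self.config = config or RFEConfig()
        table.require_both_groups()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        group: Sequence[str] | pd.Series,
        config: RFEConfig | None = None,
    ) -> "RecursiveEnsembleSelector":
        """Build a selector from a plain numeric DataFrame plus labels."""
        if not isinstance(group, pd.Series):
            group = pd.Series(list(group), index=data.index, name="group")
        return cls(FeatureTable(data.copy(), group), config)

    def fit(self) -> "EnsembleSelectionResults":
        """Run the recursion from the full panel down to one feature."""
        trace = recursive_selection(self.table, self.config)
        selection = select_optimal(trace, self.config.accuracy_cutoff)
        return EnsembleSelectionResults(self, trace, selection)


class EnsembleSelectionResults:
    """Results of a fitted :class:`RecursiveEnsembleSelector`."""

    def __init__(
        self,
        model: RecursiveEnsembleSelector,
        trace: RFETrace,
        selection: SelectionResult,
    ):
        self.model = model
        self.trace = trace
        self.selection = selection

    @property
    def selected_features_(self) -> tuple[str, ...]:
        return self.selection.features

    @property
    def n_selected_(self) -> int:
        return self.selection.n_features

    @property
    def global_accuracy_(self) -> float:
        return self.selection.global_accuracy

    @property
    def cutoff_met_(self) -> bool:
        return self.selection.cutoff_met

    def accuracy_table(self) -> pd.DataFrame:
        """Per-iteration feature count, per-family and global accuracy."""
        return self.trace.to_frame()

    def roc(self, family: str = "ridge", seed: int | None = None) -> evaluation.ROCResult:
        """Pooled cross-validated ROC of one family on the signature."""
        seed = self.model.config.base_seed if seed is None else seed
        scores = evaluation.cross_validated_scores(
            self.model.table,
            self.selection.features,
            family,
            self.model.config.n_folds,
            seed,
        )
        return evaluation.roc_auc(scores, self.model.table.labels(), family)

    def pca(self) -> evaluation.PCAProjection:
        """PCA of the z-scored selected signature."""
        return evaluation.pca_projection(self.model.table, self.selection.features)

    def report(self, outdir: str | Path) -> dict:
        """Write the accuracy-curve table and figure."""
        return evaluation.accuracy_curve_report(
            self.trace, outdir, self.model.config.accuracy_cutoff
        )

    def summary(self) -> str:
        """Human-readable account of the selection."""
        cfg = self.model.config
        counts = self.model.table.group.value_counts()
        lines = [
            "Recursive ensemble feature selection",
            "=" * 52,
            f"samples:            {self.model.table.n_samples} "
            f"({counts.get('control', 0)} control / {counts.get('antibiotic', 0)} treated)",
            f"initial features:   {len(self.trace.iterations[0].features)}",
            f"classifier families:{len(cfg.classifier_families):>4}",
            f"repeats x folds:    {cfg.n_repeats} x {cfg.n_folds}",
            f"reduction per step: {cfg.reduction_fraction:.0%}",
            f"accuracy cutoff:    {cfg.accuracy_cutoff:.0%}"
            + ("" if self.selection.cutoff_met else "  (NOT met; best set reported)"),
            "-" * 52,
            f"selected signature: {self.selection.n_features} features at "
            f"{self.selection.global_accuracy:.1%} global accuracy",
        ]
        for feat in self.selection.features:
            lines.append(f"  - {feat}")
        lines.append("-" * 52)
        lines.append("iterations (features -> global accuracy):")
        for it in self.trace.iterations:
            marker = " <== selected" if it.features == self.selection.features else ""
            lines.append(
                f"  {len(it.features):>4} -> {it.global_accuracy:.3f}{marker}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<EnsembleSelectionResults: {self.selection.n_features} features, "
            f"global accuracy {self.selection.global_accuracy:.3f}, "
            f"cutoff {'met' if self.selection.cutoff_met else 'not met'}>"
        )
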