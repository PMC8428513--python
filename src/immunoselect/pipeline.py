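"""End-to-end pipeline orchestration with a reproducibility manifest.

A single YAML config (strictly parsed: unknown keys are fatal) drives
generate -> select -> evaluate -> univariate/diversity runs.  Every
output bundle carries a manifest recording the seed, the fully resolved
config, a config hash and library versions, so any bundle can be
regenerated bit-identically from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import sklearn
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .data_model import FeatureTable
from .ensemble import RFEConfig
from .evaluation import accuracy_curve_report, pca_projection
from .model import RecursiveEnsembleSelector
from .stats import diversity_compare, univariate_screen
from .synthetic import (
    CohortConfig,
    default_schema,
    generate_cohort,
    generate_genus_counts,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_control: int = 11
    n_treated: int = 8
    n_features: int = 129
    effect_size: float = 2.0
    seed: int = 0

    def build(self) -> CohortConfig:
        schema = default_schema()
        if self.n_features < len(schema):
            # trimmed panels keep the planted signature features
            from .synthetic import DEFAULT_INFORMATIVE

            informative = [n for n in DEFAULT_INFORMATIVE]
            others = [n for n in schema.names if n not in informative]
            keep = others[: max(0, self.n_features - len(informative))] + informative
            schema = schema.subset(keep)
        return CohortConfig(
            n_control=self.n_control,
            n_treated=self.n_treated,
            schema=schema,
            effect_sizes=self.effect_size,
            seed=self.seed,
        )


class RFESettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_repeats: int = 10
    n_folds: int = 10
    reduction_fraction: float = 0.20
    accuracy_cutoff: float = 0.90
    base_seed: int = 0

    @field_validator("reduction_fraction")
    @classmethod
    def _check_fraction(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("reduction_fraction must lie in (0, 1)")
        return v

    def build(self) -> RFEConfig:
        return RFEConfig(
            n_repeats=self.n_repeats,
            n_folds=self.n_folds,
            reduction_fraction=self.reduction_fraction,
            accuracy_cutoff=self.accuracy_cutoff,
            base_seed=self.base_seed,
        )


class DiversitySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genera: int = 30
    depth: int = 10_000
    evenness_control: float = 1.0
    evenness_treated: float = 0.2


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["generate", "analyze", "full"] = "full"
    cohort: CohortSettings = CohortSettings()
    rfe: RFESettings = RFESettings()
    diversity: DiversitySettings = DiversitySettings()
    log_level: str = "INFO"


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load and strictly validate a YAML pipeline config.

    An empty (or absent) file resolves to all defaults.  Unknown keys
    raise a :class:`ConfigError` naming the key.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(str(exc)) from exc


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: PipelineConfig, outdir: Path) -> Path:
    manifest = {
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed,
        "versions": {
            "immunoselect": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "python": platform.python_version(),
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_full(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured pipeline stages and write the bundle.

    Returns a dict of the written artifact paths plus the in-memory
    results.  ``mode="generate"`` writes only the cohort table, genus
    counts and ground truth; ``"analyze"`` and ``"full"`` add
    selection, evaluation, univariate and diversity outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    artifacts: dict = {}

    logger.info("stage: generate (seed %d)", config.cohort.seed)
    table, truth = generate_cohort(config.cohort.build())
    table.write(outdir / "feature_table.csv")
    artifacts["feature_table"] = outdir / "feature_table.csv"
    truth_payload = {
        "informative_features": list(truth.informative_features),
        "effect_sizes": truth.effect_sizes,
        "directions": truth.directions,
        "realized_group_means": {
            f: {g: truth.realized_group_means.loc[f, g]
                for g in truth.realized_group_means.columns}
            for f in truth.informative_features
        },
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True)
    )
    artifacts["ground_truth"] = outdir / "ground_truth.json"

    genus = generate_genus_counts(
        n_control=config.cohort.n_control,
        n_treated=config.cohort.n_treated,
        n_genera=config.diversity.n_genera,
        depth=config.diversity.depth,
        evenness_control=config.diversity.evenness_control,
        evenness_treated=config.diversity.evenness_treated,
        seed=config.cohort.seed,
    )
    genus.write(outdir / "genus_counts.tsv")
    artifacts["genus_counts"] = outdir / "genus_counts.tsv"
    artifacts["manifest"] = _write_manifest(config, outdir)

    if config.mode == "generate":
        return artifacts

    logger.info("stage: select")
    results = RecursiveEnsembleSelector(table, config.rfe.build()).fit()
    (outdir / "rfe_trace.json").write_text(
        json.dumps(results.trace.to_dict(), indent=2, sort_keys=True)
    )
    artifacts["rfe_trace"] = outdir / "rfe_trace.json"
    (outdir / "selected_features.txt").write_text(
        "\n".join(results.selected_features_) + "\n"
    )
    artifacts["selected_features"] = outdir / "selected_features.txt"
    (outdir / "selection.json").write_text(
        json.dumps(
            {
                "n_features": results.n_selected_,
                "features": list(results.selected_features_),
                "global_accuracy": results.global_accuracy_,
                "cutoff": config.rfe.accuracy_cutoff,
                "cutoff_met": results.cutoff_met_,
            },
            indent=2, sort_keys=True,
        )
    )
    artifacts["selection"] = outdir / "selection.json"

    logger.info("stage: evaluate")
    artifacts.update(accuracy_curve_report(
        results.trace, outdir, config.rfe.accuracy_cutoff
    ))
    roc = results.roc("ridge")
    roc.to_frame().to_csv(outdir / "roc_ridge.tsv", sep="\t", index=False)
    artifacts["roc"] = outdir / "roc_ridge.tsv"
    artifacts["roc_auc"] = roc.auc
    if results.n_selected_ >= 2:
        proj = results.pca()
    else:
        # a single-feature signature has no plane to project onto;
        # fall back to the 2-feature iteration of the trace
        two = next(it for it in results.trace.iterations if len(it.features) == 2)
        proj = pca_projection(table, list(two.features))
    proj.coordinates.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
    artifacts["pca"] = outdir / "pca_coordinates.tsv"

    logger.info("stage: univariate + diversity")
    univariate_screen(table).to_csv(outdir / "univariate.tsv", sep="\t")
    artifacts["univariate"] = outdir / "univariate.tsv"
    div = diversity_compare(genus)
    div.to_frame().to_csv(outdir / "diversity.tsv", sep="\t")
    (outdir / "diversity_test.json").write_text(
        json.dumps({"U": div.u_statistic, "p": div.p_value}, indent=2)
    )
    artifacts["diversity"] = outdir / "diversity.tsv"
    artifacts["results"] = results
    return artifacts
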