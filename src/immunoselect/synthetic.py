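"""Synthetic cohort generator.

Emulates the study design the analysis pipeline expects: a small
two-group pregnancy cohort (11 control / 8 antibiotic-treated dams by
default) measured on a 129-parameter immune panel spanning five
flow-cytometry compartments, placental/intestinal qPCR fold-changes and
two cytokine panels, plus genus-level 16S count tables in which
antibiotic treatment reduces community evenness.

A configurable subset of features is "planted" as group-informative
(default: the four features reported to drive classification — splenic
Th17 and CD5+ B-cell frequencies, MLN CD4+ T-cell frequency, placental
RORgT fold-change) with a given standardized effect size.  The returned
ground truth makes the planted set exactly recoverable, so selection
procedures can be benchmarked for recovery.

Randomness is counter-based: every feature column draws from its own
stream spawned from ``(seed, feature_index)``, so adding or reordering
later features never perturbs earlier columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CONTROL,
    TREATED,
    FeatureDescriptor,
    FeatureTable,
    PanelSchema,
    SchemaError,
    ValidityError,
)

# 20 lymphocyte subsets scored in every flow compartment
_FLOW_SUBSETS = (
    "CD4_T",
    "CD8_T",
    "Th1",
    "Th2",
    "Th17",
    "Treg",
    "CD4_CD25",
    "CD4_CD69",
    "CD8_CD25",
    "CD8_CD69",
    "NK",
    "NKT",
    "B",
    "B1",
    "B2",
    "CD5_B",
    "Breg",
    "MZB",
    "pDC",
    "cDC",
)
_FLOW_COMPARTMENTS = ("spleen", "MLN", "ILN", "PCLF", "placenta")

_MRNA_GENES = ("FOXP3", "Tbet", "GATA3", "RORgT", "IL10")
_MRNA_COMPARTMENTS = ("placenta", "intestine")
_MRNA_PLACENTA_ONLY = ("IL6", "TGFb")

_CYTOKINES = ("IL1b", "IL2", "IL4", "IL6", "IL10", "IL22", "TNFa", "IFNg")

DEFAULT_INFORMATIVE = (
    "spleen_Th17",
    "spleen_CD5_B",
    "MLN_CD4_T",
    "placenta_RORgT_mRNA",
)


def default_schema() -> PanelSchema:
    """The default 129-feature immune panel.

    101 flow-cytometry subset frequencies (20 subsets in each of
    spleen/MLN/ILN/PCLF/placenta, plus one placenta-only subset),
    12 mRNA fold-changes and 16 cytokine concentrations (8 analytes in
    amniotic fluid; the same 8 in splenocyte supernatant after LPS
    background correction, where negatives are legitimate).
    """
    feats: list[FeatureDescriptor] = []
    for comp in _FLOW_COMPARTMENTS:
        for subset in _FLOW_SUBSETS:
            feats.append(
                FeatureDescriptor(
                    name=f"{comp}_{subset}",
                    assay="flow_frequency",
                    compartment=comp,
                    unit="% of parent",
                    noise_family="logit_normal",
                )
            )
    feats.append(
        FeatureDescriptor(
            name="placenta_Tim1_B",
            assay="flow_frequency",
            compartment="placenta",
            unit="% of parent",
            noise_family="logit_normal",
        )
    )
    for comp in _MRNA_COMPARTMENTS:
        for gene in _MRNA_GENES:
            feats.append(
                FeatureDescriptor(
                    name=f"{comp}_{gene}_mRNA",
                    assay="mrna_foldchange",
                    compartment=comp,
                    unit="fold-change vs beta-actin",
                    noise_family="log_normal",
                )
            )
    for gene in _MRNA_PLACENTA_ONLY:
        feats.append(
            FeatureDescriptor(
                name=f"placenta_{gene}_mRNA",
                assay="mrna_foldchange",
                compartment="placenta",
                unit="fold-change vs beta-actin",
                noise_family="log_normal",
            )
        )
    for analyte in _CYTOKINES:
        feats.append(
            FeatureDescriptor(
                name=f"amniotic_fluid_{analyte}",
                assay="cytokine",
                compartment="amniotic_fluid",
                unit="pg/mL",
                noise_family="log_normal",
            )
        )
    for analyte in _CYTOKINES:
        feats.append(
            FeatureDescriptor(
                name=f"splenocyte_supernatant_{analyte}",
                assay="cytokine",
                compartment="splenocyte_supernatant",
                unit="pg/mL (LPS-corrected)",
                noise_family="log_normal_corrected",
            )
        )
    return PanelSchema(tuple(feats))


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``effect_sizes`` maps informative feature names to the group-mean
    separation in within-group standard-deviation units, applied on the
    feature's latent (pre-transform) scale.  Effect direction alternates
    (up, down, up, down in the treated group, in the order given) to
    mirror a mixed-direction signature; override via ``directions``.
    """

    n_control: int = 11
    n_treated: int = 8
    schema: PanelSchema = field(default_factory=default_schema)
    informative_features: tuple[str, ...] = DEFAULT_INFORMATIVE
    effect_sizes: Mapping[str, float] | float = 2.0
    directions: Mapping[str, int] | None = None
    latent_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treated < 2:
            raise ValidityError("need at least 2 samples per group")
        missing = set(self.informative_features) - set(self.schema.names)
        if missing:
            raise SchemaError(
                f"informative features not in schema: {sorted(missing)}"
            )
        if isinstance(self.effect_sizes, (int, float)):
            self.effect_sizes = {
                name: float(self.effect_sizes) for name in self.informative_features
            }
        else:
            self.effect_sizes = dict(self.effect_sizes)
            extra = set(self.effect_sizes) - set(self.informative_features)
            if extra:
                raise SchemaError(
                    f"effect sizes given for non-informative features: {sorted(extra)}"
                )
        if not all(np.isfinite(v) for v in self.effect_sizes.values()):
            raise ValidityError("effect sizes must be finite")
        if self.directions is None:
            self.directions = {
                name: 1 if i % 2 == 0 else -1
                for i, name in enumerate(self.informative_features)
            }


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery benchmarks."""

    informative_features: tuple[str, ...]
    effect_sizes: dict[str, float]
    directions: dict[str, int]
    realized_group_means: pd.DataFrame  # features x {control, antibiotic}


def _feature_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _latent_location(desc: FeatureDescriptor, rng: np.random.Generator) -> float:
    """Per-feature baseline on the latent normal scale.

    Flow subsets get logit-scale locations spanning rare (~1%) to
    abundant (~50%) populations; cytokines span ~3-150 pg/mL on the log
    scale; fold-changes center at 1 (log location 0).
    """
    if desc.noise_family == "logit_normal":
        return float(rng.uniform(-4.5, 0.0))
    if desc.noise_family == "log_normal":
        if desc.assay == "cytokine":
            return float(rng.uniform(1.0, 5.0))
        return 0.0
    if desc.noise_family == "log_normal_corrected":
        return float(rng.uniform(2.0, 5.0))
    return 0.0


def _transform(latent: np.ndarray, desc: FeatureDescriptor,
               rng: np.random.Generator, latent_sd: float) -> np.ndarray:
    if desc.noise_family == "logit_normal":
        return 100.0 / (1.0 + np.exp(-latent))
    if desc.noise_family == "log_normal":
        return np.exp(latent)
    if desc.noise_family == "log_normal_corrected":
        # stimulated minus unstimulated background (both positive before
        # correction; the difference may legitimately be negative)
        stimulated = np.exp(latent)
        background = np.exp(rng.normal(latent.mean() - 1.5, latent_sd, latent.shape))
        return stimulated - background
    return latent


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one synthetic cohort.

    Deterministic given ``config.seed``.  Uninformative features are
    i.i.d. across groups from the assay's noise family; informative
    features have their treated-group latent mean shifted by
    ``direction * effect_size * latent_sd``.
    """
    n_c, n_t = config.n_control, config.n_treated
    n = n_c + n_t
    sample_ids = [f"C{i+1:02d}" for i in range(n_c)] + [
        f"T{i+1:02d}" for i in range(n_t)
    ]
    group = pd.Series(
        [CONTROL] * n_c + [TREATED] * n_t, index=sample_ids, name="group"
    )
    columns: dict[str, np.ndarray] = {}
    for j, desc in enumerate(config.schema.features):
        rng = _feature_rng(config.seed, j)
        loc = _latent_location(desc, rng)
        latent = rng.normal(loc, config.latent_sd, size=n)
        if desc.name in config.effect_sizes:
            shift = (
                config.directions[desc.name]
                * config.effect_sizes[desc.name]
                * config.latent_sd
            )
            latent[n_c:] += shift
        columns[desc.name] = _transform(latent, desc, rng, config.latent_sd)
    data = pd.DataFrame(columns, index=sample_ids)
    table = FeatureTable(data, group, config.schema.to_frame())
    means = pd.DataFrame(
        {
            CONTROL: data.iloc[:n_c].mean(),
            TREATED: data.iloc[n_c:].mean(),
        }
    )
    truth = GroundTruth(
        informative_features=tuple(config.informative_features),
        effect_sizes=dict(config.effect_sizes),
        directions=dict(config.directions),
        realized_group_means=means,
    )
    return table, truth


@dataclass
class GenusCountTable:
    """Sample x genus non-negative count matrix with group labels."""

    counts: pd.DataFrame  # index samples, columns genera, integer
    group: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidityError("genus counts must be non-negative")
        totals = self.counts.sum(axis=1)
        if (totals <= 0).any():
            empty = list(totals.index[totals <= 0])
            raise ValidityError(f"samples with zero total counts: {empty}")
        if not self.group.index.equals(self.counts.index):
            raise ValidityError("group labels not aligned with samples")

    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "group", self.group)
        out.to_csv(Path(path), sep="\t", index_label="sample_id")


def read_genus_counts(path: str | Path) -> GenusCountTable:
    raw = pd.read_csv(Path(path), sep="\t", index_col=0)
    if "group" not in raw.columns:
        raise SchemaError(f"{path}: no 'group' column found")
    group = raw["group"].astype(str)
    counts = raw.drop(columns="group").astype(int)
    return GenusCountTable(counts, group)


def generate_genus_counts(
    n_control: int = 11,
    n_treated: int = 8,
    n_genera: int = 30,
    depth: int = 10_000,
    evenness_control: float = 1.0,
    evenness_treated: float = 0.2,
    seed: int = 0,
) -> GenusCountTable:
    """Genus-level count tables with treatment-reduced evenness.

    Per-sample genus proportions are Dirichlet with a symmetric
    concentration parameter (the "evenness": smaller concentration
    yields communities dominated by few genera, hence lower Shannon
    diversity); counts are multinomial at the given sequencing depth.
    Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValidityError("sequencing depth must be positive")
    if evenness_control <= 0 or evenness_treated <= 0:
        raise ValidityError("evenness parameters must be positive")
    sample_ids = [f"C{i+1:02d}" for i in range(n_control)] + [
        f"T{i+1:02d}" for i in range(n_treated)
    ]
    group = pd.Series(
        [CONTROL] * n_control + [TREATED] * n_treated,
        index=sample_ids,
        name="group",
    )
    genera = [f"genus_{i+1:02d}" for i in range(n_genera)]
    rows = []
    for i, sid in enumerate(sample_ids):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1_000_000 + i,)))
        conc = evenness_control if group[sid] == CONTROL else evenness_treated
        props = rng.dirichlet(np.full(n_genera, conc))
        rows.append(rng.multinomial(depth, props))
    counts = pd.DataFrame(
        rows, index=pd.Index(sample_ids, name="sample_id"), columns=genera
    )
    return GenusCountTable(counts, group.rename_axis("sample_id"))
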