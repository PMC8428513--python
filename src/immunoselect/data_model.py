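"""Feature-table data model, file I/O, and assay-level preprocessing.

The analysis substrate is a labeled sample x feature table of immune
parameters measured in a two-group cohort (control vs. antibiotic-treated):
flow-cytometry subset frequencies (percent of parent population),
qPCR fold-changes relative to a reference gene, and cytokine
concentrations (pg/mL).  Each feature carries assay and compartment
metadata so that downstream generators and reports can treat the three
assay families differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CONTROL = "control"
TREATED = "antibiotic"
GROUP_LEVELS = (CONTROL, TREATED)

ASSAYS = ("flow_frequency", "mrna_foldchange", "cytokine")
COMPARTMENTS = (
    "spleen",
    "MLN",
    "ILN",
    "PCLF",
    "placenta",
    "amniotic_fluid",
    "intestine",
    "splenocyte_supernatant",
)


class SchemaError(ValueError):
    """Input file or metadata does not match the expected layout."""


class FormatError(ValueError):
    """A cell could not be parsed as a number."""


class ValidityError(ValueError):
    """A table violates a structural invariant."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature of the panel: name plus assay-level metadata."""

    name: str
    assay: str
    compartment: str
    unit: str
    noise_family: str = "normal"

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise SchemaError(f"unknown assay {self.assay!r} for feature {self.name!r}")
        if self.compartment not in COMPARTMENTS:
            raise SchemaError(
                f"unknown compartment {self.compartment!r} for feature {self.name!r}"
            )


@dataclass(frozen=True)
class PanelSchema:
    """Ordered list of feature descriptors defining an assay panel."""

    features: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names in schema: {dupes}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def subset(self, names: Iterable[str]) -> "PanelSchema":
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise SchemaError(f"features not in schema: {sorted(missing)}")
        return PanelSchema(tuple(f for f in self.features if f.name in wanted))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assay": [f.assay for f in self.features],
                "compartment": [f.compartment for f in self.features],
                "unit": [f.unit for f in self.features],
                "noise_family": [f.noise_family for f in self.features],
            },
            index=pd.Index(self.names, name="feature"),
        )


@dataclass
class FeatureTable:
    """Sample x feature numeric matrix with group labels and feature metadata.

    Parameters
    ----------
    data
        Numeric values, index = sample ids, columns = feature names.
        Missing entries are NaN (never silently zero).
    group
        Per-sample label, one of ``{"control", "antibiotic"}``, aligned
        with ``data.index``.
    feature_meta
        Per-feature record with columns ``assay``, ``compartment``,
        ``unit`` indexed by feature name, aligned with ``data.columns``.
    """

    data: pd.DataFrame
    group: pd.Series
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"assay": "cytokine", "compartment": "spleen", "unit": ""},
                index=self.data.columns,
            )
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len(self.group) != len(self.data):
            raise ValidityError(
                f"group has {len(self.group)} entries for {len(self.data)} samples"
            )
        if not self.group.index.equals(self.data.index):
            raise ValidityError("group labels are not aligned with sample ids")
        if len(self.feature_meta) != self.data.shape[1]:
            raise ValidityError(
                f"feature_meta has {len(self.feature_meta)} rows for "
                f"{self.data.shape[1]} features"
            )
        bad = set(self.group.unique()) - set(GROUP_LEVELS)
        if bad:
            raise ValidityError(f"unknown group labels: {sorted(bad)}")
        # flow frequencies are percentages; the bound no longer applies
        # once a table has been z-scored (unit tag records that)
        is_flow = self.feature_meta["assay"] == "flow_frequency"
        if "unit" in self.feature_meta.columns:
            is_flow &= self.feature_meta["unit"] != "z-score"
        flow = self.feature_meta.index[is_flow]
        if len(flow):
            vals = self.data[flow]
            if ((vals < 0) | (vals > 100)).any().any():
                raise ValidityError("flow_frequency values must lie in [0, 100]")

    def require_both_groups(self, min_per_group: int = 2) -> None:
        counts = self.group.value_counts()
        for level in GROUP_LEVELS:
            if counts.get(level, 0) < min_per_group:
                raise ValidityError(
                    f"need at least {min_per_group} samples per group; "
                    f"{level!r} has {counts.get(level, 0)}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def labels(self) -> np.ndarray:
        """Binary labels: 0 = control, 1 = antibiotic-treated."""
        return (self.group.to_numpy() == TREATED).astype(int)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        features = list(features)
        return FeatureTable(
            self.data[features].copy(),
            self.group.copy(),
            self.feature_meta.loc[features].copy(),
        )

    # -- I/O --------------------------------------------------------------
    def write(self, path: str | Path, dialect: str = "csv") -> None:
        """Write values to CSV/TSV plus a YAML metadata sidecar."""
        path = Path(path)
        sep = {"csv": ",", "tsv": "\t"}[dialect]
        out = self.data.copy()
        out.insert(0, "group", self.group)
        out.to_csv(path, sep=sep, index_label="sample_id", float_format="%.12g")
        meta = {
            name: {
                "assay": str(row["assay"]),
                "compartment": str(row["compartment"]),
                "unit": str(row["unit"]),
            }
            for name, row in self.feature_meta.iterrows()
        }
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=False)
        )


def read_feature_table(path: str | Path, dialect: str = "csv") -> FeatureTable:
    """Read a feature table from disk.

    The first column holds sample ids, a ``group`` column holds the
    two-level label, and the remaining columns are numeric features.
    Blank cells become missing values.  A ``<path>.meta.yaml`` sidecar,
    if present, supplies per-feature assay/compartment/unit metadata.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if "group" not in raw.columns:
        raise SchemaError(f"{path}: no 'group' column found")
    group = raw["group"].astype(str)
    bad = set(group.unique()) - set(GROUP_LEVELS)
    if bad:
        raise SchemaError(f"{path}: unknown group labels {sorted(bad)}")
    values = raw.drop(columns="group")
    parsed: dict[str, pd.Series] = {}
    for col in values.columns:
        try:
            parsed[col] = pd.to_numeric(values[col])
        except (ValueError, TypeError):
            offending = values[col][pd.to_numeric(values[col], errors="coerce").isna()
                                    & values[col].notna()]
            row = offending.index[0] if len(offending) else "?"
            raise FormatError(
                f"{path}: unparseable numeric cell at row {row!r}, column {col!r}"
            ) from None
    numeric = pd.DataFrame(parsed, index=values.index)
    counts = group.value_counts()
    for level in GROUP_LEVELS:
        if counts.get(level, 0) < 2:
            raise ValidityError(
                f"{path}: fewer than 2 samples in group {level!r}"
            )
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    feature_meta = None
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        feature_meta = pd.DataFrame.from_dict(meta, orient="index")
        feature_meta = feature_meta.loc[list(numeric.columns)]
    return FeatureTable(numeric, group, feature_meta)


def zscore_normalize(table: FeatureTable) -> FeatureTable:
    """Per-feature z-score with population standard deviation (ddof=0).

    Constant features map to all-zeros with a warning; an all-missing
    feature is an error.  Missing entries stay missing.
    """
    out = table.data.copy().astype(float)
    for col in out.columns:
        vals = out[col]
        n_obs = vals.notna().sum()
        if n_obs == 0:
            raise ValidityError(f"feature {col!r} has no observed values")
        if n_obs < 2:
            raise ValidityError(f"feature {col!r} has fewer than 2 observed values")
        mu = vals.mean()
        sd = vals.std(ddof=0)
        if sd == 0:
            warnings.warn(f"feature {col!r} is constant; z-scores set to 0")
            out[col] = vals.where(vals.isna(), 0.0)
        else:
            out[col] = (vals - mu) / sd
    meta = table.feature_meta.copy()
    meta["unit"] = "z-score"
    return FeatureTable(out, table.group.copy(), meta)


def lps_correct(
    stimulated: pd.Series, unstimulated: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Background-correct stimulated cytokine levels.

    Subtracts the concentration measured in unstimulated-culture
    supernatant from the LPS-stimulated one, analyte by analyte.
    Negative results are retained (clamping would bias group
    comparisons); the returned boolean series flags them.
    """
    if not stimulated.index.equals(unstimulated.index):
        raise ValidityError(
            "stimulated and unstimulated vectors are not aligned on analyte"
        )
    corrected = stimulated - unstimulated
    return corrected, corrected < 0


def relative_expression(ct_target, ct_reference):
    """Fold-change of a target gene relative to the reference gene.

    Computed as ``2**-(Ct_target - Ct_reference)`` (delta-Ct method):
    each extra amplification cycle of the target halves its inferred
    abundance.  Accepts scalars or aligned arrays.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ValidityError("Ct values must be finite")
    result = np.power(2.0, -(ct_target - ct_reference))
    if result.ndim == 0:
        return float(result)
    return result
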