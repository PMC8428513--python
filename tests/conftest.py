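import numpy as np
import pandas as pd
import pytest

from immunoselect import (
    CohortConfig,
    FeatureDescriptor,
    FeatureTable,
    PanelSchema,
    generate_cohort,
)


def small_schema(n_flow: int = 6, n_mrna: int = 2, n_cyto: int = 2) -> PanelSchema:
    """A compact panel for fast tests: a few features of each assay."""
    feats = []
    for i in range(n_flow):
        feats.append(FeatureDescriptor(
            name=f"spleen_f{i}", assay="flow_frequency", compartment="spleen",
            unit="% of parent", noise_family="logit_normal"))
    for i in range(n_mrna):
        feats.append(FeatureDescriptor(
            name=f"placenta_g{i}_mRNA", assay="mrna_foldchange",
            compartment="placenta", unit="fold-change", noise_family="log_normal"))
    for i in range(n_cyto):
        feats.append(FeatureDescriptor(
            name=f"amniotic_fluid_c{i}", assay="cytokine",
            compartment="amniotic_fluid", unit="pg/mL", noise_family="log_normal"))
    return PanelSchema(tuple(feats))


@pytest.fixture(scope="session")
def default_cohort():
    """One default 19-sample, 129-feature cohort with planted effects."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def toy_table():
    """A tiny complete table with a perfectly separating first feature."""
    rng = np.random.default_rng(7)
    n = 12
    data = pd.DataFrame(
        {
            "sep": np.r_[np.zeros(6), np.ones(6)],
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    group = pd.Series(["control"] * 6 + ["antibiotic"] * 6,
                      index=data.index, name="group")
    return FeatureTable(data, group)


def separable_table(n_per_group: int = 6) -> FeatureTable:
    data = pd.DataFrame(
        {"marker": np.r_[np.zeros(n_per_group), np.ones(n_per_group)]},
        index=[f"s{i}" for i in range(2 * n_per_group)],
    )
    group = pd.Series(
        ["control"] * n_per_group + ["antibiotic"] * n_per_group,
        index=data.index, name="group",
    )
    return FeatureTable(data, group)
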