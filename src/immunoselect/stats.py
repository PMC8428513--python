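"""Univariate screening and microbiota diversity statistics.

The univariate arm compares every immune feature between groups with a
two-sided Mann-Whitney test and flags raw p < 0.05 (no multiplicity
correction drives the flags; a Benjamini-Hochberg column is emitted
alongside for reference).  The diversity arm computes per-sample
Shannon alpha diversity on genus count tables, compares groups with the
same rank-sum engine, and provides the centered log-ratio transform for
compositional PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.composition import closure, clr, multi_replace
from statsmodels.stats.multitest import multipletests

from .data_model import CONTROL, TREATED, FeatureTable, ValidityError
from .synthetic import GenusCountTable

ALPHA = 0.05


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic of the first sample.
    ``auto`` uses exact enumeration when ``n1 * n2 <= 400`` and the
    pooled data are tie-free, otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidityError("both samples must be nonempty")
    if mode == "auto":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    elif mode in ("exact", "approximate"):
        method = "exact" if mode == "exact" else "asymptotic"
    else:
        raise ValidityError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class UnivariateResult:
    feature: str
    u_statistic: float
    p_value: float
    p_bh: float
    median_control: float
    median_treated: float
    significant: bool


def univariate_screen(table: FeatureTable) -> pd.DataFrame:
    """Mann-Whitney screen of every feature, control vs. treated.

    Missing values are dropped pairwise per feature.  The significance
    flag uses the raw p-value at alpha = 0.05; the BH-adjusted column is
    informational only.
    """
    table.require_both_groups()
    is_control = table.group == CONTROL
    rows = []
    for feat in table.feature_names:
        vals = table.data[feat]
        a = vals[is_control].dropna().to_numpy()
        b = vals[~is_control].dropna().to_numpy()
        u, p = mann_whitney(a, b)
        rows.append(
            {
                "feature": feat,
                "U": u,
                "p": p,
                "median_control": float(np.median(a)) if a.size else np.nan,
                "median_treated": float(np.median(b)) if b.size else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p"] < ALPHA
    return out


def shannon_index(counts) -> float:
    """Shannon alpha diversity H = -sum(p_i ln p_i), in nats."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidityError("total count must be positive")
    return float(sps.entropy(counts))


def clr_transform(
    table: GenusCountTable, zero_strategy: str = "pseudocount"
) -> pd.DataFrame:
    """Centered log-ratio transform of a genus count table.

    Genera absent from every sample are dropped with a warning.  Zeros
    are replaced either by adding a 0.5 pseudocount to zero cells on the
    count scale (default, deterministic) or by multiplicative
    replacement; compositions are re-closed before taking logs.  Every
    output row sums to zero.
    """
    counts = table.counts.copy()
    dead = counts.columns[(counts == 0).all(axis=0)]
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} genera absent from all samples: {list(dead)}"
        )
        counts = counts.drop(columns=dead)
    mat = counts.to_numpy(dtype=float)
    if zero_strategy == "pseudocount":
        mat = np.where(mat == 0, 0.5, mat)
        comp = closure(mat)
    elif zero_strategy == "multiplicative-replacement":
        comp = closure(mat)
        if (comp == 0).any():
            comp = multi_replace(comp)
    else:
        raise ValidityError(f"unknown zero strategy {zero_strategy!r}")
    return pd.DataFrame(clr(comp), index=counts.index, columns=counts.columns)


@dataclass
class DiversityResult:
    """Per-sample Shannon indices and the between-group comparison."""

    shannon: pd.Series
    u_statistic: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return self.shannon.to_frame("shannon_nats")


def diversity_compare(table: GenusCountTable) -> DiversityResult:
    """Shannon diversity per sample, compared between groups.

    Uses the same two-sided rank-sum engine as the univariate screen
    (the two-group Wilcoxon rank-sum and the Mann-Whitney U test are the
    same procedure).
    """
    h = table.counts.apply(lambda row: shannon_index(row.to_numpy()), axis=1)
    h.name = "shannon_nats"
    a = h[table.group == CONTROL].to_numpy()
    b = h[table.group == TREATED].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValidityError("need at least 2 samples per group")
    u, p = mann_whitney(a, b)
    return DiversityResult(shannon=h, u_statistic=u, p_value=p)
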