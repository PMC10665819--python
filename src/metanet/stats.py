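"""Post-quantification NMR metabolomics statistics.

Covers the univariate/multivariate workflow applied to kidney-tissue
metabolite concentration tables: conversion of spectrometer output
(mmol/L) to tissue concentration (ug per mg dry insoluble pellet),
probabilistic quotient normalization (PQN), per-metabolite Mann-Whitney
screening with fold changes (deliberately uncorrected for multiple
testing: the workflow is exploratory and treats type II error as the
greater risk), and autoscaled PCA summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "GROUPS",
    "MetaboliteTable",
    "UnivariateResult",
    "PcaResult",
    "convert_concentration",
    "pqn_normalize",
    "mann_whitney",
    "univariate_screen",
    "pca_scores",
]

#: Canonical group labels, in study order.
GROUPS = ("wildtype", "disease", "disease_treated")

# Exact-enumeration Mann-Whitney up to this pooled size (no ties);
# beyond it (or with ties) the tie-corrected normal approximation is used.
_EXACT_LIMIT = 12


@dataclass
class MetaboliteTable:
    """Samples x metabolites concentration matrix with group labels.

    ``data`` holds non-negative concentrations (ug/mg dry insoluble
    pellet after conversion); ``groups`` maps each sample id to exactly
    one group label.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without group label: {missing}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative concentrations")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate metabolite ids")

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def group_data(self, group: str) -> pd.DataFrame:
        mask = self.groups == group
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return self.data.loc[mask]

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep=sep, index_label="sample")

    @classmethod
    def read_csv(cls, path: str | Path, sep: str = "\t") -> "MetaboliteTable":
        df = pd.read_csv(path, sep=sep, index_col=0)
        groups = df.pop("group")
        return cls(data=df.astype(float), groups=groups)


def convert_concentration(
    c_mmol_per_l: float | np.ndarray,
    volume_ml: float,
    mw_g_per_mol: float,
    pellet_mg: float,
) -> float | np.ndarray:
    """Convert mmol/L to ug per mg of dry insoluble pellet.

    mmol/L x mL = umol in the extract; umol x g/mol = ug; divided by the
    pellet mass in mg.
    """
    if pellet_mg <= 0:
        raise ValueError("pellet mass must be positive")
    if volume_ml < 0 or mw_g_per_mol < 0 or np.any(np.asarray(c_mmol_per_l) < 0):
        raise ValueError("inputs must be non-negative")
    return c_mmol_per_l * volume_ml * mw_g_per_mol / pellet_mg


def _reference_profile(
    table: MetaboliteTable, reference: str | pd.Series
) -> pd.Series:
    if isinstance(reference, pd.Series):
        return reference.reindex(table.data.columns)
    if reference == "all-samples":
        data = table.data
    elif reference.startswith("group:"):
        data = table.group_data(reference.split(":", 1)[1])
    else:
        raise ValueError(f"unknown PQN reference policy {reference!r}")
    # Median profile across samples, each sample first scaled by its own
    # median so the reference shape is invariant to per-sample dilution.
    med = data.median(axis=1)
    if (med <= 0).any():
        bad = med.index[med <= 0].tolist()
        raise ValueError(f"samples with non-positive median profile: {bad}")
    return (data.div(med, axis=0)).median(axis=0)


def pqn_normalize(
    table: MetaboliteTable, reference: str | pd.Series = "all-samples"
) -> MetaboliteTable:
    """Probabilistic quotient normalization.

    Each sample is divided by the median of its per-metabolite quotients
    against the reference profile, removing per-sample dilution. The
    default reference is the element-wise median profile across all
    samples (computed on per-sample median-scaled profiles, which makes
    the operation exactly idempotent and exactly invariant to any
    positive per-sample scaling); ``group:<name>`` restricts the
    reference to one group, and an explicit ``pd.Series`` profile may be
    supplied directly.
    """
    if len(table.data) < 2 and not isinstance(reference, pd.Series):
        raise ValueError("PQN requires at least 2 samples")
    ref = _reference_profile(table, reference)
    usable = ref > 0
    if not usable.any():
        raise ValueError("reference profile is all zero")
    quotients = table.data.loc[:, usable].div(ref[usable], axis=1)
    factors = quotients.median(axis=1)
    bad = factors.index[~(factors > 0)].tolist()
    if bad:
        raise ValueError(f"undefined PQN quotients for samples: {bad}")
    return MetaboliteTable(
        data=table.data.div(factors, axis=0), groups=table.groups
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p, never multiplicity-adjusted.

    Exact permutation p (doubled minimum tail, capped at 1) when the
    pooled size is at most 12 and there are no ties; tie-corrected
    normal approximation otherwise. Returns ``(U, p)`` with U counted
    for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class UnivariateResult:
    """Per-metabolite screening results for one ordered group comparison."""

    comparison: tuple[str, str]  # (numerator group, denominator group)
    table: pd.DataFrame = field(repr=False)  # metabolite, U, p, log2fc, significant

    @property
    def significant(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def univariate_screen(
    table: MetaboliteTable,
    comparison: tuple[str, str],
    alpha: float = 0.05,
) -> UnivariateResult:
    """Mann-Whitney screen of every metabolite for one group comparison.

    log2FC is the log2 ratio of arithmetic group means
    (numerator / denominator); a zero denominator mean leaves log2FC
    missing with a warning while the p-value is still computed.
    """
    num, den = comparison
    da, db = table.group_data(num), table.group_data(den)
    rows = []
    for met in table.metabolites:
        u, p = mann_whitney(da[met], db[met])
        mean_num, mean_den = da[met].mean(), db[met].mean()
        if mean_den == 0 or mean_num == 0:
            warnings.warn(
                f"zero group mean for {met}; log2FC undefined", stacklevel=2
            )
            lfc = np.nan
        else:
            lfc = float(np.log2(mean_num / mean_den))
        rows.append((met, u, p, lfc, p < alpha))
    df = pd.DataFrame(
        rows, columns=["metabolite", "U", "p", "log2fc", "significant"]
    ).set_index("metabolite")
    return UnivariateResult(comparison=comparison, table=df)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    dropped: tuple[str, ...] = ()

    @property
    def cumulative_first_two_percent(self) -> float:
        return float(self.explained_variance_ratio[:2].sum() * 100.0)


def pca_scores(table: MetaboliteTable, k: int = 2) -> PcaResult:
    """PCA of the autoscaled concentration matrix.

    Columns are centred and scaled to unit variance before the singular
    value decomposition (metabolite ranges span several decades, so raw
    scaling would be dominated by the most abundant compounds). Constant
    metabolites are dropped with a warning.
    """
    if len(table.data) < 3 or table.data.shape[1] < 2:
        raise ValueError("PCA needs at least 3 samples and 2 metabolites")
    data = table.data
    std = data.std(axis=0, ddof=1)
    dropped = tuple(std.index[std == 0])
    if dropped:
        warnings.warn(f"dropping constant metabolites: {list(dropped)}", stacklevel=2)
        data = data.drop(columns=list(dropped))
        std = std.drop(labels=list(dropped))
    z = (data - data.mean(axis=0)) / std
    k = min(k, z.shape[1], len(z) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    # Full spectrum of variance for the ratio so percentages refer to the
    # total variance, not just the k retained components.
    total_var = z.var(axis=0, ddof=1).sum()
    ratio = pca.explained_variance_ / total_var
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=data.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=ratio,
        dropped=dropped,
    )
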