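"""Group-wise metabolite-metabolite correlation pattern mining.

Pearson correlation matrices are computed per experimental group, then
filtered to pairs significant (p < alpha, strict) in *both* groups of a
comparison. Two pattern classes are mined on top of the filtered sets:

``opposite_under_treatment``
    the pair correlates with opposite signs in the disease and treated
    groups (dual-significant there) while being absent from the
    wildtype-disease dual-significant set — a treatment-specific
    rewiring, not a disease trait.
``corrected_toward_wildtype``
    the pair correlates with opposite signs in wildtype and disease
    (dual-significant) and the treated group's sign matches wildtype
    (dual-significant in the disease-treated comparison) — the
    treatment restores the wildtype relationship.

The dual-significance filter makes no multiple-testing correction and
is sensitive to outlier samples; no outlier rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GROUPS, MetaboliteTable

__all__ = [
    "CorrelationMatrixSet",
    "PatternPair",
    "groupwise_pearson",
    "shared_significant_pairs",
    "concordance_matrix",
    "find_opposite_treatment_pairs",
    "find_corrected_pairs",
    "pattern_pairs_frame",
]

Pair = tuple[str, str]


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class CorrelationMatrixSet:
    """Per-group symmetric Pearson r and two-sided p matrices."""

    r: dict[str, pd.DataFrame]
    p: dict[str, pd.DataFrame]
    n: dict[str, int]

    @property
    def metabolites(self) -> list[str]:
        return list(next(iter(self.r.values())).columns)

    @property
    def groups(self) -> list[str]:
        return list(self.r)

    def pair(self, group: str, pair: Pair) -> tuple[float, float]:
        a, b = pair
        return float(self.r[group].at[a, b]), float(self.p[group].at[a, b])


def groupwise_pearson(table: MetaboliteTable) -> CorrelationMatrixSet:
    """Pearson r and two-sided p for every metabolite pair, per group.

    The p-value uses the t distribution with n-2 degrees of freedom.
    Pairs involving a within-group constant metabolite are reported as
    NaN (undefined), which downstream filters treat as non-significant.
    """
    r_by, p_by, n_by = {}, {}, {}
    for group in pd.unique(table.groups):
        data = table.group_data(group)
        n = len(data)
        if n < 4:
            raise ValueError(f"group {group!r} has fewer than 4 samples")
        mets = table.metabolites
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(data.to_numpy(), rowvar=False)
        np.fill_diagonal(r, 1.0)
        rr = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        p[np.isnan(rr)] = np.nan
        p[np.isclose(np.abs(rr), 1.0)] = 0.0
        np.fill_diagonal(p, 0.0)
        r_by[group] = pd.DataFrame(r, index=mets, columns=mets)
        p_by[group] = pd.DataFrame(p, index=mets, columns=mets)
        n_by[group] = n
    return CorrelationMatrixSet(r=r_by, p=p_by, n=n_by)


def shared_significant_pairs(
    mats: CorrelationMatrixSet,
    comparison: tuple[str, str],
    alpha: float = 0.05,
) -> set[Pair]:
    """Pairs with p strictly below alpha in *both* groups of the comparison."""
    g1, g2 = comparison
    kept: set[Pair] = set()
    for a, b in combinations(mats.metabolites, 2):
        p1 = mats.p[g1].at[a, b]
        p2 = mats.p[g2].at[a, b]
        if p1 < alpha and p2 < alpha:  # NaN compares False: undefined excluded
            kept.add(_ordered(a, b))
    return kept


def concordance_matrix(
    mats: CorrelationMatrixSet,
    comparison: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Signed sign-concordance matrix over the dual-significant pairs.

    +1 where the correlation keeps its direction across the two groups,
    -1 where it flips; all other cells are NaN (not displayed).
    """
    g1, g2 = comparison
    mets = mats.metabolites
    out = pd.DataFrame(np.nan, index=mets, columns=mets)
    for a, b in shared_significant_pairs(mats, comparison, alpha):
        sign = 1.0 if np.sign(mats.r[g1].at[a, b]) == np.sign(mats.r[g2].at[a, b]) else -1.0
        out.at[a, b] = sign
        out.at[b, a] = sign
    return out


@dataclass(frozen=True)
class PatternPair:
    pair: Pair
    pattern: str  # opposite_under_treatment | corrected_toward_wildtype
    r: tuple[float, ...]  # per group, study order
    p: tuple[float, ...]

    @property
    def groups(self) -> tuple[str, ...]:
        return GROUPS


def _annotate(mats: CorrelationMatrixSet, pair: Pair, pattern: str) -> PatternPair:
    rs, ps = [], []
    for g in GROUPS:
        r, p = mats.pair(g, pair)
        rs.append(r)
        ps.append(p)
    return PatternPair(pair=pair, pattern=pattern, r=tuple(rs), p=tuple(ps))


def find_opposite_treatment_pairs(
    mats: CorrelationMatrixSet, alpha: float = 0.05
) -> set[PatternPair]:
    """Pairs whose correlation flips sign under treatment.

    Dual-significant in the (disease, treated) comparison with opposite r
    signs, and absent from the wildtype-disease dual-significant set (the
    pattern is treatment-specific, not part of the disease phenotype).
    """
    for g in GROUPS:
        if g not in mats.r:
            raise KeyError(f"group {g!r} missing from correlation set")
    wt_dis = shared_significant_pairs(mats, ("wildtype", "disease"), alpha)
    out: set[PatternPair] = set()
    for pair in shared_significant_pairs(mats, ("disease", "disease_treated"), alpha):
        r_dis, _ = mats.pair("disease", pair)
        r_trt, _ = mats.pair("disease_treated", pair)
        if np.sign(r_dis) != np.sign(r_trt) and pair not in wt_dis:
            out.add(_annotate(mats, pair, "opposite_under_treatment"))
    return out


def find_corrected_pairs(
    mats: CorrelationMatrixSet, alpha: float = 0.05
) -> set[PatternPair]:
    """Pairs whose disease-flipped correlation is restored by treatment.

    Dual-significant with opposite signs in (wildtype, disease), and
    dual-significant in (disease, treated) with the treated sign equal
    to the wildtype sign.
    """
    for g in GROUPS:
        if g not in mats.r:
            raise KeyError(f"group {g!r} missing from correlation set")
    dis_trt = shared_significant_pairs(mats, ("disease", "disease_treated"), alpha)
    out: set[PatternPair] = set()
    for pair in shared_significant_pairs(mats, ("wildtype", "disease"), alpha):
        r_wt, _ = mats.pair("wildtype", pair)
        r_dis, _ = mats.pair("disease", pair)
        if np.sign(r_wt) == np.sign(r_dis) or pair not in dis_trt:
            continue
        r_trt, _ = mats.pair("disease_treated", pair)
        if np.sign(r_trt) == np.sign(r_wt):
            out.add(_annotate(mats, pair, "corrected_toward_wildtype"))
    return out


def pattern_pairs_frame(pairs: set[PatternPair]) -> pd.DataFrame:
    """Tabular export: one row per pattern pair with per-group r and p."""
    rows = []
    for pp in sorted(pairs, key=lambda x: (x.pattern, x.pair)):
        row: dict[str, object] = {
            "metabolite_a": pp.pair[0],
            "metabolite_b": pp.pair[1],
            "pattern": pp.pattern,
        }
        for g, r, p in zip(GROUPS, pp.r, pp.p):
            row[f"r_{g}"] = r
            row[f"p_{g}"] = p
        rows.append(row)
    cols = ["metabolite_a", "metabolite_b", "pattern"] + [
        f"{k}_{g}" for g in GROUPS for k in ("r", "p")
    ]
    return pd.DataFrame(rows, columns=cols)
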