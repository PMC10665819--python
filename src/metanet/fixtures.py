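"""Shipped fixtures: printed concentration tables and DE-count tables.

``table1_long_treatment.tsv`` and ``table2_short_treatment.tsv`` are
transcriptions of the published kidney metabolite concentration tables
(mean, SD and significance marks per group; ug/mg dry insoluble
pellet). The long-treatment table is stored exactly as printed, which
disagrees with the accompanying text in two places (32 starred
metabolites vs. "31", 11 hash marks vs. "12"); the discrepancy is kept,
not resolved.

The DE fixtures are synthetic gene-statistics tables built to carry the
published selection counts (81 FDR-significant genes, 35 up / 46 down,
in the treated-vs-disease comparison; 184 under the combined
FDR-or-fold-change rule, 55 up / 129 down; 58 of the 81 shared with the
disease-vs-wildtype comparison, 74% of those corrected in direction).
The p and FDR columns are internally consistent (FDR is the
Benjamini-Hochberg adjustment of p), so the counts are *recomputed*
from the raw columns by the selection rule, never stored.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reporter import GeneStatTable

__all__ = [
    "load_printed_table",
    "printed_mark_counts",
    "make_de_gene_tables",
]

_PRINTED = {
    "long": "table1_long_treatment.tsv",
    "short": "table2_short_treatment.tsv",
}


def load_printed_table(study: str) -> pd.DataFrame:
    """Load a printed concentration table ('long' or 'short' study)."""
    try:
        fname = _PRINTED[study]
    except KeyError:
        raise KeyError(f"study must be one of {sorted(_PRINTED)}") from None
    ref = resources.files("metanet") / "data" / fname
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False,
                         dtype={c: str for c in (
                             "disease_vs_wildtype_mark",
                             "treated_vs_wildtype_mark",
                             "treated_vs_disease_mark")})
    return df.set_index("metabolite")


def printed_mark_counts(table: pd.DataFrame) -> dict[str, int]:
    """Number of metabolites flagged per comparison by the printed marks."""
    return {
        "disease_vs_wildtype": int((table["disease_vs_wildtype_mark"] != "").sum()),
        "treated_vs_wildtype": int((table["treated_vs_wildtype_mark"] != "").sum()),
        "treated_vs_disease": int((table["treated_vs_disease_mark"] != "").sum()),
    }


def _bh(p: np.ndarray) -> np.ndarray:
    return sps.false_discovery_control(p, method="bh")


def make_de_gene_tables(seed: int = 0) -> tuple[GeneStatTable, GeneStatTable]:
    """Build the two DE fixture tables (treated-vs-disease, disease-vs-wildtype).

    The treated-vs-disease table has, by construction of its raw p and
    log2FC columns: 81 genes at BH-FDR < 0.05 (35 with positive, 46 with
    negative fold change) and 184 genes under FDR < 0.05 or |log2FC| >
    0.5 (55 up, 129 down). The disease-vs-wildtype table shares exactly
    58 of the 81 FDR-significant gene ids, 43 of which (74%) have a
    disease direction opposite to their treatment direction (i.e. the
    treatment moves them back toward wildtype).
    """
    rng = np.random.default_rng(seed)
    n_genes = 2000
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]

    # Treatment comparison: blocks of gene indices by construction.
    n_up_fdr, n_down_fdr = 35, 46  # FDR-significant
    n_up_fold, n_down_fold = 20, 83  # fold-change-only additions -> 55/129
    p = rng.uniform(0.3, 1.0, size=n_genes)
    lfc = rng.uniform(-0.45, 0.45, size=n_genes)
    blocks = {
        "up_fdr": slice(0, n_up_fdr),
        "down_fdr": slice(n_up_fdr, n_up_fdr + n_down_fdr),
        "up_fold": slice(81, 81 + n_up_fold),
        "down_fold": slice(101, 101 + n_down_fold),
    }
    n_sig = n_up_fdr + n_down_fdr
    # All signal p below the BH cut p_(81) <= 81/2000 * 0.05; nulls >= 0.3.
    p[blocks["up_fdr"]] = rng.uniform(1e-6, 1e-3, size=n_up_fdr)
    p[blocks["down_fdr"]] = rng.uniform(1e-6, 1e-3, size=n_down_fdr)
    lfc[blocks["up_fdr"]] = rng.uniform(0.6, 3.0, size=n_up_fdr)
    lfc[blocks["down_fdr"]] = -rng.uniform(0.6, 3.0, size=n_down_fdr)
    lfc[blocks["up_fold"]] = rng.uniform(0.55, 1.5, size=n_up_fold)
    lfc[blocks["down_fold"]] = -rng.uniform(0.55, 1.5, size=n_down_fold)
    treated = pd.DataFrame(
        {"p": p, "log2fc": lfc, "fdr": _bh(p)},
        index=pd.Index(genes, name="gene"),
    )

    # Disease comparison: 58 of the 81 treatment-significant ids are also
    # disease-significant; 43 of those corrected (opposite direction).
    sig_ids = np.arange(n_sig)
    shared = rng.choice(sig_ids, size=58, replace=False)
    corrected = shared[:43]
    p2 = rng.uniform(0.3, 1.0, size=n_genes)
    lfc2 = rng.uniform(-0.45, 0.45, size=n_genes)
    extra = rng.choice(np.arange(300, n_genes), size=400, replace=False)
    for idx in (*shared, *extra):
        p2[idx] = rng.uniform(1e-6, 2e-3)
    # Keep BH monotone: 458 smallest p all below 458/2000*0.05 = 0.01145.
    for idx in shared:
        direction = -np.sign(lfc[idx]) if idx in corrected else np.sign(lfc[idx])
        lfc2[idx] = direction * rng.uniform(0.6, 3.0)
    lfc2[extra] = rng.choice([-1, 1], size=extra.size) * rng.uniform(
        0.6, 3.0, size=extra.size
    )
    disease = pd.DataFrame(
        {"p": p2, "log2fc": lfc2, "fdr": _bh(p2)},
        index=pd.Index(genes, name="gene"),
    )
    return GeneStatTable(treated), GeneStatTable(disease)
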