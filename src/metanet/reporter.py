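"""Reporter-metabolite scoring of substrate-product ratios.

Transcript-level evidence is aggregated onto the metabolite ratios
(substrate-product pairs) whose reactions the transcripts' enzymes
catalyze. Gene influence is weighted in three steps (unit weights,
division by the ratio's gene count, division by each gene's maximum
weight), gene p-values are replaced by their rank-based inverse-uniform
transform, and each ratio is scored with the weighted Fisher statistic

    X_i = -sum_j w_ij * ln(p_j)

tested against a per-ratio simulated null (i.i.d. Uniform(0,1) draws,
N = 100000 by default, upper tail). Metabolites of ratios with an
estimated p < 0.05 are promoted into the path analysis.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import MetabolicModel
from .network import all_pairs

__all__ = [
    "GeneStatTable",
    "ReporterRatio",
    "ReporterResult",
    "read_gene_stats",
    "build_ratio_gene_map",
    "compute_weights",
    "rank_inverse_uniform",
    "weighted_fisher",
    "simulate_null_and_test",
    "score_ratios",
    "select_reporter_metabolites",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SIM = 100_000


@dataclass
class GeneStatTable:
    """Gene-level differential-expression statistics.

    ``table`` is indexed by unique gene id with columns ``p``,
    ``log2fc``, ``fdr`` and, after the rank transform, ``p_transformed``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"p", "log2fc", "fdr"} - set(self.table.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        p = self.table["p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def transformed(self) -> "GeneStatTable":
        out = self.table.copy()
        out["p_transformed"] = rank_inverse_uniform(out["p"].to_numpy())
        return GeneStatTable(out)


def read_gene_stats(path, sep: str = "\t") -> GeneStatTable:
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    df = df.set_index("gene")
    return GeneStatTable(df)


def ratio_id(met_a: str, met_b: str) -> str:
    a, b = sorted((met_a, met_b))
    return f"{a}~{b}"


@dataclass(frozen=True)
class ReporterRatio:
    """A substrate-product metabolite pair with its attached genes."""

    id: str
    metabolites: tuple[str, str]
    genes: tuple[str, ...]
    weights: tuple[float, ...] = ()  # parallel to genes; set by compute_weights

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def build_ratio_gene_map(model: MetabolicModel) -> list[ReporterRatio]:
    """One ratio per distinct unordered substrate-product pair of the model.

    The gene set of a ratio is the union of the gene associations of all
    reactions contributing that pair. Ratios whose contributing reactions
    carry no gene associations (e.g. diffusion transporters) cannot be
    scored and are excluded with a log entry.
    """
    genes_by_pair: dict[str, set[str]] = {}
    mets_by_pair: dict[str, tuple[str, str]] = {}
    for pr in all_pairs(model):
        rid = ratio_id(pr.substrate, pr.product)
        mets_by_pair[rid] = tuple(sorted((pr.substrate, pr.product)))
        genes_by_pair.setdefault(rid, set()).update(
            model.reactions[pr.reaction].genes
        )
    ratios = []
    for rid in sorted(genes_by_pair):
        genes = genes_by_pair[rid]
        if not genes:
            logger.info("ratio %s has no gene associations; excluded", rid)
            continue
        ratios.append(
            ReporterRatio(id=rid, metabolites=mets_by_pair[rid],
                          genes=tuple(sorted(genes)))
        )
    return ratios


def compute_weights(ratios: list[ReporterRatio]) -> list[ReporterRatio]:
    """Three-step weight normalization.

    Step 1 sets every gene-ratio weight to one; step 2 divides by the
    ratio's gene count (spreading a promiscuous ratio's evidence); step 3
    divides each gene's weights by that gene's maximum weight across
    ratios, so every gene has full influence (weight 1) somewhere.
    """
    w = {r.id: {g: 1.0 / r.n_genes for g in r.genes} for r in ratios}
    gene_max: dict[str, float] = {}
    for rw in w.values():
        for g, v in rw.items():
            gene_max[g] = max(gene_max.get(g, 0.0), v)
    return [
        replace(
            r,
            weights=tuple(w[r.id][g] / gene_max[g] for g in r.genes),
        )
        for r in ratios
    ]


def rank_inverse_uniform(p_values: np.ndarray) -> np.ndarray:
    """Replace p-values by rank/(N+1), average ranks on ties.

    Forces an exactly uniform marginal over the grid {1, ..., N}/(N+1)
    under any continuous null, and output is strictly inside (0, 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    return sps.rankdata(p, method="average") / (p.size + 1)


def weighted_fisher(ratio: ReporterRatio, genes: GeneStatTable) -> float:
    """X_i = -sum_j w_ij ln(p_j) over the ratio's genes (natural log)."""
    if len(ratio.weights) != ratio.n_genes:
        raise ValueError(f"ratio {ratio.id} has no weights; run compute_weights")
    if "p_transformed" not in genes.table.columns:
        raise ValueError("gene table lacks transformed p-values")
    missing = [g for g in ratio.genes if g not in genes.table.index]
    if missing:
        raise KeyError(f"genes {missing} of ratio {ratio.id} missing from table")
    p = genes.table.loc[list(ratio.genes), "p_transformed"].to_numpy()
    return float(-(np.asarray(ratio.weights) * np.log(p)).sum())


@dataclass(frozen=True)
class ReporterResult:
    ratio: ReporterRatio
    x_obs: float
    n_sim: int
    p_hat: float
    seed: int

    @property
    def significant(self) -> bool:
        return self.p_hat < 0.05


def simulate_null_and_test(
    ratio: ReporterRatio,
    x_obs: float,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> ReporterResult:
    """Estimate the upper-tail p of ``x_obs`` against a simulated null.

    The null draws n_sim statistics X* = -sum_j w_ij ln(U_j) with
    U_j ~ Uniform(0,1) i.i.d. (the rank transform makes the marginal
    null uniform), using the ratio's own weights. The add-one estimator
    p = (#{X* >= x_obs} + 1)/(n_sim + 1) keeps p inside
    [1/(n_sim+1), 1].
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    w = np.asarray(ratio.weights)
    u = rng.random((n_sim, w.size))
    null = -(np.log(u) @ w)
    p_hat = (int((null >= x_obs).sum()) + 1) / (n_sim + 1)
    return ReporterResult(ratio=ratio, x_obs=x_obs, n_sim=n_sim,
                          p_hat=p_hat, seed=seed)


def score_ratios(
    ratios: list[ReporterRatio],
    genes: GeneStatTable,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> list[ReporterResult]:
    """Weight, transform, score and null-test every ratio.

    Each ratio gets an independent RNG stream keyed on (seed, ratio id),
    so results do not depend on scoring order or on which other ratios
    are present.
    """
    weighted = compute_weights(ratios)
    transformed = genes.transformed()
    out = []
    for ratio in weighted:
        x = weighted_fisher(ratio, transformed)
        rng = np.random.default_rng([seed, zlib.crc32(ratio.id.encode())])
        w = np.asarray(ratio.weights)
        null = -(np.log(rng.random((n_sim, w.size))) @ w)
        p_hat = (int((null >= x).sum()) + 1) / (n_sim + 1)
        out.append(
            ReporterResult(ratio=ratio, x_obs=x, n_sim=n_sim,
                           p_hat=p_hat, seed=seed)
        )
    return out


def select_reporter_metabolites(
    results: list[ReporterResult], alpha: float = 0.05
) -> set[str]:
    """Union of both metabolites of every ratio with estimated p < alpha."""
    out: set[str] = set()
    for res in results:
        if res.p_hat < alpha:
            out.update(res.ratio.metabolites)
    return out


def results_frame(results: list[ReporterResult]) -> pd.DataFrame:
    rows = [
        {
            "ratio": r.ratio.id,
            "metabolite_a": r.ratio.metabolites[0],
            "metabolite_b": r.ratio.metabolites[1],
            "n_genes": r.ratio.n_genes,
            "X": r.x_obs,
            "p_hat": r.p_hat,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["ratio", "metabolite_a", "metabolite_b", "n_genes", "X",
                 "p_hat", "significant"],
    )
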