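"""End-to-end orchestration of the multi-omics integration pipeline.

Stage order: (optional) unit conversion -> PQN -> univariate screens ->
PCA -> correlation patterns -> DE gene selection -> reporter scoring ->
path network -> subnetwork filter -> exports. Every stage's output is
persisted to the output directory and a machine-readable run report
(record counts, warnings, seeds, config echo) is always emitted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .correlations import (
    find_corrected_pairs,
    find_opposite_treatment_pairs,
    groupwise_pearson,
    pattern_pairs_frame,
)
from .model import load_model, map_measured_metabolites
from .network import build_network, export_graph, filter_subnetworks
from .reporter import (
    GeneStatTable,
    build_ratio_gene_map,
    read_gene_stats,
    results_frame,
    score_ratios,
    select_reporter_metabolites,
)
from .stats import MetaboliteTable, pca_scores, pqn_normalize, univariate_screen

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DeSelection", "select_de_genes", "run_pipeline"]

#: Ordered univariate comparisons run by the pipeline (numerator, denominator).
COMPARISONS = (
    ("disease", "wildtype"),
    ("disease_treated", "wildtype"),
    ("disease_treated", "disease"),
)


@dataclass
class PipelineConfig:
    metabolite_table: str
    gene_table: str
    model: str
    out_dir: str
    alpha_metabolite: float = 0.05
    alpha_correlation: float = 0.05
    alpha_reporter: float = 0.05
    fdr_cut: float = 0.05
    lfc_cut: float = 0.5
    n_sim: int = 100_000
    seed: int = 0
    bridges: tuple[str, ...] = ()
    pqn_reference: str = "all-samples"
    min_significant: int = 3

    def __post_init__(self) -> None:
        for a in (self.alpha_metabolite, self.alpha_correlation,
                  self.alpha_reporter, self.fdr_cut):
            if not (0 < a < 1):
                raise ValueError("alpha/FDR levels must be in (0, 1)")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "bridges" in doc:
            doc["bridges"] = tuple(doc["bridges"])
        return cls(**doc)


@dataclass
class DeSelection:
    """Differentially expressed genes partitioned by fold-change sign."""

    up: frozenset[str]
    down: frozenset[str]
    zero: frozenset[str] = frozenset()  # selected genes with log2FC == 0

    @property
    def selected(self) -> frozenset[str]:
        return self.up | self.down | self.zero

    @property
    def total(self) -> int:
        return len(self.selected)


def select_de_genes(
    genes: GeneStatTable,
    fdr_cut: float = 0.05,
    lfc_cut: float | None = 0.5,
) -> DeSelection:
    """Select DE genes by FDR < fdr_cut OR |log2FC| > lfc_cut (union rule).

    The combined rule reads as the union because the published totals
    only reconcile that way (81 FDR-significant genes plus the
    fold-change-only genes giving 184 overall). Pass ``lfc_cut=None``
    for a pure FDR selection. Selected genes with exactly zero fold
    change are reported in their own partition rather than silently
    assigned a direction.
    """
    t = genes.table
    mask = t["fdr"] < fdr_cut
    if lfc_cut is not None:
        mask |= t["log2fc"].abs() > lfc_cut
    sel = t.loc[mask]
    return DeSelection(
        up=frozenset(sel.index[sel["log2fc"] > 0]),
        down=frozenset(sel.index[sel["log2fc"] < 0]),
        zero=frozenset(sel.index[sel["log2fc"] == 0]),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk).

    Any stage failure aborts with the failing stage named, after writing
    the partial run report.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    stage = "setup"

    def record(name: str, **counts) -> None:
        report["stages"][name] = counts
        logger.info("stage=%s %s", name,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "load"
            table = MetaboliteTable.read_csv(cfg.metabolite_table)
            genes = read_gene_stats(cfg.gene_table)
            model = load_model(cfg.model)
            record("load", samples=len(table.data),
                   metabolites=len(table.metabolites),
                   genes=len(genes.genes), reactions=len(model.reactions))

            stage = "pqn"
            normalized = pqn_normalize(table, reference=cfg.pqn_reference)
            normalized.to_csv(out / "normalized_table.tsv")
            record("pqn", samples=len(normalized.data))

            stage = "univariate"
            frames = []
            significant_mets: set[str] = set()
            for comparison in COMPARISONS:
                res = univariate_screen(normalized, comparison,
                                        alpha=cfg.alpha_metabolite)
                frame = res.table.reset_index()
                frame.insert(1, "comparison", "{}_vs_{}".format(*comparison))
                frames.append(frame)
                significant_mets |= set(res.significant)
            univariate = pd.concat(frames, ignore_index=True)
            univariate.to_csv(out / "univariate.tsv", sep="\t", index=False)
            record("univariate", tests=len(univariate),
                   significant_metabolites=len(significant_mets))

            stage = "pca"
            pca = pca_scores(normalized, k=2)
            pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            record("pca", components=pca.scores.shape[1],
                   cumulative_first_two_percent=round(
                       pca.cumulative_first_two_percent, 2))

            stage = "patterns"
            mats = groupwise_pearson(normalized)
            patterns = find_opposite_treatment_pairs(
                mats, alpha=cfg.alpha_correlation
            ) | find_corrected_pairs(mats, alpha=cfg.alpha_correlation)
            pattern_pairs_frame(patterns).to_csv(
                out / "pattern_pairs.tsv", sep="\t", index=False)
            record("patterns", pattern_pairs=len(patterns))

            stage = "de_selection"
            de = select_de_genes(genes, fdr_cut=cfg.fdr_cut, lfc_cut=cfg.lfc_cut)
            record("de_selection", up=len(de.up), down=len(de.down),
                   total=de.total)

            stage = "reporter"
            ratios = build_ratio_gene_map(model)
            scorable = [
                r for r in ratios
                if all(g in genes.table.index for g in r.genes)
            ]
            results = score_ratios(scorable, genes, n_sim=cfg.n_sim,
                                   seed=cfg.seed)
            results_frame(results).to_csv(
                out / "reporter_ratios.tsv", sep="\t", index=False)
            reporter_mets = select_reporter_metabolites(
                results, alpha=cfg.alpha_reporter)
            record("reporter", ratios=len(scorable),
                   significant=sum(r.significant for r in results),
                   reporter_metabolites=len(reporter_mets))

            stage = "network"
            mapping = map_measured_metabolites(normalized.metabolites, model)
            measured_ids = set(mapping.matched_ids)
            gene_ann = {
                g: {"p": float(genes.table.at[g, "p"]),
                    "fdr": float(genes.table.at[g, "fdr"]),
                    "log2fc": float(genes.table.at[g, "log2fc"]),
                    "de_selected": g in de.selected}
                for g in genes.table.index
            }
            met_ann = {}
            for name, ids in mapping.matched.items():
                for mid in ids:
                    met_ann[mid] = {
                        "measured_name": name,
                        "significant": name in significant_mets,
                    }
            net = build_network(
                measured=measured_ids,
                bridges=[b for b in cfg.bridges if b in model.metabolites],
                model=model,
                gene_annotations=gene_ann,
                metabolite_annotations=met_ann,
                reporter_metabolites=reporter_mets,
            )
            record("network", nodes=net.number_of_nodes(),
                   edges=net.number_of_edges(),
                   unmatched_metabolites=len(mapping.unmatched))

            stage = "filter"
            significant_nodes = {
                n for n, d in net.nodes(data=True)
                if (d["kind"] == "metabolite" and d.get("significant"))
                or (d["kind"] == "gene" and d.get("de_selected"))
            }
            filtered = filter_subnetworks(net, significant_nodes)
            record("filter", nodes=filtered.number_of_nodes(),
                   edges=filtered.number_of_edges())

            stage = "export"
            export_graph(net, out / "network_full.json")
            export_graph(filtered, out / "network_filtered.json")
            export_graph(filtered, out / "network_filtered.graphml",
                         fmt="graphml")
            record("export", files=3)

        report["warnings"] = sorted({str(w.message) for w in caught})
        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "error"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "run_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
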