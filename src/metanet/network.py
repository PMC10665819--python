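"""Substrate-product pair extraction and constrained path finding.

Reactions are decomposed into half-reactions (the redox, amino- or
phosphate-transfer couples declared in the model) and metabolites are
linked only *within* a half-reaction, only when both members carry
carbon (or form a registered cofactor couple) and neither is a hub.
Transporter steps and the producing half-reactions of uniquely-produced
metabolites carry weight zero; all other steps weigh one. Biochemical
paths of total weight one or two are then enumerated between measured
metabolites, honouring irreversibility, and assembled into an annotated
network whose small subnetworks are filtered out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .model import MetabolicModel, Reaction

__all__ = [
    "SubstrateProductPair",
    "ReactionPath",
    "extract_pairs",
    "all_pairs",
    "find_paths",
    "build_network",
    "filter_subnetworks",
    "export_graph",
    "load_graph",
]

#: Cap on consecutive zero-weight steps (transporters chain at most
#: cytosol <-> organelle <-> extracellular in practice).
MAX_ZERO_RUN = 2


@dataclass(frozen=True)
class SubstrateProductPair:
    reaction: str
    substrate: str
    product: str
    weight: int  # 0 (transporter / uniquely-produced half) or 1
    forward_only: bool


def extract_pairs(
    reaction: Reaction, model: MetabolicModel
) -> set[SubstrateProductPair]:
    """Linkable substrate-product couples of one reaction.

    Within each half-reaction, substrate ``s`` links product ``p`` iff
    both carry carbon and neither is a hub, or ``(s, p)`` is a registered
    cofactor couple. Pairs of transporter reactions and of half-reactions
    producing a uniquely-produced metabolite get weight 0.
    """
    out: set[SubstrateProductPair] = set()
    for subs, prods in model.half_reaction_partition(reaction):
        half_weight = 0 if (
            reaction.transporter
            or any(p in model.uniquely_produced for p in prods)
        ) else 1
        for s in subs:
            for p in prods:
                if model.is_cofactor_couple(s, p) or (
                    model.carbons(s) > 0
                    and model.carbons(p) > 0
                    and not model.is_hub(s)
                    and not model.is_hub(p)
                ):
                    out.add(
                        SubstrateProductPair(
                            reaction=reaction.id,
                            substrate=s,
                            product=p,
                            weight=half_weight,
                            forward_only=not reaction.reversible,
                        )
                    )
    return out


def all_pairs(model: MetabolicModel) -> set[SubstrateProductPair]:
    pairs: set[SubstrateProductPair] = set()
    for rxn in model.reactions.values():
        pairs |= extract_pairs(rxn, model)
    return pairs


@dataclass(frozen=True)
class ReactionPath:
    """A directed chain of pair steps between two endpoint metabolites."""

    steps: tuple[SubstrateProductPair, ...]
    metabolites: tuple[str, ...]  # len(steps) + 1, endpoints included

    @property
    def cost(self) -> int:
        return sum(s.weight for s in self.steps)

    @property
    def reactions(self) -> tuple[str, ...]:
        return tuple(s.reaction for s in self.steps)

    @property
    def endpoints(self) -> tuple[str, str]:
        return self.metabolites[0], self.metabolites[-1]


def _directed_edges(
    pairs: Iterable[SubstrateProductPair],
) -> dict[str, list[tuple[str, SubstrateProductPair]]]:
    adj: dict[str, list[tuple[str, SubstrateProductPair]]] = {}
    for pr in pairs:
        adj.setdefault(pr.substrate, []).append((pr.product, pr))
        if not pr.forward_only:
            adj.setdefault(pr.product, []).append((pr.substrate, pr))
    return adj


def find_paths(
    a: str,
    b: str,
    model: MetabolicModel,
    max_cost: int = 2,
    pairs: set[SubstrateProductPair] | None = None,
) -> set[ReactionPath]:
    """All simple paths from ``a`` to ``b`` with total weight in [1, max_cost].

    Steps chain product -> substrate on compartment-qualified ids (so
    compartment compatibility is implicit; transporters are the only
    cross-compartment steps). Irreversible reactions are traversed
    forward only. Zero-weight steps do not count toward the cost but at
    most ``MAX_ZERO_RUN`` may occur consecutively.
    """
    if a == b:
        raise ValueError("endpoints must differ")
    for mid in (a, b):
        if mid not in model.metabolites:
            raise KeyError(f"metabolite {mid} not in model")
    adj = _directed_edges(all_pairs(model) if pairs is None else pairs)
    found: set[ReactionPath] = set()

    def dfs(
        node: str,
        visited: tuple[str, ...],
        steps: tuple[SubstrateProductPair, ...],
        cost: int,
        zero_run: int,
    ) -> None:
        if node == b and steps and cost >= 1:
            found.add(ReactionPath(steps=steps, metabolites=visited))
            return  # simple paths cannot be extended through b again anyway
        for nxt, pr in adj.get(node, ()):
            if nxt in visited:
                continue
            ncost = cost + pr.weight
            if ncost > max_cost:
                continue
            nzero = zero_run + 1 if pr.weight == 0 else 0
            if nzero > MAX_ZERO_RUN:
                continue
            dfs(nxt, visited + (nxt,), steps + (pr,), ncost, nzero)

    dfs(a, (a,), (), 0, 0)
    return found


def build_network(
    measured: Iterable[str],
    bridges: Iterable[str],
    model: MetabolicModel,
    gene_annotations: Mapping[str, Mapping[str, float]] | None = None,
    metabolite_annotations: Mapping[str, Mapping[str, float]] | None = None,
    reporter_metabolites: Iterable[str] = (),
    max_cost: int = 2,
) -> nx.Graph:
    """Assemble the annotated metabolite network.

    Nodes are the measured metabolites, declared bridge metabolites
    (unmeasured intermediates added to prevent gaps in classic
    pathways), reporter-selected metabolites, and the genes of every
    reaction participating in a retained path. An edge joins two
    metabolite nodes when at least one path of weight <= ``max_cost``
    connects them; each gene node is attached to the endpoints of the
    paths its reactions serve. Connected components are labelled on the
    result (node attribute ``component``).
    """
    measured = set(measured)
    if not measured:
        raise ValueError("measured metabolite set is empty")
    bridges = set(bridges)
    reporter_metabolites = set(reporter_metabolites)
    nodes = measured | bridges | reporter_metabolites
    for mid in nodes:
        if mid not in model.metabolites:
            raise KeyError(f"network node {mid} not in model")

    pairs = all_pairs(model)
    g = nx.Graph()
    for mid in sorted(nodes):
        roles = []
        if mid in measured:
            roles.append("measured")
        if mid in bridges:
            roles.append("bridge")
        if mid in reporter_metabolites:
            roles.append("reporter")
        attrs = dict((metabolite_annotations or {}).get(mid, {}))
        g.add_node(mid, kind="metabolite", roles=roles, **attrs)

    for a, b in combinations(sorted(nodes), 2):
        paths = find_paths(a, b, model, max_cost=max_cost, pairs=pairs)
        if not paths:
            continue
        payload = [
            {
                "reactions": list(p.reactions),
                "metabolites": list(p.metabolites),
                "cost": p.cost,
            }
            for p in sorted(paths, key=lambda p: (p.cost, p.reactions))
        ]
        g.add_edge(a, b, kind="path", paths=payload,
                   cost=min(p.cost for p in paths))
        for p in sorted(paths, key=lambda p: (p.cost, p.reactions)):
            for rid in p.reactions:
                for gene in model.reactions[rid].genes:
                    if gene not in g:
                        attrs = dict((gene_annotations or {}).get(gene, {}))
                        g.add_node(gene, kind="gene", roles=["gene"], **attrs)
                    for endpoint in (a, b):
                        if not g.has_edge(gene, endpoint):
                            g.add_edge(gene, endpoint, kind="catalyzes",
                                       reactions=[])
                        if rid not in g.edges[gene, endpoint]["reactions"]:
                            g.edges[gene, endpoint]["reactions"].append(rid)

    _label_components(g)
    return g


def _label_components(g: nx.Graph) -> None:
    for i, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        for node in comp:
            g.nodes[node]["component"] = i


def filter_subnetworks(g: nx.Graph, significant: Iterable[str]) -> nx.Graph:
    """Drop connected components with two or fewer significant members.

    ``significant`` is the set of nodes (genes and metabolites counted
    together) considered significant; components retaining three or more
    of them are kept whole, non-significant members included. Never
    splits a component and is idempotent.
    """
    significant = set(significant)
    unknown = significant - set(g.nodes)
    if unknown:
        raise KeyError(f"significant nodes not in network: {sorted(unknown)}")
    keep: set[str] = set()
    for comp in nx.connected_components(g):
        if len(comp & significant) > 2:
            keep |= comp
    out = g.subgraph(keep).copy()
    _label_components(out)
    return out


def export_graph(g: nx.Graph, path: str | Path, fmt: str = "json") -> None:
    """Write the network as node-link JSON (default) or GraphML.

    GraphML only carries scalar attributes, so list/dict annotations are
    JSON-encoded into strings for that format.
    """
    path = Path(path)
    if fmt == "json":
        payload = nx.node_link_data(g, edges="edges")
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif fmt == "graphml":
        flat = g.copy()
        for _, attrs in flat.nodes(data=True):
            for k, v in attrs.items():
                if isinstance(v, (list, dict)):
                    attrs[k] = json.dumps(v)
        for _, _, attrs in flat.edges(data=True):
            for k, v in attrs.items():
                if isinstance(v, (list, dict)):
                    attrs[k] = json.dumps(v)
        nx.write_graphml(flat, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def load_graph(path: str | Path) -> nx.Graph:
    doc = json.loads(Path(path).read_text())
    return nx.node_link_graph(doc, edges="edges")
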