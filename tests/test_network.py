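"""Pair extraction, constrained path finding, assembly and filtering."""

import itertools

import networkx as nx
import pytest

from metanet.model import MetabolicModel, Metabolite, Reaction
from metanet.network import (
    all_pairs,
    build_network,
    export_graph,
    extract_pairs,
    filter_subnetworks,
    find_paths,
    load_graph,
)
from metanet.synthetic import enumerate_paths_bruteforce, make_toy_model


def _met(mid, name, formula, compartment="c", hub=False):
    return Metabolite(mid, name, compartment, formula, is_hub=hub)


def _ldh_model(extra_reactions=(), hubs=frozenset(), **met_overrides):
    mets = {
        "pyr_c": _met("pyr_c", "pyruvate", "C3H3O3"),
        "lac_c": _met("lac_c", "lactate", "C3H5O3"),
        "nad_c": _met("nad_c", "NAD", "C21H26N7O14P2"),
        "nadh_c": _met("nadh_c", "NADH", "C21H27N7O14P2"),
        "glu_c": _met("glu_c", "glutamate", "C5H8NO4"),
        "akg_c": _met("akg_c", "2-oxoglutarate", "C5H4O5"),
        "ala_c": _met("ala_c", "alanine", "C3H7NO2"),
        "h2o_c": _met("h2o_c", "water", "H2O", hub=True),
        "sam_c": _met("sam_c", "SAM", "C15H22N6O5S", hub=True),
    }
    mets.update(met_overrides)
    rxns = {
        "LDH": Reaction(
            "LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
            reversible=True, genes=("Ldha",),
            half_reactions=((("pyr_c",), ("lac_c",)), (("nadh_c",), ("nad_c",))),
        ),
        "ALT": Reaction(
            "ALT", {"glu_c": -1, "pyr_c": -1, "akg_c": 1, "ala_c": 1},
            reversible=True, genes=("Gpt",),
            half_reactions=((("glu_c",), ("akg_c",)), (("pyr_c",), ("ala_c",))),
        ),
    }
    for r in extra_reactions:
        rxns[r.id] = r
    return MetabolicModel(
        metabolites=mets, reactions=rxns,
        cofactor_pairs=frozenset({frozenset({"nad_c", "nadh_c"})}),
        hubs=hubs,
    )


class TestExtractPairs:
    def test_half_reaction_decoupling_ldh(self):
        # NADH + pyruvate <=> NAD+ + lactate: NADH links NAD+ and
        # pyruvate links lactate; no cross-half pair.
        model = _ldh_model()
        got = {
            (p.substrate, p.product)
            for p in extract_pairs(model.reactions["LDH"], model)
        }
        assert got == {("nadh_c", "nad_c"), ("pyr_c", "lac_c")}

    def test_transaminase_decoupling(self):
        # glutamate + pyruvate <=> AKG + alanine: glutamate-AKG and
        # pyruvate-alanine only.
        model = _ldh_model()
        got = {
            (p.substrate, p.product)
            for p in extract_pairs(model.reactions["ALT"], model)
        }
        assert got == {("glu_c", "akg_c"), ("pyr_c", "ala_c")}

    def test_carbon_free_product_yields_no_pair(self):
        rxn = Reaction(
            "DHY", {"lac_c": -1, "pyr_c": 1, "h2o_c": 1},
            reversible=False, genes=("X",),
            half_reactions=((("lac_c",), ("pyr_c", "h2o_c")),),
        )
        model = _ldh_model(extra_reactions=[rxn])
        got = {(p.substrate, p.product)
               for p in extract_pairs(model.reactions["DHY"], model)}
        assert got == {("lac_c", "pyr_c")}  # lac-h2o blocked by carbon rule

    def test_sam_never_linkable(self):
        rxn = Reaction(
            "MT", {"sam_c": -1, "glu_c": -1, "sah_c": 1, "ala_c": 1},
            reversible=False, genes=("Mt1",),
            half_reactions=((("sam_c",), ("sah_c",)), (("glu_c",), ("ala_c",))),
        )
        model = _ldh_model(
            extra_reactions=[rxn],
            sah_c=_met("sah_c", "SAH", "C14H20N6O5S"),
        )
        pairs = all_pairs(model)
        assert not any("sam_c" in (p.substrate, p.product) for p in pairs)

    def test_transporter_pairs_weight_zero(self):
        rxn = Reaction(
            "T1", {"pyr_e": -1, "pyr_c": 1},
            reversible=True, transporter=True,
            half_reactions=((("pyr_e",), ("pyr_c",)),),
        )
        model = _ldh_model(
            extra_reactions=[rxn],
            pyr_e=_met("pyr_e", "pyruvate", "C3H3O3", compartment="e"),
        )
        tp = [p for p in extract_pairs(model.reactions["T1"], model)]
        assert tp and all(p.weight == 0 for p in tp)

    def test_irreversible_pairs_forward_only(self):
        model = _ldh_model()
        rxn = Reaction(
            "IRR", {"lac_c": -1, "pyr_c": 1}, reversible=False, genes=("Y",),
            half_reactions=((("lac_c",), ("pyr_c",)),),
        )
        model2 = _ldh_model(extra_reactions=[rxn])
        got = extract_pairs(model2.reactions["IRR"], model2)
        assert all(p.forward_only for p in got)


class TestFindPaths:
    def _chain_model(self):
        mets = {
            "a_c": _met("a_c", "A", "C3H6O3"),
            "b_c": _met("b_c", "B", "C3H6O3"),
            "c_c": _met("c_c", "C", "C3H6O3"),
            "a_e": _met("a_e", "A", "C3H6O3", compartment="e"),
        }
        rxns = {
            "r1": Reaction("r1", {"a_c": -1, "b_c": 1}, reversible=True,
                           genes=("g1",), half_reactions=((("a_c",), ("b_c",)),)),
            "r2": Reaction("r2", {"b_c": -1, "c_c": 1}, reversible=True,
                           genes=("g2",), half_reactions=((("b_c",), ("c_c",)),)),
            "t1": Reaction("t1", {"a_e": -1, "a_c": 1}, reversible=True,
                           transporter=True,
                           half_reactions=((("a_e",), ("a_c",)),)),
            # second producer of b/c so the chain is not all weight-0
            "r3": Reaction("r3", {"c_c": -1, "b_c": 1}, reversible=False,
                           genes=("g3",), half_reactions=((("c_c",), ("b_c",)),)),
            "r4": Reaction("r4", {"b_c": -1, "a_c": 1}, reversible=False,
                           genes=("g4",), half_reactions=((("b_c",), ("a_c",)),)),
            "r5": Reaction("r5", {"a_c": -1, "c_c": 1}, reversible=False,
                           genes=("g5",), half_reactions=((("a_c",), ("c_c",)),)),
        }
        return MetabolicModel(metabolites=mets, reactions=rxns)

    def test_chain_costs(self):
        model = self._chain_model()
        ab = find_paths("a_c", "b_c", model)
        assert {p.reactions for p in ab if p.cost == 1} >= {("r1",)}
        ac = find_paths("a_c", "c_c", model)
        assert ("r1", "r2") in {p.reactions for p in ac}
        assert all(p.cost in (1, 2) for p in ac)

    def test_zero_weight_transporter_does_not_count(self):
        model = self._chain_model()
        paths = find_paths("a_e", "b_c", model)
        two_step = [p for p in paths if p.reactions == ("t1", "r1")]
        assert two_step and two_step[0].cost == 1

    def test_irreversible_not_traversed_backwards(self):
        model = self._chain_model()
        assert not any(
            p.reactions == ("r3",) for p in find_paths("b_c", "c_c", model)
        )

    def test_reversible_model_paths_are_symmetric(self):
        mets = {
            f"{x}_c": _met(f"{x}_c", x.upper(), "C4H8O4") for x in "abcd"
        }
        rxns = {
            f"r{i}": Reaction(
                f"r{i}", {s: -1, t: 1}, reversible=True, genes=(f"g{i}",),
                half_reactions=(((s,), (t,)),),
            )
            for i, (s, t) in enumerate(
                [("a_c", "b_c"), ("b_c", "c_c"), ("c_c", "d_c"),
                 ("a_c", "c_c"), ("b_c", "d_c"), ("d_c", "a_c")]
            )
        }
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        for a, b in itertools.combinations(mets, 2):
            fwd = {(p.reactions, p.metabolites) for p in find_paths(a, b, model)}
            rev = {
                (tuple(reversed(p.reactions)), tuple(reversed(p.metabolites)))
                for p in find_paths(b, a, model)
            }
            assert fwd == rev

    def test_matches_bruteforce_oracle_on_toy_models(self):
        for seed in range(8):
            model, truth = make_toy_model(seed, 6, 9)
            pairs = all_pairs(model)
            mets = sorted(model.metabolites)
            for a, b in itertools.permutations(mets, 2):
                mine = {
                    tuple(
                        (s.reaction, p.metabolites[i], p.metabolites[i + 1])
                        for i, s in enumerate(p.steps)
                    )
                    for p in find_paths(a, b, model, pairs=pairs)
                }
                oracle = enumerate_paths_bruteforce(
                    truth.model_oracle["pairs"], a, b
                )
                assert mine == oracle, (seed, a, b)


class TestNetworkAssembly:
    def test_bridge_metabolite_connects_components(self):
        mets = {
            "a_c": _met("a_c", "A", "C3H6O3"),
            "x_c": _met("x_c", "X", "C3H6O3"),
            "b_c": _met("b_c", "B", "C3H6O3"),
        }

        def conv(rid, s, t, rev=True):
            return Reaction(rid, {s: -1, t: 1}, reversible=rev,
                            genes=(f"g_{rid}",),
                            half_reactions=(((s,), (t,)),))

        # duplicate producers so no weight-0 degeneracy
        rxns = {r.id: r for r in [
            conv("r1", "a_c", "x_c"), conv("r1b", "a_c", "x_c"),
            conv("r2", "x_c", "b_c"), conv("r2b", "x_c", "b_c"),
            conv("r3", "b_c", "a_c"), conv("r3b", "b_c", "a_c"),
        ]}
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        # a and b joined only through x; at depth 1 without the bridge
        # (and ignoring the gene nodes of the direct a-b reactions) the
        # a<->b connection requires x as an explicit bridge node
        sparse = {k: v for k, v in rxns.items() if not k.startswith("r3")}
        model2 = MetabolicModel(metabolites=dict(mets), reactions=sparse)
        direct = build_network(["a_c", "b_c"], [], model2, max_cost=1)
        assert not nx.has_path(direct, "a_c", "b_c")
        with_bridge = build_network(["a_c", "b_c"], ["x_c"], model2, max_cost=1)
        assert nx.has_path(with_bridge, "a_c", "b_c")

    def test_empty_measured_rejected(self, toy_model):
        model, _ = toy_model
        with pytest.raises(ValueError):
            build_network([], [], model)

    def test_component_labels_match_networkx(self, toy_model):
        model, _ = toy_model
        measured = [m for m in model.metabolites if m.startswith("m")]
        net = build_network(measured, [], model)
        for comp in nx.connected_components(net):
            labels = {net.nodes[n]["component"] for n in comp}
            assert len(labels) == 1


class TestFilterSubnetworks:
    def _net(self, comps):
        g = nx.Graph()
        for i, (nodes, sig) in enumerate(comps):
            nx.add_path(g, nodes)
            for n in nodes:
                g.nodes[n]["kind"] = "metabolite"
                g.nodes[n]["significant"] = n in sig
        return g

    def test_small_components_dropped_boundary_at_three(self):
        g = self._net([
            (["a", "b", "c"], {"a", "b"}),       # 2 significant -> dropped
            (["d", "e", "f", "x"], {"d", "e", "f"}),  # 3 -> kept whole
        ])
        out = filter_subnetworks(g, {"a", "b", "d", "e", "f"})
        assert set(out.nodes) == {"d", "e", "f", "x"}

    def test_never_splits_and_idempotent(self):
        g = self._net([
            (["a", "b", "c", "d"], {"a", "b", "c"}),
            (["p", "q"], {"p"}),
        ])
        sig = {"a", "b", "c", "p"}
        once = filter_subnetworks(g, sig)
        twice = filter_subnetworks(once, sig & set(once.nodes))
        assert set(once.nodes) == set(twice.nodes) == {"a", "b", "c", "d"}

    def test_empty_network(self):
        out = filter_subnetworks(nx.Graph(), set())
        assert out.number_of_nodes() == 0


class TestExport:
    def test_round_trip_preserves_nodes_and_edges(self, tmp_path, toy_model):
        model, _ = toy_model
        measured = [m for m in model.metabolites if m.startswith("m")]
        net = build_network(measured, [], model)
        path = tmp_path / "net.json"
        export_graph(net, path)
        back = load_graph(path)
        assert set(back.nodes) == set(net.nodes)
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in net.edges
        }

    def test_graphml_export_readable(self, tmp_path, toy_model):
        model, _ = toy_model
        measured = [m for m in model.metabolites if m.startswith("m")]
        net = build_network(measured, [], model)
        path = tmp_path / "net.graphml"
        export_graph(net, path, fmt="graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == net.number_of_nodes()
        assert back.number_of_edges() == net.number_of_edges()
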