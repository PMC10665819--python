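"""Metabolic model container and JSON dialect I/O.

The model dialect is a small JSON document with four top-level keys:

``metabolites``
    list of objects: ``id``, ``name``, ``synonyms`` (list), ``chebi``
    (optional), ``compartment``, ``formula`` (Hill-style, e.g. ``C6H12O6``),
    ``is_hub`` (optional, default false).
``reactions``
    list of objects: ``id``, ``stoichiometry`` (metabolite id -> signed
    coefficient, negative = substrate), ``reversible``, ``transporter``,
    ``genes`` (list), ``half_reactions`` (optional list of
    ``[[substrate ids], [product ids]]`` couples partitioning the reaction).
``cofactor_pairs``
    list of two-element id lists; couples that are always linkable within
    their own half-reaction (e.g. a NAD+/NADH redox couple).
``hubs``
    list of metabolite ids that are never linkable (ubiquitous currency
    species such as water, protons or SAM).

Metabolite ids are compartment-qualified; transporter reactions are the
only cross-compartment edges.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelError",
    "load_model",
    "write_model",
    "parse_formula",
    "carbon_count",
    "normalize_name",
    "map_measured_metabolites",
    "MappingReport",
]


class ModelError(ValueError):
    """Raised when a model file violates the dialect schema."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into an element-count mapping."""
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"unparseable formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ModelError(f"unparseable formula {formula!r}")
    return counts


def carbon_count(formula: str) -> int:
    return parse_formula(formula).get("C", 0)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str = "c"
    formula: str = ""
    synonyms: tuple[str, ...] = ()
    chebi: str | None = None
    is_hub: bool = False

    @property
    def carbons(self) -> int:
        return carbon_count(self.formula)


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = True
    transporter: bool = False
    genes: tuple[str, ...] = ()
    # Forward-orientation couples: ((substrate ids), (product ids)) per
    # half-reaction. Empty means "not declared" (a fallback is derived).
    half_reactions: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = ()

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    cofactor_pairs: frozenset[frozenset[str]] = field(default_factory=frozenset)
    hubs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.validate()
        self.uniquely_produced = self._compute_uniquely_produced()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite {mid}"
                    )
            if not rxn.substrates or not rxn.products:
                raise ModelError(f"reaction {rxn.id} has an empty side")
            if rxn.transporter:
                sub_names = {self.metabolites[m].name for m in rxn.substrates}
                prod_names = {self.metabolites[m].name for m in rxn.products}
                if sub_names != prod_names:
                    raise ModelError(
                        f"transporter {rxn.id} must move the same species"
                    )
            if rxn.half_reactions:
                covered: list[str] = []
                for subs, prods in rxn.half_reactions:
                    covered.extend(subs)
                    covered.extend(prods)
                if sorted(covered) != sorted(rxn.stoichiometry):
                    raise ModelError(
                        f"half-reactions of {rxn.id} do not partition its "
                        "stoichiometry"
                    )
        for pair in self.cofactor_pairs:
            for mid in pair:
                if mid not in self.metabolites:
                    raise ModelError(f"cofactor pair references unknown {mid}")
                if self.is_hub(mid):
                    raise ModelError(
                        f"cofactor couple member {mid} is hub-listed; hubs are "
                        "never linkable"
                    )
        for mid in self.hubs:
            if mid not in self.metabolites:
                raise ModelError(f"hub list references unknown {mid}")

    def is_hub(self, mid: str) -> bool:
        return mid in self.hubs or self.metabolites[mid].is_hub

    def carbons(self, mid: str) -> int:
        return self.metabolites[mid].carbons

    def is_cofactor_couple(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.cofactor_pairs

    def _compute_uniquely_produced(self) -> frozenset[str]:
        """Metabolites appearing as (forward) product of exactly one reaction."""
        producers: dict[str, int] = {}
        for rxn in self.reactions.values():
            for mid in rxn.products:
                producers[mid] = producers.get(mid, 0) + 1
        return frozenset(m for m, k in producers.items() if k == 1)

    def half_reaction_partition(
        self, rxn: Reaction
    ) -> tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]:
        """Declared partition, or a fallback derived from the cofactor registry.

        The fallback pairs registered cofactor couples into their own
        half-reactions first and groups the remainder as the main
        half-reaction (with a warning, since chemical decoupling of
        electron/amino/phosphate transfers is knowledge the model should
        declare, not something stoichiometry determines).
        """
        if rxn.half_reactions:
            return rxn.half_reactions
        warnings.warn(
            f"reaction {rxn.id} lacks a half-reaction partition; deriving a "
            "fallback (cofactor couples first, remainder as main couple)",
            stacklevel=2,
        )
        subs = list(rxn.substrates)
        prods = list(rxn.products)
        couples: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
        for s in list(subs):
            for p in list(prods):
                if self.is_cofactor_couple(s, p):
                    couples.append(((s,), (p,)))
                    subs.remove(s)
                    prods.remove(p)
                    break
        if subs or prods:
            couples.append((tuple(subs), tuple(prods)))
        return tuple(couples)


# ---------------------------------------------------------------------------
# JSON I/O

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "synonyms": list(m.synonyms),
                **({"chebi": m.chebi} if m.chebi else {}),
                **({"is_hub": True} if m.is_hub else {}),
            }
            for m in sorted(model.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "reversible": r.reversible,
                "transporter": r.transporter,
                "genes": list(r.genes),
                "half_reactions": [
                    [list(subs), list(prods)] for subs, prods in r.half_reactions
                ],
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
        "cofactor_pairs": sorted(sorted(p) for p in model.cofactor_pairs),
        "hubs": sorted(model.hubs),
    }


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model in canonical form (sorted keys, stable ordering)."""
    payload = json.dumps(_model_to_dict(model), indent=1, sort_keys=True)
    Path(path).write_text(payload + "\n")


def model_from_dict(doc: Mapping) -> MetabolicModel:
    try:
        mets = {
            m["id"]: Metabolite(
                id=m["id"],
                name=m["name"],
                compartment=m.get("compartment", "c"),
                formula=m.get("formula", ""),
                synonyms=tuple(m.get("synonyms", ())),
                chebi=m.get("chebi"),
                is_hub=bool(m.get("is_hub", False)),
            )
            for m in doc["metabolites"]
        }
        rxns = {
            r["id"]: Reaction(
                id=r["id"],
                stoichiometry=dict(r["stoichiometry"]),
                reversible=bool(r.get("reversible", True)),
                transporter=bool(r.get("transporter", False)),
                genes=tuple(r.get("genes", ())),
                half_reactions=tuple(
                    (tuple(subs), tuple(prods))
                    for subs, prods in r.get("half_reactions", ())
                ),
            )
            for r in doc["reactions"]
        }
    except KeyError as exc:
        raise ModelError(f"missing required model key: {exc}") from exc
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        cofactor_pairs=frozenset(
            frozenset(p) for p in doc.get("cofactor_pairs", ())
        ),
        hubs=frozenset(doc.get("hubs", ())),
    )


def load_model(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# Measured-metabolite name mapping

_STEREO_TOKENS = frozenset(
    {"sn", "d", "l", "dl", "alpha", "beta", "cis", "trans", "myo", "scyllo"}
)


def normalize_name(name: str) -> str:
    """Case-, punctuation- and charge-insensitive canonical form of a name.

    Splits on any non-alphanumeric run (which also removes charge symbols
    such as the ``+`` of ``NAD+``), drops stereo-descriptor tokens (``sn``,
    ``D``/``L``, ``alpha`` ...) and standalone locant numbers
    (``glycero-3-phosphocholine`` -> ``glycerophosphocholine``), then joins.
    """
    tokens = re.split(r"[^0-9A-Za-z]+", name.lower())
    kept = [
        t
        for t in tokens
        if t and t not in _STEREO_TOKENS and not t.isdigit()
    ]
    return "".join(kept)


@dataclass
class MappingReport:
    matched: dict[str, tuple[str, ...]]
    ambiguous: dict[str, tuple[str, ...]]
    unmatched: tuple[str, ...]

    @property
    def matched_ids(self) -> frozenset[str]:
        return frozenset(mid for ids in self.matched.values() for mid in ids)


def map_measured_metabolites(
    names: Sequence[str], model: MetabolicModel
) -> MappingReport:
    """Map measured metabolite names onto model metabolite ids.

    A name matches a metabolite when its normalized form equals the
    normalized primary name or any normalized synonym. Compartment copies
    of the same species all match (a measured concentration is not
    compartment-resolved); a name hitting several *distinct* species is
    reported as ambiguous, not silently resolved.
    """
    index: dict[str, list[Metabolite]] = {}
    for met in model.metabolites.values():
        for alias in (met.name, *met.synonyms):
            index.setdefault(normalize_name(alias), []).append(met)

    matched: dict[str, tuple[str, ...]] = {}
    ambiguous: dict[str, tuple[str, ...]] = {}
    unmatched: list[str] = []
    for name in names:
        hits = index.get(normalize_name(name), [])
        ids = tuple(sorted({m.id for m in hits}))
        if not ids:
            unmatched.append(name)
        elif len({m.name for m in hits}) > 1:
            ambiguous[name] = ids
        else:
            matched[name] = ids
    return MappingReport(matched=matched, ambiguous=ambiguous, unmatched=tuple(unmatched))
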