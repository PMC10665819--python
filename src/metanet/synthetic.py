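"""Synthetic study generator: toy models, metabolite tables, gene statistics.

Every downstream stage of the pipeline is testable without animal data:
this module generates (a) small stoichiometric models with the
structural features the path-finding rules depend on (a redox cofactor
couple, a transporter, irreversible steps, hub species, gene
associations), (b) three-group metabolite concentration tables with
log-normal noise, implanted group mean shifts and latent-factor
correlation structure producing the opposite/corrected pair patterns,
and (c) gene-level statistics with uniform null p-values and
Beta(a, 1)-skewed signal genes attached to chosen ratios.

Each generated artifact comes with a :class:`GroundTruth` recording what
was implanted, so recovery by the corresponding pipeline stage can be
asserted. Model topology, concentrations and gene statistics draw from
independently seeded sub-streams: changing one stage's draw does not
perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import MetabolicModel, Metabolite, Reaction
from .reporter import GeneStatTable, build_ratio_gene_map
from .stats import GROUPS, MetaboliteTable

__all__ = [
    "LatentFactor",
    "SyntheticConfig",
    "GroundTruth",
    "make_toy_model",
    "simulate_metabolite_table",
    "simulate_gene_stats",
    "enumerate_paths_bruteforce",
    "opposite_pair_factor",
    "corrected_pair_factor",
]

# Sub-stream tags (mixed into the seed) for the three independent draws.
_STREAM_MODEL, _STREAM_TABLE, _STREAM_GENES = 11, 22, 33


@dataclass(frozen=True)
class LatentFactor:
    """A shared factor driving the correlation of one metabolite pair.

    ``loadings`` maps a group label to the (signed) loading of each pair
    member on the factor; groups absent from the mapping load zero, so
    the pair is uncorrelated there. The population log-scale model is
    ``log x = log(baseline * shift) + loading * F + sigma * eps`` with
    ``F ~ N(0, 1)`` shared within a sample.
    """

    metabolites: tuple[str, str]
    loadings: dict[str, tuple[float, float]]

    def correlation_sign(self, group: str) -> int:
        l1, l2 = self.loadings.get(group, (0.0, 0.0))
        if l1 == 0.0 or l2 == 0.0:
            return 0
        return 1 if l1 * l2 > 0 else -1


#: Default loading magnitude: with the default noise CV of 0.2
#: (sigma ~ 0.20 in log space) a loading of 0.3 gives a population
#: pair correlation of ~0.7, the strength of the reported pairs.
DEFAULT_LOADING = 0.3


def opposite_pair_factor(
    met_a: str, met_b: str, loading: float = DEFAULT_LOADING
) -> LatentFactor:
    """Factor implanting the treatment-flipped class: r>0 in disease,
    r<0 under treatment, uncorrelated in wildtype."""
    return LatentFactor(
        metabolites=(met_a, met_b),
        loadings={
            "disease": (loading, loading),
            "disease_treated": (loading, -loading),
        },
    )


def corrected_pair_factor(
    met_a: str, met_b: str, loading: float = DEFAULT_LOADING
) -> LatentFactor:
    """Factor implanting the corrected class: r>0 in wildtype, flipped in
    disease, restored toward wildtype under treatment."""
    return LatentFactor(
        metabolites=(met_a, met_b),
        loadings={
            "wildtype": (loading, loading),
            "disease": (loading, -loading),
            "disease_treated": (loading, loading),
        },
    )


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated three-group experiment.

    Defaults mirror the real study: about ten animals per group and
    biological noise of ~20% CV on top of baselines spanning two decades
    of concentration.
    """

    seed: int = 0
    n_per_group: int = 10
    n_metabolites: int = 12
    metabolite_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_factors: list[LatentFactor] = field(default_factory=list)
    signal_ratios: frozenset[str] = frozenset()
    signal_beta_a: float = 0.1
    noise_cv: float = 0.2
    # Null genes not mapped to any reaction, emulating the transcriptome
    # bulk of a real differential-expression table (the rank transform
    # runs over the whole table, not just network-mapped genes).
    n_background_genes: int = 200

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be at least 3")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if not (0 < self.signal_beta_a <= 1):
            raise ValueError("signal_beta_a must be in (0, 1]")
        for met, shifts in self.metabolite_effects.items():
            for g in shifts:
                if g not in GROUPS:
                    raise ValueError(f"unknown group {g!r} in effects")

    @property
    def metabolite_names(self) -> list[str]:
        return [f"M{i+1:02d}" for i in range(self.n_metabolites)]

    @property
    def sigma(self) -> float:
        """Log-normal sigma for the configured coefficient of variation."""
        return math.sqrt(math.log1p(self.noise_cv**2))


@dataclass
class GroundTruth:
    """What the generator implanted, for downstream recovery checks."""

    true_shifted_metabolites: frozenset[str] = frozenset()
    true_pattern_pairs: dict[tuple[str, str], str] = field(default_factory=dict)
    true_signal_ratios: frozenset[str] = frozenset()
    model_oracle: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy model

def make_toy_model(
    seed: int, n_core_metabolites: int = 8, n_reactions: int = 12
) -> tuple[MetabolicModel, GroundTruth]:
    """Generate a small stoichiometric model with recorded legal pairs.

    The model always contains: a NAD+/NADH redox couple (registered
    cofactor pair) riding along a fraction of the conversions as its own
    half-reaction; one transporter moving a core metabolite between the
    extracellular space and the cytosol; one SAM-dependent methylation
    whose SAM/SAH couple is blocked by the hub rule; a water byproduct
    on some conversions; at least one irreversible reaction; and 1-3
    gene associations per enzymatic reaction drawn from a shared pool.
    Every reaction is carbon-balanced through its stoichiometric
    coefficients.

    Returns the model plus a :class:`GroundTruth` whose ``model_oracle``
    enumerates the legal substrate-product pairs (with weights and
    direction constraints) by construction, independently of the
    pair-extraction code.
    """
    if n_core_metabolites < 4:
        raise ValueError("need at least 4 core metabolites")
    if n_reactions < 3:
        raise ValueError("need at least 3 reactions")
    rng = np.random.default_rng([seed, _STREAM_MODEL])

    carbons = rng.integers(3, 7, size=n_core_metabolites)
    carbons[0], carbons[1] = 4, 5  # guarantees a balanced methylation pair
    mets: dict[str, Metabolite] = {}
    for i in range(n_core_metabolites):
        c = int(carbons[i])
        mid = f"m{i+1:02d}_c"
        mets[mid] = Metabolite(
            id=mid, name=f"metabolite{i+1:02d}", compartment="c",
            formula=f"C{c}H{2*c}O{max(c - 1, 1)}",
            synonyms=(f"M{i+1:02d}",),
        )
    core_ids = list(mets)
    mets["h2o_c"] = Metabolite(id="h2o_c", name="water", compartment="c",
                               formula="H2O", is_hub=True)
    mets["nad_c"] = Metabolite(id="nad_c", name="NAD", compartment="c",
                               formula="C21H26N7O14P2", synonyms=("NAD+",))
    mets["nadh_c"] = Metabolite(id="nadh_c", name="NADH", compartment="c",
                                formula="C21H27N7O14P2")
    mets["sam_c"] = Metabolite(id="sam_c", name="SAM", compartment="c",
                               formula="C15H22N6O5S", is_hub=True)
    mets["sah_c"] = Metabolite(id="sah_c", name="SAH", compartment="c",
                               formula="C14H20N6O5S")

    gene_pool = [f"g{i+1:02d}" for i in range(max(4, n_reactions))]

    def draw_genes() -> tuple[str, ...]:
        k = int(rng.integers(1, 4))
        return tuple(sorted(set(rng.choice(gene_pool, size=k))))

    reactions: dict[str, Reaction] = {}
    # Pair list by construction: (reaction, substrate, product, forward_only,
    # products-of-that-half) -- weights resolved after all reactions exist.
    raw_pairs: list[tuple[str, str, str, bool, tuple[str, ...]]] = []

    # SAM-dependent methylation m01 -> m02 (C4+C15 = C5+C14).
    reactions["R_mt"] = Reaction(
        id="R_mt",
        stoichiometry={"m01_c": -1, "sam_c": -1, "m02_c": 1, "sah_c": 1},
        reversible=False, transporter=False, genes=draw_genes(),
        half_reactions=((("m01_c",), ("m02_c",)), (("sam_c",), ("sah_c",))),
    )
    raw_pairs.append(("R_mt", "m01_c", "m02_c", True, ("m02_c",)))
    # sam/sah couple intentionally yields no pair (SAM is a hub).

    # Transporter for a random core metabolite.
    m_t = core_ids[int(rng.integers(0, n_core_metabolites))]
    met_t = mets[m_t]
    ext_id = m_t.replace("_c", "_e")
    mets[ext_id] = Metabolite(id=ext_id, name=met_t.name, compartment="e",
                              formula=met_t.formula, synonyms=met_t.synonyms)
    reactions["T1"] = Reaction(
        id="T1", stoichiometry={ext_id: -1, m_t: 1},
        reversible=True, transporter=True, genes=(),
        half_reactions=(((ext_id,), (m_t,)),),
    )
    raw_pairs.append(("T1", ext_id, m_t, False, (m_t,)))

    for k in range(n_reactions - 2):
        i, j = rng.choice(n_core_metabolites, size=2, replace=False)
        s, p = core_ids[int(i)], core_ids[int(j)]
        cs, cp = int(carbons[int(i)]), int(carbons[int(j)])
        g = math.gcd(cs, cp)
        stoich: dict[str, float] = {s: -float(cp // g), p: float(cs // g)}
        halves = [((s,), [p])]
        if rng.random() < 0.3:
            stoich["h2o_c"] = 1.0
            halves[0] = ((s,), [p, "h2o_c"])
        if rng.random() < 0.4:
            if rng.random() < 0.5:
                red_s, red_p = "nadh_c", "nad_c"
            else:
                red_s, red_p = "nad_c", "nadh_c"
            stoich[red_s] = stoich.get(red_s, 0.0) - 1.0
            stoich[red_p] = stoich.get(red_p, 0.0) + 1.0
            halves.append(((red_s,), [red_p]))
        reversible = bool(rng.random() < 0.6) if k > 0 else False
        rid = f"R{k+1:02d}"
        reactions[rid] = Reaction(
            id=rid, stoichiometry=stoich, reversible=reversible,
            transporter=False, genes=draw_genes(),
            half_reactions=tuple(
                (tuple(su), tuple(pr)) for su, pr in halves
            ),
        )
        raw_pairs.append((rid, s, p, not reversible, tuple(halves[0][1])))
        if len(halves) > 1:
            raw_pairs.append(
                (rid, halves[1][0][0], halves[1][1][0], not reversible,
                 tuple(halves[1][1]))
            )

    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        cofactor_pairs=frozenset({frozenset({"nad_c", "nadh_c"})}),
        hubs=frozenset({"h2o_c", "sam_c"}),
    )

    # Independent weight resolution for the oracle.
    produced: dict[str, int] = {}
    for rxn in reactions.values():
        for mid, coeff in rxn.stoichiometry.items():
            if coeff > 0:
                produced[mid] = produced.get(mid, 0) + 1
    unique = {m for m, n in produced.items() if n == 1}
    oracle_pairs = [
        {
            "reaction": rid,
            "substrate": s,
            "product": p,
            "weight": 0 if (rid == "T1" or any(x in unique for x in half_prods)) else 1,
            "forward_only": fwd,
        }
        for rid, s, p, fwd, half_prods in raw_pairs
    ]
    truth = GroundTruth(model_oracle={"pairs": oracle_pairs})
    return model, truth


# ---------------------------------------------------------------------------
# Metabolite table

def simulate_metabolite_table(
    cfg: SyntheticConfig,
) -> tuple[MetaboliteTable, GroundTruth]:
    """Three-group concentration table with implanted structure.

    Baselines are drawn log-uniform over two decades (matching the
    dynamic range of tissue NMR panels, so PQN sees realistic spread);
    group means follow baseline x multiplicative shift; latent factors
    add group-specific correlated variation; multiplicative log-normal
    noise has the configured CV.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TABLE])
    mets = cfg.metabolite_names
    for met in cfg.metabolite_effects:
        if met not in mets:
            raise ValueError(f"effect references unknown metabolite {met!r}")
    for f in cfg.latent_factors:
        for met in f.metabolites:
            if met not in mets:
                raise ValueError(f"factor references unknown metabolite {met!r}")

    baseline = 10.0 ** rng.uniform(-1.5, 0.5, size=len(mets))
    sigma = cfg.sigma
    rows, index, labels = [], [], []
    for group in GROUPS:
        shift = np.ones(len(mets))
        for met, by_group in cfg.metabolite_effects.items():
            if group in by_group:
                shift[mets.index(met)] = by_group[group]
        for i in range(cfg.n_per_group):
            log_x = np.log(baseline * shift) + sigma * rng.standard_normal(len(mets))
            for f in cfg.latent_factors:
                load = f.loadings.get(group)
                if load is None:
                    continue
                value = rng.standard_normal()
                for met, lam in zip(f.metabolites, load):
                    log_x[mets.index(met)] += lam * value
            rows.append(np.exp(log_x))
            index.append(f"{group}_{i+1:02d}")
            labels.append(group)

    table = MetaboliteTable(
        data=pd.DataFrame(rows, index=index, columns=mets),
        groups=pd.Series(labels, index=index, name="group"),
    )
    pattern_pairs: dict[tuple[str, str], str] = {}
    for f in cfg.latent_factors:
        signs = {g: f.correlation_sign(g) for g in GROUPS}
        pair = tuple(sorted(f.metabolites))
        if (
            signs["disease"] != 0
            and signs["disease_treated"] == -signs["disease"]
            and signs["wildtype"] == 0
        ):
            pattern_pairs[pair] = "opposite_under_treatment"
        elif (
            signs["wildtype"] != 0
            and signs["disease"] == -signs["wildtype"]
            and signs["disease_treated"] == signs["wildtype"]
        ):
            pattern_pairs[pair] = "corrected_toward_wildtype"
    shifted = frozenset(
        met
        for met, by_group in cfg.metabolite_effects.items()
        if any(s != 1.0 for s in by_group.values())
    )
    return table, GroundTruth(
        true_shifted_metabolites=shifted, true_pattern_pairs=pattern_pairs
    )


# ---------------------------------------------------------------------------
# Gene statistics

def simulate_gene_stats(
    model: MetabolicModel, cfg: SyntheticConfig
) -> tuple[GeneStatTable, GroundTruth]:
    """Gene-level p/log2FC/FDR table with signal implanted on chosen ratios.

    Genes attached to ``cfg.signal_ratios`` draw p ~ Beta(a, 1) with
    a = ``signal_beta_a`` (a = 1 degenerates to the uniform null); all
    other genes — including ``n_background_genes`` unmapped bulk genes
    emulating the rest of the transcriptome — draw p ~ Uniform(0, 1).
    |log2FC| grows with evidence (the normal quantile of p) with a
    random sign, and FDR is the Benjamini-Hochberg adjustment of the p
    column.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_GENES])
    ratios = {r.id: r for r in build_ratio_gene_map(model)}
    unknown = set(cfg.signal_ratios) - set(ratios)
    if unknown:
        raise ValueError(f"signal ratios not derivable from model: {sorted(unknown)}")
    signal_genes = {
        g for rid in cfg.signal_ratios for g in ratios[rid].genes
    }
    genes = sorted({g for r in ratios.values() for g in r.genes})
    genes += [f"bg{i+1:04d}" for i in range(cfg.n_background_genes)]
    p = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g in signal_genes and cfg.signal_beta_a < 1.0:
            p[i] = rng.beta(cfg.signal_beta_a, 1.0)
        else:
            p[i] = rng.random()
    magnitude = sps.norm.isf(np.clip(p, 1e-300, 1.0) / 2) * 0.35
    sign = rng.choice([-1.0, 1.0], size=len(genes))
    table = pd.DataFrame(
        {
            "p": p,
            "log2fc": sign * magnitude,
            "fdr": sps.false_discovery_control(p, method="bh"),
        },
        index=pd.Index(genes, name="gene"),
    )
    return GeneStatTable(table), GroundTruth(
        true_signal_ratios=frozenset(cfg.signal_ratios)
    )


# ---------------------------------------------------------------------------
# Brute-force path oracle (ground-truth enumeration, kept independent of
# the production path finder on purpose)

def enumerate_paths_bruteforce(
    pairs: list[dict], a: str, b: str, max_cost: int = 2, max_zero_run: int = 2
) -> set[tuple[tuple[str, str, str], ...]]:
    """Exhaustively enumerate legal step sequences from ``a`` to ``b``.

    Works breadth-first over partial sequences of (reaction, from, to)
    steps taken from an explicit pair list (dicts as in
    ``GroundTruth.model_oracle['pairs']``), applying the constraints --
    simple path, total weight in [1, max_cost], at most ``max_zero_run``
    consecutive zero-weight steps, irreversible pairs forward only --
    by filtering, not by clever search. Returns the step tuples.
    """
    steps = []
    for pr in pairs:
        steps.append((pr["reaction"], pr["substrate"], pr["product"], pr["weight"]))
        if not pr["forward_only"]:
            steps.append((pr["reaction"], pr["product"], pr["substrate"], pr["weight"]))

    complete: set[tuple[tuple[str, str, str], ...]] = set()
    frontier: list[tuple[tuple, tuple[str, ...], int, int]] = [((), (a,), 0, 0)]
    while frontier:
        nxt = []
        for seq, visited, cost, zero_run in frontier:
            for rid, frm, to, w in steps:
                if frm != visited[-1] or to in visited:
                    continue
                ncost = cost + w
                nzero = zero_run + 1 if w == 0 else 0
                if ncost > max_cost or nzero > max_zero_run:
                    continue
                nseq = seq + ((rid, frm, to),)
                if to == b:
                    if ncost >= 1:
                        complete.add(nseq)
                else:
                    nxt.append((nseq, visited + (to,), ncost, nzero))
        frontier = nxt
    return complete
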