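"""Metabolic-network distances between TFs and metabolites.

The metabolic model becomes an undirected bipartite graph of metabolite
and reaction nodes. Before any path search, extracellular species,
highly connected metabolites (participating in more than ``hub_cutoff``
reactions) and a configurable cofactor list are removed — currency
metabolites would otherwise create biologically meaningless shortcuts.

A reaction is regulated by a TF when its gene set intersects the TF's
targets. The distance of a metabolite to a TF counts the reactions
beyond the nearest regulated one on the shortest path, ignoring reaction
direction: a direct substrate or product of a regulated reaction is at
distance 0, each additional linking reaction adds 1, and unreachable (or
removed) metabolites are at infinite distance. Shortest paths use
Dijkstra with unit edge weights (equivalent to breadth-first search).

Position classification of distance-0 metabolites honors reaction
direction: substrate of regulated reactions only -> upstream; product
only -> downstream; both (including via a reversible regulated
reaction) -> within.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .datamodel import MetabolicModel, RegulatoryNetwork

__all__ = [
    "DEFAULT_COFACTORS",
    "DEFAULT_INTRACELLULAR",
    "MetabolicGraph",
    "build_graph",
    "DistanceRecord",
    "tf_metabolite_distance",
    "tf_distances",
    "classify_position",
    "distance_table",
]

#: Common currency metabolites removed by default (base ids, compartment
#: suffix stripped). Overridable in ``build_graph``.
DEFAULT_COFACTORS = (
    "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "coa",
    "pi", "ppi", "h2o", "h", "co2",
)

#: Compartment labels treated as intracellular.
DEFAULT_INTRACELLULAR = ("c", "cytosol", "cytoplasm")


def strip_compartment(species_id: str, compartment: str) -> str:
    """Remove a trailing ``_<compartment>`` suffix from a species id."""
    suffix = f"_{compartment}"
    if compartment and species_id.endswith(suffix):
        return species_id[: -len(suffix)]
    return species_id


def _met_node(base_id: str) -> tuple[str, str]:
    return ("met", base_id)


def _rxn_node(rxn_id: str) -> tuple[str, str]:
    return ("rxn", rxn_id)


@dataclass
class MetabolicGraph:
    """Filtered bipartite metabolite-reaction graph with TF annotations."""

    graph: nx.Graph
    removed_metabolites: set[str]
    regulated: dict[str, set[str]]  # tf -> reaction ids
    roles: dict[str, dict[str, set[str]]]  # rxn id -> {met base id -> roles}
    reversible: dict[str, bool]
    tfs: set[str]

    @property
    def metabolites(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "met"}

    @property
    def reactions(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "rxn"}

    def regulated_reactions(self, tf: str) -> set[str]:
        if tf not in self.tfs:
            raise KeyError(f"unknown TF {tf!r}")
        return self.regulated.get(tf, set()) & self.reactions


def build_graph(
    model: MetabolicModel,
    net: RegulatoryNetwork,
    hub_cutoff: int = 50,
    cofactors: tuple[str, ...] = DEFAULT_COFACTORS,
    intracellular: tuple[str, ...] = DEFAULT_INTRACELLULAR,
) -> MetabolicGraph:
    """Build the filtered bipartite graph and annotate regulated reactions.

    Non-intracellular species are dropped (and reactions touching only
    them); metabolites in more than ``hub_cutoff`` reactions and all
    listed cofactors are removed. Metabolite nodes carry
    compartment-stripped base ids.
    """
    model.validate()
    intracell = set(intracellular)
    cofactor_set = {c.lower() for c in cofactors}

    # base-id participation with roles, restricted to intracellular species
    roles: dict[str, dict[str, set[str]]] = {}
    reversible: dict[str, bool] = {}
    for r in model.reactions:
        rroles: dict[str, set[str]] = {}
        for s in r.substrates:
            comp = model.compartments.get(s, "c")
            if comp not in intracell:
                continue
            base = strip_compartment(s, comp)
            rroles.setdefault(base, set()).add("substrate")
        for p in r.products:
            comp = model.compartments.get(p, "c")
            if comp not in intracell:
                continue
            base = strip_compartment(p, comp)
            rroles.setdefault(base, set()).add("product")
        if r.reversible:
            for base in rroles:
                rroles[base] = {"substrate", "product"}
        if not rroles:
            continue  # reaction touches only extracellular species
        roles[r.id] = rroles
        reversible[r.id] = r.reversible

    counts: dict[str, int] = {}
    for rroles in roles.values():
        for base in rroles:
            counts[base] = counts.get(base, 0) + 1
    removed = {m for m, c in counts.items() if c > hub_cutoff}
    removed |= {m for m in counts if m.lower() in cofactor_set}

    g = nx.Graph()
    for rid, rroles in roles.items():
        g.add_node(_rxn_node(rid))
        for base in rroles:
            if base in removed:
                continue
            g.add_edge(_met_node(base), _rxn_node(rid))

    # regulated reactions per TF via gene-set intersection with targets
    gene_to_rxns: dict[str, set[str]] = {}
    for r in model.reactions:
        if r.id not in roles:
            continue
        for gene in r.genes:
            gene_to_rxns.setdefault(gene, set()).add(r.id)
    regulated: dict[str, set[str]] = {}
    for tf in net.tfs:
        hits: set[str] = set()
        for target in net.regulon(tf):
            hits |= gene_to_rxns.get(target, set())
        regulated[tf] = hits

    return MetabolicGraph(
        graph=g,
        removed_metabolites=removed,
        regulated=regulated,
        roles=roles,
        reversible=reversible,
        tfs=set(net.tfs),
    )


@dataclass
class DistanceRecord:
    tf: str
    metabolite: str
    distance: float  # nonnegative int or math.inf
    position: str = "unclassified"
    witness_path: list[str] | None = None


def tf_distances(graph: MetabolicGraph, tf: str) -> dict[str, float]:
    """Distances from every metabolite in the graph to ``tf``.

    Multi-source Dijkstra from the TF's regulated reaction nodes over the
    unit-weight bipartite graph; a metabolite at edge-distance d from the
    nearest regulated reaction lies on a path with (d + 1) / 2 reactions,
    so its reported distance is (d - 1) / 2.
    """
    sources = [
        _rxn_node(r) for r in graph.regulated_reactions(tf) if _rxn_node(r) in graph.graph
    ]
    out = {m: math.inf for m in graph.metabolites}
    if not sources:
        return out
    lengths = nx.multi_source_dijkstra_path_length(graph.graph, sources, weight=None)
    for node, d in lengths.items():
        if node[0] == "met":
            out[node[1]] = (d - 1) // 2
    return out


def tf_metabolite_distance(
    graph: MetabolicGraph, tf: str, metabolite: str | frozenset[str]
) -> DistanceRecord:
    """Distance record for one pair.

    ``metabolite`` may be an annotation set of isobaric compounds; the
    distance is then the minimum over the set and the position is taken
    from the arg-min compound.
    """
    members = [metabolite] if isinstance(metabolite, str) else sorted(metabolite)
    label = members[0] if isinstance(metabolite, str) else ";".join(sorted(metabolite))
    dists = tf_distances(graph, tf)
    best_d, best_m = math.inf, None
    for m in members:
        d = dists.get(m, math.inf)
        if d < best_d:
            best_d, best_m = d, m
    position = (
        classify_position(graph, tf, best_m)
        if best_m is not None and best_d == 0
        else "unclassified"
    )
    return DistanceRecord(tf=tf, metabolite=label, distance=best_d, position=position)


def classify_position(graph: MetabolicGraph, tf: str, metabolite: str) -> str:
    """Position of a distance-0 metabolite relative to regulated reactions."""
    is_sub = is_prod = False
    for rid in graph.regulated_reactions(tf):
        rroles = graph.roles.get(rid, {})
        if metabolite not in rroles:
            continue
        if "substrate" in rroles[metabolite]:
            is_sub = True
        if "product" in rroles[metabolite]:
            is_prod = True
    if is_sub and is_prod:
        return "within"
    if is_sub:
        return "upstream"
    if is_prod:
        return "downstream"
    return "unclassified"


def distance_table(
    graph: MetabolicGraph,
    tfs: list[str],
    metabolites: list[str | frozenset[str]],
    annotations: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """DistanceRecords for the full TF x metabolite pair universe.

    ``annotations`` optionally maps a metabolite row label to its
    annotation set (isobaric compounds); the row's distance is then the
    minimum over the set.
    """
    rows = []
    for tf in tfs:
        dists = tf_distances(graph, tf)
        for m in metabolites:
            label = m if isinstance(m, str) else ";".join(sorted(m))
            members = (
                sorted(m)
                if not isinstance(m, str)
                else sorted(annotations.get(m, frozenset([m])))
                if annotations
                else [m]
            )
            best_d, best_m = math.inf, None
            for member in members:
                d = dists.get(member, math.inf)
                if d < best_d:
                    best_d, best_m = d, member
            position = (
                classify_position(graph, tf, best_m)
                if best_m is not None and best_d == 0
                else "unclassified"
            )
            rows.append(
                {
                    "tf": tf,
                    "metabolite": label,
                    "distance": best_d,
                    "position": position,
                }
            )
    return pd.DataFrame(rows)
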