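"""Linearization of NRP monomer graphs into candidate monomer sequences.

An NRP structure arrives as a directed graph whose nodes are monomers
(residue name, supported flag, methylation and stereo flags) and whose
edges are labelled inter-monomer bonds.  Bonds attributable to core
NRPS module activity (amide / double-amide bonds and the thiazole,
oxazole and pyrimidine heterocycles) form the *backbone*; everything
else (ester, glycosidic, carbon-carbon, disulfide, ...) is *tailoring*
and is removed before linearization.  Each weakly connected backbone
component is traversed along directed Hamiltonian paths; a cyclic
backbone yields one candidate sequence per ring-opening position.  If
the backbone is acyclic and has few components, all permutations of the
components are additionally emitted, which supports non-collinear
assembly lines; the individual components are always emitted on their
own, which supports short iterative products.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import permutations, product
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from nrpslink.core_model import NRPMonomer, ResidueAlphabet

__all__ = [
    "MonomerGraph",
    "CandidateNRPSequence",
    "classify_edge",
    "backbone_components",
    "linearize_component",
    "combine_components",
    "linearize_graph",
    "load_monomer_graphs",
    "save_monomer_graphs",
]

logger = logging.getLogger(__name__)

#: Bond labels attributable to core NRPS module activity.
BACKBONE_BONDS = frozenset({"amide", "double-amide", "thiazole", "oxazole", "pyrimidine"})

DEFAULT_MIN_SUPPORTED = 2
DEFAULT_MAX_NODES = 20
DEFAULT_MAX_CANDIDATES = 100
DEFAULT_MAX_PERMUTED = 3


@dataclass
class MonomerGraph:
    """A compound's monomer graph: a :class:`networkx.DiGraph` whose nodes
    carry ``residue``, ``supported``, ``methylated`` and ``stereo``
    attributes and whose edges carry a ``bond`` label."""

    compound_id: str
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if u not in self.graph.nodes or v not in self.graph.nodes:
                raise ValueError(f"{self.compound_id}: edge references unknown node")
        for node, data in self.graph.nodes(data=True):
            for key in ("residue", "supported", "methylated", "stereo"):
                if key not in data:
                    raise ValueError(f"{self.compound_id}: node {node!r} lacks {key!r}")


@dataclass(frozen=True)
class CandidateNRPSequence:
    """One candidate linear monomer sequence with its provenance."""

    monomers: tuple[NRPMonomer, ...]
    compound_id: str
    component_ids: tuple[int, ...]  # indices of source components, in order
    permutation_index: int = 0
    cycle_start: object = None  # node id opening the ring, if cyclic

    def __post_init__(self) -> None:
        if len(self.monomers) < 1:
            raise ValueError("candidate sequence must be non-empty")


def classify_edge(bond_label: str) -> str:
    """Classify a bond label as ``"backbone"`` or ``"tailoring"``.

    Unknown labels fall to the tailoring class.
    """
    if not bond_label:
        raise ValueError("empty bond label")
    label = bond_label.strip().lower()
    return "backbone" if label in BACKBONE_BONDS else "tailoring"


def backbone_components(graph: nx.DiGraph, min_supported: int = DEFAULT_MIN_SUPPORTED
                        ) -> list[nx.DiGraph]:
    """Weakly connected components of the backbone-only graph, discarding
    components with fewer than ``min_supported`` supported monomers.

    Components are returned in a deterministic order (by smallest node id,
    as strings).
    """
    if min_supported < 1:
        raise ValueError("min_supported must be >= 1")
    backbone = nx.DiGraph()
    backbone.add_nodes_from(graph.nodes(data=True))
    backbone.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True)
        if classify_edge(d["bond"]) == "backbone"
    )
    comps = []
    for nodes in nx.weakly_connected_components(backbone):
        sub = backbone.subgraph(nodes).copy()
        n_supported = sum(1 for _, d in sub.nodes(data=True) if d["supported"])
        if n_supported >= min_supported:
            comps.append(sub)
        else:
            logger.debug("discarding component with %d supported monomers", n_supported)
    comps.sort(key=lambda c: min(str(n) for n in c.nodes))
    return comps


def _hamiltonian_paths(component: nx.DiGraph, max_candidates: int) -> list[tuple]:
    """All directed Hamiltonian paths of the component (node-id tuples),
    found by exhaustive backtracking in deterministic node order."""
    nodes = sorted(component.nodes, key=str)
    n = len(nodes)
    if n == 1:
        return [(nodes[0],)]
    succ = {u: sorted(component.successors(u), key=str) for u in nodes}
    paths: list[tuple] = []

    def extend(path: list, visited: set) -> None:
        if len(paths) >= max_candidates:
            return
        if len(path) == n:
            paths.append(tuple(path))
            return
        for w in succ[path[-1]]:
            if w not in visited:
                visited.add(w)
                path.append(w)
                extend(path, visited)
                path.pop()
                visited.remove(w)

    for start in nodes:
        if len(paths) >= max_candidates:
            break
        extend([start], {start})
    return paths


def linearize_component(component: nx.DiGraph,
                        max_nodes: int = DEFAULT_MAX_NODES,
                        max_candidates: int = DEFAULT_MAX_CANDIDATES) -> list[tuple]:
    """Enumerate candidate node orders for one backbone component.

    A directed simple path yields its unique traversal; a directed simple
    cycle yields one ring-opened traversal per start node.  General
    components are searched by exhaustive backtracking over directed
    edges; components larger than ``max_nodes`` are searched with a
    capped enumeration and a warning, and components admitting no
    Hamiltonian path yield an empty list with a warning.
    """
    if component.number_of_nodes() > max_nodes:
        logger.warning(
            "component with %d nodes exceeds the exhaustive-search bound %d; "
            "enumeration capped at %d candidates",
            component.number_of_nodes(), max_nodes, max_candidates,
        )
    paths = _hamiltonian_paths(component, max_candidates)
    if not paths:
        logger.warning("component with nodes %s has no Hamiltonian path; dropped",
                       sorted(component.nodes, key=str))
    return paths


def _node_monomer(data: dict, alphabet: ResidueAlphabet) -> NRPMonomer:
    residue = alphabet.normalize(data["residue"]) if data["supported"] else alphabet.unsupported_sign
    return NRPMonomer(residue=residue, methylated=int(data["methylated"]),
                      stereo=int(data["stereo"]))


def combine_components(component_sequences: Sequence[Sequence[CandidateNRPSequence]],
                       graph_is_acyclic: bool,
                       max_permuted: int = DEFAULT_MAX_PERMUTED) -> list[CandidateNRPSequence]:
    """Combine per-component candidates into the final candidate list.

    Every per-component candidate is always emitted alone.  When the
    backbone graph is acyclic and has at most ``max_permuted``
    components, every concatenation over every permutation of the
    components (taking each component's candidates) is additionally
    emitted.
    """
    out: list[CandidateNRPSequence] = []
    for cands in component_sequences:
        out.extend(cands)
    k = len(component_sequences)
    if graph_is_acyclic and 2 <= k <= max_permuted:
        perm_index = 0
        for perm in permutations(range(k)):
            for combo in product(*(component_sequences[i] for i in perm)):
                monomers = tuple(m for cand in combo for m in cand.monomers)
                out.append(CandidateNRPSequence(
                    monomers=monomers,
                    compound_id=combo[0].compound_id,
                    component_ids=tuple(i for i in perm),
                    permutation_index=perm_index,
                ))
            perm_index += 1
    return out


def linearize_graph(mg: MonomerGraph, alphabet: ResidueAlphabet,
                    min_supported: int = DEFAULT_MIN_SUPPORTED,
                    max_nodes: int = DEFAULT_MAX_NODES,
                    max_candidates: int = DEFAULT_MAX_CANDIDATES,
                    max_permuted: int = DEFAULT_MAX_PERMUTED) -> list[CandidateNRPSequence]:
    """Full linearization of one monomer graph into candidate sequences."""
    comps = backbone_components(mg.graph, min_supported)
    if not comps:
        logger.warning("%s: no backbone component retained", mg.compound_id)
        return []
    per_component: list[list[CandidateNRPSequence]] = []
    any_cycle = False
    for idx, comp in enumerate(comps):
        if not nx.is_directed_acyclic_graph(comp):
            any_cycle = True
        cands = []
        for order in linearize_component(comp, max_nodes, max_candidates):
            monomers = tuple(_node_monomer(comp.nodes[n], alphabet) for n in order)
            is_cycle = comp.has_edge(order[-1], order[0]) and len(order) > 1
            cands.append(CandidateNRPSequence(
                monomers=monomers, compound_id=mg.compound_id,
                component_ids=(idx,), cycle_start=order[0] if is_cycle else None,
            ))
        if cands:
            per_component.append(cands)
    if not per_component:
        return []
    return combine_components(per_component, graph_is_acyclic=not any_cycle,
                              max_permuted=max_permuted)


# ---------------------------------------------------------------------------
# JSON interchange format: one document holding a list of compounds, each
# {id, nodes: [{id, residue, supported, methylated, stereo}],
#  edges: [{from, to, bond}]}.

def load_monomer_graphs(path: str | Path) -> list[MonomerGraph]:
    """Read monomer graphs from the JSON interchange format."""
    with open(path, encoding="utf-8") as fh:
        docs = json.load(fh)
    if isinstance(docs, dict):
        docs = [docs]
    graphs = []
    for doc in docs:
        g = nx.DiGraph()
        for node in doc["nodes"]:
            g.add_node(node["id"], residue=node["residue"],
                       supported=bool(node["supported"]),
                       methylated=int(node["methylated"]), stereo=int(node["stereo"]))
        for edge in doc["edges"]:
            g.add_edge(edge["from"], edge["to"], bond=edge["bond"])
        graphs.append(MonomerGraph(compound_id=doc["id"], graph=g))
    return graphs


def save_monomer_graphs(graphs: Iterable[MonomerGraph], path: str | Path) -> None:
    """Write monomer graphs to the JSON interchange format."""
    docs = []
    for mg in graphs:
        docs.append({
            "id": mg.compound_id,
            "nodes": [
                {"id": n, "residue": d["residue"], "supported": bool(d["supported"]),
                 "methylated": int(d["methylated"]), "stereo": int(d["stereo"])}
                for n, d in mg.graph.nodes(data=True)
            ],
            "edges": [
                {"from": u, "to": v, "bond": d["bond"]}
                for u, v, d in mg.graph.edges(data=True)
            ],
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(docs, fh, indent=1)
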