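"""Causal DAGs, d-separation queries, and backdoor-path screening.

Before any statistical control is applied, the hypothesis should be drawn as
a directed acyclic graph of variables and causal processes.  The Markov
condition then tells us which confounds actually require control: a
demographic variable that influences tone counts only through language
contact becomes redundant once contact itself is controlled.  This module
represents such graphs, answers d-separation queries with an explicit open
path as witness, and enumerates the variables left on open backdoor paths
given a set of controls — an empty result certifies a redundancy argument.

Graph semantics are purely qualitative: no parametric structural model, no
effect estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "CausalGraph",
    "SeparationResult",
    "d_separated",
    "screening_set",
    "read_graph",
    "write_graph",
    "humidity_tone_example_graph",
]


@dataclass(frozen=True)
class CausalGraph:
    """A directed acyclic graph of named variables with optional edge notes."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        g = self.digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise ValueError(f"graph contains a cycle: {cycle}")

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in set(self.edges)


@dataclass
class SeparationResult:
    """Outcome of one d-separation query; ``witness`` is a concrete open path
    (as a node list) present exactly when the pair is not separated."""

    x: str
    y: str
    z: frozenset
    separated: bool
    witness: list | None = None

    def __post_init__(self) -> None:
        assert (self.witness is not None) == (not self.separated)


def _check_nodes(g: CausalGraph, names) -> None:
    unknown = [n for n in names if n not in g.nodes]
    if unknown:
        raise ValueError(f"unknown node name {unknown[0]!r}")


def _path_open(dg: nx.DiGraph, path: list, z: set, z_ancestors: set) -> bool:
    """Is this skeleton path d-connecting given conditioning set z?

    Interior chains and forks are blocked by conditioning on the middle node;
    a collider transmits only if it (or a descendant, i.e. it is an ancestor
    of z) is conditioned on.
    """
    for k in range(1, len(path) - 1):
        a, v, b = path[k - 1], path[k], path[k + 1]
        collider = dg.has_edge(a, v) and dg.has_edge(b, v)
        if collider:
            if v not in z and v not in z_ancestors:
                return False
        else:
            if v in z:
                return False
    return True


def _z_ancestors(dg: nx.DiGraph, z: set) -> set:
    out = set()
    for node in z:
        out |= nx.ancestors(dg, node)
    return out


def d_separated(g: CausalGraph, x: str, y: str, z=()) -> SeparationResult:
    """d-separation query with a witness path when the pair is connected.

    Enumerates every simple path in the graph skeleton between x and y and
    applies the standard blocking rules; the first open path found is
    returned as the witness.
    """
    z = frozenset(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")
    _check_nodes(g, [x, y, *z])
    dg = g.digraph()
    skeleton = dg.to_undirected(as_view=False)
    z_anc = _z_ancestors(dg, set(z))
    for path in nx.all_simple_paths(skeleton, x, y):
        if _path_open(dg, path, set(z), z_anc):
            return SeparationResult(x, y, z, separated=False, witness=list(path))
    return SeparationResult(x, y, z, separated=True)


def screening_set(g: CausalGraph, exposure: str, outcome: str, controlled=()) -> list:
    """Variables remaining on open backdoor paths after the given controls.

    A backdoor path is a skeleton path from exposure to outcome whose first
    edge points *into* the exposure.  Paths blocked by ``controlled`` (by the
    d-separation rules) are discarded; the interior nodes of the surviving
    open paths are returned, excluding mediators (nodes on directed
    exposure-to-outcome paths).  An empty result certifies that the chosen
    controls make every other potential confounder redundant.
    """
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    controlled = frozenset(controlled)
    _check_nodes(g, [exposure, outcome, *controlled])
    dg = g.digraph()
    skeleton = dg.to_undirected(as_view=False)
    z_anc = _z_ancestors(dg, set(controlled))
    mediators = set()
    for path in nx.all_simple_paths(dg, exposure, outcome):
        mediators |= set(path[1:-1])
    open_nodes: set = set()
    for path in nx.all_simple_paths(skeleton, exposure, outcome):
        if len(path) < 3 or not dg.has_edge(path[1], path[0]):
            continue  # not a backdoor path
        if _path_open(dg, path, set(controlled), z_anc):
            open_nodes |= set(path[1:-1])
    return sorted(open_nodes - mediators - {exposure, outcome})


def read_graph(source) -> CausalGraph:
    """Read a graph from a JSON edge-list file, path, or parsed dict:
    ``{"nodes": [...], "edges": [[from, to], ...]}`` with optional
    ``annotations``.  Cycles are rejected with the cycle named."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = json.load(source)
    else:
        with open(source) as fh:
            raw = json.load(fh)
    return CausalGraph(
        nodes=tuple(raw["nodes"]),
        edges=tuple((u, v) for u, v in raw["edges"]),
        annotations=dict(raw.get("annotations", {})),
    )


def write_graph(g: CausalGraph, path) -> None:
    data = {
        "nodes": list(g.nodes),
        "edges": [list(e) for e in g.edges],
        "annotations": dict(g.annotations),
    }
    if hasattr(path, "write"):
        json.dump(data, path, indent=2)
    else:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


def humidity_tone_example_graph() -> CausalGraph:
    """Example graph for the humidity-tone hypothesis in its wider context.

    This is a synthetic, interpretive encoding built for illustration: the
    main production chain runs from ambient humidity through laryngeal
    desiccation, production cost, token frequency and cultural diffusion to
    the tone inventory, while climate also drives disease burden and
    demography, which raise language contact and hence tone borrowing — an
    alternative, non-causal route from humidity to tone.  Controlling for
    contact screens off the demographic and disease variables:
    ``screening_set(g, "humidity", "tone_inventory", {"contact"})`` is empty.
    """
    chain = [
        ("climate", "humidity"),
        ("humidity", "laryngeal_desiccation"),
        ("laryngeal_desiccation", "production_cost"),
        ("production_cost", "token_frequency"),
        ("token_frequency", "cultural_diffusion"),
        ("cultural_diffusion", "tone_inventory"),
    ]
    confound = [
        ("climate", "disease"),
        ("climate", "demography"),
        ("disease", "contact"),
        ("demography", "contact"),
        ("contact", "borrowing"),
        ("borrowing", "tone_inventory"),
    ]
    nodes = tuple(
        dict.fromkeys([n for e in chain + confound for n in e])
    )
    return CausalGraph(nodes=nodes, edges=tuple(chain + confound),
                       annotations={"note": "synthetic interpretive encoding"})
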