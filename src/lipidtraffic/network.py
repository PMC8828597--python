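"""The compartment network of lipid stations.

Tissues and fluids are nodes ("lipid stations") and metabolic adjacency is an
undirected edge.  The default mouse topology is a star: lipids made in the
liver reach the termini (CNS, heart, adipose) via the serum, so every
terminus is adjacent to serum only.  Directionality of traffic is an
interpretive label on classified lipids, not a property of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CompartmentNetwork",
    "NetworkError",
    "build_network",
    "MOUSE_ADULT",
    "MOUSE_NEONATE",
    "PRESETS",
]


class NetworkError(ValueError):
    """Raised for invalid compartment network specifications."""


@dataclass(frozen=True)
class CompartmentNetwork:
    """An undirected, connected graph of compartments.

    Attributes
    ----------
    compartments:
        Ordered tuple of compartment names; the order is used in reports.
    edges:
        Frozenset of unordered name pairs.
    origin:
        Optional biosynthetic origin (e.g. liver for de novo lipogenesis).
    hub:
        Optional transport hub (e.g. serum).
    """

    compartments: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    origin: str | None = None
    hub: str | None = None
    _graph: nx.Graph = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        names = list(self.compartments)
        if len(set(names)) != len(names):
            raise NetworkError(f"duplicate compartment names in {names}")
        declared = set(names)
        g = nx.Graph()
        g.add_nodes_from(names)
        for e in self.edges:
            pair = tuple(sorted(e))
            if len(pair) != 2:
                raise NetworkError(f"self-loop or malformed edge: {set(e)}")
            for end in pair:
                if end not in declared:
                    raise NetworkError(
                        f"edge endpoint {end!r} is not a declared compartment "
                        f"(declared: {sorted(declared)})"
                    )
            g.add_edge(*pair)
        if len(names) > 1 and not nx.is_connected(g):
            parts = [sorted(c) for c in nx.connected_components(g)]
            raise NetworkError(f"compartment network is disconnected: {parts}")
        for label, value in (("origin", self.origin), ("hub", self.hub)):
            if value is not None and value not in declared:
                raise NetworkError(f"{label} {value!r} is not a declared compartment")
        object.__setattr__(self, "_graph", g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def adjacent(self, a: str, b: str) -> bool:
        """True iff {a, b} is an edge.  Never true for a == b."""
        for name in (a, b):
            if name not in self._graph:
                raise NetworkError(f"unknown compartment {name!r}")
        return self._graph.has_edge(a, b)

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as sorted name pairs, deterministically ordered."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def __len__(self) -> int:
        return len(self.compartments)


def build_network(spec: Mapping) -> CompartmentNetwork:
    """Build and validate a :class:`CompartmentNetwork` from a config mapping.

    ``spec`` carries ``compartments`` (list of names), ``edges`` (list of
    two-element lists/tuples) and optional ``origin`` / ``hub`` labels —
    the shape used in YAML/JSON run configurations.
    """
    try:
        compartments = tuple(spec["compartments"])
        raw_edges = spec["edges"]
    except KeyError as e:
        raise NetworkError(f"network spec missing key: {e}") from e
    edges = set()
    for e in raw_edges:
        pair = tuple(e)
        if len(pair) != 2 or pair[0] == pair[1]:
            raise NetworkError(f"invalid edge {e!r}: need two distinct compartments")
        edges.add(frozenset(pair))
    return CompartmentNetwork(
        compartments=compartments,
        edges=frozenset(edges),
        origin=spec.get("origin"),
        hub=spec.get("hub"),
    )


def _star(termini: Iterable[str]) -> frozenset[frozenset[str]]:
    edges = {frozenset({"liver", "serum"})}
    edges |= {frozenset({"serum", t}) for t in termini}
    return frozenset(edges)


#: Adult mouse: separate right brain and cerebellum, adipose available.
MOUSE_ADULT = CompartmentNetwork(
    compartments=("liver", "serum", "right brain", "cerebellum", "heart", "adipose"),
    edges=_star(("right brain", "cerebellum", "heart", "adipose")),
    origin="liver",
    hub="serum",
)

#: Neonate mouse: whole brain, no adipose collected.
MOUSE_NEONATE = CompartmentNetwork(
    compartments=("liver", "serum", "brain", "heart"),
    edges=_star(("brain", "heart")),
    origin="liver",
    hub="serum",
)

PRESETS: dict[str, CompartmentNetwork] = {
    "mouse-adult": MOUSE_ADULT,
    "mouse-neonate": MOUSE_NEONATE,
}
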