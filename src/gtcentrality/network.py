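"""Neighborhood-based graph games and their Shapley centrality.

The game lives on an undirected simple graph ``⟨N, E⟩`` over genes,
together with a vector of nonnegative a-priori node weights ``k``.  A
coalition's worth is the total weight it can "reach" — its own members
plus their graph neighborhood:

    v_E^k(T) = Σ_{j ∈ T ∪ N_T(E)} k_j

The Shapley value of this game is the *game theoretic centrality* of a
node and has a local closed form: node *j* splits its weight equally
among itself and its neighbors, so

    φ_i(v_E^k) = Σ_{j ∈ N_i(E) ∪ {i}} k_j / (deg_j + 1)

With unit weights this rewards nodes adjacent to many low-degree nodes:
a hub of leaves outranks a node that is merely globally central, because
each leaf hands the hub half of its weight.  Isolated nodes keep exactly
their own weight.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

import networkx as nx

from .game import CoalitionalGame, ShapleyVector

__all__ = [
    "GeneNetwork",
    "WeightVector",
    "unit_weights",
    "graph_game_value",
    "graph_game",
    "network_shapley",
    "edge_removal_components",
]


class NetworkError(ValueError):
    """Invalid network or weight input."""


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected simple graph over gene identifiers.

    Self-loops and duplicate edges are rejected rather than cleaned:
    node degree enters the centrality formula directly, so silent
    repair would silently change scores.  Isolated nodes are first-class
    citizens — a gene can be absent from every interaction yet still
    carry weight.
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        nodes = tuple(str(n) for n in self.nodes)
        if len(set(nodes)) != len(nodes):
            raise NetworkError("duplicate node identifiers")
        node_set = set(nodes)
        edges = []
        for edge in self.edges:
            pair = frozenset(str(x) for x in edge)
            if len(pair) != 2:
                raise NetworkError(f"self-loop or malformed edge: {sorted(edge)}")
            missing = pair - node_set
            if missing:
                raise NetworkError(f"edge endpoint not in node set: {sorted(missing)}")
            edges.append(pair)
        if len(set(edges)) != len(edges):
            raise NetworkError("duplicate edges")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", frozenset(edges))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "GeneNetwork":
        """Build from an edge list, adding any extra ``nodes`` as isolated.

        Node order is first-seen order over edges, then extra nodes.
        Duplicate pairs (in either orientation) are rejected.
        """
        edge_pairs = []
        ordered: dict[str, None] = {}
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise NetworkError(f"self-loop on node {a!r}")
            pair = frozenset((a, b))
            if pair in edge_pairs:
                raise NetworkError(f"duplicate edge {sorted(pair)}")
            edge_pairs.append(pair)
            ordered.setdefault(a)
            ordered.setdefault(b)
        for n in nodes:
            ordered.setdefault(str(n))
        return cls(nodes=tuple(ordered), edges=frozenset(edge_pairs))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> frozenset[str]:
        self._require(node)
        return frozenset(next(iter(e - {node})) for e in self.edges if node in e)

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def isolated_nodes(self) -> frozenset[str]:
        touched = frozenset().union(*self.edges) if self.edges else frozenset()
        return frozenset(self.nodes) - touched

    def _require(self, node: str) -> None:
        if node not in set(self.nodes):
            raise NetworkError(f"unknown node {node!r}")


class WeightVector(Mapping[str, float]):
    """Nonnegative a-priori weight ``k_i`` for every network node.

    A zero weight is allowed (the node still contributes connectivity);
    negative weights are rejected.  Built against a specific network so
    that missing or extraneous genes fail loudly instead of defaulting.
    """

    def __init__(self, weights: Mapping[str, float], network: GeneNetwork):
        weights = {str(g): w for g, w in weights.items()}
        nodes = set(network.nodes)
        missing = nodes - weights.keys()
        extra = weights.keys() - nodes
        if missing or extra:
            raise NetworkError(
                "weight/node mismatch: "
                f"missing weights for {sorted(missing)[:5]}, "
                f"weights for unknown nodes {sorted(extra)[:5]}"
            )
        for g, w in weights.items():
            if w < 0:
                raise NetworkError(f"negative weight {w!r} for gene {g!r}")
        self._weights = {g: weights[g] for g in network.nodes}

    def __getitem__(self, gene: str) -> float:
        return self._weights[gene]

    def __iter__(self):
        return iter(self._weights)

    def __len__(self) -> int:
        return len(self._weights)


def unit_weights(network: GeneNetwork) -> WeightVector:
    """``k ≡ 1``: no a-priori knowledge, every gene weighted equally."""
    return WeightVector({g: 1 for g in network.nodes}, network)


def graph_game_value(
    network: GeneNetwork,
    k: WeightVector,
    coalition: Iterable[str],
    *,
    exact: bool = False,
) -> float | Fraction:
    """Worth ``v_E^k(T)``: total weight of ``T`` and its neighborhood."""
    coalition = frozenset(coalition)
    unknown = coalition - set(network.nodes)
    if unknown:
        raise NetworkError(f"unknown nodes in coalition: {sorted(unknown)}")
    if not coalition:
        return Fraction(0) if exact else 0.0
    reach = set(coalition)
    for edge in network.edges:
        if edge & coalition:
            reach |= edge
    total = sum(_as_fraction(k[j]) for j in reach) if exact else sum(k[j] for j in reach)
    return total


def graph_game(
    network: GeneNetwork, k: WeightVector, *, exact: bool = False
) -> CoalitionalGame:
    """The induced coalitional game ``(N, v_E^k)`` for the brute-force oracle."""
    return CoalitionalGame(
        network.nodes,
        lambda T: graph_game_value(network, k, T, exact=exact),
    )


def network_shapley(
    network: GeneNetwork, k: WeightVector, *, exact: bool = False
) -> ShapleyVector:
    """Game theoretic centrality: closed-form Shapley value of ``v_E^k``.

    ``φ_i = Σ_{j ∈ N_i ∪ {i}} k_j / (deg_j + 1)``.  Scores sum to the
    total weight ``Σ_j k_j`` (each node splits its weight among itself
    and its neighbors), so the measure is efficient by construction.
    """
    neighbors: dict[str, set[str]] = {n: set() for n in network.nodes}
    for edge in network.edges:
        a, b = tuple(edge)
        neighbors[a].add(b)
        neighbors[b].add(a)
    if exact:
        share = {j: _as_fraction(k[j]) / (len(neighbors[j]) + 1) for j in network.nodes}
        scores = {
            i: sum((share[j] for j in neighbors[i]), share[i]) for i in network.nodes
        }
    else:
        share_f = {j: k[j] / (len(neighbors[j]) + 1) for j in network.nodes}
        scores = {
            i: sum((share_f[j] for j in neighbors[i]), share_f[i])
            for i in network.nodes
        }
    return ShapleyVector(scores=scores, game_size=network.n_nodes)


def edge_removal_components(
    network: GeneNetwork, node: str
) -> frozenset[frozenset[str]]:
    """Fragmentation of ``node``'s component when its edges are cut.

    Returns the connected components, within the node's original
    connected component, after deleting every edge incident to the node
    (the node itself becomes an isolated singleton).  The number and
    size of fragments is a direct reading of how much regulatory
    activity the gene holds together.
    """
    network._require(node)
    g = network.to_networkx()
    component = nx.node_connected_component(g, node)
    sub = g.subgraph(component).copy()
    sub.remove_edges_from(list(sub.edges(node)))
    return frozenset(frozenset(c) for c in nx.connected_components(sub))


def _as_fraction(w) -> Fraction:
    if not isinstance(w, Rational):
        raise NetworkError(f"exact mode requires rational weights, got {w!r}")
    return Fraction(w)
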