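"""Worked examples and synthetic-data generators.

Two small hand-checkable instances ship with the package as plain-text
files and anchor the test suite:

* a 4-gene × 3-sample binary matrix whose microarray-game Shapley
  vector is exactly ``(3/9, 1/9, 4/9, 1/9)`` — genes g2 and g4 share a
  mutation pattern and therefore a score;
* a 14-gene interaction network with 11 edges and one disconnected
  gene (g14), whose unit-weight game theoretic centrality vector is
  exactly ``(62, 65, 90, 117, 50, 45, 45, 42, 42, 42, 50, 80, 50, 60)/60``.
  g4 (a hub of three leaves) outranks the globally more central g1;
  g8, g9 and g10 are interchangeable leaves of g4 and so must tie at
  42/60.

The random generators emulate the shape of a real study's inputs — a
case/control pair of sparse binary mutation matrices over a shared gene
set and a sparse interaction network — as independent Bernoulli entries
and an Erdős–Rényi graph.  They carry no linkage disequilibrium, family
structure or degree heterogeneity; they exist to exercise the exact
algebraic machinery, not to mimic cohort biology.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources

import networkx as nx
import numpy as np

from .microarray import BinaryFeatureMatrix
from .network import GeneNetwork

__all__ = [
    "example_matrix",
    "example_network",
    "EXAMPLE_MATRIX_SHAPLEY",
    "EXAMPLE_NETWORK_SHAPLEY",
    "random_binary_matrix",
    "random_network",
]

#: Exact microarray-game Shapley values of :func:`example_matrix`.
EXAMPLE_MATRIX_SHAPLEY: dict[str, Fraction] = {
    "g1": Fraction(3, 9),
    "g2": Fraction(1, 9),
    "g3": Fraction(4, 9),
    "g4": Fraction(1, 9),
}

#: Exact unit-weight game theoretic centralities of :func:`example_network`.
#: g8, g9, g10 are structurally interchangeable leaves of the hub g4, so
#: their three values are forced equal at 42/60.
EXAMPLE_NETWORK_SHAPLEY: dict[str, Fraction] = {
    "g1": Fraction(62, 60),
    "g2": Fraction(65, 60),
    "g3": Fraction(90, 60),
    "g4": Fraction(117, 60),
    "g5": Fraction(50, 60),
    "g6": Fraction(45, 60),
    "g7": Fraction(45, 60),
    "g8": Fraction(42, 60),
    "g9": Fraction(42, 60),
    "g10": Fraction(42, 60),
    "g11": Fraction(50, 60),
    "g12": Fraction(80, 60),
    "g13": Fraction(50, 60),
    "g14": Fraction(60, 60),
}


def _data_path(name: str):
    return resources.files("gtcentrality.data") / name


def example_matrix() -> BinaryFeatureMatrix:
    """The 4×3 worked-example matrix (genes g1..g4, samples s1..s3)."""
    from .io import read_binary_matrix

    with resources.as_file(_data_path("example_matrix.tsv")) as path:
        return read_binary_matrix(path)


def example_network() -> GeneNetwork:
    """The 14-gene, 11-edge worked-example network; g14 is isolated."""
    from .io import add_isolated_nodes, read_edge_list

    with resources.as_file(_data_path("example_network.tsv")) as path:
        net = read_edge_list(path)
    return add_isolated_nodes(net, [f"g{i}" for i in range(1, 15)])


def random_binary_matrix(
    n_genes: int,
    n_samples: int,
    density: float,
    seed: int | np.random.Generator,
) -> BinaryFeatureMatrix:
    """Random 0/1 matrix with i.i.d. Bernoulli(``density``) entries.

    Columns that come out all-zero are redrawn so that every sample
    carries at least one feature (all-zero columns are uninformative
    and would only be dropped downstream).  Deterministic per seed.
    """
    if not 0 < density < 1:
        raise ValueError(f"density must be in (0, 1), got {density}")
    if n_genes < 1 or n_samples < 1:
        raise ValueError("n_genes and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    entries = (rng.random((n_genes, n_samples)) < density).astype(np.int8)
    for j in range(n_samples):
        while entries[:, j].sum() == 0:
            entries[:, j] = (rng.random(n_genes) < density).astype(np.int8)
    return BinaryFeatureMatrix(
        gene_ids=tuple(f"g{i}" for i in range(1, n_genes + 1)),
        sample_ids=tuple(f"s{j}" for j in range(1, n_samples + 1)),
        entries=entries,
    )


def random_network(
    n_nodes: int,
    edge_probability: float,
    seed: int | np.random.Generator,
) -> GeneNetwork:
    """Erdős–Rényi G(n, p) gene network, deterministic per seed."""
    if not 0 <= edge_probability <= 1:
        raise ValueError(f"edge probability must be in [0, 1], got {edge_probability}")
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, edge_probability, seed=int(rng.integers(2**31)))
    edges = [(f"g{a + 1}", f"g{b + 1}") for a, b in sorted(g.edges())]
    return GeneNetwork.from_edges(edges, nodes=[f"g{i}" for i in range(1, n_nodes + 1)])
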