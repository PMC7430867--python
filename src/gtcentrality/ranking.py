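"""Gene prioritization protocols built on game theoretic centrality.

Two analysis protocols and a comparison utility:

* **Unweighted analysis** — rank every network node by game theoretic
  centrality with unit weights (no a-priori knowledge) and keep the top
  fraction (default 5%).
* **Combined case/control analysis** — compute microarray-game Shapley
  values separately from a case and a control binary matrix, use each
  vector as node weights for the network game, and rank genes by the
  absolute difference of the two centrality scores,
  ``δ_i = |φ_i(v_E^case) − φ_i(v_E^control)|``.  Large δ flags genes
  whose network influence differs most between affected and unaffected
  samples.
* **Classical centrality comparison** — degree, betweenness (Brandes,
  unnormalized) and PageRank rankings of the same network, plus the
  matrix of top-set overlaps between measures.

Selection keeps exactly ``floor(p·n)`` genes.  Ties in score are broken
lexicographically by gene identifier so that rankings — and the files
written from them — are deterministic.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx

from .microarray import BinaryFeatureMatrix, MatrixError, microarray_shapley
from .network import (
    GeneNetwork,
    NetworkError,
    WeightVector,
    network_shapley,
    unit_weights,
)

__all__ = [
    "GeneRanking",
    "DeltaResult",
    "OverlapMatrix",
    "TIE_POLICY",
    "rank_genes",
    "first_analysis",
    "combined_weights",
    "align_to_network",
    "second_analysis",
    "classical_centralities",
    "overlap_matrix",
]

#: Deterministic tie rule recorded in every ranking: sort by score
#: descending, break ties by lexicographic gene identifier.
TIE_POLICY = "score-desc,gene-id-asc"


@dataclass(frozen=True)
class GeneRanking:
    """Genes sorted by score, with 1-based ranks and the tie rule used."""

    entries: tuple[tuple[str, float, int], ...]
    tie_policy: str = TIE_POLICY

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.entries)

    @property
    def scores(self) -> dict[str, float]:
        return {g: s for g, s, _ in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def top_fraction(self, fraction: float) -> tuple[str, ...]:
        """The first ``floor(fraction·n)`` genes of the ranking."""
        if not 0 < fraction <= 1:
            raise ValueError(f"top fraction must be in (0, 1], got {fraction}")
        return self.gene_ids[: math.floor(fraction * len(self))]

    def without(self, genes: Iterable[str]) -> "GeneRanking":
        """A re-ranked copy with ``genes`` removed (ranks recomputed)."""
        drop = set(genes)
        kept = [(g, s) for g, s, _ in self.entries if g not in drop]
        return GeneRanking(
            entries=tuple((g, s, i + 1) for i, (g, s) in enumerate(kept)),
            tie_policy=self.tie_policy,
        )


@dataclass(frozen=True)
class DeltaResult:
    """Per-gene case and control centralities and their absolute gap δ."""

    case_scores: Mapping[str, float]
    control_scores: Mapping[str, float]

    @property
    def delta(self) -> dict[str, float]:
        return {
            g: abs(self.case_scores[g] - self.control_scores[g])
            for g in self.case_scores
        }


@dataclass(frozen=True)
class OverlapMatrix:
    """Counts of genes shared between the top sets of measure pairs.

    Symmetric; the diagonal is the top-set size of each measure.
    """

    measures: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return self.counts[self.measures.index(a)][self.measures.index(b)]


def rank_genes(scores: Mapping[str, float]) -> GeneRanking:
    """Order genes by score descending, tie-broken by gene identifier."""
    ordered = sorted(scores.items(), key=lambda kv: (-float(kv[1]), kv[0]))
    return GeneRanking(
        entries=tuple((g, s, i + 1) for i, (g, s) in enumerate(ordered))
    )


def first_analysis(
    network: GeneNetwork, top_fraction: float = 0.05
) -> tuple[GeneRanking, tuple[str, ...]]:
    """Rank all nodes by unit-weight game theoretic centrality.

    Returns the full ranking and the selected top ``floor(p·n)`` genes.
    """
    if network.n_nodes == 0:
        raise NetworkError("cannot rank an empty network")
    phi = network_shapley(network, unit_weights(network))
    ranking = rank_genes(phi.scores)
    return ranking, ranking.top_fraction(top_fraction)


def combined_weights(
    matrix: BinaryFeatureMatrix, *, exact: bool = False
) -> dict[str, float]:
    """Microarray-game Shapley values, for use as network node weights.

    This is the hinge of the combined approach: empirical co-alteration
    evidence (the matrix) becomes the a-priori weight ``k`` of the
    network game, so a gene's final score blends how often it is
    co-mutated with how it sits in the interaction network.
    """
    return dict(microarray_shapley(matrix, exact=exact).scores)


def align_to_network(
    network: GeneNetwork, weights: Mapping[str, float]
) -> tuple[GeneNetwork, dict[str, float]]:
    """Opt-in reconciliation of a weight map with a network.

    Genes with weights but missing from the network are added as
    isolated nodes; network nodes without a weight get weight 0.  The
    strict constructors reject such mismatches, so any fuzziness in the
    gene universe must pass through this explicit step.
    """
    extra = [g for g in weights if g not in set(network.nodes)]
    aligned = GeneNetwork(nodes=network.nodes + tuple(extra), edges=network.edges)
    full = {g: weights.get(g, 0) for g in aligned.nodes}
    return aligned, full


def second_analysis(
    case: BinaryFeatureMatrix,
    control: BinaryFeatureMatrix,
    network: GeneNetwork,
    top_fraction: float = 0.05,
    *,
    exact: bool = False,
) -> tuple[DeltaResult, GeneRanking, tuple[str, ...]]:
    """Case/control combined analysis ranked by δ.

    The case and control matrices must share one gene set, and that set
    must equal the network's node set (use :func:`align_to_network`
    first if it does not).
    """
    if set(case.gene_ids) != set(control.gene_ids):
        raise MatrixError("case and control matrices must share the same gene set")
    if set(case.gene_ids) != set(network.nodes):
        raise NetworkError(
            "matrix gene set and network node set differ; "
            "align them explicitly with align_to_network()"
        )
    k_case = WeightVector(combined_weights(case, exact=exact), network)
    k_control = WeightVector(combined_weights(control, exact=exact), network)
    phi_case = network_shapley(network, k_case, exact=exact)
    phi_control = network_shapley(network, k_control, exact=exact)
    result = DeltaResult(case_scores=phi_case.scores, control_scores=phi_control.scores)
    ranking = rank_genes(result.delta)
    return result, ranking, ranking.top_fraction(top_fraction)


def classical_centralities(
    network: GeneNetwork, pagerank_damping: float = 0.85
) -> dict[str, GeneRanking]:
    """Degree, betweenness and PageRank rankings of the same network.

    Degree and betweenness are unnormalized counts (Brandes algorithm
    for betweenness); PageRank uses the given damping factor with a
    uniform teleport distribution and tolerance 1e-9.
    """
    if network.n_nodes == 0:
        raise NetworkError("cannot rank an empty network")
    g = network.to_networkx()
    return {
        "degree": rank_genes(dict(g.degree())),
        "betweenness": rank_genes(nx.betweenness_centrality(g, normalized=False)),
        "pagerank": rank_genes(
            nx.pagerank(g, alpha=pagerank_damping, tol=1e-9, max_iter=1000)
        ),
    }


def overlap_matrix(
    rankings: Mapping[str, GeneRanking],
    top_fraction: float,
    *,
    exclude: Iterable[str] = (),
) -> OverlapMatrix:
    """Pairwise top-set overlap counts between ranking measures.

    ``exclude`` removes genes (typically the network's isolated nodes,
    which classical measures cannot rank meaningfully) from every
    ranking *before* truncating to the top fraction, so the compared
    sets are drawn from the same connected universe.
    """
    measures = tuple(rankings)
    universes = {frozenset(r.gene_ids) for r in rankings.values()}
    if len(universes) > 1:
        raise ValueError("all rankings must cover the same gene universe")
    exclude = set(exclude)
    tops = {
        m: set(rankings[m].without(exclude).top_fraction(top_fraction))
        for m in measures
    }
    counts = tuple(
        tuple(len(tops[a] & tops[b]) for b in measures) for a in measures
    )
    return OverlapMatrix(measures=measures, counts=counts)
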