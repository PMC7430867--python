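"""Microarray games over binary gene × sample matrices.

Given a boolean matrix ``B ∈ {0,1}^{n×m}`` (rows = genes, columns =
samples; ``B_ij = 1`` marks the presence of a feature such as a
loss-of-function mutation in gene *i* of sample *j*), each column *j*
defines a support set ``M_j`` — the genes present in that sample — and
an associated unanimity game ``u_{M_j}``.  The microarray game is their
average:

    v*(T) = |{j : ∅ ≠ M_j ⊆ T}| / |S|

i.e. the fraction of samples whose entire mutated gene set lies inside
the coalition ``T``.  Its Shapley value has a closed form that splits
each sample's unit of worth equally among the genes present in it:

    φ_i(v*) = Σ_j R_ij / |S|,   R_ij = 1/|M_j| if B_ij = 1 else 0

so it is computable in O(n·m) instead of O(2^n).

Columns with no present feature (``M_j = ∅``) carry no information about
any gene: they are excluded from the support count (with a logged
warning) while ``|S|`` remains the full number of samples.  This keeps
``v*(∅) = 0`` and makes the closed form above agree exactly with the
brute-force Shapley value of ``v*``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .game import CoalitionalGame, ShapleyVector

__all__ = ["BinaryFeatureMatrix", "microarray_value", "microarray_shapley", "microarray_game"]

logger = logging.getLogger(__name__)


class MatrixError(ValueError):
    """Invalid binary feature matrix."""


@dataclass(frozen=True)
class BinaryFeatureMatrix:
    """Validated gene × sample 0/1 matrix.

    Parameters
    ----------
    gene_ids
        Row labels (the player set); unique, case-sensitive strings.
    sample_ids
        Column labels; unique strings.
    entries
        ``(n_genes, n_samples)`` array containing only 0 and 1.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        gene_ids = tuple(str(g) for g in self.gene_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if not gene_ids or not sample_ids:
            raise MatrixError("matrix must have at least one gene and one sample")
        for label, ids in (("gene", gene_ids), ("sample", sample_ids)):
            dupes = {x for x in ids if ids.count(x) > 1}
            if dupes:
                raise MatrixError(f"duplicate {label} identifiers: {sorted(dupes)}")
        entries = np.asarray(self.entries)
        if entries.shape != (len(gene_ids), len(sample_ids)):
            raise MatrixError(
                f"entry shape {entries.shape} does not match "
                f"{len(gene_ids)} genes × {len(sample_ids)} samples"
            )
        try:
            as_int = entries.astype(np.int8)
        except (TypeError, ValueError) as exc:
            raise MatrixError(f"non-binary entries: {exc}") from None
        if not np.array_equal(as_int, entries) or not np.isin(as_int, (0, 1)).all():
            bad = entries[~np.isin(entries, (0, 1))]
            raise MatrixError(f"entries must be exactly 0 or 1; found {bad[:5].tolist()}")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "entries", as_int)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_supports(self) -> list[frozenset[str]]:
        """``M_j`` for every sample: the genes with entry 1 in column *j*."""
        genes = np.asarray(self.gene_ids, dtype=object)
        return [frozenset(genes[self.entries[:, j] == 1]) for j in range(self.n_samples)]


def _informative_supports(matrix: BinaryFeatureMatrix) -> list[frozenset[str]]:
    supports = matrix.column_supports()
    n_empty = sum(1 for M in supports if not M)
    if n_empty:
        logger.warning(
            "%d of %d sample columns have no present feature; "
            "they are excluded from the microarray game",
            n_empty,
            matrix.n_samples,
        )
    return [M for M in supports if M]


def microarray_value(
    matrix: BinaryFeatureMatrix,
    coalition: Iterable[str],
    *,
    exact: bool = False,
) -> float | Fraction:
    """Worth ``v*(T)`` of a gene coalition under the microarray game.

    The fraction of samples whose support set is nonempty and contained
    in ``coalition``, out of all samples.
    """
    coalition = frozenset(coalition)
    unknown = coalition - set(matrix.gene_ids)
    if unknown:
        raise MatrixError(f"unknown genes in coalition: {sorted(unknown)}")
    hits = sum(1 for M in _informative_supports(matrix) if M <= coalition)
    value = Fraction(hits, matrix.n_samples)
    return value if exact else float(value)


def microarray_game(matrix: BinaryFeatureMatrix, *, exact: bool = False) -> CoalitionalGame:
    """The induced coalitional game ``(N, v*)``, e.g. for the brute-force oracle."""
    supports = _informative_supports(matrix)
    m = matrix.n_samples

    def value_of(T: frozenset[str]) -> float | Fraction:
        value = Fraction(sum(1 for M in supports if M <= T), m)
        return value if exact else float(value)

    return CoalitionalGame(matrix.gene_ids, value_of)


def microarray_shapley(matrix: BinaryFeatureMatrix, *, exact: bool = False) -> ShapleyVector:
    """Shapley value of the microarray game in closed form.

    Each sample contributes ``1/(|S|·|M_j|)`` to every gene present in
    it; a gene's score is the sum over samples.  Genes with identical
    rows therefore receive identical scores, and the scores sum to the
    fraction of samples with at least one present feature.
    """
    m = matrix.n_samples
    sizes = matrix.entries.sum(axis=0)  # |M_j| per column
    scores: dict[str, Fraction | float] = {}
    for i, gene in enumerate(matrix.gene_ids):
        phi = Fraction(0)
        for j in np.flatnonzero(matrix.entries[i]):
            phi += Fraction(1, int(sizes[j]) * m)
        scores[gene] = phi if exact else float(phi)
    return ShapleyVector(scores=scores, game_size=matrix.n_genes)
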