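"""Readers and writers for matrices, edge lists, weights and rankings.

All readers validate and reject rather than repair: a malformed line is
an error naming that line, never a silent fix, because every downstream
score is keyed by gene identifier and shaped by node degree.

Edge lists come in two dialects: a plain two-column pair list, and the
scored three-column form used by protein-interaction databases such as
STRING (``protein1 protein2 combined_score``).  Scored input can be
filtered at a confidence threshold; the comparison is inclusive (``>=``)
and scale-aware — STRING publishes integer scores on a 0–1000 scale
where 0.6 on the unit scale equals 600.

Written files are deterministic: fixed column order, floats at 10
significant digits, newline-terminated, so identical inputs yield
byte-identical output.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .microarray import BinaryFeatureMatrix, MatrixError
from .network import GeneNetwork, NetworkError
from .ranking import DeltaResult, GeneRanking, OverlapMatrix

__all__ = [
    "read_binary_matrix",
    "write_binary_matrix",
    "read_edge_list",
    "write_edge_list",
    "add_isolated_nodes",
    "read_gene_list",
    "write_ranking",
    "read_ranking",
    "write_delta",
    "write_overlap",
    "SCORE_SCALES",
]

logger = logging.getLogger(__name__)

#: Declared score scales for scored edge lists: name -> (max, threshold unit).
SCORE_SCALES = {"unit": 1.0, "string": 1000.0}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _fmt(x: float) -> str:
    return f"{float(x):.10g}"


# ---------------------------------------------------------------------------
# binary matrices


def read_binary_matrix(path, *, genes_in_rows: bool = True) -> BinaryFeatureMatrix:
    """Read a labelled 0/1 matrix from tab- or comma-separated text.

    The first row holds sample identifiers and the first column gene
    identifiers (transposed when ``genes_in_rows`` is false).  Entries
    other than 0/1, duplicate identifiers and ragged rows are errors.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    if frame.empty or frame.shape[1] == 0:
        raise ParseError(f"{path}: no data rows or columns")
    if not genes_in_rows:
        frame = frame.T
    values = frame.to_numpy()
    bad = ~np.isin(values, ("0", "1"))
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise MatrixError(
            f"{path}: non-binary entry {values[r, c]!r} at data line {r + 2}, "
            f"gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    for label, ids in (("gene", frame.index), ("sample", frame.columns)):
        if ids.duplicated().any():
            dupes = sorted(set(ids[ids.duplicated()]))
            raise MatrixError(f"{path}: duplicate {label} identifiers {dupes}")
    return BinaryFeatureMatrix(
        gene_ids=tuple(frame.index.astype(str)),
        sample_ids=tuple(frame.columns.astype(str)),
        entries=values.astype(np.int8),
    )


def write_binary_matrix(matrix: BinaryFeatureMatrix, path) -> None:
    """Write a matrix as tab-separated text (round-trips through the reader)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.entries):
            fh.write(gene + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path,
    *,
    score_threshold: float | None = None,
    score_scale: str = "unit",
) -> GeneNetwork:
    """Read an undirected simple graph from a two- or three-column file.

    Columns are whitespace- or tab-delimited; lines starting with ``#``
    and a leading header line (non-numeric third column) are skipped.
    With a three-column (scored) file, ``score_threshold`` keeps an edge
    iff ``score >= threshold`` on the declared ``score_scale`` ("unit"
    for 0–1 confidences, "string" for 0–1000 integer scores).  A
    threshold on an unscored file is an error — never guess.  A pair
    listed twice is an error unless the scores agree exactly, in which
    case it is deduplicated with a warning.
    """
    path = Path(path)
    if score_scale not in SCORE_SCALES:
        raise ParseError(f"unknown score scale {score_scale!r}; use one of {sorted(SCORE_SCALES)}")
    scale_max = SCORE_SCALES[score_scale]
    seen: dict[frozenset[str], float | None] = {}
    order: list[tuple[str, str]] = []
    n_scored = n_unscored = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 2:
            a, b = fields
            score = None
            n_unscored += 1
        elif len(fields) == 3:
            a, b, score_txt = fields
            try:
                score = float(score_txt)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"{path}:{lineno}: unparseable score {score_txt!r}") from None
            if not 0 <= score <= scale_max:
                raise ParseError(
                    f"{path}:{lineno}: score {score} outside the {score_scale} "
                    f"scale [0, {_fmt(scale_max)}]"
                )
            n_scored += 1
        else:
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
        if a == b:
            raise NetworkError(f"{path}:{lineno}: self-loop on node {a!r}")
        pair = frozenset((a, b))
        if pair in seen:
            if seen[pair] != score:
                raise NetworkError(
                    f"{path}:{lineno}: edge {sorted(pair)} listed twice with "
                    f"conflicting scores {seen[pair]!r} and {score!r}"
                )
            logger.warning("%s:%d: duplicate edge %s deduplicated", path, lineno, sorted(pair))
            continue
        seen[pair] = score
        order.append((a, b))
    if not order:
        raise ParseError(f"{path}: no edges found")
    if n_scored and n_unscored:
        raise ParseError(f"{path}: mixed scored and unscored edge lines")
    if score_threshold is not None:
        if n_scored == 0:
            raise ParseError(
                f"{path}: score threshold given but the edge list has no score column"
            )
        order = [
            (a, b) for a, b in order if seen[frozenset((a, b))] >= score_threshold
        ]
    return GeneNetwork.from_edges(order)


def write_edge_list(network: GeneNetwork, path) -> None:
    """Write edges as two tab-separated columns, endpoints sorted per edge.

    Isolated nodes do not appear; persist the node universe separately
    and restore it with :func:`add_isolated_nodes`.
    """
    path = Path(path)
    lines = sorted("\t".join(sorted(e)) for e in network.edges)
    path.write_text("".join(line + "\n" for line in lines))


def add_isolated_nodes(network: GeneNetwork, universe: Iterable[str]) -> GeneNetwork:
    """Extend the node set to ``universe``; new nodes are isolated.

    The analyses require the network's node set to equal the gene set
    of the binary matrices, but interaction databases only list genes
    with known partners — the remainder enter here as isolated nodes.
    """
    universe = [str(g) for g in universe]
    missing = set(network.nodes) - set(universe)
    if missing:
        raise NetworkError(
            f"universe is missing existing network nodes: {sorted(missing)[:5]}"
        )
    extra = [g for g in universe if g not in set(network.nodes)]
    return GeneNetwork(nodes=network.nodes + tuple(extra), edges=network.edges)


def read_gene_list(path) -> tuple[str, ...]:
    """One gene identifier per line; blanks and ``#`` comments skipped."""
    path = Path(path)
    genes = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not genes:
        raise ParseError(f"{path}: no gene identifiers found")
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate gene identifiers {sorted(dupes)[:5]}")
    return tuple(genes)


# ---------------------------------------------------------------------------
# rankings and derived tables


def write_ranking(ranking: GeneRanking, path, selected: Iterable[str] = ()) -> None:
    """Write ``gene_id, score, rank, selected`` as tab-separated text."""
    path = Path(path)
    chosen = set(selected)
    with path.open("w") as fh:
        fh.write("gene_id\tscore\trank\tselected\n")
        for gene, score, rank in ranking.entries:
            fh.write(f"{gene}\t{_fmt(score)}\t{rank}\t{int(gene in chosen)}\n")


def read_ranking(path) -> tuple[GeneRanking, tuple[str, ...]]:
    """Round-trip reader for :func:`write_ranking` output."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["gene_id", "score", "rank", "selected"]:
        raise ParseError(f"{path}: not a ranking file (bad or missing header)")
    entries, selected = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        gene, score, rank, chosen = fields
        entries.append((gene, float(score), int(rank)))
        if chosen == "1":
            selected.append(gene)
    return GeneRanking(entries=tuple(entries)), tuple(selected)


def write_delta(
    result: DeltaResult, ranking: GeneRanking, path, selected: Iterable[str] = ()
) -> None:
    """Write the case/control table ordered by the δ ranking."""
    path = Path(path)
    chosen = set(selected)
    delta = result.delta
    with path.open("w") as fh:
        fh.write("gene_id\tcase_score\tcontrol_score\tdelta\trank\tselected\n")
        for gene, _, rank in ranking.entries:
            fh.write(
                f"{gene}\t{_fmt(result.case_scores[gene])}"
                f"\t{_fmt(result.control_scores[gene])}"
                f"\t{_fmt(delta[gene])}\t{rank}\t{int(gene in chosen)}\n"
            )


def write_overlap(matrix: OverlapMatrix, path) -> None:
    """Write the measure × measure overlap-count table as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("measure\t" + "\t".join(matrix.measures) + "\n")
        for name, row in zip(matrix.measures, matrix.counts):
            fh.write(name + "\t" + "\t".join(str(c) for c in row) + "\n")


def write_weights(weights: Mapping[str, float], path) -> None:
    """Write per-gene weights as two tab-separated columns."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tweight\n")
        for gene, w in weights.items():
            fh.write(f"{gene}\t{_fmt(w)}\n")
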