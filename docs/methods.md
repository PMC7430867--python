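# Methods

## Model

A coalitional game is a pair `(N, v)` with `v(∅) = 0`. The Shapley value

    φ_i(v) = Σ_{T ⊆ N, i ∈ T} (|N|−|T|)!(|T|−1)!/|N|! · (v(T) − v(T∖{i}))

is the unique allocation satisfying efficiency, symmetry, linearity and the
dummy-player axiom. Two game families are implemented, each with its
polynomial-time Shapley closed form, plus their combination:

**Microarray game.** Rows of a binary gene × sample matrix are players;
each sample column `j` contributes the unanimity game on its mutated gene
set `M_j`, and `v*(T)` is the fraction of samples with `∅ ≠ M_j ⊆ T`. The
closed form splits each sample's unit of worth equally among the genes
present in it: `φ_i = Σ_j R_ij/|S|`, `R_ij = 1/|M_j|` if `B_ij = 1` else 0.
The interpretation is frequency of *co-alteration*: a gene scores highly
when it is mutated often and in the company of few others.

**Neighborhood graph game.** On an undirected simple graph with nonnegative
node weights `k`, `v_E^k(T)` is the total weight of `T` and its neighborhood.
The Shapley value is local — `φ_i = Σ_{j ∈ N_i ∪ {i}} k_j/(deg_j+1)` — and
efficient by construction (every node splits its weight among itself and its
neighbors). With unit weights the measure rewards nodes adjacent to many
low-degree nodes: a hub of leaves is the sole conduit of its leaves' weight,
which is why it outranks nodes that are merely globally central. The
grand-coalition worth is `Σ_j k_j`, which is not 1 in general; no
normalization of `v(N)` is imposed (it holds only in the microarray setting,
where worths are sample fractions).

**Combined analysis.** The microarray Shapley vectors of a case matrix and a
control matrix, used as `k`, give two centrality vectors on the same network;
genes are ranked by `δ_i = |φ_i(case) − φ_i(control)|` and the top
`floor(p·n)` are selected (default `p = 0.05`). δ is symmetric in the two
groups; a gene with no interactions keeps exactly its own microarray weight,
so empirical evidence survives disconnection from the network. Ranking is by
δ magnitude alone; no significance filter is applied (bootstrap testing of
Shapley scores is a separate procedure and out of scope here).

## Parameters and defaults

- `top_fraction` (default 0.05): selection keeps `floor(p·n)` genes — e.g.
  48 of 965 — never rounding up, so a selection is never larger than the
  stated fraction.
- Edge-confidence threshold: inclusive (`score ≥ t`), scale-aware. Declared
  scales are `unit` (0–1 confidences, typical threshold 0.6) and `string`
  (0–1000 integer scores, the STRING database convention; 600 ≡ 0.6).
- PageRank: damping 0.85, uniform teleport, tolerance 1e-9 (iteration cap
  1000 to accommodate the tight tolerance). Degree and betweenness are
  unnormalized counts; betweenness is the standard Brandes definition.
- Brute-force solver cap: 20 players (override via `player_cap`); `2^20`
  characteristic evaluations complete in seconds, and the solver exists as
  an oracle, not a production path.
- Tie policy: rankings sort by score descending, ties broken by
  lexicographic gene identifier, recorded in the `GeneRanking` as
  `score-desc,gene-id-asc`. Deterministic output (fixed columns, floats at
  10 significant digits) makes selections and files reproducible byte for
  byte.

## Numerical choices and degenerate inputs

- **Exact mode.** Both closed forms and the brute-force oracle accept
  `exact=True` and then compute entirely in `fractions.Fraction`. All
  oracle-equivalence tests assert exact equality, not closeness; the public
  default returns floats.
- **All-zero sample columns.** A column with no present feature carries no
  information and, taken literally, would give every coalition (including ∅)
  a constant bonus, breaking `v(∅) = 0`. Such columns are excluded from the
  support count with a logged warning while the denominator `|S|` remains
  the full sample count. This is equivalent to subtracting the constant
  `v(∅)` from the raw characteristic function, leaves Shapley values
  untouched (constants cancel in marginal contributions), and keeps the
  efficiency identity `Σφ = (#nonzero columns)/|S|`. An all-zero *matrix*
  consequently scores every gene 0 rather than erroring.
- **Strict validation.** Duplicate gene/sample/node identifiers, non-0/1
  entries, self-loops, duplicate edges and negative weights are hard errors;
  readers name the offending line. Degree enters the centrality formula
  directly, so silently cleaning a duplicate edge would silently change
  scores. The single sanctioned repair: an edge pair listed in both
  orientations with identical scores is deduplicated with a warning.
- **Universe alignment.** The combined analysis requires the matrix gene set
  and network node set to coincide. Mismatches are errors; reconciliation is
  an explicit opt-in (`align_to_network`, or automatically inside the
  `rank-combined` command): matrix-only genes become isolated nodes,
  network-only nodes get weight 0 (all-zero matrix rows).
- Gene identifiers are opaque case-sensitive strings; no symbol
  normalization or alias mapping is attempted.

## Worked examples and synthetic data

Two shipped plain-text instances anchor the suite. The 4×3 matrix is the
unique pattern (up to column order) with supports {g1,g3}, {g1,g3},
{g2,g3,g4}; it yields `φ = (3/9, 1/9, 4/9, 1/9)` and `v*({g1,g3}) = 2/3`
exactly. The 14-node, 11-edge network (g14 isolated) yields the unit-weight
centrality vector `(62,65,90,117,50,45,45,42,42,42,50,80,50,60)/60`; g8, g9
and g10 are interchangeable leaves of g4, so their three scores are forced
equal at 42/60 by the symmetry axiom. Both vectors are also recomputed from
first principles by the brute-force oracle in the tests.

The random generators produce i.i.d. Bernoulli binary matrices (all-zero
columns redrawn, so every synthetic sample is informative) and Erdős–Rényi
networks, deterministic per seed. They deliberately omit features of real
cohort data — family structure, linkage disequilibrium, mutation-rate
heterogeneity, scale-free degree distributions. Passing tests therefore
demonstrate algebraic correctness of the solvers and pipelines, not
biological validity of any particular ranking on real genomes. Oracle sweeps
use 200 random matrices (≤ 8 genes × ≤ 6 samples) and 200 random weighted
graphs (≤ 8 nodes): large enough to exercise every structural case the
closed forms distinguish, small enough that exact enumeration stays
instantaneous.

## Known limitations

- Variant-level preprocessing (inheritance filtering, consequence
  annotation, compound-heterozygote encoding) is upstream of this package:
  inputs start at the binary-matrix contract, where 1 encodes a qualifying
  loss-of-function genotype for a gene in a sample.
- No statistical significance is attached to δ or to the centrality scores;
  top-fraction selection is purely rank-based.
- Only exact Shapley computation is provided; there are no sampling
  estimators, and games other than the two families above (e.g. other
  graph-restricted games or alternative solution concepts) are out of scope.
- Edges are unweighted once thresholded; confidence scores gate inclusion
  but do not scale contributions.
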