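"""Coalitional games and an exact brute-force Shapley solver.

A coalitional game is a pair ``(N, v)``: a finite, ordered set of players
``N`` and a characteristic function ``v`` mapping every coalition (subset
of ``N``) to a real worth, with ``v(∅) = 0``.  The Shapley value of player
*i* is the average marginal contribution of *i* over all join orders,

    φ_i(v) = Σ_{T ⊆ N, i ∈ T} (|N|−|T|)! (|T|−1)! / |N|! · (v(T) − v(T∖{i}))

The solver here enumerates all ``2^|N|`` coalitions with the factorial
weights above rather than all ``|N|!`` permutations; the result is
identical and the cost exponentially smaller.  It is intended as the
correctness oracle for the polynomial-time closed forms in
:mod:`gtcentrality.microarray` and :mod:`gtcentrality.network`, so it
favours exactness over scale: with rational characteristic values the
exact mode returns :class:`fractions.Fraction` scores.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

__all__ = [
    "CoalitionalGame",
    "ShapleyVector",
    "shapley_bruteforce",
    "unanimity_game",
    "DEFAULT_PLAYER_CAP",
]

#: Largest player set the brute-force solver will enumerate by default.
#: 2^20 characteristic-function evaluations complete in seconds.
DEFAULT_PLAYER_CAP = 20


class GameError(ValueError):
    """Invalid coalitional-game input."""


@dataclass(frozen=True)
class CoalitionalGame:
    """A coalitional game ``(N, v)``.

    Parameters
    ----------
    players
        Ordered player identifiers; duplicates are rejected.
    value_of
        Total characteristic function: maps any ``frozenset`` of players
        to a real worth.  Must satisfy ``value_of(frozenset()) == 0``;
        this is checked lazily by :func:`shapley_bruteforce`.
    """

    players: tuple[str, ...]
    value_of: Callable[[frozenset[str]], float] = field(repr=False)

    def __post_init__(self) -> None:
        players = tuple(self.players)
        if len(set(players)) != len(players):
            raise GameError("duplicate player identifiers")
        object.__setattr__(self, "players", players)

    def value(self, coalition: Iterable[str]) -> float:
        """Worth of ``coalition``, validating membership."""
        coalition = frozenset(coalition)
        unknown = coalition - set(self.players)
        if unknown:
            raise GameError(f"unknown players in coalition: {sorted(unknown)}")
        return self.value_of(coalition)


@dataclass(frozen=True)
class ShapleyVector:
    """Shapley scores of one game: one entry per player.

    ``scores`` preserves the player order of the source game.
    Efficiency (``sum == v(N)``) holds by construction for the solvers
    in this package.
    """

    scores: Mapping[str, float]
    game_size: int

    def __getitem__(self, player: str) -> float:
        return self.scores[player]

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(self.scores.values())

    def total(self) -> float:
        return sum(self.scores.values())


def unanimity_game(players: Iterable[str], T: Iterable[str]) -> CoalitionalGame:
    """The unanimity game ``u_T``: worth 1 on coalitions containing ``T``.

    Unanimity games form a linear basis of all coalitional games; each
    column of a binary gene × sample matrix induces one (see
    :mod:`gtcentrality.microarray`).
    """
    players = tuple(players)
    T = frozenset(T)
    if not T:
        raise GameError("unanimity game requires a nonempty carrier T")
    if not T <= set(players):
        raise GameError(f"carrier not a subset of players: {sorted(T - set(players))}")

    def value_of(W: frozenset[str]) -> int:
        return 1 if T <= W else 0

    return CoalitionalGame(players, value_of)


def shapley_bruteforce(
    game: CoalitionalGame,
    *,
    exact: bool = False,
    player_cap: int = DEFAULT_PLAYER_CAP,
) -> ShapleyVector:
    """Exact Shapley value by full coalition enumeration.

    Parameters
    ----------
    game
        The game to solve; ``v(∅)`` must be 0.
    exact
        Keep :class:`~fractions.Fraction` arithmetic throughout.  Requires
        every characteristic value to be rational (int or Fraction).
    player_cap
        Refuse games larger than this (enumeration is ``O(2^|N|)``).

    Raises
    ------
    GameError
        If ``|N|`` exceeds ``player_cap``, if ``v(∅) != 0``, or if exact
        mode meets an irrational characteristic value.
    """
    players = game.players
    n = len(players)
    if n > player_cap:
        raise GameError(f"{n} players exceeds the enumeration cap of {player_cap}")

    # Evaluate v once per coalition, indexed by bitmask over `players`.
    values: list = [None] * (1 << n)
    for mask in range(1 << n):
        coalition = frozenset(players[i] for i in range(n) if mask >> i & 1)
        v = game.value_of(coalition)
        if exact:
            if not isinstance(v, Rational):
                raise GameError(
                    "exact mode requires rational characteristic values; "
                    f"got {v!r} for {sorted(coalition)}"
                )
            v = Fraction(v)
        values[mask] = v
    if values[0] != 0:
        raise GameError(f"characteristic function must vanish on ∅, got {values[0]!r}")

    # Permutation weight depends only on |T|; precompute per size.
    fact_n = math.factorial(n)
    if exact:
        weight = [Fraction(0)] + [
            Fraction(math.factorial(n - t) * math.factorial(t - 1), fact_n)
            for t in range(1, n + 1)
        ]
        zero: Fraction | float = Fraction(0)
    else:
        weight = [0.0] + [
            math.factorial(n - t) * math.factorial(t - 1) / fact_n
            for t in range(1, n + 1)
        ]
        zero = 0.0

    scores = {}
    for i, player in enumerate(players):
        bit = 1 << i
        phi = zero
        for mask in range(1 << n):
            if mask & bit:
                phi += weight[mask.bit_count()] * (values[mask] - values[mask ^ bit])
        scores[player] = phi
    return ShapleyVector(scores=scores, game_size=n)
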