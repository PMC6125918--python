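"""Hawk-dove micro games and additive macro-strategy payoffs.

Each of ``N`` independent micro games is a symmetric hawk-dove contest over a
resource of value ``V_k`` with a fight cost ``C_k`` (``C_k > V_k > 0``): two
hawks each lose ``(V_k - C_k)/2``, a hawk takes ``V_k`` from a dove, and two
doves split the resource for ``V_k/2`` each.  A macro strategy commits to
hawk or dove in every micro game; the ``2**N`` macro strategies are
identified with species, and the payoff of one macro strategy against
another is the sum of its ``N`` micro-game payoffs.

Strategies are encoded as bitmask integers: bit ``k`` set means "play hawk
in micro game ``k``", so index 0 is the all-dove strategy and index
``2**N - 1`` is the all-hawk strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "DOVE",
    "HAWK",
    "MAX_GAMES",
    "GameParams",
    "MacroStrategySet",
    "build_strategy_set",
    "equilibrium_hawk_frequency",
    "micro_payoff",
    "min_games_for_richness",
    "sample_game_params",
    "strategy_bits",
    "strategy_label",
]

DOVE = 0
HAWK = 1

#: Default cap on the number of micro games; 2**16 strategies is the largest
#: dense payoff matrix the simulator will build without an explicit override.
MAX_GAMES = 16

SeedLike = Union[int, None, np.random.SeedSequence, np.random.Generator]


def _validate_vc(V: float, C: float) -> None:
    if not (C > V > 0):
        raise ValueError(
            f"hawk-dove regime requires C > V > 0, got V={V!r}, C={C!r}"
        )


def _parse_role(role) -> int:
    if role in (HAWK, DOVE):
        return int(role)
    if isinstance(role, str):
        r = role.strip().lower()
        if r in ("hawk", "h"):
            return HAWK
        if r in ("dove", "d"):
            return DOVE
    raise ValueError(f"role must be 'hawk' or 'dove', got {role!r}")


@dataclass(frozen=True)
class GameParams:
    """Parameters of the ``N`` hawk-dove micro games.

    Attributes
    ----------
    V : ndarray of shape (N,)
        Resource values, dimensionless fitness units.
    C : ndarray of shape (N,)
        Competition (fight) costs, same units. ``C_k > V_k > 0`` for all k.
    """

    V: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        V = np.atleast_1d(np.asarray(self.V, dtype=float))
        C = np.atleast_1d(np.asarray(self.C, dtype=float))
        if V.ndim != 1 or C.shape != V.shape:
            raise ValueError("V and C must be 1-d arrays of equal length")
        if V.size < 1:
            raise ValueError("need at least one micro game (N >= 1)")
        if not np.all((C > V) & (V > 0)):
            bad = int(np.argmin((C > V) & (V > 0)))
            raise ValueError(
                f"hawk-dove regime requires C_k > V_k > 0 for every game; "
                f"violated at game {bad}: V={V[bad]}, C={C[bad]}"
            )
        V.setflags(write=False)
        C.setflags(write=False)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "C", C)

    @property
    def N(self) -> int:
        """Number of micro games."""
        return self.V.size

    @property
    def hawk_marginals(self) -> np.ndarray:
        """Single-game mixed-equilibrium hawk frequencies ``V_k / C_k``."""
        return self.V / self.C

    # -- flat key-value config round-trip ---------------------------------
    def to_config(self) -> str:
        """Serialize to a flat ``key = value`` text block.

        Floats are written with ``repr`` so the round trip is bit-exact.
        """
        v = ", ".join(repr(float(x)) for x in self.V)
        c = ", ".join(repr(float(x)) for x in self.C)
        return f"N = {self.N}\nV = {v}\nC = {c}\n"

    @classmethod
    def from_config(cls, text: str) -> "GameParams":
        fields: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
        missing = {"N", "V", "C"} - fields.keys()
        if missing:
            raise ValueError(f"config missing keys: {sorted(missing)}")
        V = np.array([float(x) for x in fields["V"].split(",")])
        C = np.array([float(x) for x in fields["C"].split(",")])
        if int(fields["N"]) != V.size:
            raise ValueError("declared N does not match length of V")
        return cls(V=V, C=C)

    def save(self, path) -> None:
        Path(path).write_text(self.to_config())

    @classmethod
    def load(cls, path) -> "GameParams":
        return cls.from_config(Path(path).read_text())


def micro_payoff(role_self, role_other, V: float, C: float) -> float:
    """Payoff to ``role_self`` meeting ``role_other`` in one hawk-dove game."""
    _validate_vc(V, C)
    s, o = _parse_role(role_self), _parse_role(role_other)
    if s == HAWK:
        return (V - C) / 2.0 if o == HAWK else float(V)
    return 0.0 if o == HAWK else V / 2.0


def equilibrium_hawk_frequency(V: float, C: float) -> float:
    """Mixed-equilibrium hawk frequency ``p_H = V / C`` of one game."""
    _validate_vc(V, C)
    return V / C


def strategy_bits(N: int) -> np.ndarray:
    """(2**N, N) array: row j holds the hawk/dove bits of strategy j."""
    j = np.arange(2**N, dtype=np.int64)
    return ((j[:, None] >> np.arange(N)[None, :]) & 1).astype(np.int8)


def strategy_label(j: int, N: int) -> str:
    """Human-readable label, e.g. ``"HDDH"``; character k is micro game k."""
    return "".join("H" if (j >> k) & 1 else "D" for k in range(N))


@dataclass(frozen=True)
class MacroStrategySet:
    """The ``2**N`` macro strategies and their additive payoff matrix.

    ``payoff[j, m]`` is the total payoff of macro strategy ``j`` against
    ``m``, summed over the N micro games.
    """

    params: GameParams
    strategies: np.ndarray
    payoff: np.ndarray
    bits: np.ndarray = field(repr=False, default=None)

    @property
    def N(self) -> int:
        return self.params.N

    @property
    def n_strategies(self) -> int:
        return self.strategies.size

    def labels(self) -> list[str]:
        return [strategy_label(int(j), self.N) for j in self.strategies]


def build_strategy_set(params: GameParams, max_games: int = MAX_GAMES) -> MacroStrategySet:
    """Enumerate the macro strategies and build the dense payoff matrix."""
    N = params.N
    if N > max_games:
        raise ValueError(
            f"N={N} would need a {2**N} x {2**N} dense payoff matrix; "
            f"the cap is N <= {max_games} (raise max_games to override)"
        )
    bits = strategy_bits(N)
    S = 2**N
    A = np.zeros((S, S))
    for k in range(N):
        V, C = params.V[k], params.C[k]
        # rows: own role, cols: opponent role (0=dove, 1=hawk)
        table = np.array([[V / 2.0, 0.0], [V, (V - C) / 2.0]])
        b = bits[:, k].astype(np.intp)
        A += table[b[:, None], b[None, :]]
    A.setflags(write=False)
    return MacroStrategySet(
        params=params,
        strategies=np.arange(S, dtype=np.int64),
        payoff=A,
        bits=bits,
    )


def sample_game_params(
    N: int,
    v_min: float = 1.0,
    v_max: float = 1.9,
    C_value: float = 2.0,
    seed: SeedLike = None,
) -> GameParams:
    """Draw ``V_k ~ Uniform(v_min, v_max)`` i.i.d. with a common fight cost.

    The default range 1–1.9 with C=2 puts every single-game hawk equilibrium
    ``V_k/C`` in (0.5, 0.95).
    """
    if not (0 < v_min <= v_max):
        raise ValueError("need 0 < v_min <= v_max")
    if v_max >= C_value:
        raise ValueError(
            f"v_max={v_max} >= C_value={C_value} would break C > V > 0"
        )
    rng = np.random.default_rng(seed)
    V = rng.uniform(v_min, v_max, size=N)
    C = np.full(N, float(C_value))
    return GameParams(V=V, C=C)


def min_games_for_richness(n_species: int) -> int:
    """Smallest N whose 2**N macro strategies cover ``n_species`` species."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return max(1, math.ceil(math.log2(n_species)))
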