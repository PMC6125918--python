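"""Replicator dynamics over the macro-strategy simplex.

The population state is a probability vector pi over the 2**N macro
strategies.  With random mixing the expected fitness of strategy j is
``f_j = sum_m A[j, m] pi_m`` and the continuous-time replicator equation

    d pi_j / dt = pi_j (f_j - fbar),      fbar = sum_j pi_j f_j,

drives strategies with above-average fitness up and the rest down.  The
integrator works in log coordinates ``y_j = log pi_j`` (where the equation
becomes ``dy_j/dt = f_j - fbar``), which preserves positivity exactly and
keeps the very small probabilities that arise at equilibrium accurate on
the log scale used by the abundance-correlation analyses.  Strategies that
start at exactly zero stay at zero (faces of the simplex are invariant),
which the integrator exploits by working on the support only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import logsumexp

from .game import MacroStrategySet, strategy_label

__all__ = [
    "IntegrationError",
    "PopulationState",
    "Trajectory",
    "fitness_vector",
    "mean_fitness",
    "integrate_to_equilibrium",
    "marginal_hawk_frequency",
    "marginal_hawk_frequencies",
    "sample_initial_state",
]

SeedLike = Union[int, None, np.random.SeedSequence, np.random.Generator]

INIT_FAMILIES = ("uniform_random", "gaussian", "product", "equal")


class IntegrationError(RuntimeError):
    """Raised when the replicator integration fails or leaves the simplex."""


@dataclass(frozen=True)
class PopulationState:
    """Probabilities over the 2**N macro strategies at a moment in time."""

    pi: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size < 1:
            raise ValueError("pi must be a 1-d probability vector")
        if not np.all(np.isfinite(pi)):
            raise ValueError("pi contains non-finite entries")
        if pi.min() < -1e-12:
            raise ValueError(f"negative probability {pi.min()} in state")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {pi.sum()!r}, not 1")
        pi = np.clip(pi, 0.0, None)
        pi.setflags(write=False)
        object.__setattr__(self, "pi", pi)

    @property
    def n_strategies(self) -> int:
        return self.pi.size

    @property
    def N(self) -> int:
        n = self.pi.size
        N = n.bit_length() - 1
        if 2**N != n:
            raise ValueError(f"state length {n} is not a power of two")
        return N


@dataclass
class Trajectory:
    """Snapshots of a replicator run plus its convergence diagnostics."""

    times: list[float]
    states: list[PopulationState]
    converged: bool
    final_fitness_spread: float

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd

        N = self.final.N
        cols = [strategy_label(j, N) for j in range(self.final.n_strategies)]
        data = np.vstack([s.pi for s in self.states])
        frame = pd.DataFrame(data, columns=cols)
        frame.insert(0, "time", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fitness_vector(state: PopulationState, strategy_set: MacroStrategySet) -> np.ndarray:
    """Expected payoff of every macro strategy under random mixing."""
    A = strategy_set.payoff
    if A.shape[0] != state.n_strategies:
        raise ValueError(
            f"state has {state.n_strategies} strategies but the payoff "
            f"matrix is {A.shape[0]} x {A.shape[1]}"
        )
    return A @ state.pi


def mean_fitness(state: PopulationState, strategy_set: MacroStrategySet) -> float:
    f = fitness_vector(state, strategy_set)
    return float(state.pi @ f)


def _residual(p: np.ndarray, A: np.ndarray, delta: float) -> float:
    f = A @ p
    if delta:
        f = f - delta * p
    return float(np.max(np.abs(p * (f - p @ f))))


def integrate_to_equilibrium(
    initial: PopulationState,
    strategy_set: MacroStrategySet | None = None,
    tol: float = 1e-10,
    t_max: float = 1e6,
    *,
    payoff: Optional[np.ndarray] = None,
    self_inhibition: float = 0.0,
    record_times: Optional[Sequence[float]] = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the replicator equation until the motion stalls.

    Convergence is declared when the largest velocity component
    ``max_j |pi_j (f_j - fbar)|`` drops below ``tol``; ``tol=0`` disables
    the check and runs to ``t_max`` (used for fixed-horizon experiments).

    Parameters
    ----------
    payoff
        Override for the payoff matrix (e.g. a randomly perturbed one);
        defaults to ``strategy_set.payoff``.
    self_inhibition
        Within-species penalty delta: strategy j's fitness is reduced by
        ``delta * pi_j``, a negative density-dependent self-interaction.
    record_times
        Extra times at which to snapshot the state (chunk boundaries are
        always recorded).
    """
    if payoff is None:
        if strategy_set is None:
            raise ValueError("need a strategy_set or an explicit payoff matrix")
        payoff = strategy_set.payoff
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if payoff.shape[0] != initial.n_strategies:
        raise ValueError("payoff matrix does not match the state dimension")

    delta = float(self_inhibition)
    pi0 = initial.pi
    active = pi0 > 0.0
    if not active.any():
        raise ValueError("initial state has empty support")
    A = payoff[np.ix_(active, active)]
    y = np.log(pi0[active])
    y = y - logsumexp(y)

    def rhs(t, y):
        p = np.exp(y - logsumexp(y))
        f = A @ p
        if delta:
            f = f - delta * p
        return f - p @ f

    def full_state(y, t):
        p = np.zeros_like(pi0)
        p[active] = np.exp(y - logsumexp(y))
        return PopulationState(pi=p, time=t)

    extra = [] if record_times is None else list(record_times)
    pending = sorted(t for t in extra if t > 0)
    times = [0.0]
    states = [full_state(y, 0.0)]

    t = 0.0
    chunk = 32.0
    converged = _residual(np.exp(y - logsumexp(y)), A, delta) < tol if tol > 0 else False
    while not converged and t < t_max:
        t_end = min(t + chunk, t_max)
        t_eval = [s for s in pending if t < s <= t_end]
        if not t_eval or t_eval[-1] < t_end:
            t_eval.append(t_end)
        sol = solve_ivp(
            rhs, (t, t_end), y, method="DOP853", rtol=rtol, atol=atol,
            t_eval=t_eval, dense_output=False,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"replicator integration failed at t={t}: {sol.message}"
            )
        for i, ti in enumerate(sol.t):
            yi = sol.y[:, i] - logsumexp(sol.y[:, i])
            times.append(float(ti))
            states.append(full_state(yi, float(ti)))
        y = sol.y[:, -1]
        y = y - logsumexp(y)
        pending = [s for s in pending if s > t_end]
        t = t_end
        chunk = min(chunk * 2.0, 1e5)
        if tol > 0:
            converged = _residual(np.exp(y), A, delta) < tol

    final_p = np.exp(y)
    f = A @ final_p
    if delta:
        f = f - delta * final_p
    visible = final_p > 1e-8
    spread = float(f[visible].max() - f[visible].min()) if visible.any() else 0.0
    return Trajectory(
        times=times, states=states, converged=converged,
        final_fitness_spread=spread,
    )


def marginal_hawk_frequency(state: PopulationState, game_index: int) -> float:
    """Total probability of macro strategies playing hawk in one game."""
    N = state.N
    if not 0 <= game_index < N:
        raise IndexError(f"game_index {game_index} out of range for N={N}")
    j = np.arange(state.n_strategies)
    mask = (j >> game_index) & 1 == 1
    return float(state.pi[mask].sum())


def marginal_hawk_frequencies(state: PopulationState) -> np.ndarray:
    """Hawk marginals for every micro game, as a length-N vector."""
    return np.array(
        [marginal_hawk_frequency(state, k) for k in range(state.N)]
    )


def sample_initial_state(
    N: int,
    family: str = "uniform_random",
    seed: SeedLike = None,
    marginals: Optional[Sequence[float]] = None,
) -> PopulationState:
    """Draw an initial probability vector over the 2**N macro strategies.

    Families: ``uniform_random`` (i.i.d. U(0,1), normalized), ``gaussian``
    (|N(0,1)| magnitudes, normalized), ``product`` (independent per-game
    hawk marginals ``marginals``), and ``equal`` (the uniform vector).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    S = 2**N
    if family == "equal":
        pi = np.full(S, 1.0 / S)
    elif family == "uniform_random":
        rng = np.random.default_rng(seed)
        pi = rng.random(S)
        pi /= pi.sum()
    elif family == "gaussian":
        rng = np.random.default_rng(seed)
        pi = np.abs(rng.standard_normal(S))
        pi /= pi.sum()
    elif family == "product":
        if marginals is None:
            raise ValueError("the product family needs per-game marginals")
        q = np.asarray(marginals, dtype=float)
        if q.size != N or np.any((q <= 0) | (q >= 1)):
            raise ValueError("marginals must be N values strictly in (0,1)")
        j = np.arange(S)
        bits = (j[:, None] >> np.arange(N)[None, :]) & 1
        pi = np.prod(np.where(bits == 1, q, 1.0 - q), axis=1)
        pi /= pi.sum()
    else:
        raise ValueError(
            f"unknown initial family {family!r}; choose from {INIT_FAMILIES}"
        )
    return PopulationState(pi=pi, time=0.0)
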