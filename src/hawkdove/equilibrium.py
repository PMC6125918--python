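"""Analytic characterization of the equilibrium set.

An interior equilibrium of the additive multi-game replicator dynamics is
pinned down only in its N per-game hawk marginals, which must equal the
single-game mixed equilibria ``p_Hk = V_k / C_k``, plus normalization.
That is N + 1 linear constraints on 2**N probabilities, so the equilibria
form a ``2**N - N - 1``-dimensional hyperplane: the dynamics restore
perturbations perpendicular to it but are neutral within it.  Among all
points on the hyperplane, the one reached from a product-form (or equal)
initial state is the product of the per-game marginals — the Wright
manifold of the multi-game system, on which cross-ratios of strategy
probabilities are invariants of the motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .dynamics import (
    PopulationState,
    integrate_to_equilibrium,
    marginal_hawk_frequencies,
    sample_initial_state,
)
from .game import GameParams, MacroStrategySet, build_strategy_set, strategy_bits

__all__ = [
    "ConstraintReport",
    "NeutralDriftSummary",
    "constraint_matrix",
    "constraint_residuals",
    "cross_ratio",
    "hyperplane_dimension",
    "product_equilibrium",
    "verify_neutral_drift",
]

SeedLike = Union[int, None, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class ConstraintReport:
    """Residuals of the N marginal constraints plus normalization."""

    marginal_residuals: np.ndarray
    normalization_residual: float
    on_hyperplane: bool
    tolerance: float

    def to_dict(self) -> dict:
        return {
            "marginal_residuals": [float(r) for r in self.marginal_residuals],
            "normalization_residual": float(self.normalization_residual),
            "on_hyperplane": bool(self.on_hyperplane),
            "tolerance": float(self.tolerance),
        }


def constraint_residuals(
    state: PopulationState, params: GameParams, tolerance: float = 1e-5
) -> ConstraintReport:
    """How far a state sits from the equilibrium hyperplane.

    Returns the N residuals ``p_Hk - V_k/C_k`` and the normalization
    residual ``sum(pi) - 1``; ``on_hyperplane`` is true when every one of
    the N + 1 residuals is below ``tolerance`` in magnitude.
    """
    if state.N != params.N:
        raise ValueError(
            f"state has N={state.N} games but params have N={params.N}"
        )
    marg = marginal_hawk_frequencies(state) - params.hawk_marginals
    norm = float(state.pi.sum() - 1.0)
    on = bool(np.all(np.abs(marg) < tolerance) and abs(norm) < tolerance)
    return ConstraintReport(
        marginal_residuals=marg,
        normalization_residual=norm,
        on_hyperplane=on,
        tolerance=tolerance,
    )


def hyperplane_dimension(N: int) -> int:
    """Dimension ``2**N - N - 1`` of the neutral equilibrium hyperplane."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return 2**N - N - 1


def constraint_matrix(N: int) -> np.ndarray:
    """The (N+1) x 2**N linear constraint system defining the hyperplane.

    Rows 0..N-1 are the hawk-membership indicators of each micro game
    (selecting ``sum_{j in H_k} pi_j``); the last row is all ones
    (normalization).  Its rank is N + 1, which is how the hyperplane
    dimension arises as ``2**N - (N + 1)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    M = np.vstack([strategy_bits(N).T.astype(float), np.ones(2**N)])
    return M


def product_equilibrium(params: GameParams) -> PopulationState:
    """The product-form equilibrium ``pi_j = prod_k p_k^{b} (1-p_k)^{1-b}``.

    Each strategy's probability is the product of its component micro
    strategies' single-game equilibrium frequencies — the point of the
    neutral hyperplane on the Wright manifold, and the state reached by the
    replicator dynamics from any product-form (in particular the equal)
    initial condition.
    """
    p = params.hawk_marginals
    bits = strategy_bits(params.N)
    pi = np.prod(np.where(bits == 1, p, 1.0 - p), axis=1)
    return PopulationState(pi=pi / pi.sum(), time=0.0)


def cross_ratio(
    state: PopulationState, game_k: int, game_l: int, background: int = 0
) -> float:
    """Cross-ratio invariant ``(pi_a pi_d) / (pi_b pi_c)`` for two games.

    With all other games' bits fixed at ``background``, a/d play (hawk,
    hawk)/(dove, dove) in games k and l while b/c play the mixed pairs.
    The additive payoff structure makes this ratio a constant of motion of
    the replicator flow; its value 1 characterizes the Wright manifold.
    """
    N = state.N
    if not (0 <= game_k < N and 0 <= game_l < N) or game_k == game_l:
        raise IndexError("need two distinct game indices in range")
    base = background & ~(1 << game_k) & ~(1 << game_l)
    a = base | (1 << game_k) | (1 << game_l)
    b = base | (1 << game_k)
    c = base | (1 << game_l)
    d = base
    pi = state.pi
    return float((pi[a] * pi[d]) / (pi[b] * pi[c]))


@dataclass
class NeutralDriftSummary:
    """Outcome of integrating from several random interior starts."""

    n_starts: int
    max_abs_residuals: np.ndarray  # per start, worst of the N+1 residuals
    pairwise_l1: np.ndarray  # condensed upper-triangle distances
    final_states: list[PopulationState]
    all_on_hyperplane: bool

    @property
    def max_pairwise_l1(self) -> float:
        return float(self.pairwise_l1.max())

    @property
    def min_pairwise_l1(self) -> float:
        return float(self.pairwise_l1.min())

    def to_frame(self):
        """One row per start: worst residual and mean L1 distance to the
        other endpoints (CSV-ready)."""
        import pandas as pd

        n = self.n_starts
        dist = np.zeros((n, n))
        idx = 0
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = self.pairwise_l1[idx]
                idx += 1
        return pd.DataFrame(
            {
                "start": np.arange(n),
                "max_abs_residual": self.max_abs_residuals,
                "mean_l1_to_others": dist.sum(axis=1) / (n - 1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def verify_neutral_drift(
    params: GameParams,
    n_starts: int = 5,
    seed: SeedLike = None,
    tol: float = 1e-10,
    residual_tolerance: float = 1e-5,
    strategy_set: MacroStrategySet | None = None,
) -> NeutralDriftSummary:
    """Show the equilibrium set is a continuum, not a point.

    Integrates from ``n_starts`` independent uniform-random interior
    starts; every final state must satisfy the N + 1 hyperplane
    constraints, while (for N >= 2) the final states themselves differ —
    the neutral drift degrees of freedom select a different point of the
    hyperplane for every initial condition.
    """
    if n_starts < 2:
        raise ValueError("need at least two starts to compare endpoints")
    sset = strategy_set if strategy_set is not None else build_strategy_set(params)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    finals: list[PopulationState] = []
    residuals = np.empty(n_starts)
    for i, child in enumerate(ss.spawn(n_starts)):
        start = sample_initial_state(params.N, "uniform_random", seed=child)
        traj = integrate_to_equilibrium(start, sset, tol=tol)
        final = traj.final
        rep = constraint_residuals(final, params, tolerance=residual_tolerance)
        residuals[i] = max(
            np.abs(rep.marginal_residuals).max(), abs(rep.normalization_residual)
        )
        finals.append(final)
    dists = []
    for i in range(n_starts):
        for j in range(i + 1, n_starts):
            dists.append(np.abs(finals[i].pi - finals[j].pi).sum())
    return NeutralDriftSummary(
        n_starts=n_starts,
        max_abs_residuals=residuals,
        pairwise_l1=np.array(dists),
        final_states=finals,
        all_on_hyperplane=bool(np.all(residuals < residual_tolerance)),
    )
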