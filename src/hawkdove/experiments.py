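"""In-silico experiment batteries on the multi-game community.

Four batteries probe the ecology of the model:

* **Paired runs** — two communities share the same game parameters V but
  start from independent random compositions; the Pearson correlation of
  their log equilibrium abundances measures how much of the final
  abundance pattern is dictated by the shared environment versus initial
  conditions (neutral drift on the equilibrium hyperplane).
* **Perturbation/recovery** — half of one species is removed from an
  equilibrated community; negative density dependence (its fitness excess
  after the cull) drives a partial, never total, recovery.
* **Invasibility** — a species is removed, the community re-equilibrates,
  and the species is reintroduced at low density.  Because any point of
  the hyperplane equalizes fitness across *all* strategies, the
  re-equilibrated community leaves the returning species no fitness
  advantage and the very act of reintroduction tips the marginals against
  it: it declines even though it coexists stably when not removed.
* **Robustness** — the additive payoff matrix is perturbed by a random
  matrix of scale epsilon, which breaks the neutral hyperplane and slowly
  collapses diversity; a small self-inhibition term delta (a
  within-species penalty such as a species-specific pathogen) restores
  coexistence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .dynamics import (
    PopulationState,
    fitness_vector,
    integrate_to_equilibrium,
    sample_initial_state,
)
from .game import GameParams, MacroStrategySet, build_strategy_set, sample_game_params

__all__ = [
    "PairedRunRecord",
    "PairedRunSummary",
    "PerturbationRecord",
    "PerturbationSummary",
    "InvasionRecord",
    "InvasionSummary",
    "RobustnessRecord",
    "paired_run_correlation",
    "perturb_and_recover",
    "run_perturbation_battery",
    "invasibility_test",
    "run_invasibility_battery",
    "robustness_experiment",
    "diversity_count",
    "default_epsilon",
    "default_delta",
]

SeedLike = Union[int, None, np.random.SeedSequence]

#: Probabilities are floored here before taking logs; replicator dynamics
#: keep strict positivity, so the floor is a guard, not a truncation.
LOG_FLOOR = 1e-300


def _seedseq(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# paired runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedRunRecord:
    pair_id: int
    params: GameParams
    correlation: float
    converged: bool


@dataclass(frozen=True)
class PairedRunSummary:
    n_pairs: int
    n_used: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    threshold: float
    fraction_at_least: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_used": self.n_used,
            "mean": self.mean,
            "sd": self.sd,
            "ci95": list(self.ci95),
            "threshold": self.threshold,
            "fraction_at_least": self.fraction_at_least,
        }


def paired_run_correlation(
    N: int = 8,
    n_pairs: int = 100,
    v_min: float = 1.0,
    v_max: float = 1.9,
    C_value: float = 2.0,
    seed: SeedLike = None,
    tol: float = 1e-10,
    threshold: float = 0.83,
) -> tuple[list[PairedRunRecord], PairedRunSummary]:
    """Correlate log equilibrium abundances of paired independent runs.

    Each pair shares freshly sampled ``V_k ~ U(v_min, v_max)`` but draws
    two independent uniform-random initial states; both are integrated to
    equilibrium and the Pearson correlation of ``log pi`` across the 2**N
    species is recorded.  The summary reports the mean, the sample
    standard deviation, a normal-approximation 95% CI for the mean, and
    the fraction of pairs at or above ``threshold``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    records: list[PairedRunRecord] = []
    for i, child in enumerate(_seedseq(seed).spawn(n_pairs)):
        s_v, s_a, s_b = child.spawn(3)
        params = sample_game_params(N, v_min, v_max, C_value, seed=s_v)
        sset = build_strategy_set(params)
        run_a = integrate_to_equilibrium(
            sample_initial_state(N, "uniform_random", seed=s_a), sset, tol=tol
        )
        run_b = integrate_to_equilibrium(
            sample_initial_state(N, "uniform_random", seed=s_b), sset, tol=tol
        )
        ok = run_a.converged and run_b.converged
        if not ok:
            warnings.warn(
                f"pair {i} did not converge within t_max; excluded from summary"
            )
            r = np.nan
        else:
            la = np.log(np.maximum(run_a.final.pi, LOG_FLOOR))
            lb = np.log(np.maximum(run_b.final.pi, LOG_FLOOR))
            r = float(np.corrcoef(la, lb)[0, 1])
        records.append(
            PairedRunRecord(pair_id=i, params=params, correlation=r, converged=ok)
        )
    rs = np.array([rec.correlation for rec in records if rec.converged])
    mean = float(rs.mean())
    sd = float(rs.std(ddof=1)) if rs.size > 1 else 0.0
    half = 1.96 * sd / np.sqrt(rs.size)
    summary = PairedRunSummary(
        n_pairs=n_pairs,
        n_used=int(rs.size),
        mean=mean,
        sd=sd,
        ci95=(mean - half, mean + half),
        threshold=threshold,
        fraction_at_least=float((rs >= threshold).mean()),
    )
    return records, summary


# ---------------------------------------------------------------------------
# perturbation / recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationRecord:
    species_index: int
    prevalence_before: float
    prevalence_after_halving: float
    prevalence_recovered: float
    fitness_excess: float  # f_j - fbar right after the cull
    has_max_fitness: bool  # j is the top-fitness strategy after the cull

    @property
    def recovery_ratio(self) -> float:
        return self.prevalence_recovered / self.prevalence_before


@dataclass(frozen=True)
class PerturbationSummary:
    n_replicates: int
    all_partial_recovery: bool
    rank_correlation: float  # Spearman, recovery ratio vs initial prevalence
    rank_p_value: float


def perturb_and_recover(
    params: GameParams,
    seed: SeedLike = None,
    species_index: Optional[int] = None,
    fraction_removed: float = 0.5,
    tol: float = 1e-10,
    strategy_set: Optional[MacroStrategySet] = None,
) -> PerturbationRecord:
    """Cull a fraction of one species at equilibrium and watch it recover.

    The community is first integrated to equilibrium from a uniform-random
    start; the focal species' probability is multiplied by
    ``1 - fraction_removed`` and the state renormalized; re-integration
    then yields the recovered prevalence.  The record keeps the focal
    species' fitness excess over the population mean immediately after the
    cull — the negative density dependence that powers the recovery.
    """
    if not 0.0 < fraction_removed < 1.0:
        raise ValueError("fraction_removed must be in (0, 1)")
    sset = strategy_set if strategy_set is not None else build_strategy_set(params)
    ss = _seedseq(seed)
    s_init, s_pick = ss.spawn(2)
    start = sample_initial_state(params.N, "uniform_random", seed=s_init)
    eq = integrate_to_equilibrium(start, sset, tol=tol).final
    if species_index is None:
        species_index = int(np.random.default_rng(s_pick).integers(eq.n_strategies))
    j = int(species_index)
    before = float(eq.pi[j])
    if before < 1e-10:
        raise ValueError(
            f"species {j} has prevalence {before} at equilibrium; "
            "perturbing it is degenerate"
        )
    pi = eq.pi.copy()
    pi[j] *= 1.0 - fraction_removed
    pi /= pi.sum()
    perturbed = PopulationState(pi=pi, time=0.0)
    f = fitness_vector(perturbed, sset)
    fbar = float(perturbed.pi @ f)
    recovered_state = integrate_to_equilibrium(perturbed, sset, tol=tol).final
    return PerturbationRecord(
        species_index=j,
        prevalence_before=before,
        prevalence_after_halving=float(perturbed.pi[j]),
        prevalence_recovered=float(recovered_state.pi[j]),
        fitness_excess=float(f[j] - fbar),
        has_max_fitness=bool(np.argmax(f) == j),
    )


def run_perturbation_battery(
    n_replicates: int = 600,
    N: int = 3,
    fraction_removed: float = 0.5,
    v_min: float = 1.0,
    v_max: float = 1.9,
    C_value: float = 2.0,
    seed: SeedLike = None,
    tol: float = 1e-10,
) -> tuple[list[PerturbationRecord], PerturbationSummary]:
    """Repeat the cull/recovery experiment with fresh V and random focal
    species per replicate, and test whether more prevalent species recover
    better (positive rank correlation of recovery ratio with initial
    prevalence)."""
    records: list[PerturbationRecord] = []
    for child in _seedseq(seed).spawn(n_replicates):
        s_v, s_run = child.spawn(2)
        params = sample_game_params(N, v_min, v_max, C_value, seed=s_v)
        records.append(
            perturb_and_recover(
                params, seed=s_run, fraction_removed=fraction_removed, tol=tol
            )
        )
    before = np.array([r.prevalence_before for r in records])
    ratio = np.array([r.recovery_ratio for r in records])
    partial = all(
        r.prevalence_after_halving < r.prevalence_recovered < r.prevalence_before
        for r in records
    )
    rho, p = stats.spearmanr(before, ratio)
    return records, PerturbationSummary(
        n_replicates=n_replicates,
        all_partial_recovery=bool(partial),
        rank_correlation=float(rho),
        rank_p_value=float(p),
    )


# ---------------------------------------------------------------------------
# invasibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InvasionRecord:
    species_index: int
    resident_equilibrium_prevalence: float
    reintroduction_level: float
    fitness_deficit: float  # f_A - fbar at the instant of reintroduction
    final_prevalence: float
    declined: bool
    ambiguous: bool  # instantaneous and asymptotic criteria disagree


@dataclass(frozen=True)
class InvasionSummary:
    n_replicates: int
    n_declined: int
    mean_resident_prevalence: float
    sd_resident_prevalence: float

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_declined": self.n_declined,
            "mean_resident_prevalence": self.mean_resident_prevalence,
            "sd_resident_prevalence": self.sd_resident_prevalence,
        }


def invasibility_test(
    params: GameParams,
    seed: SeedLike = None,
    species_index: Optional[int] = None,
    reintroduction_level: float = 0.01,
    tol: float = 1e-10,
    strategy_set: Optional[MacroStrategySet] = None,
    skip_reequilibration: bool = False,
) -> InvasionRecord:
    """Remove a species, let the community re-equilibrate, reintroduce it
    at low density, and record whether it declines.

    ``declined`` requires both the instantaneous criterion (the species'
    fitness is below the population mean at the moment of reintroduction)
    and the asymptotic one (its final prevalence falls below the
    reintroduction level); if the two disagree the record is flagged
    ``ambiguous``.  With ``skip_reequilibration`` the community is *not*
    allowed to converge between removal and reintroduction — the control
    that turns the invasibility test back into a perturbation experiment,
    in which the species recovers instead.
    """
    if not 0.0 < reintroduction_level < 1.0:
        raise ValueError("reintroduction_level must be in (0, 1)")
    sset = strategy_set if strategy_set is not None else build_strategy_set(params)
    ss = _seedseq(seed)
    s_init, s_pick = ss.spawn(2)
    start = sample_initial_state(params.N, "uniform_random", seed=s_init)
    eq = integrate_to_equilibrium(start, sset, tol=tol).final
    if species_index is None:
        species_index = int(np.random.default_rng(s_pick).integers(eq.n_strategies))
    j = int(species_index)
    resident = float(eq.pi[j])

    pi = eq.pi.copy()
    pi[j] = 0.0
    pi /= pi.sum()
    community = PopulationState(pi=pi, time=0.0)
    if not skip_reequilibration:
        community = integrate_to_equilibrium(community, sset, tol=tol).final

    pi = community.pi * (1.0 - reintroduction_level)
    pi[j] = reintroduction_level
    reintroduced = PopulationState(pi=pi / pi.sum(), time=0.0)
    f = fitness_vector(reintroduced, sset)
    below_mean = bool(f[j] < float(reintroduced.pi @ f))
    final = integrate_to_equilibrium(reintroduced, sset, tol=tol).final
    fell = bool(final.pi[j] < reintroduction_level)
    return InvasionRecord(
        species_index=j,
        resident_equilibrium_prevalence=resident,
        reintroduction_level=reintroduction_level,
        fitness_deficit=float(f[j] - reintroduced.pi @ f),
        final_prevalence=float(final.pi[j]),
        declined=fell and below_mean,
        ambiguous=fell != below_mean,
    )


def run_invasibility_battery(
    n_replicates: int = 600,
    N: int = 3,
    reintroduction_level: float = 0.01,
    v_min: float = 1.0,
    v_max: Optional[float] = None,
    C_value: float = 2.0,
    seed: SeedLike = None,
    tol: float = 1e-10,
    resample_params: bool = True,
) -> tuple[list[InvasionRecord], InvasionSummary]:
    """The full invasibility battery: fresh V (by default) and a random
    focal species per replicate.

    ``v_max`` defaults to the coverability bound ``C (N-1) / N``.  Decline
    after re-equilibration is a consequence of the community reaching the
    neutral hyperplane in the focal species' absence, which requires the
    remaining ``2**N - 1`` species to realize the marginals ``V_k/C_k``
    on their own; removal of the all-hawk species is only coverable when
    ``sum_k V_k/C_k <= N - 1``, guaranteed below the bound.  Beyond it the
    removed species' niche goes unfilled and reintroduction succeeds —
    a different (and genuine) ecological regime, reachable by passing a
    larger ``v_max`` explicitly.
    """
    if v_max is None:
        v_max = C_value * (N - 1) / N
    records: list[InvasionRecord] = []
    fixed: Optional[GameParams] = None
    fixed_set: Optional[MacroStrategySet] = None
    for child in _seedseq(seed).spawn(n_replicates):
        s_v, s_run = child.spawn(2)
        if resample_params or fixed is None:
            params = sample_game_params(N, v_min, v_max, C_value, seed=s_v)
            sset = build_strategy_set(params)
            if not resample_params:
                fixed, fixed_set = params, sset
        else:
            params, sset = fixed, fixed_set
        records.append(
            invasibility_test(
                params,
                seed=s_run,
                reintroduction_level=reintroduction_level,
                tol=tol,
                strategy_set=sset,
            )
        )
    res = np.array([r.resident_equilibrium_prevalence for r in records])
    return records, InvasionSummary(
        n_replicates=n_replicates,
        n_declined=int(sum(r.declined for r in records)),
        mean_resident_prevalence=float(res.mean()),
        sd_resident_prevalence=float(res.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# robustness to payoff perturbation, with self-inhibition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RobustnessRecord:
    epsilon: float
    delta: float
    extinction_threshold: float
    diversity_over_time: list[tuple[float, int]]
    final_state: PopulationState

    @property
    def final_diversity(self) -> int:
        return self.diversity_over_time[-1][1]


def diversity_count(state: PopulationState, threshold: float) -> int:
    """Number of strategies whose prevalence exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return int(np.sum(state.pi > threshold))


def default_epsilon(params: GameParams) -> float:
    """Default payoff-perturbation magnitude: 1% of the mean resource value.

    Small enough that the perturbed game is still recognizably the additive
    multi-game, large enough that the loss of the neutral hyperplane shows
    as a diversity collapse within a 1e4 time-unit horizon.
    """
    return 0.01 * float(params.V.mean())


def default_delta(params: GameParams) -> float:
    """Default self-inhibition strength: 50% of the mean resource value.

    The coefficient multiplies a species' own prevalence, so its fitness
    effect is of order delta/S — small next to payoffs of order V.  It must
    nonetheless dominate the random perturbation twice over: the epsilon*R
    term destabilizes neutral directions at rate ~ epsilon*sqrt(2S), and it
    displaces the interior equilibrium additively by ~ (epsilon/delta)*|R
    pi|, which must stay below the rarest species' abundance for every
    species to survive.  delta/epsilon = 50 satisfies both with margin for
    communities of up to a few dozen species.
    """
    return 0.5 * float(params.V.mean())


def robustness_experiment(
    params: GameParams,
    epsilon: float,
    delta: float,
    horizon: float = 2000.0,
    extinction_threshold: float = 1e-6,
    seed: SeedLike = None,
    n_records: int = 41,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> RobustnessRecord:
    """Integrate with payoff ``A + epsilon*R`` and self-inhibition delta.

    ``R`` has i.i.d. standard-normal entries fixed by the seed.  The
    perturbation breaks payoff additivity, destroying the neutral
    hyperplane; diversity (count of strategies above the extinction
    threshold) is recorded on an even time grid up to the horizon.
    """
    if epsilon < 0 or delta < 0:
        raise ValueError("epsilon and delta must be >= 0")
    sset = build_strategy_set(params)
    ss = _seedseq(seed)
    s_R, s_init = ss.spawn(2)
    S = sset.n_strategies
    A = sset.payoff
    if epsilon > 0:
        A = A + epsilon * np.random.default_rng(s_R).standard_normal((S, S))
    start = sample_initial_state(params.N, "uniform_random", seed=s_init)
    grid = np.linspace(0.0, horizon, n_records)
    traj = integrate_to_equilibrium(
        start,
        sset,
        tol=0.0,
        t_max=horizon,
        payoff=A,
        self_inhibition=delta,
        record_times=grid[1:],
        rtol=rtol,
        atol=atol,
    )
    # snapshots at the requested grid times (chunk-boundary extras dropped)
    wanted = {float(t) for t in grid}
    series = [
        (t, diversity_count(s, extinction_threshold))
        for t, s in zip(traj.times, traj.states)
        if t in wanted
    ]
    return RobustnessRecord(
        epsilon=float(epsilon),
        delta=float(delta),
        extinction_threshold=float(extinction_threshold),
        diversity_over_time=series,
        final_state=traj.final,
    )
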