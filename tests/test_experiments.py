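import numpy as np
import pytest

from hawkdove.dynamics import integrate_to_equilibrium, sample_initial_state
from hawkdove.experiments import (
    default_delta,
    default_epsilon,
    diversity_count,
    invasibility_test,
    paired_run_correlation,
    perturb_and_recover,
    robustness_experiment,
    run_invasibility_battery,
)
from hawkdove.game import sample_game_params


class TestPairedRuns:
    def test_identical_initial_states_give_perfect_correlation(self, n3_set):
        start = sample_initial_state(3, "uniform_random", seed=1)
        a = integrate_to_equilibrium(start, n3_set).final
        b = integrate_to_equilibrium(start, n3_set).final
        r = np.corrcoef(np.log(a.pi), np.log(b.pi))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_shared_parameters_induce_positive_correlation(self):
        """Shared V with independent starts: correlations are systematically
        positive at N=8 regardless of the (unknown) value of C."""
        records, summary = paired_run_correlation(N=8, n_pairs=20, seed=77)
        assert summary.n_used == 20
        assert all(r.converged for r in records)
        assert summary.mean > 0.0
        assert -1.0 <= min(r.correlation for r in records)
        assert max(r.correlation for r in records) <= 1.0

    def test_summary_bookkeeping(self):
        _, summary = paired_run_correlation(N=2, n_pairs=5, seed=3)
        assert summary.ci95[0] <= summary.mean <= summary.ci95[1]
        assert 0.0 <= summary.fraction_at_least <= 1.0


@pytest.fixture(scope="module")
def record(n3_params, n3_set):
    return perturb_and_recover(
        n3_params, seed=5, fraction_removed=0.5, strategy_set=n3_set
    )


class TestPerturbRecover:
    def test_partial_recovery(self, record):
        assert (
            record.prevalence_after_halving
            < record.prevalence_recovered
            < record.prevalence_before
        )

    def test_negative_density_dependence(self, record):
        # the culled species' fitness exceeds the mean right after the cull
        assert record.fitness_excess > 0

    def test_culled_species_has_top_fitness(self, n3_params, n3_set):
        """Only the culled species gains fitness in *all* its micro games,
        so it tops the fitness vector, for any focal species."""
        for j in range(8):
            rec = perturb_and_recover(
                n3_params, seed=j, species_index=j, strategy_set=n3_set
            )
            assert rec.has_max_fitness

    def test_vanishing_perturbation_limit(self, n3_params, n3_set):
        rec = perturb_and_recover(
            n3_params, seed=5, fraction_removed=1e-9, strategy_set=n3_set
        )
        assert rec.prevalence_recovered == pytest.approx(
            rec.prevalence_before, rel=1e-6
        )

    def test_invalid_fraction_rejected(self, n3_params):
        with pytest.raises(ValueError):
            perturb_and_recover(n3_params, seed=0, fraction_removed=1.0)


class TestInvasibility:
    def test_reintroduced_species_declines(self, n3_params, n3_set):
        rec = invasibility_test(
            n3_params, seed=11, reintroduction_level=0.01, strategy_set=n3_set
        )
        assert rec.declined
        assert not rec.ambiguous
        assert rec.fitness_deficit < 0
        assert rec.final_prevalence < 0.01

    def test_skipping_reequilibration_turns_decline_into_recovery(
        self, n3_params, n3_set
    ):
        """Without letting the community re-converge, removal +
        reintroduction is just a perturbation, and the species recovers —
        the re-equilibration step is what closes the niche."""
        invaded = invasibility_test(
            n3_params, seed=11, species_index=2, strategy_set=n3_set
        )
        control = invasibility_test(
            n3_params, seed=11, species_index=2, strategy_set=n3_set,
            skip_reequilibration=True,
        )
        assert invaded.declined
        assert not control.declined
        assert control.final_prevalence > control.reintroduction_level

    def test_same_species_recovers_under_perturbation(self, n3_params, n3_set):
        """Invasibility asymmetry: the species that declines after removal
        and re-equilibration recovers after a mere halving."""
        inv = invasibility_test(
            n3_params, seed=21, species_index=3, strategy_set=n3_set
        )
        pert = perturb_and_recover(
            n3_params, seed=21, species_index=3, strategy_set=n3_set
        )
        assert inv.declined
        assert pert.prevalence_recovered > pert.prevalence_after_halving

    def test_level_validation(self, n3_params):
        with pytest.raises(ValueError):
            invasibility_test(n3_params, seed=0, reintroduction_level=0.0)
        with pytest.raises(ValueError):
            invasibility_test(n3_params, seed=0, reintroduction_level=1.0)

    def test_battery_defaults_to_coverable_regime(self):
        """By default V stays below C(N-1)/N, so the seven remaining
        species can always realize the equilibrium marginals and every
        reintroduction fails."""
        records, summary = run_invasibility_battery(n_replicates=10, seed=1)
        assert summary.n_declined == 10
        assert not any(r.ambiguous for r in records)
        assert 0 < summary.mean_resident_prevalence < 1


class TestRobustness:
    def test_diversity_count(self):
        state = sample_initial_state(8, "equal")
        assert diversity_count(state, 1e-6) == 256
        assert diversity_count(state, 0.3) == 0
        from hawkdove.dynamics import PopulationState

        assert diversity_count(PopulationState(pi=np.array([1.0, 0, 0, 0])), 1e-6) == 1
        with pytest.raises(ValueError):
            diversity_count(state, 0.0)

    def test_unperturbed_community_retains_every_species(self):
        params = sample_game_params(3, v_max=4 / 3, seed=2)
        rec = robustness_experiment(
            params, epsilon=0.0, delta=0.0, horizon=500.0,
            extinction_threshold=1e-8, seed=3,
        )
        assert all(d == 8 for _, d in rec.diversity_over_time)

    def test_perturbation_collapses_and_self_inhibition_rescues(self):
        params = sample_game_params(4, v_max=4 / 3, seed=11)
        eps, delta = default_epsilon(params), default_delta(params)
        collapse = robustness_experiment(
            params, epsilon=eps, delta=0.0, horizon=1e4,
            extinction_threshold=1e-8, seed=12,
        )
        rescue = robustness_experiment(
            params, epsilon=eps, delta=delta, horizon=1e4,
            extinction_threshold=1e-8, seed=12,
        )
        assert collapse.final_diversity < 16
        assert rescue.final_diversity == 16

    def test_negative_epsilon_rejected(self, n3_params):
        with pytest.raises(ValueError):
            robustness_experiment(n3_params, epsilon=-0.1, delta=0.0)
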