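import numpy as np
import pytest

from hawkdove.dynamics import PopulationState, sample_initial_state
from hawkdove.sad import (
    AbundanceTable,
    compare_abundances,
    detect_multimodality,
    fit_lognormal,
    generate_synthetic_census,
    octave_histogram,
    read_abundance_table,
    state_to_abundances,
    summarize_abundances,
)


class TestStateToAbundances:
    def test_uniform_split(self):
        state = PopulationState(pi=np.full(4, 0.25))
        table = state_to_abundances(state, 100)
        assert np.array_equal(table.counts, [25, 25, 25, 25])

    def test_dominant_species_takes_whole_census(self):
        state = PopulationState(pi=np.array([0.999, 0.001/3, 0.001/3, 0.001/3]))
        table = state_to_abundances(state, 10)
        assert table.counts[0] == 10
        assert table.n_observed == 1  # zero counts retained but unobserved

    def test_rounding_bound(self):
        state = sample_initial_state(5, "uniform_random", seed=0)
        table = state_to_abundances(state, 997)
        assert abs(table.total - 997) <= 2**4  # half a count per species

    def test_model_labels_are_strategy_strings(self):
        state = sample_initial_state(2, "equal")
        assert state_to_abundances(state, 8).labels == ["DD", "HD", "DH", "HH"]


class TestFitLognormal:
    def test_equal_values_have_zero_spread(self):
        fit = fit_lognormal([7.0, 7.0, 7.0, 7.0])
        assert fit.log_sd == 0.0
        assert fit.log_mean == pytest.approx(np.log(7.0))

    def test_recovers_parameters_of_lognormal_sample(self):
        draws = np.random.default_rng(1).lognormal(0.0, 1.0, size=10_000)
        fit = fit_lognormal(draws)
        assert fit.log_mean == pytest.approx(0.0, abs=0.05)
        assert fit.log_sd == pytest.approx(1.0, abs=0.05)
        assert fit.p_value > 0.01

    def test_rejects_too_few_values(self):
        with pytest.raises(ValueError):
            fit_lognormal([1.0, 2.0])


class TestOctaveHistogram:
    def test_worked_example(self):
        hist = octave_histogram([1, 1, 2, 3, 4])
        assert hist == [(1, 2), (2, 2), (4, 1)]

    def test_single_species(self):
        assert octave_histogram([5]) == [(1, 0), (2, 0), (4, 1)]

    def test_conserves_species_count(self):
        counts = np.random.default_rng(0).integers(1, 4000, size=150)
        hist = octave_histogram(counts)
        assert sum(c for _, c in hist) == 150

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            octave_histogram([1, 0, 2])


class TestMultimodality:
    def test_gaussian_sample_is_unimodal(self):
        x = np.random.default_rng(3).normal(size=400)
        assert detect_multimodality(x) == 1

    def test_separated_mixture_is_bimodal(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)])
        assert detect_multimodality(x) == 2

    def test_deterministic(self):
        x = np.random.default_rng(5).normal(size=50)
        assert detect_multimodality(x) == detect_multimodality(x)

    def test_needs_ten_values(self):
        with pytest.raises(ValueError):
            detect_multimodality(np.arange(9.0))


class TestReadAbundanceTable:
    def test_plain_two_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("sp1,10\nsp2,3\n")
        table = read_abundance_table(p)
        assert table.labels == ["sp1", "sp2"]
        assert np.array_equal(table.counts, [10, 3])

    def test_header_autodetected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("species,count\nsp1,10\nsp2,3\n")
        assert read_abundance_table(p).n_species == 2

    def test_tsv(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sp1\t4\nsp2\t8\n")
        assert read_abundance_table(p, format="tsv").total == 12

    @pytest.mark.parametrize(
        "content, message",
        [
            ("", "empty"),
            ("sp1,-4\n", "negative"),
            ("sp1,10,extra\n", "malformed"),
            ("sp1,1.5\n", "malformed"),
        ],
    )
    def test_distinct_errors(self, tmp_path, content, message):
        p = tmp_path / "bad.csv"
        p.write_text(content)
        with pytest.raises(ValueError, match=message):
            read_abundance_table(p)


class TestSyntheticCensus:
    def test_shape_and_positivity(self):
        table = generate_synthetic_census(200, 3.0, 1.5, seed=0)
        assert table.n_species == 200
        assert table.counts.min() >= 1

    def test_zero_spread_gives_equal_counts(self):
        table = generate_synthetic_census(50, 3.0, 0.0, seed=0)
        assert len(set(table.counts.tolist())) == 1

    def test_round_trip_recovers_parameters(self):
        """Census generation followed by a lognormal fit returns the
        generating log-moments within sampling error."""
        mu, sigma, n = 4.0, 1.2, 10_000
        table = generate_synthetic_census(n, mu, sigma, seed=8)
        fit = fit_lognormal(table.counts)
        se_mu, se_sd = sigma / np.sqrt(n), sigma / np.sqrt(2 * n)
        assert abs(fit.log_mean - mu) < 3 * se_mu
        assert abs(fit.log_sd - sigma) < 3 * se_sd + 0.01  # rounding bias


def test_summary_octaves_cover_observed_species():
    table = generate_synthetic_census(300, 3.0, 1.5, seed=2)
    summary = summarize_abundances(table)
    assert summary.n_species_observed == 300
    assert sum(c for _, c in summary.octave_histogram) == 300
    truncated = summarize_abundances(table, top_k=120)
    assert truncated.n_species_observed == 120


def test_compare_abundances_detects_shift():
    a = generate_synthetic_census(200, 3.0, 1.0, seed=1)
    b = generate_synthetic_census(200, 6.0, 1.0, seed=2)
    same = compare_abundances(a, generate_synthetic_census(200, 3.0, 1.0, seed=3))
    diff = compare_abundances(a, b)
    assert diff.pvalue < 1e-6
    assert same.pvalue > 0.01


def test_abundance_table_validation():
    with pytest.raises(ValueError):
        AbundanceTable(labels=["a"], counts=np.array([0]))  # no positive count
    with pytest.raises(ValueError):
        AbundanceTable(labels=["a", "b"], counts=np.array([1]))
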