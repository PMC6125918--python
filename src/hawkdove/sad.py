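"""Species abundance distributions: construction, fitting, comparison.

Equilibrium states of the multi-game community are turned into
census-style abundance tables, binned into Preston octaves, fitted by a
lognormal (the distribution that emerges from the model's random products
of per-game equilibrium frequencies, just as random sums give a normal),
and screened for multimodality, which arises when the resource values V
themselves are drawn from a multi-modal distribution.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .dynamics import PopulationState
from .game import strategy_label

__all__ = [
    "AbundanceTable",
    "LognormalFit",
    "SADSummary",
    "state_to_abundances",
    "fit_lognormal",
    "octave_histogram",
    "detect_multimodality",
    "read_abundance_table",
    "generate_synthetic_census",
    "summarize_abundances",
    "compare_abundances",
]

SeedLike = Union[int, None, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class AbundanceTable:
    """Labelled integer counts, one species per row."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        if len(self.labels) != counts.size:
            raise ValueError("labels and counts must have equal length")
        if counts.size < 1 or np.any(counts < 0):
            raise ValueError("counts must be nonnegative and non-empty")
        if counts.max() == 0:
            raise ValueError("at least one count must be positive")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_species(self) -> int:
        return len(self.labels)

    @property
    def n_observed(self) -> int:
        """Species with a strictly positive count."""
        return int(np.sum(self.counts > 0))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def positive_counts(self) -> np.ndarray:
        return self.counts[self.counts > 0]

    def to_csv(self, path, sep: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=sep)
            w.writerow(["species", "count"])
            for lab, c in zip(self.labels, self.counts):
                w.writerow([lab, int(c)])


def state_to_abundances(
    state: PopulationState,
    community_size: int,
    labels: Optional[Sequence[str]] = None,
) -> AbundanceTable:
    """Scale model frequencies to a census of ``community_size`` individuals.

    Counts are rounded per species, so the total can differ from
    ``community_size`` by at most half the number of species.  Species that
    round to zero are kept with count 0 (observed richness is the number of
    positive counts).
    """
    if community_size < 1:
        raise ValueError("community_size must be >= 1")
    if labels is None:
        N = state.N
        labels = [strategy_label(j, N) for j in range(state.n_strategies)]
    counts = np.rint(state.pi * community_size).astype(np.int64)
    return AbundanceTable(labels=list(labels), counts=counts)


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood normal fit to log abundances."""

    log_mean: float
    log_sd: float
    statistic: float  # Lilliefors (KS with estimated parameters)
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "log_mean": self.log_mean,
            "log_sd": self.log_sd,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
        }


def fit_lognormal(values) -> LognormalFit:
    """Fit a lognormal to positive abundances and test the fit.

    The ML estimates are the mean and (biased, ML) standard deviation of
    the natural logs.  Goodness of fit is the Lilliefors statistic — the
    Kolmogorov-Smirnov distance to a normal whose parameters were
    estimated from the same sample, the standard check when comparing an
    empirical abundance distribution to a fitted lognormal.
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size < 3:
        raise ValueError("need at least 3 positive values to fit")
    logs = np.log(v)
    mu = float(logs.mean())
    sd = float(logs.std(ddof=0))
    if sd == 0.0:
        return LognormalFit(mu, 0.0, np.nan, np.nan, int(v.size))
    stat, p = lilliefors(logs, dist="norm")
    return LognormalFit(mu, sd, float(stat), float(p), int(v.size))


def octave_histogram(counts) -> list[tuple[int, int]]:
    """Preston octave histogram: bin b holds ``2**b <= count < 2**(b+1)``.

    Returns ``(lower_bound, n_species)`` pairs for every octave from 0 up
    to the octave of the most abundant species (empty octaves included),
    so the counts always sum to the number of species.
    """
    c = np.asarray(counts)
    if c.size == 0 or np.any(c <= 0):
        raise ValueError("octave binning needs strictly positive counts")
    octaves = np.floor(np.log2(c)).astype(int)
    top = int(octaves.max())
    return [(2**b, int(np.sum(octaves == b))) for b in range(top + 1)]


def detect_multimodality(log_values, grid_size: int = 512) -> int:
    """Count modes of a Gaussian KDE of the log abundances.

    Uses Silverman's bandwidth rule, so the mode count is a deterministic
    function of the input sample.
    """
    x = np.asarray(log_values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 values for mode detection")
    if np.ptp(x) == 0.0:
        return 1
    kde = stats.gaussian_kde(x, bw_method="silverman")
    span = 0.15 * np.ptp(x)
    grid = np.linspace(x.min() - span, x.max() + span, grid_size)
    d = kde(grid)
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    return int(np.sum(interior))


def read_abundance_table(path, format: str = "csv") -> AbundanceTable:
    """Read a two-column (species, count) table.

    A header row is detected automatically when the second field of the
    first row is not numeric.  Malformed rows, negative counts and empty
    files each raise a distinct error message.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"format must be 'csv' or 'tsv', got {format!r}")
    sep = "," if format == "csv" else "\t"
    text = Path(path).read_text()
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=sep) if r]
    if not rows:
        raise ValueError(f"abundance table {path} is empty")

    def parse_count(fieldtext: str):
        try:
            x = float(fieldtext)
        except ValueError:
            return None
        if x != int(x):
            return None
        return int(x)

    def looks_numeric(fieldtext: str) -> bool:
        try:
            float(fieldtext)
        except ValueError:
            return False
        return True

    start = 0
    if len(rows[0]) >= 2 and not looks_numeric(rows[0][1]):
        start = 1  # header
        if len(rows) == 1:
            raise ValueError(f"abundance table {path} has a header but no data")
    labels, counts = [], []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) != 2:
            raise ValueError(f"malformed row {i}: expected 2 fields, got {len(row)}")
        c = parse_count(row[1])
        if c is None:
            raise ValueError(f"malformed row {i}: count {row[1]!r} is not an integer")
        if c < 0:
            raise ValueError(f"negative count {c} for species {row[0]!r} (row {i})")
        labels.append(row[0])
        counts.append(c)
    return AbundanceTable(labels=labels, counts=np.array(counts, dtype=np.int64))


def generate_synthetic_census(
    n_species: int,
    log_mean: float = 3.0,
    log_sd: float = 1.5,
    seed: SeedLike = None,
) -> AbundanceTable:
    """Synthetic lognormal census emulating field abundance tables.

    Counts are rounded lognormal draws with a floor of one individual —
    roughly the shape of large forest or plankton censuses of a few
    hundred species — for tests and demos only; no real census ships with
    the package.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=log_mean, sigma=log_sd, size=n_species)
    counts = np.maximum(1, np.rint(draws)).astype(np.int64)
    labels = [f"sp{i + 1:04d}" for i in range(n_species)]
    return AbundanceTable(labels=labels, counts=counts)


@dataclass(frozen=True)
class SADSummary:
    n_species_observed: int
    log_mean: float
    log_sd: float
    octave_histogram: list[tuple[int, int]]
    modes: Optional[int]

    def to_dict(self) -> dict:
        return {
            "n_species_observed": self.n_species_observed,
            "log_mean": self.log_mean,
            "log_sd": self.log_sd,
            "octave_histogram": [[int(b), int(c)] for b, c in self.octave_histogram],
            "modes": self.modes,
        }


def summarize_abundances(table: AbundanceTable, top_k: Optional[int] = None) -> SADSummary:
    """Octave histogram, log-moments and mode count of a census.

    ``top_k`` truncates to the most abundant species before summarizing
    (presentation cut-off for very rich communities).
    """
    pos = np.sort(table.positive_counts())[::-1]
    if top_k is not None:
        pos = pos[:top_k]
    logs = np.log(pos.astype(float))
    modes = detect_multimodality(logs) if pos.size >= 10 else None
    return SADSummary(
        n_species_observed=int(pos.size),
        log_mean=float(logs.mean()),
        log_sd=float(logs.std(ddof=0)),
        octave_histogram=octave_histogram(pos),
        modes=modes,
    )


def compare_abundances(model: AbundanceTable, empirical: AbundanceTable):
    """Rank-based two-sample comparison of log abundances.

    Mann-Whitney U on the positive counts of the two tables (ranks are
    invariant under the log transform); returns the scipy result object
    with ``statistic`` and ``pvalue``.
    """
    return stats.mannwhitneyu(
        model.positive_counts(), empirical.positive_counts(), alternative="two-sided"
    )
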