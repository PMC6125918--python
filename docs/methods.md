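# Methods

## The model

A community is built from `N` independent hawk-dove micro games, one per
limiting resource (light, nitrogen, a niche axis...).  Micro game `k` has a
resource value `V_k` and a fight cost `C_k`, constrained to `C_k > V_k > 0`
so the single game has the classical interior mixed equilibrium with hawks
at frequency `p_k = V_k / C_k`.  The per-encounter payoffs in one game are

|            | other hawk      | other dove |
|------------|-----------------|------------|
| self hawk  | `(V - C) / 2`   | `V`        |
| self dove  | `0`             | `V / 2`    |

A *macro strategy* commits to hawk or dove in every game; there are `2**N`
of them, encoded as bitmasks (bit `k` set = hawk in game `k`), and each is
identified with a species.  Payoffs are additive across games, and
individuals mix randomly, so the expected fitness of species `j` is
`f_j = (A pi)_j` where `A` is the summed payoff matrix and `pi` the vector
of species frequencies.  Frequencies evolve by the deterministic
continuous-time replicator equation `dpi_j/dt = pi_j (f_j - fbar)`.

Because fitness depends on the composition only through the `N` hawk
marginals, the equilibrium conditions are the `N` marginal equations
`p_k(pi) = V_k / C_k` plus normalization: `N + 1` linear constraints on
`2**N` unknowns.  The equilibria form a hyperplane of dimension
`2**N - N - 1` that is attracting transversally and neutral within — the
combinatorial coexistence mechanism: a handful of resources supports
exponentially many species, and which point of the hyperplane is reached
depends on the initial composition.  The quantities that encode that
dependence are the cross-ratios `(pi_a pi_d)/(pi_b pi_c)` over pairs of
games (Wright-manifold invariants of additive multi-game replicator
dynamics), which the integrator conserves to ~1e-13 relative and the test
suite checks to 1e-6.  From any product-form initial condition (including
the equal vector) all cross-ratios equal 1 and the reached equilibrium is
the product state `pi_j = prod_k p_k^{b_jk} (1 - p_k)^{1 - b_jk}`.

## Parameters and defaults

- `V_k ~ Uniform(1, 1.9)` i.i.d. and `C_k = 2` for every game: the
  abundance-pattern experiments' conditions (N=8, giving 256 species, the
  smallest community covering a ~200-species census; a 512-species variant
  uses N=9 with V up to 1.99).  `C` is a free per-game parameter
  everywhere; only `V` is sampled because with a common cost the marginals
  `V_k/2` already span (0.5, 0.95).
- Initial states: `uniform_random` (i.i.d. U(0,1), normalized — the
  default), `gaussian` (half-normal magnitudes, normalized; the mapping of
  a Gaussian onto the simplex is a package choice), `product` (given
  marginals), `equal`.
- Integration: the replicator ODE in log coordinates `y = log pi`
  (`dy_j/dt = f_j - fbar`), which preserves positivity exactly and keeps
  tiny frequencies accurate on the log scale the abundance analyses use;
  DOP853 with `rtol=1e-10`, `atol=1e-12`, renormalized at chunk
  boundaries (drift per chunk is at the 1e-15 level).  Strategies starting
  at exactly zero stay at zero: simplex faces are invariant, and the
  integrator restricts itself to the support.
- Convergence: `max_j |pi_j (f_j - fbar)| < tol`, default `tol = 1e-10`,
  `t_max = 1e6` time units (typical convergence time is ~100-300 units
  because the hyperplane is strongly attracting).  At convergence each
  species' fitness is within `tol / pi_j` of the mean.
- Seeding: every battery takes one root seed; replicate streams are
  spawned from it with `numpy.random.SeedSequence.spawn`, so each
  replicate is independently reproducible and adding replicates never
  perturbs earlier ones.

## Experiment batteries

**Paired runs** (default N=8, 100 pairs).  Each pair shares a fresh V draw
but uses two independent uniform-random starts; both runs are integrated
to equilibrium and the Pearson correlation of `log pi` across the 256
species is recorded, along with the mean, SD, a normal 95% CI and the
fraction of pairs at or above 0.83 (the correlation reported between real
tree communities on different continents' plots).  The shared V fixes the
product-form backbone of the equilibrium; the independent starts move the
endpoints within the neutral hyperplane, so the correlation measures
environment versus drift.

**Perturbation/recovery** (default N=3, 600 replicates, half of one
randomly chosen species removed).  Culling a species leaves it the only
strategy favoured in *all* its micro games, so its fitness tops the
fitness vector (negative density dependence); it recovers to strictly
between the culled and the original level — partial, because the cull also
moved the cross-ratios, selecting a different point of the hyperplane.

**Invasibility** (default N=3, 600 replicates, reintroduction at 0.01).
Removal followed by re-equilibration lets the remaining `2**N - 1` species
reoccupy the hyperplane; every composition there equalizes fitness across
*all* strategies — including the absent one — so the returning species
has no advantage, and the act of reintroduction tips every marginal
against it: it declines, instantaneously (fitness below the mean) and
asymptotically (final prevalence below 0.01).  Both criteria must agree or
the replicate is flagged ambiguous.  This argument requires the remaining
species to be able to realize the marginals at all: removal of the
all-hawk species is coverable only when `sum_k V_k/C_k <= N - 1`.  The
battery therefore defaults to `v_max = C (N-1) / N` (4/3 at N=3, C=2),
the *coverable-removal regime*, where reintroduction fails in every
replicate and the focal species' prior equilibrium share is 0.124 ± 0.072
(mean 1/8 by exchangeability over the randomly chosen focal species).
With V sampled up to 1.9 instead, ~10% of removals (concentrated on the
all-hawk and two-hawk species) are uncoverable; the community then
re-equilibrates *off* the hyperplane with the vacated niche unfilled and
the reintroduced species genuinely invades — a distinct regime, reachable
via `--vmax`, in which the invasibility test is informative again.

**Robustness** (default N=4, coverable-regime V).  The payoff matrix is
perturbed to `A + eps R` with `R` i.i.d. standard normal, which destroys
additivity and with it the neutral hyperplane; diversity (species above an
extinction threshold, default 1e-8) then erodes over a 1e4-unit horizon.
Adding a self-inhibition term — strategy `j`'s fitness reduced by
`delta * pi_j`, e.g. a species-specific pathogen — restores a stable
interior equilibrium.  Defaults `eps = 0.01 * mean(V)` and
`delta = 0.5 * mean(V)`: the symmetrized random matrix destabilizes
neutral directions at rate ~`eps * sqrt(2S)` (`S = 2**N` species), and
displaces the interior equilibrium additively by ~`(eps/delta) |R pi|`,
which must stay below the rarest species' abundance (at least `(1/3)**N`
in the coverable regime) for full retention; `delta/eps = 50` satisfies
both with margin for communities up to a few dozen species.  Note the
self-inhibition coefficient multiplies a frequency, so its fitness effect
is of order `delta / S` — small against payoffs of order `V`.

## Species abundance distributions

Equilibrium frequencies are scaled to censuses by per-species rounding
(species rounding to zero are kept, observed richness counts positives).
Log abundances are summarized by their ML normal fit; goodness of fit is
the Lilliefors statistic (Kolmogorov-Smirnov against a normal with
estimated parameters), the standard check when the lognormal's parameters
come from the same sample.  The lognormal shape itself is the model's
central limit: `log pi_j` is a sum of `N` per-game terms, so random
products converge to lognormals as random sums do to normals.  At N=8
with V ~ U(1, 1.9) the fit is accepted at the 1% level in ~49 of 50 runs
(more powerful shape tests such as Shapiro-Wilk accept ~75-80%, as they
resolve the residual 8-term discreteness of the sum).  Octave histograms
use Preston's log2 bins `2**b <= count < 2**(b+1)`.  Mode counting uses a
Gaussian KDE with Silverman's bandwidth on a fixed 512-point grid, hence
deterministic; drawing V from the two-point set {1.05, 1.9} (three
contested, five near-neutral resources) yields >= 2 modes robustly,
because the contested games contribute log-abundance increments of
+-log(0.95/0.05)/2 that separate the species into clusters by their hawk
count on the contested resources.

## Synthetic censuses

`generate_synthetic_census` emulates field abundance tables (a few hundred
species, lognormal counts, minimum one individual) for tests and demos.
It reproduces the marginal count distribution only: no spatial structure,
sampling effort, detection bias, or taxonomic error.  Tests that pass
against it show the pipeline arithmetic is right, not that the model fits
any particular real census; comparisons to real data require a
user-supplied two-column table.

## Numerical and design notes

- Probabilities are never clipped during integration; a 1e-300 floor is
  applied before logs purely as an overflow guard (replicator dynamics
  preserve positivity, so it never binds).
- The convergence tolerance, `t_max`, and the log-coordinate integrator
  are package choices; equivalence with other replicator integration
  schemes holds at the level of equilibria (and of the conserved
  cross-ratios), not of time parameterizations.
- `fit_lognormal` on constant data returns `log_sd = 0` with a NaN test
  statistic (no spread to test).
- Degenerate requests fail loudly: perturbing a species below 1e-10
  prevalence, reintroduction levels outside (0,1), `N > 16` dense payoff
  matrices without an explicit override.
- Batteries report problem sizes alongside results; the shipped defaults
  (100 pairs at N=8, 600 replicates at N=3, robustness at N=4) match the
  experiment designs above and run in a few minutes on one CPU.

## Known limitations

- Deterministic, fully mixed, fixed species pool: no demographic noise,
  speciation, immigration, or spatial structure by design.
- The coverable-removal bound `v_max = C (N-1)/N` is the exact condition
  only for the all-hawk/all-dove removals; intermediate species impose
  weaker conditions, so the default is conservative.
- Payoff-perturbation robustness is demonstrated, not characterized: the
  collapse rate's dependence on `eps`, `S` and the spectrum of `R` is
  outside scope.
- Empirical comparison is rank-based (Mann-Whitney on log abundances);
  no binned-likelihood model competition is implemented.
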