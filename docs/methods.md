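# Methods

`neutralassembly` tests whether microbial communities — OTU tables of 16S
read counts, samples × taxa — are assembled by stochastic neutral dynamics
or by deterministic (niche / host) filtering, at two complementary scales:
whole communities under Hubbell's discrete neutral theory, and individual
species under Sloan's continuous neutral model.

## Community scale: the Etienne sampling formula

### Model

Hubbell's neutral theory treats all individuals of all species as
demographically equivalent. A local community of `J` individuals is
assembled by a death–replacement process coupled to an infinite
metacommunity: each vacancy is filled by an immigrant with probability `m`
(equivalently through the immigration parameter `I = m (J−1)/(1−m)`),
otherwise by local reproduction; metacommunity diversity is governed by the
fundamental biodiversity number `θ`. The probability of observing a
species-abundance distribution `D = (n_1, …, n_S)` is the Etienne sampling
formula

    P(D | θ, m, J) = J! / (∏_i n_i ∏_j φ_j!) · θ^S / (I)_J
                     · Σ_{A=S}^{J} K(D, A) I^A / (θ)_A

with `(x)_n` the rising factorial, `A` the number of immigrant ancestors,
`φ_j` the number of species with abundance `j`, and

    K(D, A) = Σ_{a_1+…+a_S = A} ∏_i s̄(n_i, a_i) s̄(a_i, 1) / s̄(n_i, 1),

where `s̄(n, a)` are unsigned Stirling numbers of the first kind and
`s̄(n, 1) = (n−1)!`.

### Numerics

All arithmetic is in log space. The Stirling triangle is built by the
recurrence `s̄(n+1, a) = n s̄(n, a) + s̄(n, a−1)` with `logaddexp`, cached
process-wide, rows grown lazily to the largest abundance seen. `log K(D, ·)`
is computed by sequentially convolving the per-species log-weight vectors
`w_i(a) = s̄(n_i, a)(a−1)!/(n_i−1)!`, `a = 1…n_i`, with log-sum-exp;
singleton species only shift the ancestor count and are skipped, and species
are processed in ascending abundance to keep the running vector short. This
is the only numerically stable polynomial-time route we know of; the raw
terms overflow doubles already at `J` of a few hundred. Rising factorials
are log-gamma differences. Correctness is pinned by three independent
oracles in the test suite: exact rational brute-force enumeration over
ancestor configurations (small `J`), conservation of probability over all
partitions of `J ≤ 8`, and the closed-form Ewens sampling formula in the
`I → ∞` limit (relative error < 1e−5 at `I = 1e9`).

### Maximum likelihood

`EtienneModel.fit` maximizes the log-likelihood over `(log θ, logit m)` by
Nelder–Mead from a 4×4 start grid, `θ ∈ {5, 20, 80, 320}` ×
`m ∈ {0.1, 0.5, 0.9, 0.999}`, tolerance 1e−6 on the log-likelihood. The
surface has a well-known ridge trading `θ` against `m` — single-sample
estimates of `θ` are stable only in the median over replicate communities,
and occasional fits run far along the ridge; the multi-start grid guards
against the worst traps. `log K(D, ·)` is computed once per community, so a
parameter evaluation is O(J) and a full fit takes a fraction of a second at
`J ≈ 1000`. Communities with `S = 1` or `S = J` lie on the parameter
boundary; they are fitted anyway, flagged `converged_ = False`, with a
warning.

### The exact neutrality test

For each sample: fit `(θ̂, m̂)`; simulate `n_sim = 100` communities at
`(θ̂, Î, J)` by the sequential construction (urn) scheme; evaluate every
simulated community's log-likelihood at the same `(θ̂, Î)`; set
`log L0` = the observed sample's maximized log-likelihood and `log L1` = the
mean of the simulated log-likelihoods (the log geometric-mean likelihood —
the arithmetic-mean alternative is also recorded, but it is dominated by the
single most likely simulation); form the deviation

    q = −2 [log L0 − log L1]

and score it against the upper tail of χ²(df = 1). The community passes
(is judged neutral) when `p > 0.05`.

Design choices that were genuinely open, and why we settled them this way:

- **No refit per simulation.** Simulated communities are evaluated at the
  parameters fitted to the observed sample. Refitting all 100 simulations
  costs ~100× and, measured on neutral data, makes calibration *worse*
  (pass rate 0.48 vs 0.85): the per-simulation maximization adds spread
  without removing the bias.
- **Signed, one-sided statistic.** `q` is used with its sign: the test
  rejects only when the observed sample is atypically *unlikely* under its
  own fitted neutral model (`log L1 ≫ log L0`), and `p = 1` when
  `log L0 ≥ log L1`. A two-sided `|q|` variant is available
  (`two_sided=True`) but is anti-conservative on genuinely neutral data
  (pass rate 0.57 measured at θ=30, m=0.9, J=1000, against 0.85 for the
  one-sided default): because `log L0` is a maximized likelihood it
  typically exceeds `log L1` by about one unit, and the per-sample
  log-likelihood has an intrinsic spread of ~2.6 — wider than the χ²(1)
  scale — so the harmless "more likely than its replicates" side alone
  pushes many neutral communities past the two-sided threshold.
- **χ²(1) is a heuristic.** The statistic is not a classical likelihood
  ratio between nested models; the χ² reference is applied as prescribed by
  the test's operational definition. The one-sided version is mildly
  anti-conservative (~15% rejection of neutral communities at the 5% level
  in our calibration) — acceptable as a screening test, and the simulated
  log-likelihoods are returned so users can substitute an empirical
  reference distribution.

### What the one-sided test cannot see (known limitation)

Deviations can land on either side. Communities assembled by *mixing or
roughening* processes (e.g. host filtering producing excess dominance, the
typical real-gut signature) are atypically unlikely — `log L1 ≫ log L0` —
and are caught. Communities that are *more compressible* than neutral draws
are not: multinomial samples from one fixed composition (our niche
generator's construction, metacommunity tilted by a per-sample lognormal
selection factor) condition away the metacommunity sampling variance and
sit on the `log L0 ≫ log L1` side, where the one-sided test never rejects.
Against that alternative the two-sided variant has power (0.73 at selection
strength 2, J = 1000) at the cost of calibration, and the Sloan species
test detects it cleanly (see below). Choose the variant to match the
alternative you care about.

## Species scale: Sloan's neutral community model

### Model

One species with relative abundance `p_i` in a source community; a
destination community of `N_T` individuals (operationally: the rounded mean
reads per destination sample). Per death, the replacement is an immigrant
with probability `m`. The abundance of the species is a birth–death chain
with the transition probabilities given in the module docstring; the stay
probability is computed as the complement of the up and down moves, so
the three probabilities sum to one exactly for every state. At stationarity the relative
abundance is approximately `Beta(N_T m p_i, N_T m (1−p_i))`; the package
also provides the chain's *exact* stationary law by detailed balance, which
the tests use as an oracle (the beta law is its diffusion approximation;
sup-CDF distance ≈ 0.005 at `N_T = 200, m = 0.1, p = 0.3`).

### Fitting and classification

A species is *detected* in a sample when its relative read abundance
exceeds a threshold `d`; default `d = 1/N_T`, one read at average depth
(the detection notion is operational and exposed as a knob). Then:

1. `p_i` = mean relative abundance over source samples; `x_i` = fraction of
   the `N` destination samples where species `i` is detected.
2. Predicted occurrence `F_i(m) = 1 − BetaCDF(d; N_T m p_i, N_T m (1−p_i))`;
   `m̂` minimizes `Σ_i (x_i − F_i(m))²` by bounded scalar minimization on
   `(0, 1)` (tolerance 1e−6; the objective is one-dimensional and smooth).
   `R² = 1 − SS_res/SS_tot` measures goodness of fit; `R² ≥ 0.5` is the
   conventional pass threshold for the model as a whole, and `R²` is NaN
   (with a warning) when all `x_i` are equal.
3. Each species gets a 95% binomial interval around `F_i(m̂)` for `N`
   samples — Wilson score by default, Clopper–Pearson (`interval="exact"`)
   optionally; no analytic interval recipe is canonical for this model
   family, and the Wilson score is the established practice. Species are
   classified `above` / `neutral` / `below` by interval membership; the
   classification is total and exclusive.

Sources with `p_i = 0` or `1` are handled as the beta law's degenerate
limits (`F_i = 0` or `1`). Taxa absent from both sample sets are dropped.

### Balanced resampling

Group comparisons draw `n_per_group = 50` source and destination samples
per repeat (same draw serves both roles in a same-group design), repeat 30
times, and report means and SDs over repeats; per-repeat seeds are
`seed + repeat`. Groups smaller than the draw are resampled with
replacement and flagged. An unpaired t-test on per-repeat neutral
percentages compares designs.

## Synthetic data

The generators emulate the structure of a two-group gut-microbiome study:
2 groups × 30 samples (defaults), per-sample depth `J = 1000` with ±50%
uniform variation, and a log-series metacommunity drawn by a Hoppe urn at
`θ = 30` over 1e5 individuals (a few hundred taxa) — sample sizes, depths
and richness in the ranges typical of 454-era 16S surveys. Default
migration is `m = 0.15`, in the range reported for host-associated
communities. Three regimes:

- `etienne_neutral` — dispersal-limited urn draws with immigrants from the
  shared metacommunity: positive control for the community test. Note the
  samples are conditioned on one realized metacommunity, a slightly
  "too typical" regime for the exact test's lower tail; the calibration
  experiments therefore use the unconditional sequential-construction
  simulator directly.
- `sloan_neutral` — per-taxon beta draws (stationary law) renormalized and
  read-sampled multinomially: positive control for the species test. The
  multinomial read step is not part of Sloan's continuous model; at default
  depths it biases `m̂` by only a few percent (well inside the ±25%
  recovery tolerance verified in the tests).
- `niche` — per-sample weights `p_i · exp(s · z_i · e_s)` with fixed taxon
  responses `z_i ~ N(0,1)`, sample environments `e_s ~ N(0,1)` and
  selection strength `s`, plus an optional multiplicative group effect on a
  random taxon subset (a crude Firmicutes/Bacteroidetes-style shift).
  `s = 0` with no group effect reduces exactly to multinomial sampling of
  the metacommunity.

What passing tests on these data do **not** show: real 16S data carry
compositional artifacts, chimeras, depth-dependent detection and taxon
correlations none of which are modeled; the niche generator produces
lognormal tilts, not the full range of deterministic assembly. Recovery and
calibration results are statements about the models' own data-generating
assumptions.

## Problem sizes and determinism

Calibration experiments in the tests and the acceptance script use 100
communities at `J = 1000` (community scale) and 50 samples × ~200 taxa at
`J = 1000` (species scale) — large enough for stable rates, small enough to
run on a laptop in minutes. Every random quantity flows from an explicit
seed through `numpy.random.default_rng` / `SeedSequence`; identical config
and seed give byte-identical pipeline reports (reports embed a config hash
and no timestamps). The chain-stationarity check thins the trajectory at
five relaxation times (`5 N_T/m` steps) so the KS test sees effectively
independent draws, and maps lattice states to the unit interval with a
half-step continuity correction.
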