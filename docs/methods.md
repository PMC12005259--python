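# Methods

## Model

A haploid asexual population of constant size `N` carries one non-recombining
block of `L` biallelic sites with additive allelic effects scaled to 0 (`−`)
and 1 (`+`), so a haplotype's genotypic value is its `+` count,
`z = n₊ = L − n₋`.  Fitness is Gaussian, `W(z) = exp[−s(z−θS)²]`, with `s`
the selection strength per squared phenotypic unit (`s = 1/(2Vs)` in the
standard quantitative-genetic parameterization; environmental noise is
absorbed into `s`).  Sites mutate reversibly at per-site rates `u10`
(`+ → −`) and `u01 = β·u10` with bias `β ∈ (0,1]`; the trait mean expected
under mutation and drift alone is `θN = Lβ/(1+β)`.  Because the block never
recombines and equal-effect sites are exchangeable, the population state
reduces to counts over the `L+1` haplotype classes.  Diploid results follow
by substituting `2N`.

Each generation applies, in fixed order,

1. **mutation** — deterministic expected flux on class frequencies: class
   `z` sends `z·u10` of its frequency to `z−1` and `(L−z)·u01` to `z+1`.
   This is first-order (double mutants within a generation ignored), valid
   under the enforced constraint `L·u10 ≤ 0.1`; whether mutation should
   instead be drawn stochastically per class is isolated behind the
   `mutation_step` interface, and at these rates the difference is absorbed
   by the multinomial drift step one line later;
2. **selection** — reweighting by `W(z)`, normalized by mean fitness.  When
   `s·max(z−θS)²` exceeds ~600 the weights are applied relative to the
   fittest occupied class each generation (log-domain shift), so sharp
   optima do not underflow while mass is still far away;
3. **drift** — a single multinomial draw of `N` individuals.

Drift is therefore the only stochastic step, and a run is bit-reproducible
from its 64-bit seed (numpy PCG64).

**Initialization.** Runs start monomorphic at the class nearest `θN`
(configurable to all-`−`/all-`+` for edge-optimum studies).  This choice
minimizes burn-in transients; a first-half/second-half stationarity
diagnostic (3 combined block-bootstrap SEs) guards the shortened desk-scale
burn-ins described below.

**Neutral marker.** A biallelic neutral locus with symmetric mutation rate
`μ` (default `u10`) doubles the class state; it has no fitness effect and is
dragged through the same joint multinomial drift, so its heterozygosity
`2p(1−p)` reflects the coalescent effective size felt by linked neutral
variation.  The marker starts at frequency ½; the drift timescale `~N` is
far shorter than any burn-in used, so the start point is immaterial.

**Several site-effect classes.** When sites split into classes
`(L_x, s_x)` (ordered by decreasing `s_x`), the state becomes a sparse map
over per-class `+` counts and selection acts on the performance score
`P = Σ n_x (s_x/s_1)` through `W = exp[−s_1(P−θ_P)²]`.  This fitness form is
an interpretation chosen so a one-unit performance deficit costs `≈ s_1`
near the optimum, reducing exactly to the single-type model when one class
is present (a single-class scheme delegates to the single-type engine).

## Parameter choices

- **Mutation-rate scaling.** `u10 = c·N^(−γ)` with defaults `c = 0.0011`,
  `γ = 0.76`, reflecting the empirical negative scaling of per-site mutation
  rates with (coalescent) population size; `N·u10` then rises from ~0.01 at
  `N = 10⁴` to ~0.108 at `N = 2×10⁸`.  (The alternative anchor of `10⁻⁷` at
  `N = 10⁴` sometimes quoted for this scaling is inconsistent with the
  `c, γ` pair, which evaluates to `1.0×10⁻⁶` there; the pair is used because
  it reproduces the stated `Nu10` range, and both constants are arguments.)
- **Rescaling.** Large-`N` scenarios are reduced to `N' ≥ 1000` holding
  `Nu10`, `Nu01`, `Ns` fixed, subject to `s ≤ 0.1` and `L·u10 ≤ 0.1`; the
  stationary behavior depends on the products, and the reduction factor is
  the largest admissible one.
- **Schedules.** The conservative defaults are burn-in `1000·N` generations
  and assays every `N/10` (the "paper" preset scale).  Desk-scale presets —
  the sizes used by the test suite and the acceptance script — burn in for
  `100·N'` generations from the `θN` start and sample every 10 generations.
  Time averages are unbiased under autocorrelation; the denser schedule just
  buys more samples per wall-clock unit, and Monte-Carlo errors are always
  quoted from block bootstraps with blocks spanning several mixing times
  (the mean-phenotype mixing time is roughly the class-substitution time,
  `~1/(L·u10)` generations when drift matters, `~1/s` when selection is
  near-deterministic; per-cell budgets are set from these, e.g. 10⁷
  generations for the slowest `L = 10, Ns = 1` cell).

## Analytic layer

All printed steady-state results are implemented as stated, with two
documented subtleties:

- **κ conventions.**  The variance ratio `κ = σN²/σS²` enters the Gaussian
  approximation `μ(z̄) = (κθS+θN)/(κ+1)`, `σ²(z̄) = σN²/(κ+1)`.  The no-bias
  narrative value is `κ ≈ 2NLs` ("unbiased" convention, used on the
  weak-selection MAD pathway `|δ̄|₁ = √(L/π(2NLs+1))`), while the printed
  biased-mutation deviations require `κ = 4NesLβ/(1+β)²` with
  `σN² = Lβ/(1+β)²`, `σS² = 1/(4Nes)` ("biased" convention — `NesL` at
  `β = 1`, a factor-2 tension).  Both are implemented and named; each
  downstream formula uses the convention under which it was printed, and the
  discrepancy is surfaced rather than reconciled.
- **Folded-normal MAD.**  When the distribution of means overlaps the
  optimum (within ~2 SD, a configurable threshold), the mean absolute
  deviation is computed as `E|X−θS|` for
  `X ~ Normal(μ(z̄), σ²(z̄))` — the natural formalization of separately
  evaluating deviations above and below the optimum; it is labelled an
  interpretation.

The exact stationary law `Φs(z) = C·Φn(z)·W(z)^{2Ne}`, with `Φn` the
binomial `(L, β/(1+β))`, keeps the `2Ne` exponent as printed (including for
haploids) and is evaluated in the log domain so `2Nes` up to 10⁶ is safe.

**φ inference.**  `Ne` is defined operationally: the population size at
which a predictor reproduces the observed deviation of means.  Two
inversions are provided, both closed-form:

- `method="mean"` solves the general-optimum signed deviation
  `θS − μ(z̄) = L(1+β)[x(1+β)−β]/(4NesLβ+(1+β)²)` for `Ne` (valid whenever
  `θS > θN`, including the half-Gaussian `x = 1`);
- `method="mad"` solves the blended MAD with `Ne` substituted only inside
  the variance-ratio term `|δ̄|₁` and census `N` kept elsewhere, for the
  no-bias interior optimum.

Inversion uses the raw observed deviation (fixation plus segregating
components together), matching the operational definition; no segregating
correction is pre-subtracted.  An observed MAD below the predictor's
large-`Ne` floor means the cell shows less deviation than the theory allows
at any effective size — no interference signal — and is reported as
`φ = ∞` and excluded from minima; this occurs where `Ns` is well beyond
`L/20` and the MAD is dominated by the `Ne`-independent mutation load, i.e.
exactly where the weak-selection formula is documented not to apply.  Where
the Gaussian spread `σ(z̄)` falls below one class spacing, the continuous
approximation overestimates the discrete MAD, and inversion can return
`φ > 1`; this is reported as measured.

## What the studies show (and their limits)

- **No-bias sweep** (`β = 1`, `θS = L/2`, `L ∈ {10,100}`, `Ns ∈ {1,10}`,
  ≥10⁵ sampled means per cell): inverted `φ` of every informative cell stays
  at or above 1 — interference is minimal in this regime, consistent with
  the ~15% bound on `Ne` depression.
- **Neutral-marker depression** (`L = 100`, `Ns = 10`): the marker's
  time-averaged heterozygosity is dominated by rare, long drift excursions
  (it is monomorphic most of the time at `2Nμ ≈ 0.02`), so single runs are
  extremely noisy (SE ≈ 25 percentage points per 10⁶-generation pair).  The
  study pools ≥10 seed-paired replicate pairs and quotes the delta-method SE
  of the pooled ratio across replicates; at that size the depression is
  below ~15% with SE ≈ 6–8 points.
- **Large-block interference** (`L = 1000`, `β = 0.33`, interior optimum):
  interference grows with both `Ns` and the mutation input `L·N·u10`, which
  under the rate scaling rises with census size.  A 2×2 sweep over
  `Ns ∈ {10,30}` and census `N ∈ {10⁶,10⁸}` (each rescaled to `N' = 1000`)
  gives `φ` between ~0.02 and ~0.07; the low-input corner
  (`N = 10⁴`, `Ns = 10`) gives `φ ≈ 0.13`, so the sub-0.1 regime is a
  property of the stronger-input cells, as expected.  `L = 10⁴` blocks are
  beyond desk scale and are not run.
- **Simulator–theory concordance**: at weak per-block mutation
  (`N = 100`, `L = 4`, `Ns = 0.5`, `Nu = 0.025`) rounded sampled means
  follow the exact stationary law.  Consecutive samples are strongly
  autocorrelated, so the chi-square is computed on a thinned subset
  (spacing 5000 generations ≫ the substitution time), with bins of expected
  count <5 merged; a chi-square on the raw autocorrelated sample count
  would reject any model.  Sharper optima (e.g. `Ns = 10` at these sizes)
  concentrate >99.99% of the stationary mass on one class and leave nothing
  for a goodness-of-fit test to resolve.

**What desk scale does not show.**  The rescaled runs preserve `Nu10`,
`Nu01`, `Ns` exactly, but burn-ins of `100·N'` generations and 10⁵–10⁶
sampled generations resolve MADs and `φ` to a few percent at best — far
from the 10⁶–10⁸ assay intervals a cluster-scale study would use — and the
slowest-mixing corners (`L = 10⁴`, extreme bias, `Ns ≈ 1` with tiny
`L·u10`) are out of reach.  The synthetic scenarios also idealize real
data: equal allelic effects within a class, no recombination, no epistasis
beyond that induced by the fitness function, constant `N`, and a
known fitness function — so passing tests validate the implementation and
the printed approximations in their stated domains, not the biology of any
particular trait.

## Numerical notes

- Frequencies are renormalized after every mutation and selection step;
  conservation is enforced to 10⁻¹² in tests, and drift counts sum to `N`
  exactly by construction.
- Ties (`z̄` exactly at `θS`) count toward the "below" side of the
  conditional decomposition — stated for determinism; measure-zero in
  practice.
- Block-bootstrap SEs default to blocks of 50 samples but every study
  overrides the block length to span ≥3 estimated mixing times.
- The composite-bias extremum is located by a 0.005-step grid search plus
  bounded scalar refinement (no closed form is assumed), returning
  `β = 1/3` to 10⁻⁶.
- `φ` estimates propagate the observed statistic's Monte-Carlo SE through
  the inversion by finite differences; one-sided where a perturbation
  leaves the invertible range.
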