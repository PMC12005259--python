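# driftbarrier

Wright–Fisher simulation and steady-state theory for the divergence of mean
phenotypes under persistent Gaussian selection, in asexual (fully linked)
populations with biased reversible mutation.

## The problem

How far should the mean of a quantitative trait wander from its selective
optimum?  Even under constant stabilizing selection, finite populations drift
around (or away from) the optimum to a degree set by the **drift barrier** —
the point where the fitness gain of further refinement falls below the power
of random genetic drift, ~1/Ne.  For a trait encoded by `L` fully linked
biallelic sites with `+`/`−` allelic effects 1/0, genotypic value
`z = n₊ ∈ {0..L}`, and Gaussian fitness

```
W(z) = exp[−s (z − θS)²]
```

the steady-state distribution of population means depends on `Ns` (selection
vs. drift), `L`, the mutation bias `β = u01/u10`, and where the optimum `θS`
sits relative to the neutral expectation `θN = Lβ/(1+β)`.  Linkage couples
everything: simultaneously segregating mutations interfere, so the effective
size governing divergence, `Ne = φN`, can fall orders of magnitude below the
census size.

The package is aimed at population geneticists who want to simulate this
regime exactly (haplotype-class Wright–Fisher dynamics), evaluate the
analytic approximations against it, and measure `φ` by inversion.

## What it provides

- **`driftbarrier.engine`** — the forward simulator.  The population is a
  count vector over the `L+1` haplotype classes; each generation applies
  deterministic mutation flux between adjacent classes, Gaussian selection
  re-weighting, and one multinomial drift draw.  Variants embed a neutral
  marker (doubling the state) or handle several site-effect classes on a
  sparse state ("performance" scale).  Big-`N` scenarios run after rescaling
  `N` down while holding `Nu10`, `Nu01`, `Ns` fixed.
- **`driftbarrier.theory`** — the analytic layer: the exact stationary
  distribution of quasi-fixed means `Φs(z) ∝ Φn(z)·W(z)^{2Ne}` (a multistate
  Li–Bulmer form) and its mean; Gaussian approximations
  `μ(z̄) = (κθS + θN)/(κ+1)`, `σ²(z̄) = σN²/(κ+1)` with
  `κ = σN²/σS²`; mean-absolute-deviation (MAD) predictors for the
  drift-dominated regime `|δ̄|₁ = √(L/π(2NLs+1))`, the mutation-load regime
  `|δ̄|₂ = Lu10(1+β)/s`, and the blend
  `|δ̄| = |δ̄|₂ + (|δ̄|₁−|δ̄|₂)e^{−2Ns/L}`; half-Gaussian and general-optimum
  deviations; a free-recombination benchmark `(1−ln β)/(4Ns)`; the
  folded-normal MAD; and `estimate_phi`, which solves the predictors for the
  `Ne` that matches an observed deviation.
- **`driftbarrier.summaries`** — MAD, conditional above/below-optimum
  deviations, marker heterozygosity, block-bootstrap Monte-Carlo errors, and
  a stationarity diagnostic.
- **`driftbarrier.studies`** — packaged end-to-end studies (the no-bias φ
  sweep, the neutral-marker depression comparison, the large-block
  interference sweep, simulator-vs-theory concordance).
- **`driftbarrier` CLI** — thin subcommands `simulate`, `theory`, `phi`,
  `sweep`, `presets` over the same library, with TSV/JSON outputs and
  reproducibility manifests.

## Worked example

`examples/03_phi_interference.py` measures selective interference in a large
linked block (`L = 1000`, `β = 0.33`, `Ns = 10`, census `N = 10⁸` rescaled
to 1000):

```
cell: N=1000 (rescaled), s=0.01, u10=9.15e-05, theta_N=248.1, theta_S=500.0
grand mean               499.122
deviation from optimum    0.8780  (Ne=N theory would give 0.0337)
stationarity check     pass
phi = Ne/N                0.0383   (Ne = 38)
```

The population mean settles ~0.88 trait units below the optimum — about 26×
farther than drift at the census size would explain.  Solving the
Gaussian-approximation mean formula for the matching effective size gives
`φ ≈ 0.04`: interference among the linked segregating mutations makes drift
act as if the population were 25-fold smaller.  The other examples cover the
interior-optimum MAD against theory (`01`), the analytic scaling surfaces
(`02`), multi-type performance gradients (`04`), and linked neutral
heterozygosity (`05`); each prints a short interpretation with its numbers.

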