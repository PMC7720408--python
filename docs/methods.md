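# Methods

## The estimation problem

Mendelian randomization (MR) estimates the causal effect of an exposure
on an outcome using genetic variants as instrumental variables. In the
designs this package targets, the instrument–exposure association study
(D₁) and the instrument–outcome association study (D₂) may share any
fraction of their participants: one-sample (full overlap), two-sample
(disjoint) and everything in between. The package treats all of these
as a single one-sample analysis with missing data: individuals observed
in only one study have their unobserved exposures or outcome treated as
extra unknowns and sampled inside the MCMC.

Data are organised into three disjoint groups drawn from one
population:

* **A** — instruments **Z**, exposures **X** and outcome *Y* all observed;
* **B** — **Z** and **X** observed, *Y* missing (exposure study only);
* **C** — **Z** and *Y* observed, **X** missing (outcome study only).

D₁ = A ∪ B and D₂ = A ∪ C; the overlap rate is n_A / (n_A + n_B).

## Structural model

Three instruments, three exposures, one continuous outcome and a scalar
latent confounder U:

    U  ~ N(0, 0.1)                                    (variance)
    X₁ | Z₁, U      ~ N(ω₁ + α₁Z₁ + δ₁U, σ₁²)
    X₂ | Z₂, U      ~ N(ω₂ + α₂Z₂ + δ₂U, σ₂²)
    X₃ | Z₂, Z₃, U  ~ N(ω₃ + α₃Z₂ + α₄Z₃ + δ₃U, σ₃²)
    Y  | X, U       ~ N(ω_Y + β₁X₁ + β₂X₂ + β₃X₃ + δ₄U, σ_Y²)

Z₂ loads on two exposures (horizontal pleiotropy), giving four
instrument-strength parameters α₁..α₄. The β's are the causal effects
of interest. Instruments are assumed mutually independent, with no
direct exposure–exposure edges and no direct Z→Y or Z→U edges (the
standard IV assumptions: relevance, independence of confounders,
exclusion restriction — Z₂ violates exclusion for any single-exposure
analysis, which is why the multivariable model is needed).

U is one latent scalar per individual with *fixed* prior variance 0.1.
Its scale is not identifiable from the likelihood; the δ coefficients
carry the confounding magnitude, and (δ, U) → (−δ, −U) leaves the
likelihood invariant. Post-sampling, each chain's δ draws are aligned
to a positive average loading so multi-chain summaries are comparable;
the β's are unaffected.

## Priors

| parameter | prior | rationale |
|---|---|---|
| β₁..β₃ | N(0, 10²) | diffuse on the estimands |
| α₁..α₄ | N(1, 0.3²) | instrument strengths bounded away from 0 |
| δ₁..δ₄, ω's | N(0, 10²) | weakly informative (δ/ω priors are a package choice; any proper alternative is configurable) |
| σ₁,σ₂,σ₃,σ_Y | Inv-Gamma(3, 2) on the **sd** | literal reading of "priors of the standard deviation parameters"; a variance-scale option (`PriorSpec(sigma_param="variance")`) exists for exact conjugate sampling |
| U_i | N(0, 0.1) | fixed, see above |

Whether the inverse-gamma prior sits on σ or σ² is ambiguous; both are
implemented, the sd scale is the default, and with n = 400 observations
per equation the choice is numerically immaterial (the likelihood
dominates this prior by three orders of magnitude).

## Sampler

Each iteration:

1. **Impute** the missing outcomes of group B and exposures of group C.
2. **Merge** into a complete dataset.
3. **Update** parameters with one sweep of exact Gibbs steps on the
   complete data: the four regression blocks (ω₁,α₁,δ₁), (ω₂,α₂,δ₂),
   (ω₃,α₃,α₄,δ₃) and (ω_Y,β,δ₄) are linear-Gaussian and drawn from
   their exact multivariate-normal full conditionals; each U_i is drawn
   from its exact scalar-normal full conditional with precision
   1/0.1 + Σ_k δ_k²/σ_k² + δ₄²/σ_Y²; each σ is updated by random-walk
   Metropolis on log σ (step 0.15) against the Inv-Gamma-on-sd prior,
   or by an exact inverse-gamma draw when the variance-scale prior is
   selected.

With no missing data step 1 is a no-op and the scheme is a plain
one-sample Gibbs sampler.

### Two imputation schemes

`SamplerConfig.imputation` selects how step 1 draws the missing values:

* **`"full-conditional"` (default).** Y\* ~ N(ω_Y + β·x + δ₄u_i, σ_Y²)
  for group B, and X\* for group C from the Gaussian full conditional
  given (Z, Y, U) — exposure-equation mean plus the outcome-likelihood
  correction, with constant precision diag(1/σ²) + ββ′/σ_Y². Together
  with step 3 this is a valid Gibbs sampler on the joint posterior of
  parameters and missing data — exactly what a joint MCMC fit (e.g. in
  a probabilistic programming language) of the augmented model does.
* **`"literal"`.** Y\* ~ N(ω_Y + β·x, σ_Y²) and
  X\*_k ~ N(ω_k + (α·z)_k, σ_k²): the confounder term is omitted (it has
  zero mean) and the observed Y of group C is not conditioned on.

The literal scheme is *not* the full conditional, and the difference is
not benign: because imputed values carry no confounder signal, the
outcome noise σ_Y absorbs the unexplained δ₄U variation of the imputed
rows, U recovery degrades for all rows, and residual confounding leaks
into β. In our Monte Carlo runs this produces materially biased null
estimates at partial overlap with weak instruments and strong
confounding (mean ≈ 0.11 instead of ≈ 0 at 60% overlap, α = 0.1,
δ = 1, with coverage far below nominal), whereas the full-conditional
scheme reproduces the near-nominal coverage that a correctly specified
joint Bayesian analysis should — and does — show. The default is
therefore the full-conditional scheme; the literal one is kept for
sensitivity analysis.

### Iterations, initialization, intervals

* Defaults: 3000 iterations, 1000 warmup, 1 chain. The posterior is
  low-dimensional and nearly conjugate; mixing is fast (bulk ESS in the
  hundreds within a few hundred retained draws). A multi-chain option
  exists, with split-R̂ and bulk ESS (via ArviZ) computed lazily from
  the retained draws. The replication runs in this repository use 1200
  iterations with 400 warmup, which gives Monte-Carlo error well below
  the tolerances being checked.
* Initialization: β = 0, δ = 0, ω = 0, σ = 1, α at its prior mean 1,
  U = 0; imputations drawn once from the step-1 formulas at these
  values.
* Credible intervals are equal-tailed percentile intervals with linear
  interpolation between order statistics (the common default; HPD is
  not used).
* Degenerate inputs: an empty group skips its imputation step; with
  n_B = n_C = 0 the algorithm reduces to one-sample MCMC; an entirely
  empty dataset is rejected; with zero rows, repeated parameter sweeps
  sample the prior (used as a validation property).

## Classic comparators

* **2SLS** (one-sample, 100% overlap): exposures on (1, Z), then Y on
  (1, X̂), via `statsmodels`' instrumental-variables estimator, with
  classical homoskedastic standard errors (residuals at observed X,
  n − 4 degrees of freedom) and Wald 95% CIs with the normal 1.96
  multiplier (n = 400 makes the t correction immaterial).
* **Multivariable fixed-effect IVW** (otherwise): per-instrument
  summary statistics from simple regressions with intercept — γ̂_jk
  (exposure k on instrument j, group B) and Γ̂_j (Y on instrument j,
  group C) — combined by weighted least squares with weights
  se(Γ̂_j)⁻², covariance (γ̂′Wγ̂)⁻¹. With three instruments and three
  exposures the system is exactly identified and β̂ = γ̂⁻¹Γ̂ regardless
  of the weights. For a partially overlapping design, IVW uses groups B
  and C only: discarding the overlap is what makes it a valid
  two-sample analysis, at an obvious cost in precision. Multivariable
  (not univariable) forms are used because Z₂ is pleiotropic:
  univariable IVW would be misspecified for β₂.

No installed Python package provides multivariable IVW, so it is
implemented directly (a 3×3 weighted least squares); 2SLS and the
summary-statistic regressions go through `statsmodels`/`scipy`.

## Synthetic-data generator

The generator implements the package's simulation study design: a
population of n = 1000 individuals from the structural model, split
without replacement into groups A/B/C with
n_A = round(rate · 400) (half-to-even; every study rate yields an
integer) and n_B = n_C = 400 − n_A.

Defaults, and the reasoning where the study design leaves a value open:

| parameter | default | reasoning |
|---|---|---|
| α (instrument strengths) | 0.5 or 0.1 | the study's two levels |
| β (causal effects) | 0.3 or 0 | the study's two levels |
| δ₁..δ₃ (confounding on X) | 1, 0.5 or 0.1 | the study's three levels |
| δ₄ (confounding on Y) | 1 | fixed in the study design |
| Z distribution | Binomial(2, maf), maf = 0.3, independent | instruments are SNP dosages; an N(0,1) option exists; reported metrics are insensitive to this choice |
| ω (intercepts) | 0 | intercepts affect no reported metric |
| σ₁..σ₃, σ_Y (noise sds) | 0.1 | calibrated jointly with u_sd against the closed-form 2SLS sampling sd (below) |
| u_sd (generative confounder sd) | 0.1 | see below |
| replicate seeds | hash(base_seed, cell index, replicate index) | any single cell is re-runnable in isolation |

**Calibrating the confounder scale.** The study conditions place the
classic comparator in a precise-but-confounded regime: 2SLS at n = 400
with strong instruments should estimate each effect to roughly ±0.02
(sd), an order of magnitude tighter than the confounded OLS bias it
corrects. The 2SLS sampling sd is √(Var(δ₄U + ε_Y) / (n · α² · VarZ))
per (approximately orthogonal) exposure. With confounder *variance*
0.1 and δ₄ = 1 this has a floor of ≈ 0.05 for any dosage instrument
and any σ. With confounder *sd* 0.1 (variance 0.01) and σ_Y = 0.1 the
closed form gives ≈ 0.022 at α = 0.5, ≈ 0.109 at α = 0.1 and ≈ 0.046
for two-sample IVW — the intended regime. The generator therefore uses
u_sd = 0.1 while the fitted model's U prior keeps variance 0.1 (where
it only fixes units).

**What the generator does not emulate:** linkage disequilibrium or any
correlation among instruments, binary or ordinal outcomes, non-linear
or interaction effects, direct exposure–exposure effects, selection or
measurement error, and missingness mechanisms other than
missing-at-random by design. Passing tests therefore demonstrate
correctness of the method under its own assumptions, not robustness to
their violation in real cohorts.

## Replication harness and problem sizes

`run_grid` enumerates overlap rate × instrument strength × confounding
× effect level (72 cells at defaults), runs `n_replicates` independent
replicates per cell, and aggregates per method and exposure: mean and
sd (n−1) of the point estimates, coverage of the true effect by the
95% interval, and power (interval excludes zero; defined only under
the alternative). Failed replicates are recorded, logged and excluded
rather than silently imputed.

The repository's own test and acceptance runs use desk-scale sizes
chosen so Monte-Carlo error sits comfortably inside the tolerances
checked: 100 replicates for the one-sample cells, 30 per overlap rate
for the power sweep, 50–100 for the null-coverage spot checks, all with
the 1200/400 sampler settings. Full-scale runs (200 replicates × 72
cells) go through the same code path (`bayesmr replicate`).

## Known limitations

* The δ sign convention makes per-chain δ summaries comparable, but δ
  magnitudes remain only weakly identified when confounding is weak.
* The literal imputation scheme is retained exactly as specified and
  documented biased; it should not be used for inference.
* Only the 3-instrument/3-exposure graph of the study design is
  implemented; the `ModelGraph` type validates alternative incidence
  patterns but the sampler's regression blocks are specialised to the
  default graph.
* Weak-instrument settings (α = 0.1) show the expected inflation of
  posterior spread and mild bias at low overlap; no weak-IV-robust
  correction is attempted.
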