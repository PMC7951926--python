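# Methods

This note documents the statistical model, the sampler, the synthetic
data generator and the numerical choices behind `arealrisk`, at the
level of detail a user needs to judge what the package's passing tests
do and do not establish.

## Model

Counts follow `Y_it | μ_it ~ Poisson(E_it μ_it)` with expected counts
`E_it = (ΣY/ΣN)·N_it` from internal standardization — the rate pooled
over *all* areas and periods applied to each cell's population.  Two
identities follow by construction and are enforced to numerical
precision: `Σ E = Σ Y`, and the E-weighted mean of `SIR = Y/E` equals 1.

The log relative risk decomposes as
`log μ_it = α + x_it'β + φ_i + δ_it`.  There is deliberately no
temporal main effect in the default model; a yearly effect `γ_t`
(iid normal, centred) is available behind `ModelSpec(temporal_trend=True)`
for data with strong secular trends.  The interaction `δ_it` is
independent normal per cell (Knorr-Held Type I); structured space-time
interactions are out of scope.

Spatial priors for `φ` (W = binary contiguity, D = diag of neighbour
counts):

* **ICAR**: precision `τ(D − W)`, improper; used inside BYM with a
  sum-to-zero constraint per connected component.
* **BYM**: `φ = u + v` with `u ~ ICAR(τ_u)` and `v ~ iid N(0, τ_v⁻¹)`.
  Only `u + v` is identified; the package monitors and tests
  identifiable quantities (fitted `μ`, `sd(φ)`), not the split.
* **Proper CAR**: precision `τ(D − γW)`, `γ ∈ [0, 0.99]`.  The
  parametrization is the standard proper-CAR form.  An isolated area
  (no neighbours) has zero conditional precision under this prior; the
  sampler falls back to conditional precision `τ` for such areas (the
  matrix constructor stays exactly `τ(D − γW)`).
* **Leroux**: precision `[ρ(D − W) + (1 − ρ)I]/σ²`, whose full
  conditionals have mean `ρΣ_j w_ij φ_j / (ρd_i + 1 − ρ)` and variance
  `σ²/(ρd_i + 1 − ρ)`; `ρ = 0` is independence, `ρ = 1` the ICAR.
* **iid** and **none** complete the family set for baselines and
  oracle fixtures.

Contiguity from polygons defaults to queen (any boundary intersection)
with a rook option (shared boundary of positive length); geometry
predicates are exact (snap tolerance zero), so callers pre-clean
geometries.  Isolated areas are retained with a warning rather than
rejected.

## Priors

The source analyses of this model class rarely print their hyperpriors,
so the defaults are chosen weakly informative and are configurable:
`α, β ~ N(0, 10²)` on the log scale, random-effect precisions
`~ Gamma(1, 0.01)`, `ρ ~ U(0, 1)`, `γ ~ U(0, 0.99)`.  Covariates enter
on their natural survey scales (percent; income in thousands), so each
`exp(β)` reads as relative risk per unit of that scale.  Any
hyperparameter can be pinned via `HyperPriors(fixed={...})`, which the
posterior-oracle test uses.

## Sampler

Inference is MCMC, not a Laplace approximation: the deliverable is the
joint posterior, and any sampler passing the diagnostics and the
integration oracle is conformant.  The implementation is adaptive
Metropolis-within-Gibbs with vectorised blocks:

* **(α, β)** — one joint adaptive-Metropolis block (Haario-style
  covariance adaptation, target acceptance 0.25).  Covariates are
  centred internally (`α_c = α + x̄'β`) to decorrelate the intercept;
  reported `α` is transformed back per draw.  The chain starts at the
  fixed-effects Poisson MLE from a few IWLS steps, with the IWLS
  covariance seeding the proposal.
* **CAR fields (u or φ)** — single-site random-walk MH run one graph
  colour class at a time: a greedy proper colouring guarantees no two
  updated areas are adjacent, so a whole class updates in one
  vectorised step with exact conditionals (target acceptance 0.44,
  per-site adaptive scales).
* **iid effects (v, δ, γ_t)** — their full conditionals are mutually
  independent, so all sites update simultaneously.
* **Precisions** — conjugate Gibbs.  The ICAR quadratic form uses rank
  `n − (number of components)`.
* **ρ and γ** — reflected random walks on their supports; the
  log-determinants `Σ log(ρλ_k + 1 − ρ)` and `Σ log(1 − γν_k)` come
  from one eigendecomposition of `D − W` (resp. `D^{-1/2}WD^{-1/2}`)
  per fit.
* **Scale moves** — one joint non-centred move per field and sweep,
  `(f, τ) → (c·f, τ/c²)` with log-normal `c`.  The Gaussian field prior
  is invariant under the map, so the acceptance ratio reduces to the
  likelihood change plus `−2a·log c − b(τ/c² − τ)` from the
  Gamma(a, b) prior (plus the field Jacobian when τ is pinned).  This
  traverses the variance funnel that single-site updates cross slowly.
* **Ridge move** — covariates that vary mostly in space are nearly
  confounded with `φ`: the likelihood constrains `x'β + φ` while only
  the field prior separates them.  One extra MH move per coefficient
  proposes `β_j → β_j + db` while subtracting the per-area time-mean
  covariate pattern from the field; the acceptance ratio involves only
  the (cheap) field and coefficient priors and the small likelihood
  term from the time-varying covariate component.  Without this move,
  effective sample sizes for `β` collapse on spatially smooth
  covariates.

Identifiability constraints are applied by recentring: `u` is centred
per connected component each sweep with the removed mean absorbed into
the intercept (an exact reparameterization on connected graphs — the
ICAR prior is invariant to component-wise shifts — and a documented
approximation on disconnected ones); `δ` is centred per year, with the
mean level moved to the intercept (or to `γ_t` when the temporal trend
is on).  Proposal scales adapt by Robbins-Monro during warm-up only
and are frozen for the retained draws.

Diagnostics: split-R̂ and bulk ESS (arviz) on the intercept, each
coefficient, `sd(φ)`, `τ_δ`, and `ρ`/`γ` where present; a single chain
is split in half.  A `ConvergenceWarning` fires above R̂ = 1.01.  The
test fixtures target R̂ ≤ 1.01 / ESS ≥ 400 on the oracle fixture;
replicate studies run shorter chains and tolerate R̂ ≈ 1.05-1.1, which
affects interval width slightly but not the tested conclusions.

## Model comparison

All criteria are computed from the pointwise Poisson log-likelihood
matrix over retained draws, with the factorial constant included so
that a degenerate (single-point) posterior yields exactly
`DIC = WAIC = −2Σ log-lik = 2 × CPO score`.  DIC plugs the posterior
mean of `μ` (rate scale) into the deviance — with this convention the
Poisson pD is non-negative by Jensen's inequality.  WAIC uses the
variance form (pWAIC2).  CPO uses the harmonic-mean identity per cell,
computed with max-shift; the scalar score is `−Σ log CPO_it`, the
standard scalarization for which smaller is better (the aggregation
behind printed CPO values in the source literature is not stated; this
choice is fixed and documented).  A warning fires when any cell's
harmonic mean rests on < 1% of draws (importance-weight ESS).

## Synthetic data generator

The generator defines the study conditions under which everything is
tested; its defaults are fixed, not tuned:

* **Lattice** — 7×12 rook grid (84 areas), standing in for the
  84-zip-code study region; any `Lattice` can be substituted.
* **Populations and covariates** — spatially smooth surfaces: a Leroux
  latent field (ρ = 0.6) standardized to unit marginal variance,
  scaled to the survey means/CVs of the emulated panel (population
  mean 30,237, CV 45.5%; % renters 50.9, CV 31.5%; % white 23.8,
  CV 97%; % crowded 6.97, CV 64.3%; income generated directly in
  thousands; etc.).  Percent covariates clip to [0, 100]; positive
  covariates are log-normal with matching mean and CV.  Per-year
  values add independent noise at 10% of the cross-sectional spread —
  the modest yearly drift visible in rolling survey estimates.  This
  temporal variation matters: with covariates exactly constant in
  time, `x'β` is wholly confounded with `φ` and no inference engine
  could separate them.
* **Effects** — covariate truths default to relative risks 1.03
  (% renters), 0.97 (% white), 0.90 (% crowded housing); BYM field
  scales sd_u = 0.5 (structured), sd_v = 0.3 (unstructured);
  interaction sd_δ = 0.15; Leroux ρ = 0.7 — typical disease-mapping
  magnitudes.  The baseline rate is calibrated so the expected total
  count is 2,630, the emulated study's event total.
* **Truth record** — `GeneratorTruth` stores every effect plus the
  true relative-risk surface `μ = λ/E*` (Poisson mean over true
  pooled-rate expecteds), and reproduces `log μ = α + x'β + φ + δ`
  exactly, cell by cell.
* **Events** — optional event-level fixtures with timestamps uniform
  within each year, either matching a panel's counts exactly or
  hitting given yearly totals (449/487/473/555/666 for the emulated
  study).  No within-year seasonality is claimed or generated.

What the generator does **not** emulate: survey sampling error and the
rolling-average structure of real covariate panels, within-year event
seasonality, secular temporal trends in risk (the default model has no
temporal main effect), and irregular real-world zip-code geometry.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions — not robustness to
the misspecifications real data bring.

## GMRF sampling

`sample_gmrf` draws via eigendecomposition of the dense precision
(fine for the few-hundred-area scale this package targets).  Singular
ICAR precisions require the sum-to-zero flag; their null directions
are excluded, which for a graph Laplacian makes draws sum to zero on
each connected component.  For nonsingular precisions the constraint
is applied by conditioning-by-kriging.  Eigenvalues below
`1e-10 × max` count as null.

## Replicate-study design and problem sizes

The package's own end-to-end checks run at the study scale (84 areas,
5 years, ~2,630 events) with single chains of 1,200-4,000 retained
draws per fit — sizes chosen so a full replicate study (10-20 fits)
completes in minutes while leaving Monte-Carlo error well below the
effects being tested:

* **Coverage** — 20 replicates, BYM fit, 95% intervals should cover
  the generating relative risks and match their signs in ≥ 18/20.
* **Smoothing** — model-based RR has strictly smaller mean absolute
  error against the true `μ` surface than the raw SIR in ≥ 9/10
  replicates (typical MAE ratio ≈ 0.5).
* **Selection** — BYM-generated data, all three priors fitted,
  winners tallied by DIC and WAIC over 10 replicates.

## Known limitations

* **Spatial-prior selection is weakly powered.**  On panels of this
  size the three CAR families produce near-identical smoothed
  surfaces; DIC/WAIC gaps between them are 0-3 units with
  dataset-dependent sign, comparable to the criteria's own
  Monte-Carlo error.  A symmetric cross-design experiment (generate
  from each family, fit all three) recovers *no* family reliably —
  the selection tally in the replicate study should be read as a
  measurement of this near-equivalence, not as a defect of any single
  criterion.  Practitioners comparing CAR priors on a single dataset
  of this size should not over-interpret few-unit criterion
  differences.
* The BYM split (u vs v) and, under strong confounding, `β` vs `φ`
  are only weakly identified; intervals for `β` on spatially smooth
  covariates lean on the field prior and can be mildly narrow when
  chains are short.
* Harmonic-mean CPO is variance-unstable in heavy-tailed cells; the
  package warns rather than smooths (no PSIS).
* Dense eigendecompositions bound practical problem size to a few
  thousand areas.
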