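# Methods

## Model and tests

All methods target the Gaussian linear model `Y = b0 + X b + e`,
`e ~ N(0, s²)`, with `X` an n × k dosage matrix (0/1/2) for one variant
group and the global null `H0: b = 0`. No covariates are modelled; traits
are assumed exchangeable under the null, which is what licenses the
permutation calibration below. File readers orient every variant to its
minor allele; the simulator's output is used as generated.

The score-based tests share the components
`U = Σ_i (Y_i − Ȳ) X_i` and `V = s0² Σ_i (X_i − X̄)(X_i − X̄)'` with
`s0² = Σ_i (Y_i − Ȳ)²/(n − 1)`:

* **Score** `U'V⁻U` uses an eigendecomposition of V with eigenvalues
  below `1e-10 × max eigenvalue` truncated; the chi-squared reference df
  is the retained rank. Rare variants at MAF 0.005 with n = 400 make
  near-singular and zero-variance columns routine, so the generalized
  inverse is the default, not an error path.
* **SSU / SSUw** compare `U'U` (resp. `U' diag(V)⁻¹ U`) to a weighted sum
  of 1-df chi-squareds. The tail probability is computed by Imhof's
  characteristic-function inversion on Gauss–Legendre panels whose width
  tracks the integrand's oscillation frequency (panels are summed until
  two consecutive contributions fall below 1e-11; a single weight reduces
  to an exact chi-squared). A Satterthwaite moment-matching fallback
  covers quadrature failures; results match Monte-Carlo tail estimates to
  ~1e-3 and exact chi-squared identities to ~1e-8.
* **UminP** `max_j U_j²/v_j` needs the rectangle probability
  `P(|Z_j| ≤ c ∀j)` under the score correlation matrix, computed with the
  Genz quasi-Monte-Carlo integrator (absolute tolerance 1e-5, fixed
  internal seed for reproducibility). Variants with |correlation| ≥
  1 − 1e-8 are collapsed first — the rectangle event is identical for
  them, and the reduction keeps the integrand non-degenerate.
* **F / Sum** are the classical overall F-test (rank-reduced when the
  design is collinear) and the 1-df burden regression on the genotype row
  sum.
* **aSum** flips the coding (`X → 2 − X`) of variants whose marginal
  slope is negative with marginal p ≤ α₀ = 0.1, then computes the burden
  log-likelihood-ratio statistic `n log(RSS0/RSS1)`. Because the flip is
  data-driven, its p-value always comes from permutation, with the
  *whole* procedure (marginal fits and flips included) recomputed per
  permutation.

Zero-variance (monomorphic) columns are dropped inside SSUw/UminP and
absorbed by the generalized inverse elsewhere; the drop is logged at
debug level since it is an expected event for rare variants, not an
anomaly. A constant trait yields degenerate-flagged results with p = 1.

## Penalized fits

Four penalty families on column-centered data with an unpenalized
intercept (`b0 = Ȳ − X̄'b`): Lasso `λΣ|b_j|`; graph-fused Lasso
`λ₁Σ|b_j| + λ₂Σ_{j<j'}|b_j − r(j,j')b_j'|` over the complete pair graph
with `r` either +1 or the sign of the column correlation (undefined
correlations default to +1); TLP-S `λ₁Σ J_τ(|b_j|)` and TLP-SG adding
`λ₂Σ_{j<j'} J_τ(||b_j| − |b_j'||)`, where `J_τ(x) = min(x/τ, 1)`.

Solvers:

* Separable L1 problems (Lasso and all DC surrogates with per-coefficient
  weights and linear terms) use cyclic coordinate descent on the Gram
  matrices, so one sweep costs O(k²) per problem independent of n, and a
  whole batch of problems (e.g. all permutations of one dataset) is
  solved simultaneously with vectorized updates. Inner tolerance 1e-8 on
  the coefficient change (1e-6 in the batched "fast" mode used inside
  permutation loops).
* Fused surrogates use ADMM with residual balancing (ρ doubled/halved
  when primal and dual residuals diverge by 10×) and a pre-factorized
  normal matrix; the exact objective is tracked at check points and the
  best iterate visited is returned, so the reported solution never
  regresses.
* The non-convex TLP objectives run a difference-of-convex (DC) outer
  loop: the concave part of `J_τ` is linearized at the current iterate,
  giving a convex majorizer whose minimizer cannot increase the true
  objective; the loop stops when the objective improves by less than
  1e-6 (at most 100 outer iterations). Coefficients beyond τ receive a
  cancelling linear term, i.e. no shrinkage — the mechanism behind the
  near-unbiasedness of TLP estimates and their step-function solution
  paths.
* **Warm starts.** TLP-S starts the DC loop from *two* deterministic
  points — the convex surrogate solution Lasso(λ₁/τ) and Lasso(λ₁) — and
  keeps the lower attained objective. The dual start matters: for small
  τ the surrogate penalty λ₁/τ is enormous, its solution is exactly
  zero, and zero is a DC fixed point, so a single surrogate start
  silently collapses the fit on every small-τ grid point. TLP-SG starts
  from the TLP-S solution; because its sign linearization is only local,
  each DC candidate is accepted per problem only if it lowers the exact
  objective. Convergence is to a local minimizer; reproducibility comes
  from the deterministic initialization, and the k ≤ 2 dense-grid oracle
  tests bound the gap to the global minimum at 1e-3 on small problems.

## Tuning-parameter selection

Grid search minimizing `AIC = −2 log L + 2p` with
`log L = (−n log ŝ² − n − p − 1)/2`, `ŝ² = RSS/(n − p − 1)`, and the
effective parameter count `p` equal to the number of non-zero
coefficients (Lasso, TLP-S), non-zero unique coefficients (gflasso r=1),
or non-zero unique absolute coefficients (gflasso r=cor, TLP-SG).
"Non-zero" means `|b_j| > 1e-3` — deliberately the same threshold the
post-selection statistics use — and "unique" means separated by more than
1e-4 after sorting; both are configurable, since no principled value
exists for either. Candidates with `n − p − 1 < 1` get AIC = +∞; if every
candidate is degenerate the null fit is returned with a warning. Ties
break toward the lexicographically smallest parameter tuple. Default
grids: 50 equally spaced λ on [0.001, 10] (Lasso); five equally spaced
points on [0.001, 1] for λ₁ and [0.001, 0.5] for λ₂ and τ ("equally
spaced" read as linear, not log, spacing). Cross-validation is
deliberately absent: with rare variants, training folds routinely contain
monomorphic columns whose effects are unidentifiable.

## Permutation calibration

For penalized-fit statistics the null distribution is intractable, so
p-values come from B trait permutations (default B = 100) with the *full*
pipeline — AIC grid search included — re-run on every permuted trait;
skipping the per-permutation tuning anti-conservatively biases the test
because the observed data get a tuning advantage. The p-value is the
strict-inequality fraction `Σ_b I(T < T0_b)/B` (ties count as
non-rejection): p = 0 is attainable, and an optional `(Σ+1)/(B+1)` mode
exists for users needing strictly positive valid p-values. Permutations
are keyed by (seed, b) through NumPy's SeedSequence, so results are
reproducible and independent across replicates. All B + 1 problems share
the design matrix, so the engine solves them as one batch; the
post-selection SSU/SSUw statistics restrict U and diag(V) to variants
with `|b̂_j| > 1e-3` (empty selection gives statistic 0), and diag(V) is
permutation-invariant, which the batched computation exploits. The 1-df
statistic regresses Y on the fitted linear predictor `X b̂` (statistic 0
when the predictor is constant, e.g. b̂ = 0). Post-selection SSU/SSUw are
wired to TLP-SG (and to the unpenalized `ols` family, which exists to
cross-check the engine against the asymptotic tests); other combinations
sit behind an explicit flag.

## Simulator

Each replicate draws per-variant allele frequencies (uniform on
[0.005, 0.01] for rare variants) and builds haplotypes by thresholding a
latent MVN(0, R) vector with AR1 correlation `R[j,j'] = 0.8^|j−j'|` at
`Φ⁻¹(1 − f_j)`; a genotype is the sum of two independent haplotypes. The
latent-threshold construction gives allele-level LD of roughly 0.36 at
lag 1 for adjacent rare variants. In the mixed scheme two randomly placed
positions are common variants: the *same* latent block is thresholded at
a frequency drawn uniformly on [0.2, 0.7], so common variants are in LD
with their rare neighbours, as inside a real gene — common variants then
partially tag the causal rare variants, which is exactly what makes the
variance-dominated SSU statistic behave so differently in this scheme.
Traits are `Y = 0.3 + Xb + e` with noise standard deviation 2. Six causal
positions are drawn uniformly per replicate and the six case-specific
effect values are assigned to them in random order; a common variant
drawn causal has its effect divided by 10 so it cannot dominate the
trait. Case 0 is the global null for type-I studies. Monomorphic columns
are kept (they occur with real frequency at these MAFs); downstream code
must tolerate them.

What the generator does *not* emulate: realistic site-frequency spectra
(frequencies are uniform on a narrow band, not coalescent-derived),
recombination or LD decay beyond the stationary AR1 profile, genotyping
error and missingness, covariates and population structure, and any
non-Gaussian trait architecture. Passing tests therefore demonstrate
correctness and calibration of the machinery under idealized LD and noise
— not performance guarantees on real sequence data.

## Problem sizes and reproducibility

Power and calibration checks in the test suite use n = 400 with k = 6
variant groups; type-I calibration runs 500 replicates for the
closed-form tests and aSum, and 50–100 replicates for the
permutation-calibrated penalized pipelines, whose per-replicate cost is
two to three orders of magnitude higher (each replicate is 101 AIC grid
searches). `scripts/acceptance.py` uses 1000 replicates per power
estimate and 500 per estimator mean so the Monte-Carlo error of each
reported number (~0.01 for a power near 0.8) is small against the
comparison tolerances. Every simulated table cell is regenerable from
(scheme, case, n_noncausal, n, seed) alone.

## Known limitations

* The DC solvers find local minima; the dual warm start removes the known
  degenerate basin at small τ, but no multistart search is attempted
  beyond it.
* AIC with the counting rules above has no supporting theory for the
  grouping penalties; the uniqueness tolerance operationalizes "number of
  groups" pragmatically.
* The AIC-tuned Lasso shrinks a selected coefficient by roughly
  λ/(column sum of squares) — about 1.0 at the selected λ on the mixed
  k = 30 design — so its mean estimate of a true 1.5 effect lands near
  0.3. The published comparison values for this estimator (~0.93, with
  selection counts implying a similar sparsity) are mutually inconsistent
  with that arithmetic and could not be reproduced by the stated
  objective on any λ in the stated grid; the reimplementation reports
  what the stated procedure actually yields.
* Binary traits, covariate adjustment and family data are out of scope.
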