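# Methods

## Model

The package implements a mixture multidimensional nominal response model for
ordinal questionnaire data under faking. Conditional on class membership
ζ_n = c, the probability of person n choosing category k of item i is a
softmax over category logits (α_i ∘ s_ik)'θ_n + γ_ik^c. The D = T + 1 latent
dimensions are T substantive traits and one faking dimension; θ_n ~ MVN(0, Σ)
with unit variances (so Σ is a correlation matrix) and mean 0 for
identification. Category indexing is 0-based (0..K) throughout.

Scoring weights are fixed constants. An item's measured trait carries the
evenly spaced weights (0, 1, …, K) — the partial credit pattern, so the
single-dimension special case is exactly a partial credit model — while the
faking row carries the item's category desirabilities. Empirical desirability
ratings are mapped linearly onto 0–6 using the *possible* range of the rating
instrument (`rescale_desirability`), so that all dimensions share one metric;
the instrument range is an explicit argument because it differs between
studies.

Classes are defined structurally by which dimensions are allowed to load:
S&F (measured trait + faking), S-only (trait only), F-only (faking only).
Non-fixed slopes are class-invariant so the same latent variables are
measured in every class; intercepts are class-specific to absorb different
response distributions. The mixture is at the person level — one ζ_n per
response vector; item-level strategy switching is out of scope. Class
membership follows a latent multinomial logistic regression on covariates
with all S&F coefficients fixed to 0; when the S&F class is not part of a
specification, the first remaining class becomes the reference. The three
non-mixture models (traits+faking, traits-only, faking-only) are the C = 1
special cases of the same code path.

Missing responses (coded −1) are skipped in the likelihood
(missing-at-random). All likelihood work is in log space with log-sum-exp
marginalization; with 15–30 items the within-class response-vector
probabilities underflow linear-space arithmetic.

## Estimation

Priors: slopes N⁺(0, 2²) (the positive truncation also signs the latent
dimensions), intercepts N(0, 5²) with γ_i0^c ≡ 0, latent correlations
pairwise U(−1, 1) restricted to positive-definite matrices (an LKJ(1) flag
exists; over correlation matrices it is the same flat density), regression
coefficients N(0, 2²).

The sampler is an own adaptive Metropolis-within-Gibbs scheme:

* **Person parameters.** ζ_n is marginalized out of the likelihood, and θ_n
  is random-walk updated against the resulting person-level mixture, in two
  blocks (traits jointly; faking alone) with per-person adaptive scales.
  Marginal updates let a person's faking score feel the S&F likelihood in
  proportion to the current responsibilities instead of being frozen by a
  hard assignment.
* **Item parameters.** Memberships are drawn from their exact full
  conditional (the responsibilities), which makes every (class, item) block
  conditionally independent; slope and intercept scalar moves then run
  vectorized across items and classes, and the memberships are discarded — a
  partially collapsed Gibbs step equivalent to the fully augmented sampler.
* **Correlations.** Each pairwise correlation is drawn from its full
  conditional by inverse-CDF sampling on a fine grid restricted to the
  positive-definite interval. Because the correlation enters Σ through a
  rank-2 linear update, det Σ(r) and tr(adj(Σ(r)) S_θ) are exact quadratics
  in r, so the whole grid is interpolated from three small-matrix
  evaluations.
* **Interweaving moves.** Two likelihood-invariant moves traverse the
  classically slow ridges of IRT posteriors: a per-dimension rescaling
  (θ_d → cθ_d, α_·d → α_·d/c) and a per-dimension location shear
  (θ_d → θ_d + δ with the compensating intercept shift). Both leave all
  category probabilities unchanged, so they cost only prior evaluations.
* **Stabilized burnin.** Starting values come from classical scores
  (standardized scale means for traits; a standardized desirability-weighted
  sum for faking) — chains started at θ = 0 cannot distinguish the S&F from
  the S-only measurement model. The latent regression is additionally frozen
  at uniform class probabilities for the first half of burnin so the class
  measurement models separate on likelihood alone before class-proportion
  feedback can starve a class (the rich-get-richer failure mode of mixture
  samplers).

Proposal scales adapt toward acceptance 0.44 (scalars) / 0.30 (small blocks)
during burnin only and are then frozen. Responsibilities, person-mean class
proportions, the per-person marginal log-likelihood and the deviance are
recorded at every retained draw; thinned full-state snapshots support
posterior predictive checks and person-parameter recovery. Point estimates
are posterior means; class assignment is modal (ties, a measure-zero event,
break toward the lowest class index and are recorded). Convergence is
checked with the split-chain potential scale reduction factor over all
monitored continuous parameters (slopes, intercepts, correlations,
regression coefficients), with 1.1 as the acceptability bound.

Sampler defaults mirror the reference analysis (4 chains, 2000 burnin, 5000
retained); `EMPIRICAL_CONFIG` (12 chains, 5000/10000) and the reduced
`DESK_CONFIG` (2 chains, 500/1000) are named presets. The `sweeps` setting
(default 3) controls how many full update sweeps constitute one recorded
iteration; it trades wall time for effective sample size per draw.

`fit_with_fixed_items` scores a new sample with slopes, intercepts and
correlations frozen at previously estimated values, estimating only person
parameters, memberships and an intercept-only membership regression — the
transfer-scoring workflow for applying a calibrated model to, e.g., a
low-stakes sample.

## Fit indices

WAIC and LOOIC operate on the person-level marginal log-likelihood (classes
summed out): one person's response vector is one observation. WAIC uses the
sample-variance penalty; LOOIC is Pareto-smoothed importance sampling via
arviz with Pareto-k diagnostics surfaced as warnings. DIC evaluates the
deviance at posterior means of all continuous parameters (memberships stay
marginalized — mixture DIC is ill-defined under plugged-in discrete
assignments) with the variance-based effective-parameter count p_V =
Var(D)/2; the classic mean-minus-plugin variant is available behind a flag.

The posterior-predictive SRMR draws complete replicated datasets from
randomly selected posterior states (person parameters and memberships
included), averages the replicated Pearson item-intercorrelation matrices,
and reports the root mean square discrepancy to the observed
intercorrelations over item pairs (default 200 replicates; constant items
are skipped and logged). Entropy is 1 − ΣΣ(−π log π)/(N log C), using the
log-C denominator so two-class specifications remain valid.

## Synthetic data generator

The generator emulates high-stakes personality assessment data and defines
the study conditions: 3 trait scales × 10 items (desk scale: 5) on a 7-point
scale, N = 1500 (desk: 300), ten class-proportion conditions ranging from
equal thirds through dominant-class and absent-class patterns to pure
single-class populations. Per replication: slopes ~ U(0.5, 1); faking
weights from three equidistant shape families spanning 0–6 (monotone rise;
nonmonotone rise peaking one category below the maximum then one step down;
inverted-U peaking at the midpoint), allocated round-robin within each scale
(10 items → 4/3/3); class-specific intercepts as negative cumulative sums of
sorted U(−2, 2) thresholds (sortedness makes the intercept sequence concave);
person parameters MVN with trait-pair correlations {0.3, −0.3, 0} assigned
at random per replication and faking uncorrelated with the traits; three
covariates (null, weak |slope| ~ N(1, 0.2²), strong ~ N(2, 0.2²), half of
the nonzero slopes sign-flipped) with intercepts solved so expected class
proportions match the condition (closed form when slopes vanish, otherwise a
damped fixed point on a fixed Monte-Carlo covariate sample, verified to
0.005); memberships sampled from the implied multinomial probabilities; and
responses from the class-conditional categorical distributions. Classes with
target proportion 0 are excluded from generation entirely (cleaner than
driving an intercept to −∞, identical distribution).

What the generator does *not* emulate: idiosyncratic, non-equidistant
empirical desirability curves (arbitrary weight files are accepted but not
generated), local item dependence, careless responding, missing data, and
person-by-item strategy switching. Passing recovery tests on these data
therefore demonstrate the estimator's correctness under the model's own
assumptions, not robustness to real-data violations of them.

## Recovery study and reduced scale

`run_study` orchestrates conditions × replications × the four models and
scores proportion bias/RMSE and per-class hit rates, regression-coefficient
recovery (re-referenced to the generating reference class when S&F is
absent), item-slope and intercept bias, latent-correlation bias, Fisher-z
mean correlations of person-parameter estimates with truth, and
correct-selection percentages for DIC/WAIC/LOOIC (exact ties count as
incorrect and are logged). Two presets exist: `paper` (N=1500, 10 items per
trait, 30 replications, 4 chains × 2000/5000 — a multi-hour run) and `desk`
(N=300, 5 items per trait, 3 replications, 2 chains × 500/1000), the scale
used by the package's own acceptance checks. At desk scale roughly a fifth
of the data of the reference design is available, so individual replications
show wider dispersion; checks average over replications and directional
contrasts (misspecified-model biases) are asserted as orderings, not
magnitudes.

Problem size matters qualitatively, not just in variance: comparing fully
converged long chains against fits with item parameters fixed at truth shows
that below roughly N=300 with 15 items the *posterior itself* can prefer a
configuration in which moderate fakers from the traits+faking class are
absorbed by the traits-only class (its free class-specific intercepts soak
up the average faking effect, and the extra dimension is Occam-penalized),
capping that class's hit rate well below the large-sample value on some
datasets. At N=450 with 21 items classification is back in the large-sample
regime (per-class hit rates ≈ 0.97–0.98). `scripts/acceptance.py` therefore
uses N=450 / 7 items per trait for its equal-thirds replications — the
smallest design whose posterior still behaves like the full study — while
keeping N=300 / 5 items per trait for the single-class run, where the
posterior is unambiguous.

## Numerical and design notes

* Category coding is 0-based everywhere; 1-based input files are shifted
  behind an explicit flag.
* The intercept-threshold transform defines τ for categories 1..K with
  γ_0 := 0 (a threshold for the fixed first category would be unidentified).
* The fixed-point intercept solver raises with diagnostics if the target
  proportions cannot be matched on the Monte-Carlo sample.
* Degenerate inputs: constant items trigger a warning before fitting;
  enumeration guards reject out-of-range categories with row/column named.
* The likelihood kernels are numba-compiled; each item loads on at most two
  dimensions (its trait and faking), which the fused loops exploit.
* Chain-level seeding uses `numpy.random.SeedSequence.spawn`, so any integer
  seed yields independent, reproducible chains; rerunning a fit with the
  same configuration reproduces draws exactly.

## Known limitations

* At desk scale the S&F class is the hardest to pin down: test-takers whose
  faking score is near 0 are nearly indistinguishable from S-only
  respondents, which caps per-class hit rates below the large-sample values
  and can leave residual split-chain R-hat around 1.1–1.3 on unlucky
  datasets within the short desk-scale chains.
* Proportionality-constant class parameterizations, an independence F-only
  class, person-by-item mixtures and response-time extensions are not
  implemented.
* PSIS-LOO relies on arviz; its Pareto-k warnings should be heeded for
  small posterior samples.
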