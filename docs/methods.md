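# Methods

This note records the model, the estimation choices, and the reasoning
behind the defaults, at the level of detail a maintainer or a careful user
needs. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

**Measurement part.** Observation `y_it` (J continuous items) in latent
state k follows a factor model `y = ν_k + Λ_k η + ε`, `η ~ N(0, I_{F_k})`,
`ε ~ N(0, Ψ_k)` with diagonal Ψ_k, so the state-conditional distribution is
`N(ν_k, Λ_k Λ_kᵀ + Ψ_k)`. Identification fixes the factor covariance to the
identity and the factor means to zero per state; intercepts are therefore
state-specific item means. Strict invariance holds within a state by
construction; states absorb all loading/intercept/uniqueness differences.

**Dynamic part.** The latent state follows a continuous-time Markov chain.
Off-diagonal transition intensities are log-linear in covariates,
`q_st(x) = exp(β_st,0 + Σ_p β_st,p x_p)`; diagonals are minus the row sums,
so rows of Q sum to zero and `P(Δ, x) = expm(Q(x)·Δ)` is row-stochastic for
any interval Δ > 0. Initial state probabilities are baseline-category logits
with state 1 as reference. Because intensities, not probabilities, are
parameterized, unequal intervals are handled exactly; with all intervals
fixed at 1 the model reduces to a discrete-time latent Markov model with
`P = expm(Q)` (verified against an independent discrete-time forward
recursion in the tests).

**Three-step estimation.** Step 1 fits the mixture ignoring the temporal
ordering. Step 2 assigns each observation to its modal state and
cross-classifies modal against posterior mass to estimate
`P(modal = s | true = t)` (the posterior-mass operationalization of the
"true" state is the standard maximum-likelihood three-step convention).
Step 3 fits the transition model to the modal sequences with those
misclassification probabilities fixed as the emission model. Without this
correction the random component of the assignments masquerades as real
switching and biases staying probabilities downward; the paired comparison
in the acceptance tests measures exactly this.

## Step-1 estimation choices

- **EM scheme.** E-step: posterior state memberships. M-step: per state, a
  factor-analysis EM on the posterior-weighted mean and covariance, run for
  a fixed 25 inner iterations. Each outer iteration is therefore a
  generalized EM step and the loglikelihood is monotone; every fit records
  its trace and the largest observed decrease (asserted ≈ 0 in the tests).
- **Starts.** Each start draws the initial posterior matrix from a flat
  Dirichlet per observation; the first M-step turns that into parameters
  (principal-component initialization for the inner factor EM). The number
  of starts defaults to 25; all randomness flows from one seed through
  `numpy.random.SeedSequence` spawning.
- **Convergence.** Absolute loglikelihood change below `tolerance`
  (default 1e-8) within `max_iterations` (default 1000); both are user
  settable. A fit that never reaches the tolerance is flagged and a
  re-estimation advice message is logged.
- **Degeneracies.** Unique variances are floored at 1e-4 times the item
  variance (flagged when hit) to prevent Heywood blow-ups; a start in which
  any state's expected size falls below one observation counts as failed.
- **Identification of Λ.** After EM, each state's loadings are put in a
  canonical form via SVD (ΛᵀΛ diagonal, descending, signs fixed), which
  pins down the F(F−1)/2 rotational degrees of freedom that the likelihood
  cannot see. Parameter counting follows the same convention:
  `(K−1) + Σ_k [J·F_k − F_k(F_k−1)/2 + 2J]`.
- **Rotation.** Oblique quartimin (oblimin with γ = 0) via a
  gradient-projection algorithm written for this package, from 10 random
  orthonormal starts plus the identity; the loading matrix is normalized to
  unit root-mean-square before rotation because the quartic criterion is
  not scale-invariant while its optimum is. Factors are reflected so each
  factor's largest-|loading| item is positive and ordered by explained
  common variance. Which oblique criterion the field's other
  implementations use is not standardized; quartimin is the conventional
  default and is not claimed to be equivalent to any other choice.
- **BIC.** `−2·LL + n_par·ln N` with N the number of observations, since
  the step-1 likelihood is a product over observations.
- **Model selection.** For each number of states, one representative per
  multiset of factor counts is fitted ([3 2 3], [3 3 2] and [2 3 3] are the
  same model), and states are relabelled by descending size so labels are
  stable across runs. The CHull procedure takes the upper convex hull of
  the (n_par, LL) cloud (collinear models are kept on the hull) and selects
  the interior model with the largest scree ratio; a near-flat incoming
  slope, or a winning ratio of ~1, raises an artificial-inflation flag, and
  the output always carries the reminder that boundary models cannot be
  selected by ratio.

## Step-2 choices

Natural logarithms in R²_entropy (the base cancels in the ratio). Total
classification error is `1 − mean(max_k posterior)`; the off-diagonal mass
of the error-count matrix divided by N coincides with it in expectation,
and the first form is what the diagnostics report. A warning recommends
full-information estimation when R²_entropy < .5, where the error
correction itself becomes unreliable.

## Step-3 choices

- **Covariate timing.** The transition over `(j−1, j]` uses the covariates
  observed at occasion j−1: the intensity governs leaving the origin state,
  so the origin occasion's covariate values apply.
- **Optimization.** Quasi-Newton (L-BFGS-B) on the free coefficients, from
  a moment-based start (modal frequencies for the logits; matrix logarithm
  of the smoothed modal transition table for the intensity intercepts) plus
  `n_starts` random starts (intensity intercepts ~ U(ln .05, ln .5),
  covariate effects ~ U(−.1, .1), logits ~ U(−1, 1)). Covariates are
  standardized internally for conditioning; estimates and their covariance
  are mapped back to the user scale, under which the Wald statistic is
  exactly invariant. After L-BFGS the optimum is polished with a few damped
  quasi-Newton steps using low-noise central-difference gradients, which is
  what makes standard errors and Wald statistics stable to ~1e-6.
- **Inference.** Standard errors from the inverse of a central
  finite-difference Hessian with steps `3e-4·(1+|θ|)` — the step balances
  truncation (~h²) against rounding noise (~ε/h²) for loglikelihoods of
  this magnitude. Per covariate, the Wald omnibus statistic
  `θ_cᵀ V_c⁻¹ θ_c` with df equal to the number of coefficients carrying
  that covariate; two-tailed p for individual z statistics. A singular
  Hessian (typically a transition never observed in small samples) reports
  unavailable standard errors rather than fabricated ones.
- **BIC** uses the number of subjects as sample size — subjects are the
  independent units of the transition likelihood. The emission matrix is
  fixed, not counted in n_par.
- **Forward recursion.** Scaled (normalized per step) and vectorized across
  subjects; transition matrices for all intervals are computed in one
  batched scaling-and-squaring matrix exponential (degree-13 Taylor after
  scaling the stack below norm 1/2; agrees with scipy's expm to ~1e-14).
  The single-matrix `transition_matrix` entry point delegates to scipy.
- **Initial covariates** act at the first occasion only and should be
  subject-constant; time-varying covariates belong on the transitions.
  Subjects with a single occasion are admitted and contribute only
  initial-state information.

## Synthetic-data generator

The generator defines the study conditions used everywhere in the tests:
100 subjects; occasions per subject ~ round(N(47.76, 6.56²)) clipped to
[30, 60]; intervals gamma-distributed with mean 1.22 and SD 1.02 (unit:
days) truncated at 0.05; 18 items on a 0–100 scale; three states with
[3 2 3] factors. Primary pattern loadings are 10 with unique variances 100
(standardized loadings ≈ .71, communality ≈ .5); state intercepts differ by
at least one within-state SD between states, giving the well-separated
design the three-step estimator assumes (R²_entropy ≈ .8 at these
settings). Initial probabilities are (.42, .34, .24). Baseline intensities
at sample-mean covariate scores are (.155, .10, .10, .33, .28, .14) for
(1→2, 1→3, 2→1, 2→3, 3→1, 3→2); a binary intervention (switching on for a
random half of subjects after a third of their occasions) lowers the rates
into state 1 and raises the rates out of it, and an i.i.d. N(49.65, 15.11²)
negative-event score does the opposite. State paths are simulated with one
matrix-exponential jump per interval, covariates held at their
origin-occasion values — exactly the process the fitted likelihood assumes.

What the generator does *not* emulate: within-subject autocorrelation of
covariates and factor scores beyond the state process, response styles,
floor/ceiling censoring of the 0–100 scale, missing occasions recorded as
rows, or any particular published dataset's parameter values. Passing
recovery tests on these data therefore show correctness of the estimator
under its own assumptions, not robustness to their violation.

## Problem sizes in the test suite

The simulation studies run at sizes chosen for a single CPU: model-recovery
and loading-recovery replications use 30 subjects (~1 450 observations,
candidate states 2–3 with 2–3 factors, 3 EM starts); transition-probability
recovery uses 30 subjects at the full ~48 occasions; Wald-calibration uses
200 replications of 30 subjects × ~12 occasions with a standard-normal null
covariate (replications whose Hessian is singular — a transition pair never
observed — contribute no test and are excluded from the rejection rate;
they are asserted to be rare). Coverage of the transition probabilities is
assessed entrywise with delta-method standard errors pooled over
replications.

## Known limitations

Confirmatory (fixed-zero) patterns, cross-state equality constraints,
categorical indicators, missing data, subject-specific transition
parameters and latent subject groups are out of scope. The Wald test is
asymptotic; in very small panels it can be mildly anti-conservative, and
rare transitions can make the information matrix singular. The three-step
correction assumes a reasonably good state separation (R²_entropy ≥ .5);
below that, full-information estimation is preferable.
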