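# Methods

## Model

`ioglmhmm` implements a K-state input–output hidden Markov model for
two-alternative forced-choice behavior in which both layers are
generalized linear models of per-trial covariates.

**Choice emissions.** In state k the probability of a rightward choice
on trial t is a Bernoulli GLM,

    p(y_t = 1 | x_t^ob, z_t = k) = logistic(x_t^ob · w_k^ob),

with observation covariates x_t^ob = (normalized signed contrast,
previous choice ∈ {−1,+1}, previously rewarded side ∈ {−1,+1}, bias ≡ 1).
The previously rewarded side is the product of the previous choice code
and the previous reward code (+1 correct / −1 incorrect): it is the
unique ±1 covariate encoding "repeat after reward, switch after
failure". Signed contrast is divided by the population SD of contrasts
pooled across the training sessions; the fitted constant is stored with
the fit and reused verbatim for held-out sessions.

**State transitions.** The move from state i into state j before trial
t is a multinomial GLM with one covariate filter per *destination* state
and a baseline logit per state pair:

    p(z_t = j | z_{t−1} = i, x_t^tr) ∝ exp(B_ij + w_j^tr · x_t^tr).

Sharing destination filters across origins keeps the parameter count at
K·D_tr + K² instead of K²·D_tr while still letting trial history drive
switches. Transition covariates are causally exponential-filtered
versions of the ±1 choice, rewarded-side, and reward series plus three
warm-up temporal bases.

**History filter.** The filter is first-order recursive with decay
e^(−1/τ) and a strict one-trial lag: f_1 = 0, f_t = e^(−1/τ) f_{t−1} +
s_{t−1}. It is unnormalized (a constant ±1 input saturates at
1/(1−e^(−1/τ)) ≈ 4.52 at the default τ = 4 trials) and resets at every
session boundary. τ = 4 is the default because cross-validation over τ
on the mouse dataset this model family was developed for selects that
value; it is a shipped constant, not recomputed. Filtered covariates
are not re-standardized after filtering — the Gaussian prior on weights
absorbs their scale. The filter equation itself is a design choice (the
source analyses specify only "exponential filtering with time constant
τ"); strict causality was chosen so row t of the transition design
never contains trial-t information, which the test suite enforces as a
permutation-invariance property.

**Warm-up bases.** Three non-overlapping raised-cosine bumps tile
trials 1–100 of each session, peak-normalized to 1 and identically zero
afterward. Only the count, span and linear independence are
constrained by the source analyses; disjoint raised cosines were chosen
for smoothness and a trivially full-rank basis.

**First-trial padding.** History covariates of a session's first trial
are set to 0, the neutral point of a ±1 code, rather than dropping the
trial — this keeps session lengths intact for the forward–backward
recursions.

## Priors and identifiability

MAP fitting uses independent zero-mean Gaussians on all weights:
variance σ_ob² on W_ob and σ_tr² on both W_tr and B, plus a
Dirichlet(γ_π) prior on the initial distribution with γ_π = 1
(uniform). Defaults σ_ob = σ_tr = 4 follow the validation grid search
{0.25, 0.5, 1, 2, 4, 8, 16} for this model family; `grid_search_sigma`
re-runs that search for new data. Including B under the Gaussian prior
is essential: the row-softmax is invariant to adding a constant to a
row of B, and the likelihood is invariant to adding one constant vector
to every destination filter, so without the prior those directions are
flat. No state is pinned as a reference; regularization alone resolves
the degeneracy (the test suite verifies the likelihood invariance and
that the prior strictly prefers the centered solution, and
`posterior_sd_weights` raises on the near-zero Hessian eigenvalues that
appear when the priors are switched off). Log-prior normalization
constants are dropped throughout; all comparisons are at fixed
hyperparameters.

## Inference and fitting

The E-step uses scaled forward–backward messages: each forward message
is renormalized per trial with the scale factors accumulated, so the
marginal log-likelihood is exact and the recursion cannot underflow; no
probability clipping occurs inside the recursion. Sessions are
independent chains re-seeded with π. Sessions of equal length share
one vectorized scan (the simulator produces equal-length sessions), so
the E-step on tens of sessions costs one time loop.

The M-step maximizes the expected complete-data log-likelihood plus
log-prior: π has the closed-form Dirichlet-regularized update
(Σ_sessions φ_{1,k} + γ_π − 1, floored at 0, normalized); W_ob and
{W_tr, B} are optimized by L-BFGS-B with analytic gradients
(exponential-family forms; a finite-difference check is part of the
suite). The transition block runs a capped number of quasi-Newton
steps per EM iteration (generalized EM, 20 steps by default): since
L-BFGS-B is warm-started at the current parameters and never returns a
worse point, the log-posterior trace remains monotone while the
expensive early M-steps are spread over cheap later iterations. A
trace decrease beyond 1e−6 raises a hard error. Convergence: change in
log-posterior below `tol` (default 1e−4) or `max_iters` (default 300).
For K = 1 the first M-step already solves the penalized logistic
regression exactly, so the fit closes after one iteration.

Initialization follows the noisy-GLM recipe: a pooled 1-state penalized
Bernoulli GLM is fitted, each state's observation row is that vector
plus Gaussian noise (scale 0.2 by default — the recipe's noise scale is
unstated in the source analyses, so it is configurable), transition
filters start at zero, B at a +1 diagonal (sticky start), π uniform.
`fit_with_restarts` defaults to 50 independently seeded restarts and
returns the best final log-posterior; it also accepts a warm-start
parameter set so the global-then-individual protocol (fit pooled data,
then warm-start per-group fits from the pooled optimum) is a two-call
recipe and per-group fits need no permutation alignment.

Weight uncertainty is Laplace: the Hessian of the negative log
posterior over flattened {W_ob, W_tr, B} is built by central
differences of the analytic gradient, where each evaluation reruns the
E-step (Fisher's identity makes the E-step gradient the exact marginal
gradient), so the full rather than conditional curvature is obtained.
A non-positive-definite Hessian is reported with its null directions,
never silently pseudo-inverted.

## Evaluation

Cross-validation assigns whole sessions to k = 5 folds (never splitting
a session). Held-out sessions are scored by one forward pass under
training parameters and the training contrast normalizer. Scores are
bits per trial, (L_t − L_0)/(T_t log 2), against a baseline Bernoulli
model whose rate is the training-set MLE of p(right) (a fixed-0.5
baseline is available by flag; the minimal constant-rate Bernoulli was
chosen as the baseline since only "a Bernoulli model for observed data"
is specified). 2^(bpt·n) converts a per-trial gain into the factor by
which the better model makes n trials of data more probable.
`compare_transition_models` fits the full model and the static ablation
(W_tr ≡ 0, B free) on identical folds and restart seeds, so the paired
per-fold Δbpt isolates the transition GLM; percentile-bootstrap 68%/95%
CIs over folds are attached.

## Task simulator

The generator reproduces the block-structured task: 90 unbiased trials
(p_right = 0.5), then uncued alternation between p_right = 0.8 and 0.2
blocks; contrast magnitudes uniform on {0, 6.25, 12.5, 25, 50, 100}%,
signed by the drawn stimulus side. Block lengths are
shifted-truncated-geometric: length = min + W with W geometric of
hazard h, truncated at 100; h is solved (Brent) so the truncated mean
equals the 50-trial target exactly — using the naive hazard
1/(mean − min) would leave the truncated mean at ≈ 47.9. The task's
two published mean block lengths (50 and ≈ 58) are reconciled toward
50; the mean is configurable.

The agent samples z_1 ~ π, then per trial: transition covariates from
the online filter state, z_t from row z_{t−1} of the per-trial
transition matrix, the choice from the state's Bernoulli GLM, reward
+1 iff the choice matches the rewarded side — defined by the stimulus
side, which on zero-contrast trials is the side drawn from the block
probability — and finally the filters absorb the simulated trial. A
test asserts bit-for-bit agreement between the covariates the agent
built online and those `featurization` reconstructs from the saved
trial table.

Shipped ground-truth templates (K = 2 and K = 4) are synthetic,
hand-chosen to mirror the qualitative state structure reported for
mice: engaged states with a large stimulus weight (3.5) and small bias,
disengaged states with a small stimulus weight (0.5) and |bias| = 2;
baseline self-transition logits of 2.5–3 (self-probability ≈ 0.92,
i.e. dwell ≈ 13 trials at neutral covariates); choice/side filters
signed by the destination's side preference (±0.25), reward filter
+0.25 into disengaged and −0.25 into engaged states (the satiety
signature), and a positive first warm-up basis into disengaged states.
They are not fitted values from any dataset.

## What the simulator does and does not establish

Passing tests on simulated data show the estimator is correct and
well-calibrated *under the model*: data generated by the exact
generative process, equal-length sessions, no lapses, omissions,
response-time structure, learning drift, or within-state
nonstationarity. Real behavior violates all of these to some degree,
so recovery accuracy and the benchmark Δbpt measured here bound what to
expect on real data from above, and the Δbpt magnitude is
generator-dependent (it grows with the strength of the planted
transition filters).

## Problem sizes and numerical choices

The shipped test and acceptance workloads use scaled sizes chosen as
the package's own verification budget: oracle equivalence on 50 random
instances with T ≤ 8, K ≤ 3 at 1e−8; EM monotonicity over 20 restarts
of a 10-session × 200-trial dataset; recovery over 20 replicates of the
prescribed 40-session × 500-trial 2-state generator (per-replicate
fits use one restart, tol 1e−3 — at this scale the per-fit sampling SD
of the engaged stimulus weight is ≈ 0.15, so recovery accuracy is
asserted on the replicate-averaged weights while filter-sign
correctness is asserted per replicate); the ablation benchmark on 15
sessions × 300 trials with 5 folds. Ties in maximum-posterior labeling
go to the lowest state index. Probabilities are clipped (at 1e−300)
only at reporting boundaries such as log π in the expected
complete-data log-likelihood, never inside the recursions.

## Known limitations

Single shared τ (no per-covariate or fitted τ); no Viterbi decoding
(states are labeled by per-trial posterior argmax, matching how the
analyses define occupancy); no hierarchical priors across animals; EM
finds local MAP optima — restarts mitigate but do not guarantee the
global optimum; the Laplace SDs are asymptotic and ignore posterior
skew; trials flagged by validation are reported, never imputed — how a
retained no-response trial should be encoded is deliberately left
undefined.
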