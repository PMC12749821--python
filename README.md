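# ioglmhmm

An input–output GLM-HMM for two-alternative forced-choice behavior:
a hidden Markov model over discrete decision-making strategies whose
**choice emissions** are per-state Bernoulli GLMs and whose **state
transitions** are a multinomial GLM driven by exponentially filtered
trial history. It is built for analyses of block-structured perceptual
tasks (e.g. mice reporting the side of a visual grating while the
stimulus prior alternates between biased blocks), where animals switch
between engaged and biased strategies and the interesting question is
*what drives the switches*.

## Model

With latent state `z_t ∈ {1..K}`, choice `y_t ∈ {0,1}` and two covariate
sets per trial:

```
p(y_t = 1 | x_t_ob, z_t = k)          = logistic(x_t_ob · w_k_ob)            (choice)
p(z_t = j | z_{t-1} = i, x_t_tr)      ∝ exp(B_ij + w_j_tr · x_t_tr)          (transition)
```

Observation covariates: normalized signed contrast, previous choice
(±1), previously rewarded side (±1), bias. Transition covariates:
exponentially filtered (τ = 4 trials) choice / rewarded-side / reward
history plus three warm-up bases over a session's first 100 trials.
One filter **per destination state** plus baseline logits `B` keeps
transitions compact while letting history drive them.

Fitting is MAP expectation–maximization: exact scaled forward–backward
E-step, L-BFGS-B M-step with analytic gradients, Gaussian priors
(σ = 4) on all weights and a flat Dirichlet on the initial
distribution, with multi-restart initialization from a noisy 1-state
GLM. Model comparison uses session-level 5-fold cross-validation
scored in **bits per trial**, `(L_t − L_0)/(T_t log 2)`, against a
train-fitted Bernoulli baseline; `Δbpt · n` is then a log2 likelihood
ratio. A block-structured task simulator with a generative GLM-HMM
agent provides ground-truth data for recovery and ablation benchmarks.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import numpy as np
import ioglmhmm as ig

# simulate a 2-state agent (engaged vs. biased-R) on the block task
cfg  = ig.default_feature_config()                      # tau=4, known contrast SD
task = ig.generate_task(ig.TaskConfig(n_sessions=10, trials_per_session=300), seed=0)
data, truth = ig.simulate_agent(task, ig.default_params(2), cfg, seed=1)

# fit a 2-state model by MAP/EM with restarts
designs, sd = ig.prepare_designs(data, ig.FeatureConfig())
fit = ig.fit_with_restarts(designs, K=2, n_restarts=3, seed=2, tol=1e-3)
print(np.round(fit.params.W_ob, 2))
print(ig.classify_states(fit.params, ig.FeatureConfig()))

# compare against a static-transition ablation, 5-fold CV
cmp = ig.compare_transition_models(data, K=2, k=5, seed=3, n_restarts=1,
                                   max_iters=100, tol=1e-3)
print(f"delta bpt = {cmp['delta_bpt']:.4f} +- {cmp['delta_bpt_fold_se']:.4f}")
print(f"factor per 1000 trials = {ig.likelihood_ratio_factor(cmp['delta_bpt'], 1000):.3g}")
```

Output (seeds as shown):

```
[[ 3.    0.26 -0.1  -0.26]
 [ 0.59 -0.03  0.18  2.04]]
['engaged-L', 'biased-R']
delta bpt = 0.0477 +- 0.0129
factor per 1000 trials = 2.23e+14
```

The fitted rows recover the generator's two strategies (up to state
order and finite-sample noise): an engaged state with a steep stimulus
weight and near-zero bias, and a biased state with a flat psychometric
curve and strong rightward bias. The positive Δbpt says held-out
choices are far more probable under input-driven transitions than
under a fixed transition matrix — here the per-trial gain compounds to
a ~10^14 likelihood ratio over 1000 trials.

The same pipeline is available from the shell:

```
ioglmhmm simulate --out sim --k-states 4 --seed 0
ioglmhmm fit      --trials sim/trials.csv --out fit --k-states 4
ioglmhmm eval     --trials sim/trials.csv --out ev --compare-transitions
ioglmhmm analyze  --trials sim/trials.csv --params fit/params.json --out an
```

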