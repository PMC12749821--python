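"""MAP fitting by expectation-maximization.

E-step: exact scaled forward-backward posteriors (:mod:`.infer`).
M-step: the expected complete-data log-likelihood plus log prior is
maximized by L-BFGS-B with analytic gradients — the Bernoulli and
softmax terms are standard exponential-family forms — jointly over the
observation weights and over {transition filters, baseline logits},
while the initial-state distribution has the closed-form
Dirichlet-regularized update pi_k ∝ sum_sessions phi_{1,k} + gamma - 1.

Because each M-step is warm-started at the current parameters and
L-BFGS-B never returns a worse point than its start, the log-posterior
trace is monotone up to E-step round-off; a decrease beyond tolerance is
raised as a hard error since it signals a gradient bug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .features import FeatureConfig
from .infer import forward_backward_all
from .model import ModelParams, PriorConfig, log_prior

_LBFGS_OPTS = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}
# The transition M-step is the expensive block; a capped number of
# quasi-Newton steps per EM iteration (generalized EM) preserves
# monotonicity — L-BFGS-B never returns a point worse than its start —
# while shifting work to the cheap warm-started later iterations.
_LBFGS_TRANS_OPTS = {"maxiter": 20, "ftol": 1e-12, "gtol": 1e-8}
#: allowed numerical slack on EM monotonicity, in log-posterior units
MONOTONE_SLACK = 1e-6


class EMMonotonicityError(RuntimeError):
    pass


class SingularHessianError(RuntimeError):
    def __init__(self, msg: str, null_directions: np.ndarray):
        super().__init__(msg)
        self.null_directions = null_directions


@dataclass
class FitResult:
    params: ModelParams
    logpost_trace: np.ndarray
    converged: bool
    reason: str
    n_iters: int
    restart_index: int
    seed: int
    prior: PriorConfig
    feature_config: FeatureConfig | None = None
    all_traces: list = field(default_factory=list)

    @property
    def logpost(self) -> float:
        return float(self.logpost_trace[-1])

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "logpost_trace": np.asarray(self.logpost_trace).tolist(),
            "converged": self.converged,
            "reason": self.reason,
            "n_iters": self.n_iters,
            "restart_index": self.restart_index,
            "seed": self.seed,
            "prior": self.prior.to_dict(),
            "feature_config": self.feature_config.to_dict() if self.feature_config else None,
        }


# ---------------------------------------------------------------- M-step


def _stack_obs(designs, bundles):
    X = np.concatenate([d.X_ob for d in designs])
    y = np.concatenate([np.asarray(d.y, dtype=float) for d in designs])
    phi = np.concatenate([b.phi for b in bundles])
    return X, y, phi


def _obs_negloglik(w_flat, X, y, phi, lam, K):
    """Negative expected Bernoulli log-likelihood + ridge, with gradient.

    Separable across states: state k's term is
    sum_t phi_{t,k} [ y_t log p_{t,k} + (1-y_t) log(1-p_{t,k}) ].
    """
    W = w_flat.reshape(K, -1)
    logits = X @ W.T  # (N, K)
    # log p and log(1-p) via log-sigmoid for stability
    ll = phi * (y[:, None] * log_expit(logits) + (1.0 - y[:, None]) * log_expit(-logits))
    f = -float(ll.sum()) + 0.5 * lam * float(np.sum(W**2))
    resid = phi * (y[:, None] - expit(logits))  # (N, K)
    grad = -(resid.T @ X) + lam * W
    return f, grad.ravel()


def _stack_trans(designs, bundles):
    """Rows t = 2..T of every session: covariates, mu slices, phi at t-1."""
    Xs, mus, phis = [], [], []
    for d, b in zip(designs, bundles):
        if len(d) < 2:
            continue
        Xs.append(d.X_tr[1:])
        mus.append(b.mu)
        phis.append(b.phi[:-1])
    if not Xs:
        return None
    return np.concatenate(Xs), np.concatenate(mus), np.concatenate(phis)


def _trans_negloglik(theta, Xt, mu, phi_from, lam, K, D, free_filters):
    """Negative expected multinomial transition log-likelihood + ridge.

    Variables: destination filters W_tr (frozen at 0 when
    ``free_filters`` is False, the static-transition ablation) followed
    by the baseline logits B.  Gradient w.r.t. the logits of the move
    into trial t is mu_t - phi_{t-1} (x) A_t, the usual softmax form.
    """
    if free_filters:
        W = theta[: K * D].reshape(K, D)
        B = theta[K * D:].reshape(K, K)
    else:
        W = np.zeros((K, D))
        B = theta.reshape(K, K)
    logits = B[None] + (Xt @ W.T)[:, None, :]  # (M, K, K)
    # stable softmax/logsumexp sharing one exp pass
    m = logits.max(axis=2, keepdims=True)
    e = np.exp(logits - m)
    s = e.sum(axis=2)
    lse = m[:, :, 0] + np.log(s)  # (M, K)
    f = -float(np.sum(mu * logits)) + float(np.sum(phi_from * lse))
    f += 0.5 * lam * (float(np.sum(W**2)) + float(np.sum(B**2)))
    A = e / s[:, :, None]
    G = mu - phi_from[:, :, None] * A  # (M, K, K) gradient of ECLL wrt logits
    gB = -G.sum(axis=0) + lam * B
    if free_filters:
        gW = -(G.sum(axis=1).T @ Xt) + lam * W
        return f, np.concatenate([gW.ravel(), gB.ravel()])
    return f, gB.ravel()


def _update_pi(bundles, prior: PriorConfig, K: int) -> np.ndarray:
    counts = np.sum([b.phi[0] for b in bundles], axis=0) + (prior.gamma_pi - 1.0)
    counts = np.clip(counts, 0.0, None)
    if counts.sum() <= 0:
        return np.full(K, 1.0 / K)
    return counts / counts.sum()


def _maximize_obs(designs, bundles, params, prior):
    X, y, phi = _stack_obs(designs, bundles)
    res = minimize(
        _obs_negloglik, params.W_ob.ravel(),
        args=(X, y, phi, prior.lambda_ob, params.K),
        jac=True, method="L-BFGS-B", options=_LBFGS_OPTS,
    )
    return res.x.reshape(params.K, params.D_ob)


def _maximize_trans(designs, bundles, params, prior, ablate):
    stacked = _stack_trans(designs, bundles)
    if stacked is None:
        return params.W_tr, params.B
    Xt, mu, phi_from = stacked
    K, D = params.K, params.D_tr
    theta0 = (
        params.B.ravel() if ablate else np.concatenate([params.W_tr.ravel(), params.B.ravel()])
    )
    res = minimize(
        _trans_negloglik, theta0,
        args=(Xt, mu, phi_from, prior.lambda_tr, K, D, not ablate),
        jac=True, method="L-BFGS-B", options=_LBFGS_TRANS_OPTS,
    )
    if ablate:
        return np.zeros((K, D)), res.x.reshape(K, K)
    return res.x[: K * D].reshape(K, D), res.x[K * D:].reshape(K, K)


# ---------------------------------------------------------------- fitting


def fit_bernoulli_glm(designs, prior: PriorConfig | None = None,
                      w0: np.ndarray | None = None) -> np.ndarray:
    """Penalized 1-state Bernoulli GLM on pooled trials (the EM seed)."""
    prior = prior or PriorConfig()
    X = np.concatenate([d.X_ob for d in designs])
    y = np.concatenate([np.asarray(d.y, dtype=float) for d in designs])
    phi = np.ones((len(y), 1))
    w0 = np.zeros(X.shape[1]) if w0 is None else np.asarray(w0, dtype=float)
    res = minimize(
        _obs_negloglik, w0, args=(X, y, phi, prior.lambda_ob, 1),
        jac=True, method="L-BFGS-B", options=_LBFGS_OPTS,
    )
    if not res.success and res.status != 2:  # status 2: precision loss, still usable
        raise RuntimeError(f"1-state GLM fit failed: {res.message}")
    return res.x


def initialize_params(
    designs,
    K: int,
    seed: int,
    noise_scale: float = 0.2,
    prior: PriorConfig | None = None,
    sticky_diag: float = 1.0,
    feature_config: FeatureConfig | None = None,
) -> ModelParams:
    """Initialization: noisy copies of a 1-state GLM, zero transitions.

    Every observation-weight row is the pooled penalized Bernoulli GLM
    fit plus independent Gaussian noise (so states start distinct but
    plausible); transition filters start at zero (no initial knowledge
    of input-driven switching); B starts at zero except a common
    positive diagonal offset so the chain starts sticky; pi is uniform.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    w = fit_bernoulli_glm(designs, prior)
    D_ob = w.size
    W_ob = np.tile(w, (K, 1))
    if K > 1 and noise_scale > 0:
        W_ob = W_ob + noise_scale * rng.standard_normal((K, D_ob))
    D_tr = designs[0].X_tr.shape[1]
    B = sticky_diag * np.eye(K)
    obs_names = feature_config.obs_covariates if feature_config else ()
    tr_names = feature_config.tr_covariates if feature_config else ()
    return ModelParams(
        pi=np.full(K, 1.0 / K), W_ob=W_ob, W_tr=np.zeros((K, D_tr)), B=B,
        obs_names=obs_names, tr_names=tr_names,
    )


def em_fit(
    designs,
    init: ModelParams,
    prior: PriorConfig | None = None,
    max_iters: int = 300,
    tol: float = 1e-4,
    ablate_transitions: bool = False,
    seed: int = 0,
    restart_index: int = 0,
    feature_config: FeatureConfig | None = None,
) -> FitResult:
    """Run EM to a local MAP optimum.

    Stops when the log-posterior improves by less than ``tol`` between
    consecutive iterations, or at ``max_iters``.  With
    ``ablate_transitions`` the destination filters are pinned at zero
    and only the baseline logits B are learned (a static-transition
    HMM), which is the comparison model for input-driven transitions.
    """
    prior = prior or PriorConfig()
    params = init.copy()
    if ablate_transitions:
        params.W_tr = np.zeros_like(params.W_tr)
    trace: list[float] = []
    converged, reason = False, "max_iters"
    for it in range(max_iters + 1):
        bundles = forward_backward_all(designs, params)
        lp = float(sum(b.logZ for b in bundles)) + log_prior(params, prior)
        if trace and lp < trace[-1] - MONOTONE_SLACK:
            raise EMMonotonicityError(
                f"log-posterior decreased at iteration {it}: {trace[-1]:.8f} -> {lp:.8f}"
            )
        trace.append(lp)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged, reason = True, "tol"
            break
        if it == max_iters:
            break
        params.pi = _update_pi(bundles, prior, params.K)
        params.W_ob = _maximize_obs(designs, bundles, params, prior)
        if params.K > 1:
            params.W_tr, params.B = _maximize_trans(
                designs, bundles, params, prior, ablate_transitions
            )
        if params.K == 1:
            # one M-step solves the penalized GLM exactly; record the
            # optimum and stop
            bundles = forward_backward_all(designs, params)
            lp = float(sum(b.logZ for b in bundles)) + log_prior(params, prior)
            trace.append(lp)
            converged, reason = True, "K=1 closed after one M-step"
            break
    return FitResult(
        params=params, logpost_trace=np.asarray(trace), converged=converged,
        reason=reason, n_iters=len(trace) - 1, restart_index=restart_index,
        seed=seed, prior=prior, feature_config=feature_config,
    )


def fit_with_restarts(
    designs,
    K: int,
    prior: PriorConfig | None = None,
    n_restarts: int = 50,
    seed: int = 0,
    noise_scale: float = 0.2,
    init: ModelParams | None = None,
    feature_config: FeatureConfig | None = None,
    **em_kwargs,
) -> FitResult:
    """Best-of-``n_restarts`` EM fits from independently seeded inits.

    The default of 50 restarts follows the robust-fitting protocol for
    this model family; small problems rarely need more than a handful.
    When ``init`` is given it is used for restart 0 (warm start, e.g.
    from a pooled global fit) and noisy re-initializations fill the
    rest.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best: FitResult | None = None
    traces, errors = [], []
    for r, s in enumerate(seeds):
        try:
            start = (
                init if (init is not None and r == 0)
                else initialize_params(designs, K, int(s), noise_scale, prior,
                                       feature_config=feature_config)
            )
            fit = em_fit(designs, start, prior, seed=int(s), restart_index=r,
                         feature_config=feature_config, **em_kwargs)
        except EMMonotonicityError:
            raise
        except Exception as exc:  # noqa: BLE001 - aggregate per-restart failures
            errors.append(f"restart {r}: {exc}")
            continue
        traces.append(fit.logpost_trace)
        if best is None or fit.logpost > best.logpost:
            best = fit
    if best is None:
        raise RuntimeError("all restarts failed:\n" + "\n".join(errors))
    best.all_traces = traces
    return best


DEFAULT_SIGMA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


def grid_search_sigma(
    train_designs,
    val_designs,
    K: int,
    grid=DEFAULT_SIGMA_GRID,
    seed: int = 0,
    n_restarts: int = 3,
    **em_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Select the Gaussian prior SD by validation bits per trial.

    One shared sigma is used for both weight groups.  The shipped
    package default (sigma = 4) is a fixed convention, not recomputed
    here; this search is for users re-tuning on their own data.
    """
    from .evaluate import baseline_log_likelihood, bits_per_trial
    from .infer import marginal_loglik

    grid = tuple(grid)
    if not grid:
        raise ValueError("sigma grid must be non-empty")
    y_train = np.concatenate([d.y for d in train_designs])
    y_val = np.concatenate([d.y for d in val_designs])
    l0 = baseline_log_likelihood(y_train, y_val)
    rows = []
    for sigma in grid:
        prior = PriorConfig(sigma_ob=sigma, sigma_tr=sigma)
        fit = fit_with_restarts(train_designs, K, prior, n_restarts=n_restarts,
                                seed=seed, **em_kwargs)
        ll = marginal_loglik(val_designs, fit.params)
        rows.append({
            "sigma": sigma, "val_loglik": ll,
            "val_bpt": bits_per_trial(ll, l0, len(y_val)),
        })
    table = pd.DataFrame(rows)
    best = float(table.loc[table["val_bpt"].idxmax(), "sigma"])
    return best, table


# ------------------------------------------------------- weight uncertainty


def _flatten_weights(params: ModelParams) -> np.ndarray:
    return np.concatenate([params.W_ob.ravel(), params.W_tr.ravel(), params.B.ravel()])


def _unflatten_weights(theta: np.ndarray, like: ModelParams) -> ModelParams:
    K, D_ob, D_tr = like.K, like.D_ob, like.D_tr
    p = like.copy()
    i = 0
    p.W_ob = theta[i: i + K * D_ob].reshape(K, D_ob); i += K * D_ob
    p.W_tr = theta[i: i + K * D_tr].reshape(K, D_tr); i += K * D_tr
    p.B = theta[i:].reshape(K, K)
    return p


def grad_log_posterior_weights(designs, params: ModelParams, prior: PriorConfig) -> np.ndarray:
    """Gradient of the log posterior w.r.t. flattened {W_ob, W_tr, B}.

    Uses the Fisher identity: the gradient of the marginal log-likelihood
    equals the gradient of the expected complete-data log-likelihood
    evaluated at posteriors computed at the same parameters.
    """
    bundles = forward_backward_all(designs, params)
    X, y, phi = _stack_obs(designs, bundles)
    _, g_obs = _obs_negloglik(params.W_ob.ravel(), X, y, phi, prior.lambda_ob, params.K)
    stacked = _stack_trans(designs, bundles)
    if stacked is None:
        g_tr = np.concatenate([
            prior.lambda_tr * params.W_tr.ravel(), prior.lambda_tr * params.B.ravel()
        ])
    else:
        Xt, mu, phi_from = stacked
        theta = np.concatenate([params.W_tr.ravel(), params.B.ravel()])
        _, g_tr = _trans_negloglik(theta, Xt, mu, phi_from, prior.lambda_tr,
                                   params.K, params.D_tr, True)
    return -np.concatenate([g_obs, g_tr])  # negate: helpers return neg-loglik grads


def posterior_sd_weights(fit: FitResult, designs, step: float = 1e-4,
                         eig_tol: float = 1e-8) -> dict:
    """Laplace posterior SDs from the inverse Hessian at the optimum.

    The Hessian of the negative log posterior over flattened
    {W_ob, W_tr, B} is formed by central differences of the analytic
    gradient (each evaluation is a fresh E-step, so the full — not
    conditional — Hessian is obtained).  A non-positive-definite result
    raises :class:`SingularHessianError` carrying the offending
    directions rather than silently pseudo-inverting; with priors
    disabled the softmax shift degeneracy makes this the expected
    outcome.
    """
    params, prior = fit.params, fit.prior
    theta0 = _flatten_weights(params)
    n = theta0.size
    H = np.empty((n, n))
    for i in range(n):
        h = step * (1.0 + abs(theta0[i]))
        tp, tm = theta0.copy(), theta0.copy()
        tp[i] += h
        tm[i] -= h
        gp = grad_log_posterior_weights(designs, _unflatten_weights(tp, params), prior)
        gm = grad_log_posterior_weights(designs, _unflatten_weights(tm, params), prior)
        H[:, i] = (gp - gm) / (2.0 * h)
    Hneg = -0.5 * (H + H.T)  # symmetrized Hessian of the negative log posterior
    eigvals, eigvecs = np.linalg.eigh(Hneg)
    if eigvals.min() <= eig_tol:
        bad = eigvecs[:, eigvals <= eig_tol]
        raise SingularHessianError(
            f"Hessian not positive definite (min eigenvalue {eigvals.min():.3e})", bad
        )
    sd = np.sqrt(np.diag(np.linalg.inv(Hneg)))
    K, D_ob, D_tr = params.K, params.D_ob, params.D_tr
    i1, i2 = K * D_ob, K * D_ob + K * D_tr
    return {
        "W_ob": sd[:i1].reshape(K, D_ob),
        "W_tr": sd[i1:i2].reshape(K, D_tr),
        "B": sd[i2:].reshape(K, K),
    }
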