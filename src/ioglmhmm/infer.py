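"""Exact E-step quantities via scaled forward-backward recursions.

Messages are rescaled to sum to one at every trial and the scale factors
are accumulated, so the session marginal log-likelihood logZ is exact
while the recursion never underflows.  The forward recursion is seeded
with pi_k * p(y_1 | z_1 = k) and propagated through the per-trial
transition matrices; posteriors follow the standard smoothing identities

    phi_{t,k}    = P(z_t = k | Y, X)          (T x K, rows sum to 1)
    mu_{t,j,k}   = P(z_t = j, z_{t+1} = k | Y, X)   ((T-1) x K x K)

Sessions are independent chains, each re-seeded with pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, bernoulli_loglik_matrix, transition_tensor


class NumericalInferenceError(FloatingPointError):
    pass


@dataclass
class PosteriorBundle:
    """Forward-backward output for one session.

    alpha_hat / beta_hat are the scaled messages; ``log_c`` records the
    per-trial scaling constants, so the unscaled forward message is
    alpha_hat[t] * exp(log_c[: t + 1].sum()) and logZ = log_c.sum().
    """

    phi: np.ndarray
    mu: np.ndarray
    logZ: float
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    log_c: np.ndarray

    @property
    def T(self) -> int:
        return self.phi.shape[0]

    @property
    def K(self) -> int:
        return self.phi.shape[1]


def _scan(E: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Batched scaled forward-backward.

    E : (S, T, K) likelihood of the observed choice per trial and state.
    A : (S, T, K, K) transition matrices; A[:, t] governs the move into
        trial t, so index 0 is unused.
    Returns (alpha_hat, beta_hat, log_c, phi, mu) with a leading batch
    axis S everywhere.
    """
    S, T, K = E.shape
    alpha = np.empty((S, T, K))
    beta = np.empty((S, T, K))
    log_c = np.empty((S, T))

    a = pi[None, :] * E[:, 0]
    c = a.sum(axis=1)
    if np.any(c <= 0) or not np.all(np.isfinite(c)):
        raise NumericalInferenceError("non-finite forward message at trial 0")
    alpha[:, 0] = a / c[:, None]
    log_c[:, 0] = np.log(c)
    for t in range(1, T):
        a = np.einsum("sj,sjk->sk", alpha[:, t - 1], A[:, t]) * E[:, t]
        c = a.sum(axis=1)
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise NumericalInferenceError(f"non-finite forward message at trial {t}")
        alpha[:, t] = a / c[:, None]
        log_c[:, t] = np.log(c)

    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = np.einsum("sjk,sk->sj", A[:, t + 1], E[:, t + 1] * beta[:, t + 1])
        beta[:, t] = b / np.exp(log_c[:, t + 1])[:, None]
        if not np.all(np.isfinite(beta[:, t])):
            raise NumericalInferenceError(f"non-finite backward message at trial {t}")

    phi = alpha * beta
    # with this scaling phi rows are already normalized; renormalize to
    # absorb rounding so downstream sums are exact
    phi /= phi.sum(axis=2, keepdims=True)
    if T > 1:
        mu = (
            alpha[:, :-1, :, None]
            * A[:, 1:]
            * (E[:, 1:] * beta[:, 1:])[:, :, None, :]
            / np.exp(log_c[:, 1:])[:, :, None, None]
        )
        mu /= mu.sum(axis=(2, 3), keepdims=True)
    else:
        mu = np.empty((S, 0, K, K))
    return alpha, beta, log_c, phi, mu


def forward_backward(
    X_ob: np.ndarray, X_tr: np.ndarray, choices: np.ndarray, params: ModelParams
) -> PosteriorBundle:
    """Run scaled forward-backward on one session."""
    X_ob = np.atleast_2d(X_ob)
    X_tr = np.atleast_2d(X_tr)
    choices = np.asarray(choices)
    if not (len(X_ob) == len(X_tr) == len(choices)):
        raise ValueError("designs and choices must be aligned")
    E = np.exp(bernoulli_loglik_matrix(X_ob, choices, params.W_ob))[None]
    A = transition_tensor(X_tr, params)[None]
    alpha, beta, log_c, phi, mu = _scan(E, A, params.pi)
    return PosteriorBundle(
        phi=phi[0], mu=mu[0], logZ=float(log_c[0].sum()),
        alpha_hat=alpha[0], beta_hat=beta[0], log_c=log_c[0],
    )


def _grouped(designs):
    """Yield (indices, stacked E, stacked A) for sessions grouped by length."""
    by_len: dict[int, list[int]] = {}
    for i, d in enumerate(designs):
        by_len.setdefault(len(d), []).append(i)
    for T, idx in by_len.items():
        yield idx, T


def forward_backward_all(designs, params: ModelParams) -> list[PosteriorBundle]:
    """E-step over many sessions, batching sessions of equal length.

    Equal-length sessions share one vectorized scan, which is what makes
    EM on simulator-scale datasets (tens of sessions x hundreds of
    trials) cheap; ragged collections fall back to per-session scans
    within each length group.
    """
    bundles: list[PosteriorBundle | None] = [None] * len(designs)
    for idx, _T in _grouped(designs):
        E = np.stack(
            [np.exp(bernoulli_loglik_matrix(designs[i].X_ob, designs[i].y, params.W_ob)) for i in idx]
        )
        A = np.stack([transition_tensor(designs[i].X_tr, params) for i in idx])
        alpha, beta, log_c, phi, mu = _scan(E, A, params.pi)
        for s, i in enumerate(idx):
            bundles[i] = PosteriorBundle(
                phi=phi[s], mu=mu[s], logZ=float(log_c[s].sum()),
                alpha_hat=alpha[s], beta_hat=beta[s], log_c=log_c[s],
            )
    return bundles  # type: ignore[return-value]


def marginal_loglik(designs, params: ModelParams) -> float:
    """Sum of per-session marginal log-likelihoods log P(Y | X, params)."""
    return float(sum(b.logZ for b in forward_backward_all(designs, params)))


def expected_complete_loglik(
    bundle: PosteriorBundle,
    X_ob: np.ndarray,
    X_tr: np.ndarray,
    choices: np.ndarray,
    params: ModelParams,
) -> float:
    """Expected complete-data log-likelihood E_{z|Y}[log p(Y, z)].

    sum_t sum_{j,k} mu log A_t  +  sum_t sum_k phi log p(y_t | .)
    +  sum_k phi_{1,k} log pi_k.
    """
    ll_obs = float(np.sum(bundle.phi * bernoulli_loglik_matrix(X_ob, choices, params.W_ob)))
    A = transition_tensor(X_tr, params)
    ll_tr = float(np.sum(bundle.mu * np.log(np.clip(A[1:], 1e-300, None))))
    init = float(
        np.sum(bundle.phi[0] * np.log(np.clip(params.pi, 1e-300, None)), where=bundle.phi[0] > 0)
    )
    return ll_obs + ll_tr + init


def map_states(bundle: PosteriorBundle) -> np.ndarray:
    """Per-trial maximum-posterior state labels; ties go to the lowest index."""
    return np.argmax(bundle.phi, axis=1)
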