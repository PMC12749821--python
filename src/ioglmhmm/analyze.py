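"""Derived behavioral/state quantities from fitted models and posteriors.

Psychometric curves per state and their state-probability-weighted
mixture; the baseline transition-bias matrix and the covariate-averaged
transition matrix; geometric expected dwell times; fractional occupancy,
state-change counts and first-transition latencies from maximum-
posterior labels; session-normalized state-probability time courses; and
the engaged/disengaged response-time separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureConfig
from .infer import PosteriorBundle, map_states
from .model import ModelParams, transition_tensor
from scipy.special import expit, softmax


@dataclass
class StateSummary:
    occupancy: np.ndarray                      # (K,) over all labeled trials
    occupancy_by_block: dict = field(default_factory=dict)  # block label -> (K,)
    state_changes: list[int] = field(default_factory=list)  # per session
    expected_dwell: np.ndarray | None = None   # (K,) trials
    first_transition_latency: list[int] = field(default_factory=list)  # per block
    state_prob_timecourse: np.ndarray | None = None  # (K, n_grid)


def psychometric_curves(
    params: ModelParams,
    contrast_grid: np.ndarray,
    feature_config: FeatureConfig,
) -> np.ndarray:
    """(K, len(grid)) P(rightward) per state over signed contrasts.

    History covariates sit at their neutral value 0 and bias at 1, so
    each curve is the state's choice rule stripped of trial history:
    logistic(w_stim * c / sd + w_bias).
    """
    if isinstance(feature_config.contrast_sd, str):
        raise ValueError("needs a numeric contrast_sd (training-set normalizer)")
    grid = np.asarray(contrast_grid, dtype=float)
    names = list(feature_config.obs_covariates)
    X = np.zeros((grid.size, len(names)))
    X[:, names.index("stimulus")] = grid / float(feature_config.contrast_sd)
    X[:, names.index("bias")] = 1.0
    return expit(params.W_ob @ X.T)


def predictive_state_probs(bundle: PosteriorBundle, X_tr: np.ndarray,
                           params: ModelParams) -> np.ndarray:
    """One-step-ahead state probabilities p(z_t | y_{1:t-1}, X).

    Trial 1 uses pi; trial t propagates the filtered posterior through
    the trial-t transition matrix.  These are the weights the model
    itself would use before seeing trial t's choice.
    """
    A = transition_tensor(X_tr, params)
    pred = np.empty_like(bundle.alpha_hat)
    pred[0] = params.pi
    for t in range(1, len(pred)):
        pred[t] = bundle.alpha_hat[t - 1] @ A[t]
    return pred


def model_psychometric_curve(
    params: ModelParams,
    contrast_grid: np.ndarray,
    feature_config: FeatureConfig,
    bundles: list[PosteriorBundle],
    X_tr_list: list[np.ndarray],
) -> np.ndarray:
    """State-weighted model psychometric curve along observed sessions.

    Per-state curves are averaged with weights equal to the mean
    one-step-ahead (predictive) state probability over all trials, i.e.
    the mixture the model assigns before each choice, contingent on the
    state sampled at the preceding trial.
    """
    curves = psychometric_curves(params, contrast_grid, feature_config)
    pred = np.concatenate(
        [predictive_state_probs(b, X, params) for b, X in zip(bundles, X_tr_list)]
    )
    weights = pred.mean(axis=0)
    return weights @ curves


def empirical_psychometric(signed_contrast: np.ndarray, choices: np.ndarray):
    """Observed P(right) per unique signed contrast, with binomial 95% CI."""
    from scipy.stats import beta

    levels = np.unique(signed_contrast)
    p, lo, hi, n = [], [], [], []
    for c in levels:
        m = signed_contrast == c
        k, tot = int(choices[m].sum()), int(m.sum())
        p.append(k / tot)
        # Jeffreys interval
        lo.append(float(beta.ppf(0.025, k + 0.5, tot - k + 0.5)) if tot else np.nan)
        hi.append(float(beta.ppf(0.975, k + 0.5, tot - k + 0.5)) if tot else np.nan)
        n.append(tot)
    return levels, np.array(p), np.array(lo), np.array(hi), np.array(n)


def expected_dwell_times(A_bar: np.ndarray) -> np.ndarray:
    """Geometric expected holding time per state: 1 / (1 - A_kk).

    ``A_bar`` is the covariate-averaged transition matrix.  A
    self-transition probability of 1 yields ``inf`` (a flag, not an
    error).
    """
    A_bar = np.asarray(A_bar, dtype=float)
    if not np.allclose(A_bar.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("A_bar rows must sum to 1")
    stay = np.diag(A_bar)
    with np.errstate(divide="ignore"):
        return np.where(stay >= 1.0, np.inf, 1.0 / (1.0 - stay))


def transition_bias_and_matrix(params: ModelParams,
                               X_tr_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(row-softmax of B alone, mean over trials of per-trial matrices).

    The first is the model's default transition expectation prior to
    input modulation; the second is the covariate-averaged matrix used
    for dwell times.
    """
    bias = softmax(params.B, axis=1)
    tensors = [transition_tensor(X, params)[1:] for X in X_tr_list]  # drop unused row 0
    avg = np.concatenate(tensors).mean(axis=0)
    return bias, avg


def _block_segments(block_p_right: np.ndarray):
    """Contiguous (start, end, p_right) runs of the block label."""
    change = np.flatnonzero(np.diff(block_p_right) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(block_p_right)]))
    return [(int(s), int(e), float(block_p_right[s])) for s, e in zip(starts, ends)]


def state_summaries(
    bundles: list[PosteriorBundle],
    block_labels: list[np.ndarray] | None = None,
    congruent_states: dict[float, np.ndarray] | None = None,
    n_grid: int = 100,
) -> StateSummary:
    """Occupancy, state changes, latencies, and the state-probability time course.

    ``block_labels`` gives per-session block p(right) arrays;
    ``congruent_states`` maps a block probability to the set of state
    indices congruent with it (e.g. right-preferring states for
    p_right = 0.8), as classified from fitted bias weights.  Latency is
    the trial count from block onset to the first maximum-posterior
    label inside the congruent set.
    """
    K = bundles[0].K
    labels = [map_states(b) for b in bundles]
    allz = np.concatenate(labels)
    occupancy = np.bincount(allz, minlength=K) / allz.size
    changes = [int(np.sum(np.diff(z) != 0)) for z in labels]

    occ_by_block: dict[float, np.ndarray] = {}
    latencies: list[int] = []
    if block_labels is not None:
        for z, bp in zip(labels, block_labels):
            for p in np.unique(bp):
                m = bp == p
                occ_by_block.setdefault(float(p), np.zeros(K))
                occ_by_block[float(p)] += np.bincount(z[m], minlength=K)
            if congruent_states:
                for start, end, p in _block_segments(bp):
                    if p not in congruent_states:
                        continue
                    hits = np.flatnonzero(np.isin(z[start:end], congruent_states[p]))
                    if hits.size:
                        latencies.append(int(hits[0]))
        occ_by_block = {p: v / v.sum() for p, v in occ_by_block.items()}

    grid = np.linspace(0.0, 1.0, n_grid)
    courses = []
    for b in bundles:
        x = np.linspace(0.0, 1.0, b.T)
        courses.append(np.stack([np.interp(grid, x, b.phi[:, k]) for k in range(K)]))
    timecourse = np.mean(courses, axis=0)

    return StateSummary(
        occupancy=occupancy,
        occupancy_by_block=occ_by_block,
        state_changes=changes,
        first_transition_latency=latencies,
        state_prob_timecourse=timecourse,
    )


def classify_states(params: ModelParams, feature_config: FeatureConfig | None = None) -> list[str]:
    """Label states engaged/biased x L/R from fitted observation weights.

    A state is "engaged" when its |stimulus weight| exceeds the
    across-state median, and L/R follows the sign of its bias weight.
    """
    names = list(feature_config.obs_covariates) if feature_config else None
    i_stim = names.index("stimulus") if names else 0
    i_bias = names.index("bias") if names else params.D_ob - 1
    w_stim = np.abs(params.W_ob[:, i_stim])
    w_bias = params.W_ob[:, i_bias]
    thresh = np.median(w_stim)
    out = []
    for k in range(params.K):
        kind = "engaged" if w_stim[k] > thresh else "biased"
        side = "R" if w_bias[k] >= 0 else "L"
        out.append(f"{kind}-{side}")
    return out


def _quantile(x: np.ndarray, q: float) -> float:
    return float(np.quantile(x, q, method="linear"))


def rt_engagement_separation(
    response_times: np.ndarray,
    labels: np.ndarray,
    engaged_states: np.ndarray,
    q: float = 0.9,
    n_boot: int = 5000,
    seed: int = 0,
) -> dict:
    """Delta T90: disengaged minus engaged 90th-percentile response time.

    Percentile bootstrap over trials (resampling within each group)
    yields the 95% CI.
    """
    response_times = np.asarray(response_times, dtype=float)
    if response_times.shape != np.asarray(labels).shape:
        raise ValueError("response_times and labels must be aligned")
    engaged = np.isin(labels, engaged_states)
    rt_e, rt_d = response_times[engaged], response_times[~engaged]
    if rt_e.size == 0 or rt_d.size == 0:
        raise ValueError("both engaged and disengaged trials are required")
    delta = _quantile(rt_d, q) - _quantile(rt_e, q)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _quantile(rng.choice(rt_d, rt_d.size), q) - _quantile(
            rng.choice(rt_e, rt_e.size), q
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"delta_t90": float(delta), "ci95": (float(lo), float(hi)), "n_boot": n_boot}
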