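"""Session-level cross-validation and bits-per-trial model comparison.

Held-out sessions are scored by a single forward pass under the
training-fitted parameters (and training-fitted contrast normalizer);
the score is reported relative to a baseline Bernoulli model as

    L_bpt = (L_t - L_0) / (T_t * log 2),

so that Delta_bpt * n_trials is a log2 likelihood ratio: a model 0.015
bpt better makes 400 trials of data 2^6 = 64 times more probable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureConfig, prepare_designs
from .fit import FitResult, fit_with_restarts
from .infer import forward_backward_all, map_states
from .model import PriorConfig
from .trial_io import SessionSet


@dataclass
class EvalResult:
    """Tidy per-fold evaluation of one model arm."""

    model_tag: str
    per_fold: list[dict] = field(default_factory=list)

    @property
    def bpt_per_fold(self) -> np.ndarray:
        return np.array([f["bpt"] for f in self.per_fold])

    @property
    def mean_bpt(self) -> float:
        return float(self.bpt_per_fold.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"model_tag": self.model_tag, "fold": i, **f} for i, f in enumerate(self.per_fold)]
        )


def session_kfold_split(data: SessionSet, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Assign whole sessions to k folds, deterministically under ``seed``.

    Sessions are never split within a fold; the default k = 5 matches
    the standard protocol for this analysis.
    """
    n = len(data)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n_sessions, got k={k}, n={n}")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(order[i::k]) for i in range(k)]


def baseline_log_likelihood(
    y_train: np.ndarray, y_test: np.ndarray, rate: float | None = None
) -> float:
    """Log-likelihood of test choices under a single Bernoulli rate.

    The rate is the training-set MLE of p(rightward) unless fixed (e.g.
    0.5 for a coin-flip baseline).  This constant-rate Bernoulli is the
    minimal baseline observation model.
    """
    if rate is None:
        rate = float(np.mean(y_train))
    rate = float(np.clip(rate, 1e-12, 1.0 - 1e-12))
    y_test = np.asarray(y_test, dtype=float)
    return float(np.sum(y_test * np.log(rate) + (1.0 - y_test) * np.log(1.0 - rate)))


def bits_per_trial(test_ll: float, baseline_ll: float, n_trials: int) -> float:
    """(L_t - L_0) / (T_t log 2)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return (test_ll - baseline_ll) / (n_trials * np.log(2.0))


def likelihood_ratio_factor(bpt: float, n_trials: int) -> float:
    """2^(bpt * n): how much more probable the data are under the better model."""
    return float(2.0 ** (bpt * n_trials))


def _fit_and_score_fold(
    data: SessionSet,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    K: int,
    prior: PriorConfig,
    config: FeatureConfig,
    seed: int,
    n_restarts: int,
    ablate: bool,
    baseline_rate: float | None,
    **em_kwargs,
) -> tuple[dict, FitResult, list]:
    from .infer import marginal_loglik

    train = data.subset(train_idx)
    test = data.subset(test_idx)
    train_designs, sd = prepare_designs(train, config)
    test_designs, _ = prepare_designs(test, config, contrast_sd=sd)
    fit = fit_with_restarts(
        train_designs, K, prior, n_restarts=n_restarts, seed=seed,
        ablate_transitions=ablate, **em_kwargs,
    )
    y_train = np.concatenate([d.y for d in train_designs])
    y_test = np.concatenate([d.y for d in test_designs])
    test_ll = marginal_loglik(test_designs, fit.params)
    l0 = baseline_log_likelihood(y_train, y_test, baseline_rate)
    record = {
        "train_sessions": [data.sessions[i].session_id for i in train_idx],
        "test_sessions": [data.sessions[i].session_id for i in test_idx],
        "test_ll": test_ll,
        "baseline_ll": l0,
        "n_test_trials": int(len(y_test)),
        "bpt": bits_per_trial(test_ll, l0, len(y_test)),
    }
    return record, fit, test_designs


def cross_validate(
    data: SessionSet,
    K: int,
    prior: PriorConfig | None = None,
    config: FeatureConfig | None = None,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 3,
    ablate_transitions: bool = False,
    baseline_rate: float | None = None,
    **em_kwargs,
) -> EvalResult:
    """k-fold session-level cross-validation of one model configuration."""
    prior = prior or PriorConfig()
    config = config or FeatureConfig()
    folds = session_kfold_split(data, k, seed)
    all_idx = np.arange(len(data))
    tag = "static-transitions" if ablate_transitions else ("1-state" if K == 1 else "with-GLM-T")
    result = EvalResult(model_tag=tag)
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        record, _, _ = _fit_and_score_fold(
            data, train_idx, test_idx, K, prior, config, seed + i, n_restarts,
            ablate_transitions, baseline_rate, **em_kwargs,
        )
        result.per_fold.append(record)
    return result


def _bootstrap_ci(values: np.ndarray, seed: int, n_boot: int = 2000,
                  levels=(68.0, 95.0)) -> dict:
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    out = {}
    for lv in levels:
        lo, hi = np.percentile(means, [(100 - lv) / 2, 100 - (100 - lv) / 2])
        out[f"ci{int(lv)}"] = (float(lo), float(hi))
    return out


def compare_transition_models(
    data: SessionSet,
    K: int,
    prior: PriorConfig | None = None,
    config: FeatureConfig | None = None,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 3,
    baseline_rate: float | None = None,
    **em_kwargs,
) -> dict:
    """Paired comparison: input-driven vs. static transitions.

    Both arms are fitted on identical folds with identical restart
    seeds, so the per-fold bpt difference is attributable to the
    transition model alone.  Also returns, per arm, each held-out
    trial's maximum-posterior state probability, for the
    state-confidence scatter diagnostic.
    """
    prior = prior or PriorConfig()
    config = config or FeatureConfig()
    folds = session_kfold_split(data, k, seed)
    all_idx = np.arange(len(data))
    full = EvalResult(model_tag="with-GLM-T")
    static = EvalResult(model_tag="static-transitions")
    scatter = {"with-GLM-T": [], "static-transitions": []}
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        for ablate, res, tag in ((False, full, "with-GLM-T"),
                                 (True, static, "static-transitions")):
            record, fit, test_designs = _fit_and_score_fold(
                data, train_idx, test_idx, K, prior, config, seed + i,
                n_restarts, ablate, baseline_rate, **em_kwargs,
            )
            res.per_fold.append(record)
            for b in forward_backward_all(test_designs, fit.params):
                scatter[tag].append(b.phi[np.arange(b.T), map_states(b)])
    delta = full.bpt_per_fold - static.bpt_per_fold
    fold_se = float(delta.std(ddof=1) / np.sqrt(len(delta)))
    return {
        "full": full,
        "static": static,
        "delta_bpt_per_fold": delta,
        "delta_bpt": float(delta.mean()),
        "delta_bpt_fold_se": fold_se,
        "delta_bpt_ci": _bootstrap_ci(delta, seed),
        "map_state_prob": {tag: np.concatenate(v) for tag, v in scatter.items()},
    }
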