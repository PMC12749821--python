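"""Block-structured task simulator and generative GLM-HMM agent.

Task structure: each session opens with 90 unbiased trials (right-side
stimulus probability 0.5), after which the right-stimulus probability
alternates between 0.8 and 0.2 in uncued blocks whose lengths follow a
shifted, truncated geometric law on [20, 100] trials with a 50-trial
mean.  Contrast magnitudes are drawn uniformly from
{0, 6.25, 12.5, 25, 50, 100}% and signed by the stimulus side.

Agent: latent states are sampled from the multinomial transition GLM,
choices from the per-state Bernoulli GLM, with every history covariate
(choice, rewarded side, reward, and their exponential filters) updated
recursively from the *simulated* trial history, so generated data carry
exactly the statistical structure the model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, softmax

from .features import FeatureConfig, warmup_bases
from .model import ModelParams
from .trial_io import Session, SessionSet

DEFAULT_CONTRAST_SET = (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0)

#: population SD of signed contrast when magnitudes are uniform over the
#: default set and sides are balanced: sqrt(mean(c^2)) = 0.4712...
DEFAULT_CONTRAST_SD = float(np.sqrt(np.mean(np.square(DEFAULT_CONTRAST_SET))))


@dataclass(frozen=True)
class TaskConfig:
    n_unbiased: int = 90
    p_right_blocks: tuple[float, float] = (0.8, 0.2)
    block_min: int = 20
    block_max: int = 100
    block_mean_target: float = 50.0
    contrast_set: tuple[float, ...] = DEFAULT_CONTRAST_SET
    n_sessions: int = 20
    trials_per_session: int = 500

    def __post_init__(self) -> None:
        if not self.block_min <= self.block_mean_target <= self.block_max:
            raise ValueError("need block_min <= block_mean_target <= block_max")
        if not self.contrast_set:
            raise ValueError("contrast_set must be non-empty")


def block_switch_hazard(config: TaskConfig) -> float:
    """Per-trial switch hazard giving the target mean block length.

    A block lasts min + W trials, W geometric on {1, 2, ...} with
    success probability h, truncated so the block never exceeds
    block_max.  The truncated mean is min + (1 - (1-h)^M) / h with
    M = block_max - block_min; h is solved so this equals the target.
    """
    M = config.block_max - config.block_min
    target = config.block_mean_target - config.block_min
    if target <= 0:
        return 1.0

    def mean_minus_target(h):
        return (1.0 - (1.0 - h) ** M) / h - target

    if mean_minus_target(1.0 - 1e-12) > 0:
        raise ValueError("block_mean_target infeasible for given min/max")
    return float(brentq(mean_minus_target, 1e-9, 1.0 - 1e-12, xtol=1e-12))


def sample_block_length(rng: np.random.Generator, config: TaskConfig,
                        hazard: float | None = None) -> int:
    h = block_switch_hazard(config) if hazard is None else hazard
    w = rng.geometric(h)  # support {1, 2, ...}
    return int(min(config.block_min + w, config.block_max))


def generate_task(config: TaskConfig, seed: int = 0) -> SessionSet:
    """Generate stimuli and block labels (no choices) for every session."""
    rng = np.random.default_rng(seed)
    hazard = block_switch_hazard(config)
    magnitudes = np.asarray(config.contrast_set, dtype=float)
    sessions = []
    for s in range(config.n_sessions):
        T = config.trials_per_session
        p_right = np.empty(T)
        p_right[: config.n_unbiased] = 0.5
        t = config.n_unbiased
        p = config.p_right_blocks[rng.integers(2)]
        while t < T:
            length = sample_block_length(rng, config, hazard)
            p_right[t: t + length] = p
            t += length
            p = config.p_right_blocks[0] if p == config.p_right_blocks[1] else config.p_right_blocks[1]
        side = np.where(rng.random(T) < p_right, 1.0, -1.0)
        contrast = side * rng.choice(magnitudes, size=T)
        table = pd.DataFrame(
            {
                "session_id": f"sim-{s:03d}",
                "trial_index": np.arange(T),
                "signed_contrast": contrast,
                "block_p_right": p_right,
                "stim_side": side,
            }
        )
        sessions.append(Session(f"sim-{s:03d}", table))
    return SessionSet(sessions, {"source": "task_simulator", "seed": seed})


@dataclass
class GroundTruth:
    """Generator parameters and per-session latent-state sequences."""

    params: ModelParams
    feature_config: FeatureConfig
    states: list[np.ndarray] = field(default_factory=list)
    X_ob: list[np.ndarray] = field(default_factory=list)
    X_tr: list[np.ndarray] = field(default_factory=list)


def default_feature_config(tau: float = 4.0) -> FeatureConfig:
    """Feature settings with the normalizer frozen at the task's known SD."""
    return FeatureConfig(tau=tau, contrast_sd=DEFAULT_CONTRAST_SD)


def simulate_agent(
    task: SessionSet,
    params: ModelParams,
    feature_config: FeatureConfig,
    seed: int = 0,
) -> tuple[SessionSet, GroundTruth]:
    """Sample latent states and choices from a GLM-HMM agent.

    The trial loop maintains the exponential-filter states online: at
    trial t the transition covariates hold history filtered through
    trial t-1, state z_t is drawn (from pi at t = 1, else from row
    z_{t-1} of the per-trial transition matrix), the choice from the
    state's Bernoulli GLM, and the reward is +1 iff the choice matches
    the rewarded side (drawn from the block probability on zero-contrast
    trials).  Filters then absorb the simulated trial.
    """
    if isinstance(feature_config.contrast_sd, str):
        raise ValueError("simulate_agent needs a numeric contrast_sd in feature_config")
    sd = float(feature_config.contrast_sd)
    decay = np.exp(-1.0 / feature_config.tau)
    rng = np.random.default_rng(seed)
    K = params.K
    truth = GroundTruth(params=params.copy(), feature_config=feature_config)
    sessions = []
    for sess in task:
        T = len(sess)
        contrast = sess.signed_contrast
        p_right = sess.table["block_p_right"].to_numpy(dtype=float)
        bases = warmup_bases(T, feature_config)
        X_ob = np.empty((T, 4))
        X_tr = np.empty((T, 3 + feature_config.n_bases))
        z = np.empty(T, dtype=int)
        y = np.empty(T, dtype=int)
        reward = np.empty(T, dtype=int)
        f_choice = f_side = f_reward = 0.0
        prev_choice = prev_side = 0.0
        for t in range(T):
            X_tr[t] = np.concatenate(([f_choice, f_side, f_reward], bases[t]))
            if t == 0:
                z[t] = rng.choice(K, p=params.pi)
            else:
                logits = params.B[z[t - 1]] + params.W_tr @ X_tr[t]
                z[t] = rng.choice(K, p=softmax(logits))
            X_ob[t] = (contrast[t] / sd, prev_choice, prev_side, 1.0)
            p_r = expit(X_ob[t] @ params.W_ob[z[t]])
            y[t] = int(rng.random() < p_r)
            if contrast[t] != 0.0:
                rewarded_side = 1.0 if contrast[t] > 0 else -1.0
            elif "stim_side" in sess.table.columns:
                # zero-evidence trials: the task still has a (hidden)
                # stimulus side that defines the rewarded response
                rewarded_side = float(sess.table["stim_side"].iloc[t])
            else:
                rewarded_side = 1.0 if rng.random() < p_right[t] else -1.0
            choice_signed = 2.0 * y[t] - 1.0
            reward[t] = 1 if choice_signed == rewarded_side else -1
            side_code = choice_signed * reward[t]
            f_choice = decay * f_choice + choice_signed
            f_side = decay * f_side + side_code
            f_reward = decay * f_reward + reward[t]
            prev_choice, prev_side = choice_signed, side_code
        table = sess.table.copy()
        table["choice"] = y
        table["reward"] = reward
        sessions.append(Session(sess.session_id, table))
        truth.states.append(z)
        truth.X_ob.append(X_ob)
        truth.X_tr.append(X_tr)
    out = SessionSet(sessions, dict(task.metadata) | {"agent_seed": seed, "contrast_sd": sd})
    return out, truth


def default_params(K: int, style: str = "input-driven",
                   n_bases: int = 3) -> ModelParams:
    """Synthetic ground-truth parameter templates for K = 2 or K = 4.

    These are hand-chosen generator values for tests and benchmarks
    (engaged states: large stimulus weight, small bias; biased states:
    the reverse), not fitted estimates from any real dataset.  Style
    ``"input-driven"`` signs the choice/side filters by the destination
    state's side preference and points the reward filter into
    disengaged states; ``"static"`` zeroes all transition filters.
    """
    zeros_b = [0.0] * n_bases
    if K == 2:
        W_ob = np.array([
            [3.5, 0.3, 0.1, 0.0],    # engaged: steep psychometric, no bias
            [0.5, 0.1, 0.1, 2.0],    # biased-R (disengaged): flat, strong right bias
        ])
        W_tr = np.array([
            [-0.25, -0.25, -0.25] + zeros_b,           # into engaged: low recent reward
            [0.25, 0.25, 0.25] + [0.8] + zeros_b[1:],  # into biased-R: reward/right history
        ])
        B = np.array([[2.5, 0.0], [0.0, 2.5]])
        pi = np.array([0.5, 0.5])
    elif K == 4:
        W_ob = np.array([
            [3.5, 0.3, 0.1, -0.5],   # Engaged-L
            [3.5, 0.3, 0.1, 0.5],    # Engaged-R
            [0.5, 0.1, 0.1, -2.0],   # Biased-L
            [0.5, 0.1, 0.1, 2.0],    # Biased-R
        ])
        W_tr = np.array([
            [-0.25, -0.25, -0.25] + zeros_b,
            [0.25, 0.25, -0.25] + zeros_b,
            [-0.25, -0.25, 0.25] + [0.8] + zeros_b[1:],
            [0.25, 0.25, 0.25] + [0.8] + zeros_b[1:],
        ])
        B = 3.0 * np.eye(4)
        pi = np.full(4, 0.25)
    else:
        raise ValueError("templates are shipped for K = 2 and K = 4 only")
    if style == "static":
        W_tr = np.zeros_like(W_tr)
    elif style != "input-driven":
        raise ValueError(f"unknown style {style!r}")
    cfg = default_feature_config()
    return ModelParams(pi=pi, W_ob=W_ob, W_tr=W_tr, B=B,
                       obs_names=cfg.obs_covariates, tr_names=cfg.tr_covariates)


def make_benchmark_pair(
    K: int = 2,
    task_config: TaskConfig | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
) -> dict:
    """Two matched synthetic datasets: static vs. input-driven transitions.

    Dataset "static" is generated with all transition filters at zero
    (a fixed transition matrix); dataset "input-driven" uses the signed
    filter template.  Both come with ground truth, for the paired
    model-comparison benchmark.
    """
    task_config = task_config or TaskConfig()
    feature_config = feature_config or default_feature_config()
    rng = np.random.default_rng(seed)
    out = {}
    for style in ("static", "input-driven"):
        task = generate_task(task_config, seed=int(rng.integers(2**31 - 1)))
        data, truth = simulate_agent(
            task, default_params(K, style), feature_config,
            seed=int(rng.integers(2**31 - 1)),
        )
        out[style] = (data, truth)
    return out


def save_ground_truth(truth: GroundTruth, path) -> None:
    import json

    payload = {
        "params": truth.params.to_dict(),
        "feature_config": truth.feature_config.to_dict(),
        "states": [z.tolist() for z in truth.states],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
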