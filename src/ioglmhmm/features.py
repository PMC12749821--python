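"""Design-matrix construction for the observation and transition GLMs.

Observation covariates (per trial t): normalized signed contrast,
previous choice (±1), previously rewarded side (±1, the product of
previous choice and previous reward), and a constant bias of 1.

Transition covariates: causal exponentially filtered versions of the ±1
previous-choice, previously-rewarded-side, and reward series (one shared
time constant tau, in trials), followed by three warm-up temporal basis
functions supported on the first 100 trials of a session.

All history covariates are strictly causal: row t of either design
matrix depends only on trials before t.  The filter state and the
history codes reset at every session boundary, and the first trial of a
session carries 0 in every history column (the neutral point of a ±1
code).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .trial_io import Session, SessionSet

DEFAULT_OBS_COVARIATES = ("stimulus", "prev_choice", "prev_stim_side", "bias")
DEFAULT_TR_COVARIATES = (
    "filt_prev_choice",
    "filt_prev_stim_side",
    "filt_prev_reward",
    "basis_1",
    "basis_2",
    "basis_3",
)


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization settings.

    tau
        Exponential-filter time constant in trials (cross-validation on
        the mouse data behind this model family selects tau = 4).
    n_bases / warmup_span
        Number of warm-up basis functions and the trial span they cover.
    contrast_sd
        Normalizer for signed contrast: either the string ``"fit"``
        (population SD of signed contrast pooled across sessions) or a
        fixed positive number reused from a training set.
    """

    tau: float = 4.0
    n_bases: int = 3
    warmup_span: int = 100
    contrast_sd: float | str = "fit"
    obs_covariates: tuple[str, ...] = DEFAULT_OBS_COVARIATES
    tr_covariates: tuple[str, ...] = DEFAULT_TR_COVARIATES

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.warmup_span < self.n_bases:
            raise ValueError("warmup_span must be >= n_bases")
        for names in (self.obs_covariates, self.tr_covariates):
            if not names or len(set(names)) != len(names):
                raise ValueError("covariate name lists must be non-empty and duplicate-free")
        if not isinstance(self.contrast_sd, str) and self.contrast_sd <= 0:
            raise ValueError("contrast_sd must be positive")

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "n_bases": self.n_bases,
            "warmup_span": self.warmup_span,
            "contrast_sd": self.contrast_sd,
            "obs_covariates": list(self.obs_covariates),
            "tr_covariates": list(self.tr_covariates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        for key in ("obs_covariates", "tr_covariates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class DesignMatrices:
    """Per-session regressor matrices: X_ob is T x D_ob, X_tr is T x D_tr."""

    X_ob: np.ndarray
    X_tr: np.ndarray
    obs_names: tuple[str, ...]
    tr_names: tuple[str, ...]


def normalize_contrast(data: SessionSet, config: FeatureConfig) -> tuple[SessionSet, float]:
    """Fit (or pass through) the contrast normalizer.

    With ``contrast_sd="fit"`` the normalizer is the population standard
    deviation of signed contrast pooled over every trial of every
    session.  The fitted constant is recorded in ``data.metadata`` so
    that held-out sessions are normalized with the training-set value.
    """
    if isinstance(config.contrast_sd, str):
        if config.contrast_sd != "fit":
            raise ValueError(f"unknown contrast_sd mode {config.contrast_sd!r}")
        pooled = np.concatenate([s.signed_contrast for s in data])
        sd = float(np.std(pooled))  # population SD (ddof=0)
        if sd <= 0.0:
            raise DegenerateInputError("signed contrast has zero variance; cannot fit normalizer")
    else:
        sd = float(config.contrast_sd)
    data.metadata["contrast_sd"] = sd
    return data, sd


def signed_history_codes(session: Session) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial ±1 codes for choice, previously-rewarded side, and reward.

    Returned arrays are *current-trial* values (choice_t in ±1,
    side_t = choice_t * reward_t, reward_t in ±1); shifting by one trial
    to obtain history covariates is the caller's job.
    """
    choice = 2 * session.choices.astype(float) - 1.0
    reward = session.rewards.astype(float)
    return choice, choice * reward, reward


def _lagged(series: np.ndarray) -> np.ndarray:
    out = np.zeros_like(series)
    out[1:] = series[:-1]
    return out


def exponential_filter(series: np.ndarray, tau: float) -> np.ndarray:
    """Causal, strictly-history exponential filter.

    f_1 = 0 and f_t = exp(-1/tau) * f_{t-1} + s_{t-1} for t >= 2, so the
    output at trial t accumulates only trials before t.  Unnormalized:
    a constant ±1 input saturates at 1/(1 - exp(-1/tau)).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    decay = np.exp(-1.0 / tau)
    # IIR recursion f_t = decay * f_{t-1} + u_t with u_t = s_{t-1}, u_1 = 0
    return lfilter([1.0], [1.0, -decay], _lagged(series))


def warmup_bases(T: int, config: FeatureConfig) -> np.ndarray:
    """Warm-up temporal basis: T x n_bases, zero beyond ``warmup_span``.

    Three (by default) non-overlapping raised-cosine bumps tile trials
    1..warmup_span; disjoint supports make them linearly independent and
    each column is peak-normalized to 1.  Sessions shorter than the span
    receive the leading rows of the full basis.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    span, nb = config.warmup_span, config.n_bases
    t = np.arange(span, dtype=float)
    full = np.zeros((span, nb))
    width = span / nb
    for b in range(nb):
        start = b * width
        inside = (t >= start) & (t < start + width)
        phase = (t[inside] - start + 0.5) / width
        full[inside, b] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    full /= full.max(axis=0, keepdims=True)
    out = np.zeros((T, nb))
    out[: min(T, span)] = full[: min(T, span)]
    return out


def build_observation_design(session: Session, config: FeatureConfig,
                             contrast_sd: float) -> np.ndarray:
    """Observation design matrix: stimulus, prev_choice, prev_stim_side, bias."""
    choice, side, _ = signed_history_codes(session)
    cols = {
        "stimulus": session.signed_contrast / contrast_sd,
        "prev_choice": _lagged(choice),
        "prev_stim_side": _lagged(side),
        "bias": np.ones(len(session)),
    }
    return np.column_stack([cols[name] for name in config.obs_covariates])


def build_transition_design(session: Session, config: FeatureConfig) -> np.ndarray:
    """Transition design matrix: filtered history codes then warm-up bases.

    Row t holds only information available before trial t: the filtered
    columns are strictly causal and the basis columns are deterministic
    functions of the within-session trial index.
    """
    choice, side, reward = signed_history_codes(session)
    bases = warmup_bases(len(session), config)
    cols = {
        "filt_prev_choice": exponential_filter(choice, config.tau),
        "filt_prev_stim_side": exponential_filter(side, config.tau),
        "filt_prev_reward": exponential_filter(reward, config.tau),
    }
    for b in range(config.n_bases):
        cols[f"basis_{b + 1}"] = bases[:, b]
    return np.column_stack([cols[name] for name in config.tr_covariates])


def build_designs(session: Session, config: FeatureConfig, contrast_sd: float) -> DesignMatrices:
    return DesignMatrices(
        X_ob=build_observation_design(session, config, contrast_sd),
        X_tr=build_transition_design(session, config),
        obs_names=config.obs_covariates,
        tr_names=config.tr_covariates,
    )


@dataclass
class SessionDesign:
    """Fitting-ready view of one session: designs plus the choice vector."""

    session_id: str
    X_ob: np.ndarray
    X_tr: np.ndarray
    y: np.ndarray
    block_p_right: np.ndarray | None = None
    aux: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.y)


def prepare_designs(
    data: SessionSet,
    config: FeatureConfig,
    contrast_sd: float | None = None,
) -> tuple[list[SessionDesign], float]:
    """Build per-session design matrices for a whole dataset.

    ``contrast_sd`` overrides the config (used to apply a training-set
    normalizer to held-out sessions); otherwise the normalizer is taken
    from the config, fitting it from the data when set to ``"fit"``.
    """
    if contrast_sd is None:
        _, contrast_sd = normalize_contrast(data, config)
    designs = []
    for s in data:
        d = build_designs(s, config, contrast_sd)
        bpr = (
            s.table["block_p_right"].to_numpy(dtype=float)
            if "block_p_right" in s.table.columns
            else None
        )
        aux = {}
        if "response_time" in s.table.columns:
            aux["response_time"] = s.table["response_time"].to_numpy(dtype=float)
        designs.append(
            SessionDesign(s.session_id, d.X_ob, d.X_tr, s.choices, bpr, aux)
        )
    return designs, contrast_sd


def config_with_sd(config: FeatureConfig, contrast_sd: float) -> FeatureConfig:
    """Copy of ``config`` with the normalizer frozen at a numeric value."""
    return replace(config, contrast_sd=contrast_sd)
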