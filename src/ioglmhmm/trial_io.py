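"""Reading, validating and writing trial-level behavioral tables.

The on-disk format is a flat comma-delimited UTF-8 table with a header
row; one file may hold many sessions.  Mandatory columns are
``session_id, trial_index, signed_contrast, choice, reward``; the
optional columns ``block_p_right`` and ``response_time`` plus any
unknown columns are preserved as auxiliary per-trial covariates.

Choices are encoded 0/1 (left/right) at the file level; featurization
maps them to the signed ±1 codes used by the model.  Rewards are signed
binary: −1 incorrect, +1 correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = ("session_id", "trial_index", "signed_contrast", "choice", "reward")

#: columns carried through but not required
OPTIONAL_COLUMNS = ("block_p_right", "response_time")


class TrialFormatError(ValueError):
    """A file is structurally unusable (e.g. missing a mandatory column)."""


class TrialValidationError(ValueError):
    """A row holds an out-of-contract value (e.g. a non-binary choice)."""


@dataclass
class Session:
    """One behavioral session: a trial table sorted by ``trial_index``."""

    session_id: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def choices(self) -> np.ndarray:
        return self.table["choice"].to_numpy(dtype=int)

    @property
    def rewards(self) -> np.ndarray:
        return self.table["reward"].to_numpy(dtype=int)

    @property
    def signed_contrast(self) -> np.ndarray:
        return self.table["signed_contrast"].to_numpy(dtype=float)


@dataclass
class SessionSet:
    """Ordered collection of sessions plus dataset-level metadata.

    ``metadata`` may carry a source description and, once fitted, the
    contrast normalization constant under key ``"contrast_sd"``.
    """

    sessions: list[Session]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sessions:
            raise TrialValidationError("SessionSet must hold at least one session")
        for s in self.sessions:
            if len(s) == 0:
                raise TrialValidationError(f"session {s.session_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self) -> Iterable[Session]:
        return iter(self.sessions)

    @property
    def n_trials(self) -> int:
        return sum(len(s) for s in self.sessions)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.table for s in self.sessions], ignore_index=True)

    def subset(self, indices: Iterable[int]) -> "SessionSet":
        return SessionSet([self.sessions[i] for i in indices], dict(self.metadata))


def _check_rows(df: pd.DataFrame, *, strict: bool) -> list[str]:
    """Collect per-row contract violations; raise on the first if strict."""
    findings: list[str] = []

    def report(mask: np.ndarray, what: str) -> None:
        for row in np.flatnonzero(mask):
            msg = f"row {row}: {what} = {df.iloc[row][what.split()[0]]!r}"
            if strict:
                raise TrialValidationError(msg)
            findings.append(msg)

    choice = df["choice"].to_numpy()
    reward = df["reward"].to_numpy()
    report(~np.isin(choice, (0, 1)), "choice not in {0, 1}")
    report(~np.isin(reward, (-1, 1)), "reward not in {-1, +1}")
    contrast = df["signed_contrast"].to_numpy(dtype=float)
    report(~np.isfinite(contrast) | (np.abs(contrast) > 1), "signed_contrast outside [-1, 1]")
    return findings


def _group_sessions(df: pd.DataFrame) -> list[Session]:
    sessions = []
    for sid, grp in df.groupby("session_id", sort=False):
        grp = grp.sort_values("trial_index", kind="stable").reset_index(drop=True)
        if grp["trial_index"].duplicated().any():
            raise TrialValidationError(f"session {sid!r}: duplicated trial_index")
        sessions.append(Session(str(sid), grp))
    return sessions


def read_trials(path, dialect: dict | None = None) -> SessionSet:
    """Read a trial CSV into a :class:`SessionSet` grouped by session.

    Parameters
    ----------
    path
        CSV file with at least the mandatory columns.
    dialect
        Optional keyword overrides passed to :func:`pandas.read_csv`
        (e.g. ``{"sep": "\\t"}``).

    Raises
    ------
    TrialFormatError
        If a mandatory column is missing.
    TrialValidationError
        If a row carries a non-binary choice or reward.
    """
    df = pd.read_csv(path, **(dialect or {}))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    _check_rows(df, strict=True)
    return SessionSet(_group_sessions(df), {"source": str(path)})


def write_trials(data: SessionSet, path) -> str:
    """Write a :class:`SessionSet` to CSV; round-trips through :func:`read_trials`."""
    df = data.to_frame()
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(
            f"cannot write incomplete trial table, missing: {', '.join(missing)}"
        )
    # mandatory columns first, auxiliary columns in original order after
    cols = list(MANDATORY_COLUMNS) + [c for c in df.columns if c not in MANDATORY_COLUMNS]
    df[cols].to_csv(path, index=False)
    return str(path)


def validate_sessions(data: SessionSet) -> list[dict]:
    """Report per-session contract violations without mutating anything.

    Returns a list of findings, each a dict with keys ``session_id``,
    ``kind`` (``"gap"`` or ``"range"``) and ``detail``.  Flagged trials
    are reported, never dropped; exclusion is a caller decision.
    """
    report: list[dict] = []
    for s in data:
        idx = s.table["trial_index"].to_numpy(dtype=int)
        steps = np.diff(idx)
        for pos in np.flatnonzero(steps != 1):
            report.append(
                {
                    "session_id": s.session_id,
                    "kind": "gap",
                    "detail": f"trial_index jumps {idx[pos]} -> {idx[pos + 1]}",
                }
            )
        for finding in _check_rows(s.table, strict=False):
            report.append({"session_id": s.session_id, "kind": "range", "detail": finding})
    return report
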