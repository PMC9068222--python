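"""Canonical trial-table format and run configuration.

Trial tables are plain comma-separated text with 1-based trial and epoch
indices and angles in degrees.  Validation reports the first offending data
line by its line number in the file (header = line 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import FEEDBACK_MODES, PROBE_TYPES

__all__ = ["TRIAL_COLUMNS", "TrialTableError", "read_trials", "write_trials",
           "validate_trials", "RunConfig"]

TRIAL_COLUMNS = [
    "subject_id",
    "trial",
    "epoch",
    "target_deg",
    "rotation_deg",
    "feedback_mode",
    "probe_type",
    "reach_angle_deg",
    "clamp_error_deg",
]


class TrialTableError(ValueError):
    """Malformed trial table; the message names the offending file line."""


def _line_of(df: pd.DataFrame, mask: np.ndarray) -> int:
    # +2: header line plus 1-based numbering
    return int(np.flatnonzero(mask)[0]) + 2


def validate_trials(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "clamp_error_deg"]
    if missing:
        raise TrialTableError(f"{source}: missing columns {missing}")
    if "clamp_error_deg" not in df.columns:
        df = df.assign(clamp_error_deg=np.nan)
    bad = ~df["feedback_mode"].isin(FEEDBACK_MODES)
    if bad.any():
        raise TrialTableError(
            f"{source}, line {_line_of(df, bad.to_numpy())}: unknown feedback_mode "
            f"{df.loc[bad, 'feedback_mode'].iloc[0]!r}"
        )
    bad = ~df["probe_type"].isin(PROBE_TYPES)
    if bad.any():
        raise TrialTableError(
            f"{source}, line {_line_of(df, bad.to_numpy())}: unknown probe_type "
            f"{df.loc[bad, 'probe_type'].iloc[0]!r}"
        )
    for col in ("trial", "epoch"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 1)
        if bad.any():
            raise TrialTableError(
                f"{source}, line {_line_of(df, bad.to_numpy())}: invalid {col} value"
            )
    for col in ("rotation_deg", "reach_angle_deg"):
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            raise TrialTableError(
                f"{source}, line {_line_of(df, bad.to_numpy())}: non-numeric {col}"
            )
    for sid, grp in df.groupby("subject_id", sort=False):
        t = grp["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise TrialTableError(
                f"{source}, line {int(grp.index[k]) + 2}: non-increasing trial index "
                f"for subject {sid!r}"
            )
    clamped = df["feedback_mode"] == "clamped"
    bad = clamped & ~np.isfinite(pd.to_numeric(df["clamp_error_deg"], errors="coerce"))
    if bad.any():
        raise TrialTableError(
            f"{source}, line {_line_of(df, bad.to_numpy())}: clamped trial without clamp_error_deg"
        )
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a canonical trial table (CSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_trials(df, source=str(path))


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order (round-trip lossless)."""
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    cols = [c for c in TRIAL_COLUMNS if c in table.columns] + extra
    table[cols].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Declarative run configuration loaded from YAML.

    A seed is mandatory: every stochastic stage draws from it, so two runs
    with equal configuration are identical.
    """

    seed: int
    model: str = "competition"
    schedule: dict = field(default_factory=lambda: {"kind": "abrupt"})
    cohort: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    output_dir: str = "."

    _KNOWN = {"seed", "model", "schedule", "cohort", "fit", "bootstrap", "output_dir"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must declare a seed")
        if not isinstance(raw.get("schedule", {}), dict) or "kind" not in raw.get(
            "schedule", {"kind": "abrupt"}
        ):
            raise ValueError("schedule config must be a mapping with a 'kind'")
        return cls(**raw)
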