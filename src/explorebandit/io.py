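"""Session/memory CSV serialization, validation, and run manifests.

The interchange format is plain UTF-8 CSV with a header row — one row per
trial (see ``docs/data_dictionary.md`` for the column contract) — plus
JSON for scalar results.  Every artifact directory written by the CLI
contains a ``manifest.json`` recording the command, configuration, seed,
package version and SHA-256 hashes of the inputs, so runs are
reproducible byte for byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .task import MEMORY_COLUMNS, SESSION_COLUMNS, SessionData

__all__ = [
    "ValidationError",
    "read_sessions",
    "write_sessions",
    "read_memory",
    "write_memory",
    "sessions_to_frame",
    "sessions_from_frame",
    "write_manifest",
]

CHOICE_VALUES = {"left", "right", "missed"}
OUTCOME_VALUES = {"win", "loss", "none"}


class ValidationError(ValueError):
    """A session/memory table violates the data dictionary."""


def sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    if not sessions:
        raise ValidationError("no sessions to serialize")
    return pd.concat([s.trials for s in sessions], ignore_index=True)[SESSION_COLUMNS]


def sessions_from_frame(frame: pd.DataFrame) -> List[SessionData]:
    _validate_sessions(frame)
    out = []
    for pid, chunk in frame.groupby("participant_id", sort=False):
        out.append(
            SessionData(
                participant_id=str(pid),
                age_years=float(chunk["age_years"].iloc[0]),
                trials=chunk.reset_index(drop=True),
            )
        )
    return out


def _validate_sessions(frame: pd.DataFrame) -> None:
    if frame.empty:
        raise ValidationError("empty session table")
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    bad = ~frame["choice"].isin(CHOICE_VALUES)
    if bad.any():
        rows = frame.index[bad].tolist()[:5]
        raise ValidationError(
            f"invalid choice values (allowed {sorted(CHOICE_VALUES)}) at rows {rows}"
        )
    bad = ~frame["outcome"].isin(OUTCOME_VALUES)
    if bad.any():
        rows = frame.index[bad].tolist()[:5]
        raise ValidationError(
            f"invalid outcome values (allowed {sorted(OUTCOME_VALUES)}) at rows {rows}"
        )
    made = frame["choice"] != "missed"
    mismatch = made != (frame["outcome"] != "none")
    if mismatch.any():
        rows = frame.index[mismatch].tolist()[:5]
        raise ValidationError(f"outcome must be present iff a choice was made; rows {rows}")
    for col in ("prob_left", "prob_right"):
        vals = frame[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError(f"{col} outside [0, 1]")
    rts = frame["rt_sec"].to_numpy(dtype=float)
    if np.any(rts[np.isfinite(rts)] <= 0):
        raise ValidationError("rt_sec must be positive where present")
    for pid, chunk in frame.groupby("participant_id", sort=False):
        key = chunk["block"].to_numpy() * 100_000 + chunk["trial"].to_numpy()
        if not (np.diff(key) > 0).all():
            raise ValidationError(f"trials of {pid!r} not ordered by (block, trial)")


def read_sessions(path: str | Path) -> List[SessionData]:
    """Read and validate a session CSV into per-participant sessions."""
    path = Path(path)
    try:
        # round_trip parsing keeps write -> read -> write byte-identical
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path} is empty") from None
    return sessions_from_frame(frame)


def write_sessions(sessions: Sequence[SessionData] | pd.DataFrame, path: str | Path) -> None:
    frame = sessions if isinstance(sessions, pd.DataFrame) else sessions_to_frame(sessions)
    _validate_sessions(frame)
    frame.to_csv(path, index=False)


def read_memory(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEMORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"memory table missing columns: {missing}")
    return frame


def write_memory(sessions: Sequence[SessionData] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(sessions, pd.DataFrame):
        frame = sessions
    else:
        tables = [s.memory for s in sessions if s.memory is not None]
        if not tables:
            raise ValidationError("no memory tables to serialize")
        frame = pd.concat(tables, ignore_index=True)
    frame[MEMORY_COLUMNS].to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: Optional[int],
    config: Optional[Mapping] = None,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Write ``manifest.json`` describing one CLI run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "package": "explorebandit",
        "version": __version__,
        "config": dict(config or {}),
        "input_hashes": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
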