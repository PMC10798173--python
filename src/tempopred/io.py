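"""CSV / JSON serialization for pipeline artifacts.

All tabular artifacts are plain long-format CSV with fixed headers; result
summaries are JSON.  Readers validate the schema strictly so that silent
column drift between pipeline stages fails loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import Session

TRIALS_COLUMNS = [
    "subject",
    "block",
    "condition_std_ms",
    "trial_index",
    "soa_ms",
    "is_target",
    "is_deviant",
]
RESPONSE_COLUMNS = ["correct", "rt_ms"]
RATINGS_COLUMNS = ["subject", "block", "condition_std_ms", "rating"]


def session_to_frame(session: Session) -> pd.DataFrame:
    """Long-format trial table for one session (no responses)."""
    rows = []
    for b_i, block in enumerate(session.blocks, start=1):
        std = block.condition.std_soa
        for t in block.trials:
            rows.append(
                (
                    session.subject_id,
                    b_i,
                    std,
                    t.index,
                    t.soa_ms,
                    int(t.is_target),
                    int(t.is_deviant),
                )
            )
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def write_trials_csv(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIALS_COLUMNS + RESPONSE_COLUMNS if c in frame.columns]
    missing = [c for c in TRIALS_COLUMNS if c not in cols]
    if missing:
        raise ValueError(f"trials frame missing columns: {missing}")
    frame[cols].to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRIALS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trials CSV missing columns: {missing}")
    if "correct" in frame.columns and not frame["correct"].dropna().isin([0, 1]).all():
        raise ValueError("correct column must be 0/1")
    if not frame["is_target"].isin([0, 1]).all():
        raise ValueError("is_target column must be 0/1")
    if (frame.loc[frame["trial_index"] > 1, "soa_ms"].isna()).any():
        raise ValueError("soa_ms missing on a non-initial trial")
    return frame


def write_ratings_csv(frame: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RATINGS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ratings frame missing columns: {missing}")
    frame[RATINGS_COLUMNS].to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in RATINGS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ratings CSV missing columns: {missing}")
    if ((frame["rating"] < 0) | (frame["rating"] > 10)).any():
        raise ValueError("ratings must lie in [0, 10]")
    return frame


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, allow_nan=False) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
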