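"""File formats and seed derivation.

Everything on disk is plain CSV (UTF-8, dot decimal separator, Unix
newlines, times printed to 6 decimal places):

* signal file: ``time_s, emg_uv`` — one continuous channel;
* event file: the long-format schedule table (see
  :func:`startlelab.schedules.schedule_to_table`);
* generic tables (trial scores, outcomes, ANOVA) round-trip through
  :func:`write_table` / :func:`read_table`.

A single global seed deterministically derives every per-subject,
per-stage random stream via :func:`derive_rng`.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_signal",
    "read_signal",
    "write_events",
    "read_events",
    "write_table",
    "read_table",
    "derive_rng",
    "derive_seed",
]

FLOAT_FORMAT = "%.6f"

EVENT_COLUMNS = [
    "subject_id", "session", "run", "block_index", "block_type", "trial_index",
    "phase", "event_type", "onset_s", "duration_s", "condition_label",
]


def derive_seed(global_seed: int, *keys) -> int:
    """Deterministic substream seed from the global seed and a sequence of
    string/int keys (stage name, subject id, ...)."""
    words = [int(global_seed) & 0xFFFFFFFF]
    for k in keys:
        words.append(zlib.crc32(str(k).encode("utf-8")))
    ss = np.random.SeedSequence(words)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(global_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, *keys))


def write_signal(path, time_s, emg_uv) -> None:
    df = pd.DataFrame({"time_s": np.asarray(time_s), "emg_uv": np.asarray(emg_uv)})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_signal(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column signal file; validates the header, monotone time
    and the absence of missing values."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "emg_uv"]:
        raise ValueError(f"{path}: expected header time_s,emg_uv, got {list(df.columns)}")
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: missing value at line {line}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        line = int(np.argmax(np.diff(t) <= 0)) + 3
        raise ValueError(f"{path}: time column not strictly increasing at line {line}")
    return t, df["emg_uv"].to_numpy(dtype=float)


def write_events(events: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events[EVENT_COLUMNS].to_csv(
        path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event file missing columns {missing}")
    if df["onset_s"].isna().any():
        line = int(df["onset_s"].isna().idxmax()) + 2
        raise ValueError(f"{path}: missing onset at line {line}")
    # onsets must be sorted within each subject-session-run
    for (sid, sess, run), g in df.groupby(["subject_id", "session", "run"], sort=False):
        onsets = g["onset_s"].to_numpy()
        if np.any(np.diff(onsets) < 0):
            bad = int(g.index[int(np.argmax(np.diff(onsets) < 0)) + 1]) + 2
            raise ValueError(
                f"{path}: unsorted onsets for {sid}/{sess}/run {run} at line {bad}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
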