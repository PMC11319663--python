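"""Condition means, potentiation difference scores, outlier truncation and
working-memory behaviour aggregation.

The analyzed quantities are per subject-session condition means of startle
t-scores and anxiety ratings, and their potentiation difference scores:

* ``FPS``  (fear-potentiated startle)    = mean(P_cue) - mean(P_iti)
* ``APS_ITI`` (anxiety-potentiated startle) = mean(U_iti) - mean(N_iti)

Values beyond two sample standard deviations of their analysis group are
truncated to the boundary, using the moments of the original vector in a
single pass.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scoring import MISSING_NOISY

log = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "REQUIRED_CONDITIONS",
    "condition_means",
    "difference_scores",
    "truncate_outliers",
    "truncate_groups",
    "behavior_aggregate",
]

CONDITIONS = ["N_cue", "N_iti", "P_cue", "P_iti", "U_cue", "U_iti"]
#: Conditions that must have at least one valid trial for the difference
#: scores to exist.
REQUIRED_CONDITIONS = ["P_cue", "P_iti", "U_iti", "N_iti"]


def condition_means(
    trials: pd.DataFrame,
    value_col: str,
    measure: str,
) -> pd.DataFrame:
    """Per subject-session condition means over non-missing trials.

    ``trials`` is a tidy per-trial frame with columns ``subject_id``,
    ``session``, ``condition_label``, ``value_col`` and optionally
    ``status`` (rows with status ``missing_noisy`` are excluded; zero-coded
    trials remain).  Subject-sessions lacking any required condition are
    dropped with a warning.  Returns one row per subject-session with one
    column per condition plus ``n_valid_total`` and ``measure``.
    """
    if trials.empty:
        raise ValueError("condition_means: empty trial table")
    df = trials
    if "status" in df.columns:
        df = df[df["status"] != MISSING_NOISY]
    rows = []
    for (sid, sess), g in df.groupby(["subject_id", "session"], sort=True):
        means = g.groupby("condition_label")[value_col].mean()
        counts = g.groupby("condition_label")[value_col].count()
        missing = [c for c in REQUIRED_CONDITIONS if counts.get(c, 0) == 0]
        if missing:
            log.warning(
                "dropping %s/%s (%s): no valid trials in %s",
                sid, sess, measure, ", ".join(missing),
            )
            continue
        row = {"subject_id": sid, "session": sess, "measure": measure}
        for c in CONDITIONS:
            row[c] = float(means[c]) if c in means.index else np.nan
            row[f"n_{c}"] = int(counts.get(c, 0))
        row["n_valid_total"] = int(counts.sum())
        rows.append(row)
    if not rows:
        raise ValueError("condition_means: no subject-session had complete data")
    return pd.DataFrame(rows)


def difference_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Add FPS and APS_ITI columns to a condition-means table."""
    out = table.copy()
    for col in REQUIRED_CONDITIONS:
        if col not in out.columns:
            raise ValueError(f"difference_scores: missing condition column {col!r}")
        if out[col].isna().any():
            bad = out.loc[out[col].isna(), ["subject_id", "session"]].iloc[0]
            raise ValueError(
                f"difference_scores: condition {col!r} undefined for "
                f"{bad['subject_id']}/{bad['session']}"
            )
    out["FPS"] = out["P_cue"] - out["P_iti"]
    out["APS_ITI"] = out["U_iti"] - out["N_iti"]
    return out


def truncate_outliers(values, k: float = 2.0) -> np.ndarray:
    """Truncate values beyond ``mean +/- k x sample SD`` to the boundary.

    The bounds come from the moments of the *original* vector and are
    applied exactly once (no re-estimation after truncation).  A constant
    vector is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("truncation needs at least 2 values")
    m = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy()
    return np.clip(x, m - k * sd, m + k * sd)


def truncate_groups(
    table: pd.DataFrame,
    value_cols: list[str],
    k: float = 2.0,
    group_cols: tuple[str, ...] = ("session", "measure"),
) -> pd.DataFrame:
    """Apply :func:`truncate_outliers` to each value column within each
    analysis cell (default: per coil session per measure, across subjects)."""
    out = table.copy()
    for _, idx in out.groupby(list(group_cols)).groups.items():
        for col in value_cols:
            out.loc[idx, col] = truncate_outliers(out.loc[idx, col].to_numpy(), k=k)
    return out


def behavior_aggregate(trial_responses: pd.DataFrame) -> pd.DataFrame:
    """Aggregate Sternberg behaviour to cell means and WM difference scores.

    Input columns: ``subject_id``, ``session``, ``trial_type`` (sort /
    maintain), ``block_condition`` (safe / threat), ``correct`` (bool),
    ``rt_s`` and ``is_shock_trial``.  Shock trials are discarded before
    aggregation.  Returns one row per subject-session-condition with
    percent correct and mean RT for both trial types plus the sort-maintain
    difference scores.
    """
    df = trial_responses[~trial_responses["is_shock_trial"].astype(bool)].copy()
    if df.empty:
        raise ValueError("behavior_aggregate: no analyzable trials")
    if (df["rt_s"] <= 0).any():
        raise ValueError("behavior_aggregate: non-positive reaction time")
    cells = (
        df.groupby(["subject_id", "session", "block_condition", "trial_type"])
        .agg(percent_correct=("correct", lambda c: 100.0 * np.mean(c.astype(float))),
             mean_rt_s=("rt_s", "mean"),
             n_trials=("rt_s", "size"))
        .reset_index()
    )
    rows = []
    for (sid, sess, cond), g in cells.groupby(["subject_id", "session", "block_condition"]):
        by_type = g.set_index("trial_type")
        for t in ("sort", "maintain"):
            if t not in by_type.index:
                raise ValueError(
                    f"behavior_aggregate: {sid}/{sess}/{cond} has no {t} trials"
                )
        rows.append(
            {
                "subject_id": sid,
                "session": sess,
                "block_condition": cond,
                "sort_percent_correct": by_type.loc["sort", "percent_correct"],
                "maintain_percent_correct": by_type.loc["maintain", "percent_correct"],
                "sort_mean_rt_s": by_type.loc["sort", "mean_rt_s"],
                "maintain_mean_rt_s": by_type.loc["maintain", "mean_rt_s"],
                "wm_percent_correct_diff": by_type.loc["sort", "percent_correct"]
                - by_type.loc["maintain", "percent_correct"],
                "wm_rt_diff_s": by_type.loc["sort", "mean_rt_s"]
                - by_type.loc["maintain", "mean_rt_s"],
            }
        )
    return pd.DataFrame(rows)
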