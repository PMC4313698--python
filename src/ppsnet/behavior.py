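"""Behavioral analysis pipeline for the audio-tactile interaction task.

Trial tables hold vocal reaction times to a tactile stimulus on the hand
delivered at one of five delays (T1..T5 = 300, 800, 1500, 2200, 2700 ms)
from the onset of a task-irrelevant looming (IN) or receding (OUT)
sound.  Because IN and OUT sounds traverse the same trajectory in
opposite directions, delay labels are recoded to perceived sound
distance bins D1 (farthest) .. D5 (closest): T1..T5 map directly for IN
sounds and in reverse for OUT sounds.

The pipeline drops catch trials and missed detections, trims reaction
times farther than two standard deviations from their subject-by-
condition cell mean (single pass), summarizes cell means with
between-subject SEMs, and fits the boundary sigmoid to RT versus
touch-delivery time per session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .boundary import BoundaryFit, fit_sigmoid

DELAY_MS: dict[str, float] = {"T1": 300.0, "T2": 800.0, "T3": 1500.0,
                              "T4": 2200.0, "T5": 2700.0}
DELAY_LABELS = tuple(DELAY_MS)
DISTANCE_LABELS = ("D1", "D2", "D3", "D4", "D5")
DIRECTIONS = ("IN", "OUT")
TRAININGS = ("synchronous", "asynchronous")
SESSIONS = ("before", "after1", "after2", "after")  # "after" = pooled blocks

REQUIRED_COLUMNS = ("subject", "training", "session", "direction",
                    "delay", "rt_ms", "catch")


def recode_distance(direction: str, delay_label: str) -> str:
    """Perceived-distance bin for a (sound direction, delay) pair.

    IN sounds approach: the later the touch, the closer the sound
    (T1 -> D1 farthest ... T5 -> D5 closest).  OUT sounds recede, so the
    mapping reverses (T1 -> D5, ..., T5 -> D1).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown sound direction {direction!r}")
    if delay_label not in DELAY_LABELS:
        raise ValueError(f"unknown delay label {delay_label!r}")
    idx = DELAY_LABELS.index(delay_label)
    if direction == "OUT":
        idx = len(DELAY_LABELS) - 1 - idx
    return DISTANCE_LABELS[idx]


def canonical_delay_ms(direction: str, delay_label: str) -> float:
    """Touch-delivery time (ms) on the IN-sound axis for a trial's
    perceived distance bin (used so IN and OUT trials share one x-axis)."""
    dist = recode_distance(direction, delay_label)
    return DELAY_MS[DELAY_LABELS[DISTANCE_LABELS.index(dist)]]


def read_trials(source, sep: str = ",") -> pd.DataFrame:
    """Strict reader for delimited trial tables.

    Validates the header, label vocabularies and the catch-trial
    convention (catch trials carry no RT), and adds the ``distance``
    recoding column.
    """
    df = pd.read_csv(source, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["catch"] = df["catch"].astype(bool)
    for col, allowed in (("training", TRAININGS), ("session", SESSIONS),
                         ("direction", DIRECTIONS), ("delay", DELAY_LABELS)):
        bad = set(df[col].unique()) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} labels: {sorted(bad)}")
    if df.loc[df["catch"], "rt_ms"].notna().any():
        raise ValueError("catch trials must not carry an RT")
    if (df.loc[~df["catch"], "rt_ms"].dropna() <= 0).any():
        raise ValueError("tactile RTs must be positive (ms)")
    df["distance"] = [recode_distance(d, t)
                      for d, t in zip(df["direction"], df["delay"])]
    return df


def drop_catch_and_misses(df: pd.DataFrame) -> pd.DataFrame:
    """Remove catch trials and missed detections (no recorded RT)."""
    return df[(~df["catch"]) & df["rt_ms"].notna()].copy()


def catch_accuracy(df: pd.DataFrame) -> float:
    """Fraction of catch trials correctly withheld (reported, not analyzed)."""
    catch = df[df["catch"]]
    if len(catch) == 0:
        return float("nan")
    return float(catch["rt_ms"].isna().mean())


def trim_outliers(df: pd.DataFrame,
                  group_cols: Iterable[str] = ("subject", "training"),
                  n_sd: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass 2-SD trimming of RTs per subject-by-condition cell.

    The cell mean and SD are computed once on the incoming trials, then
    trials with ``|rt - mean| > n_sd * sd`` are removed.  Returns the
    filtered table and a per-cell report of removed counts.
    """
    group_cols = list(group_cols)
    df = drop_catch_and_misses(df)
    if len(df) == 0:
        report = pd.DataFrame(columns=group_cols + ["n_trials", "n_trimmed"])
        return df, report
    stats = df.groupby(group_cols)["rt_ms"].agg(["mean", "std", "size"])
    stats["std"] = stats["std"].fillna(0.0)  # single-trial cells: keep
    merged = df.join(stats, on=group_cols)
    keep = (merged["rt_ms"] - merged["mean"]).abs() <= n_sd * merged["std"]
    filtered = df[keep.to_numpy()].copy()
    report = (
        merged.assign(trimmed=~keep)
        .groupby(group_cols)
        .agg(n_trials=("rt_ms", "size"), n_trimmed=("trimmed", "sum"))
        .reset_index()
    )
    return filtered, report


def summarize_rt(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per training x session x direction x distance.

    Subject means are computed first, then averaged across subjects
    (balanced aggregation); the SEM is over subject means and is NaN for
    single-subject cells.
    """
    cell = ["training", "session", "direction", "distance"]
    subj = (df.groupby(cell + ["subject"])["rt_ms"].mean()
              .rename("subj_mean").reset_index())
    out = (subj.groupby(cell)["subj_mean"]
               .agg(mean_rt_ms="mean",
                    sem_rt_ms=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                    n_subjects="size")
               .reset_index())
    return out


def boundary_per_session(df: pd.DataFrame, direction: str = "IN",
                         training: str | None = None,
                         pool_after: bool = True,
                         level: str = "subject_means"
                         ) -> dict[str, BoundaryFit]:
    """Sigmoid boundary fit of RT vs touch-delivery time, per session.

    ``level='subject_means'`` fits the five per-distance subject-mean
    averages; ``level='trials'`` pools all trial-level points.  After
    blocks are pooled into one "after" session by default, since one
    post-training curve is reported per condition.
    """
    data = df[df["direction"] == direction].copy()
    if training is not None:
        data = data[data["training"] == training]
    if pool_after:
        data["session"] = data["session"].replace(
            {"after1": "after", "after2": "after"})
    data["x_ms"] = [canonical_delay_ms(d, t)
                    for d, t in zip(data["direction"], data["delay"])]
    fits: dict[str, BoundaryFit] = {}
    for session, grp in data.groupby("session"):
        if level == "subject_means":
            cell = (grp.groupby(["x_ms", "subject"])["rt_ms"].mean()
                       .groupby("x_ms").mean())
            if len(cell) < 4:
                continue
            fits[session] = fit_sigmoid(cell.index.to_numpy(),
                                        cell.to_numpy())
        elif level == "trials":
            if grp["x_ms"].nunique() < 4:
                continue
            fits[session] = fit_sigmoid(grp["x_ms"].to_numpy(),
                                        grp["rt_ms"].to_numpy())
        else:
            raise ValueError(f"unknown level {level!r}")
    return fits
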