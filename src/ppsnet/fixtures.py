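"""Bundled published summary tables and a synthetic trial generator.

``paper_fixture_tables`` carries the group mean reaction times (+/- SEM,
ms) of the audio-tactile interaction task for both sound directions and
training conditions, as printed in the study the model reproduces; cells
that were never printed (the post-synchronous D1 IN mean, and the whole
post-asynchronous IN row) are NaN and flagged.  ``generate_rt_dataset``
produces trial-level tables with a known underlying sigmoid so the
trim-and-fit pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (DELAY_LABELS, DELAY_MS, DISTANCE_LABELS,
                       canonical_delay_ms, recode_distance, validate_trials)
from .boundary import sigmoid

_IN_ROWS = [
    # training, session, means D1..D5, sems D1..D5
    ("synchronous", "before",
     [517.0, 497.0, 464.0, 459.0, 455.0], [23.0, 24.0, 22.0, 23.0, 26.0]),
    ("synchronous", "after",
     [np.nan, 470.0, 450.0, 439.0, 439.0], [np.nan, 23.0, 22.0, 22.0, 22.0]),
    ("asynchronous", "before",
     [484.0, 481.0, 444.0, 440.0, 433.0], [24.0, 26.0, 25.0, 28.0, 25.0]),
    ("asynchronous", "after",
     [np.nan] * 5, [np.nan] * 5),
]

_OUT_ROWS = [
    ("synchronous", "before",
     [505.0, 474.0, 460.0, 476.0, 477.0], [27.0, 24.0, 25.0, 25.0, 26.0]),
    ("synchronous", "after",
     [466.0, 451.0, 447.0, 457.0, 445.0], [26.0, 23.0, 23.0, 23.0, 23.0]),
    ("asynchronous", "before",
     [466.0, 443.0, 426.0, 447.0, 449.0], [22.0, 22.0, 21.0, 20.0, 23.0]),
    ("asynchronous", "after",
     [485.0, 471.0, 457.0, 474.0, 451.0], [27.0, 31.0, 32.0, 30.0, 29.0]),
]


def _rows_to_frame(rows, direction: str) -> pd.DataFrame:
    records = []
    for training, session, means, sems in rows:
        for dist, m, s in zip(DISTANCE_LABELS, means, sems):
            records.append({
                "training": training, "session": session,
                "direction": direction, "distance": dist,
                "mean_rt_ms": m, "sem_rt_ms": s,
                "missing": bool(np.isnan(m)),
            })
    return pd.DataFrame.from_records(records)


def paper_fixture_tables() -> dict[str, pd.DataFrame]:
    """Published group summaries: ``{"in_means": ..., "out_means": ...}``."""
    return {"in_means": _rows_to_frame(_IN_ROWS, "IN"),
            "out_means": _rows_to_frame(_OUT_ROWS, "OUT")}


def fixture_mean(direction: str, training: str, session: str,
                 distance: str) -> tuple[float, float, bool]:
    """(mean, sem, missing) for one summary cell."""
    key = "in_means" if direction == "IN" else "out_means"
    tab = paper_fixture_tables()[key]
    row = tab[(tab["training"] == training) & (tab["session"] == session)
              & (tab["distance"] == distance)]
    if len(row) != 1:
        raise KeyError((direction, training, session, distance))
    r = row.iloc[0]
    return float(r["mean_rt_ms"]), float(r["sem_rt_ms"]), bool(r["missing"])


@dataclass(frozen=True)
class SyntheticRTSpec:
    """Generative model for trial-level RT tables.

    RTs follow the boundary sigmoid of touch-delivery time (defaults
    emulate the pre-training looming-sound curve: slow ~515 ms for early
    touches, fast ~455 ms for late ones, midpoint near 1055 ms), plus an
    additive per-subject intercept and Gaussian trial noise, with a
    small rate of large positive outliers (attentional lapses).
    """

    ymin: float = 455.0
    ymax: float = 60.0
    xc: float = 1055.0
    b: float = -150.0          # negative: RT falls as the delay grows
    n_subjects: int = 16
    trials_per_cell: int = 8
    noise_sd: float = 50.0     # ms, trial-level Gaussian noise
    subject_sd: float = 20.0   # ms, random intercept across subjects
    outlier_rate: float = 0.02
    outlier_shift: float = 400.0  # ms, added to outlying trials
    catch_fraction: float = 0.23  # tactile trials are 77% of all trials
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must lie in [0, 1)")


def generate_rt_dataset(spec: SyntheticRTSpec,
                        training: str = "synchronous",
                        session: str = "before",
                        directions: tuple[str, ...] = ("IN", "OUT"),
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trial table drawn from ``spec`` (reproducible given its seed).

    Each (subject, direction, delay) cell receives ``trials_per_cell``
    tactile trials; the RT mean is the sigmoid evaluated at the trial's
    touch-delivery time on the canonical looming-sound axis, so IN and
    OUT trials of the same perceived distance share an expected RT.
    Catch trials (sound only, no RT) are appended to keep tactile trials
    at ``1 - catch_fraction`` of the total.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    offsets = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects)
    records = []
    for s_idx in range(spec.n_subjects):
        subject = f"S{s_idx + 1:02d}"
        for direction in directions:
            for delay in DELAY_LABELS:
                x = canonical_delay_ms(direction, delay)
                mu = sigmoid(x, spec.ymin, spec.ymax, spec.xc, spec.b)
                rts = mu + offsets[s_idx] + rng.normal(
                    0.0, spec.noise_sd, size=spec.trials_per_cell)
                lapses = rng.uniform(size=spec.trials_per_cell) < spec.outlier_rate
                rts = rts + lapses * spec.outlier_shift
                for rt in rts:
                    records.append({
                        "subject": subject, "training": training,
                        "session": session, "direction": direction,
                        "delay": delay, "rt_ms": max(float(rt), 1.0),
                        "catch": False,
                    })
    n_tactile = len(records)
    n_catch = int(round(n_tactile * spec.catch_fraction
                        / (1.0 - spec.catch_fraction)))
    for k in range(n_catch):
        records.append({
            "subject": f"S{int(rng.integers(spec.n_subjects)) + 1:02d}",
            "training": training, "session": session,
            "direction": directions[int(rng.integers(len(directions)))],
            "delay": DELAY_LABELS[int(rng.integers(len(DELAY_LABELS)))],
            "rt_ms": np.nan, "catch": True,
        })
    return validate_trials(pd.DataFrame.from_records(records))


def fixture_trials_from_means(direction: str = "IN",
                              training: str = "synchronous",
                              sessions: tuple[str, ...] = ("before",),
                              ) -> pd.DataFrame:
    """Degenerate one-trial-per-cell table whose subject means equal the
    published cell means exactly (one pseudo-subject), for worked examples."""
    records = []
    for session in sessions:
        for dist in DISTANCE_LABELS:
            mean, _, missing = fixture_mean(direction, training, session, dist)
            if missing:
                continue
            delay = DELAY_LABELS[DISTANCE_LABELS.index(dist)]
            if direction == "OUT":
                delay = DELAY_LABELS[len(DELAY_LABELS) - 1
                                     - DELAY_LABELS.index(delay)]
            records.append({"subject": "GROUP", "training": training,
                            "session": session, "direction": direction,
                            "delay": delay, "rt_ms": mean, "catch": False})
    return validate_trials(pd.DataFrame.from_records(records))
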