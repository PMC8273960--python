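"""Epoch-level acceleration to per-subject daily behaviour compositions.

Wrist-accelerometer output is summarised as average acceleration (ENMO, in
milligravity) per 60-s epoch.  Epochs within the waking, worn part of the
day are classified by intensity cut-points — sedentary below 40 mg, light
activity from 40 to just under 100 mg, moderate-to-vigorous at 100 mg and
above (45 mg separates SB from LIPA in the sensitivity set) — and counted
into daily minutes.  A day is valid when wear covers at least two-thirds
of waking time; a subject enters the analysis with at least 2 valid
weekdays and 2 valid weekend days, and days are combined as a 5/7 - 2/7
weekday/weekend weighted mean when fewer than 7 valid days are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutpointSet",
    "DEFAULT_CUTPOINTS",
    "SENSITIVITY_CUTPOINTS",
    "DailySummary",
    "classify_epoch",
    "classify_epochs",
    "summarize_day",
    "aggregate_subject",
    "aggregate_epoch_table",
]

logger = logging.getLogger(__name__)

WEEKDAY_WEIGHT = 5.0 / 7.0
WEEKEND_WEIGHT = 2.0 / 7.0
MIN_VALID_WEEKDAYS = 2
MIN_VALID_WEEKEND_DAYS = 2
WEAR_FRACTION_REQUIRED = 2.0 / 3.0


@dataclass(frozen=True)
class CutpointSet:
    """Intensity thresholds in milligravity for 60-s epochs."""

    sb_upper_mg: float = 40.0
    mvpa_lower_mg: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.sb_upper_mg < self.mvpa_lower_mg:
            raise ValueError("need 0 < sb_upper_mg < mvpa_lower_mg")


DEFAULT_CUTPOINTS = CutpointSet(40.0, 100.0)
SENSITIVITY_CUTPOINTS = CutpointSet(45.0, 100.0)


@dataclass(frozen=True)
class DailySummary:
    """One calendar day of classified waking wear time."""

    date: _date
    is_weekend: bool
    sb_min: float
    lipa_min: float
    mvpa_min: float
    wear_min: float
    waking_min: float

    @property
    def valid(self) -> bool:
        return self.wear_min >= WEAR_FRACTION_REQUIRED * self.waking_min


def classify_epoch(enmo_mg: float, cuts: CutpointSet = DEFAULT_CUTPOINTS) -> str:
    """Classify one epoch's ENMO into 'SB', 'LIPA' or 'MVPA'.

    Half-open intervals: SB is [0, sb_upper), LIPA [sb_upper, mvpa_lower),
    MVPA [mvpa_lower, inf) — exhaustive and disjoint at any mg value.
    """
    if enmo_mg < 0:
        raise ValueError("ENMO cannot be negative")
    if enmo_mg < cuts.sb_upper_mg:
        return "SB"
    if enmo_mg < cuts.mvpa_lower_mg:
        return "LIPA"
    return "MVPA"


def classify_epochs(
    enmo_mg, cuts: CutpointSet = DEFAULT_CUTPOINTS
) -> np.ndarray:
    """Vectorised :func:`classify_epoch` over an array of ENMO values."""
    e = np.asarray(enmo_mg, dtype=float)
    if np.any(e < 0):
        raise ValueError("ENMO cannot be negative")
    out = np.where(
        e < cuts.sb_upper_mg, "SB", np.where(e < cuts.mvpa_lower_mg, "LIPA", "MVPA")
    )
    return out


def summarize_day(
    epochs: pd.DataFrame, cuts: CutpointSet = DEFAULT_CUTPOINTS
) -> DailySummary:
    """Summarise one day of 60-s epochs into behaviour minutes.

    ``epochs`` needs columns ``timestamp`` (datetime-like), ``enmo_mg``,
    ``wear`` and ``waking`` (boolean/0-1); all rows must share one
    calendar day.  Minutes are epoch counts over waking wear time.
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch sequence")
    ts = pd.to_datetime(epochs["timestamp"])
    days = ts.dt.normalize().unique()
    if len(days) != 1:
        raise ValueError("epochs span more than one calendar day")
    day = pd.Timestamp(days[0])
    waking = epochs["waking"].astype(bool).to_numpy()
    wear = epochs["wear"].astype(bool).to_numpy()
    in_play = waking & wear
    labels = classify_epochs(epochs["enmo_mg"].to_numpy()[in_play], cuts)
    return DailySummary(
        date=day.date(),
        is_weekend=day.dayofweek >= 5,
        sb_min=float(np.sum(labels == "SB")),
        lipa_min=float(np.sum(labels == "LIPA")),
        mvpa_min=float(np.sum(labels == "MVPA")),
        wear_min=float(in_play.sum()),
        waking_min=float(waking.sum()),
    )


def aggregate_subject(
    days: Sequence[DailySummary],
) -> Optional[tuple[float, float, float]]:
    """Combine valid days into one (SB, LIPA, MVPA) pre-closure mean.

    Returns ``None`` (an exclusion, logged) when fewer than 2 valid
    weekdays or 2 valid weekend days are available.  With 7 valid days
    the plain mean is used; otherwise the weekday and weekend means are
    recombined with calendar weights 5/7 and 2/7.
    """
    valid = [d for d in days if d.valid]
    wk = [d for d in valid if not d.is_weekend]
    we = [d for d in valid if d.is_weekend]
    if len(wk) < MIN_VALID_WEEKDAYS or len(we) < MIN_VALID_WEEKEND_DAYS:
        logger.info(
            "subject excluded: %d valid weekdays, %d valid weekend days",
            len(wk),
            len(we),
        )
        return None

    def _mean(ds: Iterable[DailySummary]) -> np.ndarray:
        arr = np.array([[d.sb_min, d.lipa_min, d.mvpa_min] for d in ds])
        return arr.mean(axis=0)

    if len(valid) == 7:
        m = _mean(valid)
    else:
        m = WEEKDAY_WEIGHT * _mean(wk) + WEEKEND_WEIGHT * _mean(we)
    return float(m[0]), float(m[1]), float(m[2])


def aggregate_epoch_table(
    epochs: pd.DataFrame, cuts: CutpointSet = DEFAULT_CUTPOINTS
) -> pd.DataFrame:
    """Aggregate a multi-subject epoch table into a cohort table.

    ``epochs`` needs a ``subject_id`` column on top of the per-day schema.
    Output columns: subject_id, sb_min, lipa_min, mvpa_min, waking_min,
    n_valid_days; subjects failing the validity rule are omitted (and
    counted in the log).
    """
    rows = []
    n_excluded = 0
    ts = pd.to_datetime(epochs["timestamp"])
    for sid, sub in epochs.groupby("subject_id", sort=True):
        summaries = [
            summarize_day(day_df, cuts)
            for _, day_df in sub.groupby(ts.loc[sub.index].dt.normalize())
        ]
        agg = aggregate_subject(summaries)
        if agg is None:
            n_excluded += 1
            continue
        waking = float(np.mean([d.waking_min for d in summaries if d.valid]))
        rows.append(
            {
                "subject_id": sid,
                "sb_min": agg[0],
                "lipa_min": agg[1],
                "mvpa_min": agg[2],
                "waking_min": waking,
                "n_valid_days": sum(d.valid for d in summaries),
            }
        )
    if n_excluded:
        logger.info("excluded %d subject(s) failing the valid-day rule", n_excluded)
    return pd.DataFrame(rows)
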