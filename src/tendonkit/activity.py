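"""Locomotor-activity metrics for home-cage monitoring traces.

The raw input is a per-cage locomotion index sampled at fixed cadence
(default one minute), dimensionless in [0, 1], recorded under a 12 h/12 h
light/dark schedule.  The metrics computed here are the standard home-cage
summaries: daily light/dark means, 3-hour circadian bin profiles, night
activity normalized to a pre-surgery baseline, and group aggregates
normalized to a matched control group.

Day indexing is anchored on the surgery day (day 0); pre-surgery days carry
negative indices.  A "day" runs from lights-on to the next lights-on, so the
dark period of day *d* is the 12 h following that day's lights-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTrace",
    "split_day_night",
    "bin_3h",
    "aggregate_bins_by_period",
    "normalize_to_baseline",
    "normalize_to_control",
    "weekly_periods",
]

SECONDS_PER_DAY = 86_400


@dataclass
class ActivityTrace:
    """One cage's locomotion-index series with its light schedule.

    Parameters
    ----------
    cage_id : str
        Identifier of the cage (one mouse per cage after surgery).
    start : datetime
        Timestamp of the first sample.
    values : ndarray
        Locomotion index per sample, each in [0, 1].
    period : int
        Sampling period in seconds (default 60).
    lights_on, lights_off : datetime.time
        Clock times of the light schedule; the packaged schedule is
        07:00–19:00 lights on.
    surgery_day : datetime.date
        Calendar date of the surgery; defines day index 0.
    """

    cage_id: str
    start: datetime
    values: np.ndarray
    period: int = 60
    lights_on: time = time(7, 0)
    lights_off: time = time(19, 0)
    surgery_day: date | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def samples_per_day(self) -> int:
        return SECONDS_PER_DAY // self.period

    def validate(self) -> None:
        if self.period <= 0 or SECONDS_PER_DAY % self.period:
            raise ValueError(f"period {self.period}s must divide one day")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"cage {self.cage_id}: non-finite samples present")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError(f"cage {self.cage_id}: locomotion index outside [0, 1]")
        if self.values.size % self.samples_per_day:
            raise ValueError(
                f"cage {self.cage_id}: length {self.values.size} is not a whole "
                f"number of days at period {self.period}s"
            )
        if self.surgery_day is None:
            raise ValueError(f"cage {self.cage_id}: surgery_day is required")

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.values.size, freq=pd.Timedelta(seconds=self.period)
        )

    def frame(self) -> pd.DataFrame:
        """Per-sample table with day index, light flag and 3-h bin index."""
        ts = self.timestamps()
        on = _seconds_of_day(self.lights_on)
        off = _seconds_of_day(self.lights_off)
        sod = (
            ts.hour.to_numpy() * 3600 + ts.minute.to_numpy() * 60 + ts.second.to_numpy()
        )
        # shift clocks so lights-on is the day boundary
        shifted = ts - pd.Timedelta(seconds=on)
        day = (shifted.normalize() - pd.Timestamp(self.surgery_day)).days
        is_light = (sod >= on) & (sod < off)
        since_on = (sod - on) % SECONDS_PER_DAY
        bin_idx = since_on // (3 * 3600)
        return pd.DataFrame(
            {
                "cage_id": self.cage_id,
                "day_index": np.asarray(day),
                "is_light": is_light,
                "bin": bin_idx.astype(int),
                "activity": self.values,
            }
        )


def _seconds_of_day(t: time) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


def split_day_night(trace: ActivityTrace) -> pd.DataFrame:
    """Daily light/dark mean activity.

    A sample belongs to the light period iff its clock time lies in
    [lights_on, lights_off); the dark period of a day is the 12 h that follow
    that day's lights-off.  Returns one row per day with columns
    ``day_index``, ``light_mean``, ``dark_mean``.
    """
    trace.validate()
    if trace.values.size < trace.samples_per_day:
        raise ValueError(f"cage {trace.cage_id}: trace shorter than one full day")
    df = trace.frame()
    out = (
        df.groupby(["day_index", "is_light"])["activity"]
        .mean()
        .unstack("is_light")
        .rename(columns={True: "light_mean", False: "dark_mean"})
        .reset_index()
    )
    out.insert(0, "cage_id", trace.cage_id)
    return out[["cage_id", "day_index", "light_mean", "dark_mean"]]


def bin_3h(trace: ActivityTrace) -> pd.DataFrame:
    """Mean activity in eight 3-h bins per day, bin 0 starting at lights-on.

    Returns a tidy table with columns ``day_index``, ``bin`` (0–7) and
    ``mean``.  The mean of the eight bin means equals the 24-h mean exactly.
    """
    trace.validate()
    if (3 * 3600) % trace.period:
        raise ValueError(f"period {trace.period}s does not divide 3 h evenly")
    df = trace.frame()
    out = (
        df.groupby(["day_index", "bin"])["activity"].mean().rename("mean").reset_index()
    )
    out.insert(0, "cage_id", trace.cage_id)
    return out


def weekly_periods(n_days_post: int = 27) -> dict[str, list[int]]:
    """Named day ranges: baseline (pre-surgery) plus post-surgery weeks.

    Weeks are days 1–7, 8–14, 15–21 and 22 up to ``n_days_post`` after
    surgery; the baseline covers all negative day indices.
    """
    periods: dict[str, list[int]] = {"baseline": []}  # filled by caller from data
    edges = [(1, 7), (8, 14), (15, 21), (22, n_days_post)]
    for i, (lo, hi) in enumerate(edges, start=1):
        periods[f"week{i}"] = list(range(lo, hi + 1))
    return periods


def aggregate_bins_by_period(
    binned: pd.DataFrame, periods: dict[str, list[int] | range]
) -> pd.DataFrame:
    """Mean ± SEM of 3-h bin activity over named day ranges.

    ``binned`` is the tidy output of :func:`bin_3h` (rows from several cages
    may be concatenated).  ``periods`` maps a period name to the day indices
    it covers; ranges must not overlap.  SEM uses the n−1 sample SD across
    contributing (cage, day) rows.
    """
    seen: set[int] = set()
    for name, days in periods.items():
        days = set(days)
        if not days:
            raise ValueError(f"period {name!r} is empty")
        if seen & days:
            raise ValueError(f"period {name!r} overlaps a previous period")
        seen |= days
    rows = []
    for name, days in periods.items():
        sub = binned[binned["day_index"].isin(list(days))]
        if sub.empty:
            raise ValueError(f"period {name!r} matches no data")
        g = sub.groupby("bin")["mean"]
        agg = g.agg(["mean", "sem", "count"]).reset_index()
        agg.insert(0, "period", name)
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={"count": "n"})


def normalize_to_baseline(
    summaries: pd.DataFrame,
    baseline_days: int = 3,
    post_days: range = range(0, 28),
) -> pd.DataFrame:
    """Night activity of days 0–27 divided by the mean night activity of the
    last ``baseline_days`` pre-surgery days.

    ``summaries`` is the output of :func:`split_day_night` for one cage.
    Returns columns ``cage_id``, ``day_index``, ``normalized`` with value 1.0
    meaning equal to the baseline.
    """
    cage = summaries["cage_id"].iloc[0] if len(summaries) else "?"
    base_idx = list(range(-baseline_days, 0))
    base = summaries[summaries["day_index"].isin(base_idx)]
    if len(base) < baseline_days:
        raise ValueError(
            f"cage {cage}: need {baseline_days} pre-surgery days, found {len(base)}"
        )
    ref = base["dark_mean"].mean()
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"cage {cage}: baseline night activity {ref!r} is not positive")
    post = summaries[summaries["day_index"].isin(list(post_days))].copy()
    post["normalized"] = post["dark_mean"] / ref
    return post[["cage_id", "day_index", "normalized"]].reset_index(drop=True)


def normalize_to_control(
    group: list[pd.DataFrame],
    control: list[pd.DataFrame],
    day_range: range = range(0, 28),
) -> np.ndarray:
    """Per-animal mean normalized night activity divided by the control mean.

    Each element of ``group`` / ``control`` is one animal's output of
    :func:`normalize_to_baseline`; controls must be matched on wheel access.
    Returns one ratio per animal in ``group``.
    """
    if not control:
        raise ValueError("control group is empty")

    def animal_mean(df: pd.DataFrame) -> float:
        sub = df[df["day_index"].isin(list(day_range))]
        return float(sub["normalized"].mean())

    ctrl = float(np.mean([animal_mean(df) for df in control]))
    if ctrl <= 0:
        raise ValueError(f"control mean normalized activity {ctrl} is not positive")
    return np.array([animal_mean(df) / ctrl for df in group])
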