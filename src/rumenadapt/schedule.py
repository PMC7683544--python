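"""Sampling schedule of the diet-challenge design.

The reference design samples rumen fluid on nine days spread over five
weeks: two baseline days on the standard diet (d1, d2 with d2 = d1 + 3),
four consecutive days immediately after the switch to the
high-concentrate diet (d3..d6), and then one day per week for three more
weeks (d7 = d6 + 4, d8 = d7 + 6, d9 = d8 + 7).  The calendar gap between
d2 and d3 is configurable (default 4 days) because it is not fixed by
the design; it only enters the analysis through the weight of the d2->d3
trajectory step.

Week labels group the sampling days: W1 = {d1, d2} (standard diet),
W2 = {d3..d6} (first week on the new diet), W3 = {d7}, W4 = {d8},
W5 = {d9}.  The within-week covariate ``days_since_change`` counts days
on the new diet during W2 (1..4 for d3..d6) and is zero elsewhere; it
carries the short-term "days" slope of the longitudinal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ScheduleError

__all__ = ["SamplingSchedule", "default_schedule", "annotate_schedule"]

#: Week membership of the nine sampling days in the reference design.
DEFAULT_WEEK_OF_DAY: dict[int, int] = {
    1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 2, 7: 3, 8: 4, 9: 5,
}


def _default_offsets(d2_to_d3_gap: int = 4) -> tuple[int, ...]:
    d1 = 0
    d2 = d1 + 3
    d3 = d2 + d2_to_d3_gap
    d4, d5, d6 = d3 + 1, d3 + 2, d3 + 3
    d7 = d6 + 4
    d8 = d7 + 6
    d9 = d8 + 7
    return (d1, d2, d3, d4, d5, d6, d7, d8, d9)


@dataclass(frozen=True)
class SamplingSchedule:
    """Calendar layout of the sampling days.

    Parameters
    ----------
    day_offsets
        Calendar offsets (days since the first sampling day) of the
        labelled sampling days, in label order.
    diet_change_before
        Day label on which the high-concentrate diet is first delivered
        (default 3).
    week_of_day
        Mapping from day label to week label (1..5 in the reference
        design).
    """

    day_offsets: tuple[int, ...] = field(default_factory=_default_offsets)
    diet_change_before: int = 3
    week_of_day: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_WEEK_OF_DAY)
    )

    def __post_init__(self) -> None:
        offs = tuple(int(o) for o in self.day_offsets)
        object.__setattr__(self, "day_offsets", offs)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ScheduleError("day_offsets must be strictly increasing")
        labels = set(range(1, len(offs) + 1))
        if set(self.week_of_day) != labels:
            raise ScheduleError(
                "week_of_day must cover exactly the day labels "
                f"{sorted(labels)}, got {sorted(self.week_of_day)}"
            )
        if self.diet_change_before not in labels:
            raise ScheduleError(
                f"diet_change_before={self.diet_change_before} is not a day label"
            )

    @property
    def n_days(self) -> int:
        return len(self.day_offsets)

    @property
    def day_labels(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_days + 1))

    def offset_of(self, day_label: int) -> int:
        try:
            return self.day_offsets[int(day_label) - 1]
        except IndexError:
            raise ScheduleError(f"day label {day_label} not in schedule") from None

    def week_of(self, day_label: int) -> int:
        try:
            return int(self.week_of_day[int(day_label)])
        except KeyError:
            raise ScheduleError(f"day label {day_label} not in schedule") from None

    def days_since_change(self, day_label: int) -> int:
        """Days on the new diet, counted only during the first post-change week.

        The first post-change day carries value 1; days outside the
        first post-change week return 0, mirroring the indicator that
        restricts the short-term slope to that week.
        """
        day_label = int(day_label)
        change_week = self.week_of(self.diet_change_before)
        if self.week_of(day_label) != change_week:
            return 0
        if day_label < self.diet_change_before:
            return 0
        return (
            self.offset_of(day_label) - self.offset_of(self.diet_change_before) + 1
        )

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "day_offsets": list(self.day_offsets),
            "diet_change_before": self.diet_change_before,
            "week_of_day": {int(k): int(v) for k, v in self.week_of_day.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SamplingSchedule":
        return cls(
            day_offsets=tuple(d["day_offsets"]),
            diet_change_before=int(d.get("diet_change_before", 3)),
            week_of_day={int(k): int(v) for k, v in d["week_of_day"].items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "SamplingSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_schedule(d2_to_d3_gap: int = 4) -> SamplingSchedule:
    """The reference nine-day schedule, with a configurable d2->d3 gap."""
    return SamplingSchedule(day_offsets=_default_offsets(d2_to_d3_gap))


def annotate_schedule(
    records: pd.DataFrame, schedule: SamplingSchedule | None = None
) -> pd.DataFrame:
    """Attach week labels and the short-term day covariate to measurements.

    Adds (or overwrites) columns ``week``, ``days_since_change`` and, if
    absent, ``day_offset``.  Idempotent: annotating an already annotated
    table gives the same result.

    Raises
    ------
    ScheduleError
        If a ``day_label`` in the table is not covered by the schedule.
    """
    schedule = schedule or default_schedule()
    labels = set(records["day_label"].unique())
    known = set(schedule.day_labels)
    missing = sorted(labels - known)
    if missing:
        raise ScheduleError(f"day labels {missing} not covered by the schedule")

    out = records.copy()
    out["week"] = out["day_label"].map(schedule.week_of).astype(int)
    out["days_since_change"] = (
        out["day_label"].map(schedule.days_since_change).astype(int)
    )
    if "day_offset" not in out.columns or out["day_offset"].isna().any():
        out["day_offset"] = out["day_label"].map(schedule.offset_of).astype(int)
    return out
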