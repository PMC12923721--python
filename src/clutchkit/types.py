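"""Domain types for a clutch-enlargement field study.

Time is measured in float days from a season origin (day 0 = 24 May,
the earliest laying date in the study window); a nest's laying day is
the day its last egg was laid.  Groups are coded control = 0,
enlarged = 1 throughout, so "group" coefficients read as the effect of
carrying the extra egg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

GROUPS = ("control", "enlarged")
TRAITS = ("mass", "tarsus", "bill", "head_bill")

#: Interval status codes for nest visit histories.
ALIVE, FAILED, HATCHED = "alive", "failed", "hatched"


@dataclass
class NestHistory:
    """One nest's visit history: the unit of the daily-survival likelihood.

    ``intervals`` are (start_day, end_day, status) triples; a ``failed``
    or ``hatched`` status may only terminate the history.  A hatched or
    still-active nest is a right-censored success.
    """

    nest_id: str
    group: str
    laying_day: float
    first_found_day: float
    intervals: list[tuple[float, float, str]]
    hatch_day: float | None = None
    n_eggs: int = 4

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"nest {self.nest_id}: unknown group {self.group!r}")
        prev_end = -math.inf
        for i, (s, e, status) in enumerate(self.intervals):
            if e <= s:
                raise ValueError(
                    f"nest {self.nest_id}: interval {i} has nonpositive length"
                )
            if s < prev_end:
                raise ValueError(f"nest {self.nest_id}: intervals overlap at {i}")
            if status not in (ALIVE, FAILED, HATCHED):
                raise ValueError(f"nest {self.nest_id}: bad status {status!r}")
            if status in (FAILED, HATCHED) and i != len(self.intervals) - 1:
                raise ValueError(
                    f"nest {self.nest_id}: terminal status {status!r} not last"
                )
            prev_end = e

    @property
    def fate(self) -> str:
        return self.intervals[-1][2] if self.intervals else ALIVE

    @property
    def end_day(self) -> float:
        return self.intervals[-1][1] if self.intervals else self.first_found_day


@dataclass
class EggSeries:
    """One egg: dimensions and repeated masses by incubation age (days)."""

    egg_id: str
    nest_id: str
    length_cm: float
    breadth_cm: float
    measurements: list[tuple[float, float]] = field(default_factory=list)
    hatched: bool | None = None  # None: no outcome observed (nest lost, or egg lost singly)
    lost: bool = False  # lost singly from a surviving nest (partial clutch loss)

    def __post_init__(self) -> None:
        if not (self.length_cm >= self.breadth_cm > 0):
            raise ValueError(
                f"egg {self.egg_id}: need length >= breadth > 0, "
                f"got L={self.length_cm}, B={self.breadth_cm}"
            )
        for age, mass in self.measurements:
            if age < 0 or mass <= 0:
                raise ValueError(
                    f"egg {self.egg_id}: bad measurement (age={age}, mass={mass})"
                )


@dataclass
class ChickObservation:
    """One capture event of a chick; morphometrics may be missing (None)."""

    chick_id: str
    brood_id: str
    group: str
    age: float
    mass: float | None = None
    tarsus: float | None = None
    bill: float | None = None
    head_bill: float | None = None
    habitat: str | None = None  # "terrestrial" or "marine"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"chick {self.chick_id}: negative age {self.age}")
        if self.habitat not in (None, "terrestrial", "marine"):
            raise ValueError(f"chick {self.chick_id}: bad habitat {self.habitat!r}")


@dataclass
class ChickFate:
    """Entry/exit times (days since hatch) and event flag for one chick."""

    chick_id: str
    brood_id: str
    group: str
    entry_day: float
    exit_day: float
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if not 0.0 <= self.entry_day < self.exit_day:
            raise ValueError(
                f"chick {self.chick_id}: need 0 <= entry < exit, "
                f"got ({self.entry_day}, {self.exit_day})"
            )


@dataclass
class ByGroup:
    """A pair of values, one per experimental group."""

    control: float
    enlarged: float

    def __getitem__(self, group: str) -> float:
        if group not in GROUPS:
            raise KeyError(group)
        return getattr(self, group)

    def as_dict(self) -> dict[str, float]:
        return {"control": self.control, "enlarged": self.enlarged}
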