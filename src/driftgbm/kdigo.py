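"""KDIGO serum-creatinine AKI staging.

Implements the SCr-based KDIGO criteria on daily-aggregated inpatient
data.  Stage 1 is an SCr of at least 1.5 times baseline, or a rise of at
least 0.3 mg/dL within the trailing 48 hours; stage 2 is at least 2.0
times baseline; stage 3 is at least 3.0 times baseline, or an SCr of at
least 4.0 mg/dL following an acute rise of at least 0.3 mg/dL within 48
hours, or initiation of renal replacement therapy (RRT).  Urine-output
criteria are deliberately not implemented.

The baseline creatinine is the most recent pre-admission value inside a
configurable lookback window when one exists, otherwise the admission
value.  The baseline is fixed for the whole stay.  Ratio criteria
compare each day's value against this fixed baseline; the 48-hour delta
criterion compares against the minimum value observed in the trailing
2-day window on the daily grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ScrSeries",
    "BaselineScr",
    "StageEvent",
    "compute_baseline",
    "stage_series",
    "daily_stages",
    "label_encounter",
]

#: comparison slack so that float noise on exact-threshold values
#: (e.g. a rise of 0.30000000000000004) cannot flip a stage
_EPS = 1e-9

DEFAULT_BASELINE_LOOKBACK_DAYS = 365


@dataclass(frozen=True)
class ScrSeries:
    """Ordered serum-creatinine measurements for one encounter.

    ``days`` are integer offsets from admission (day 0); negative days
    are pre-admission values used only for baseline determination and
    the trailing 48-hour windows near admission.  ``values`` are in
    mg/dL and must be strictly positive.
    """

    days: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValueError("days and values must have equal length")
        if any(v <= 0 for v in self.values):
            raise ValueError("SCr values must be strictly positive")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "ScrSeries":
        pairs = sorted(pairs)
        return cls(tuple(int(d) for d, _ in pairs), tuple(float(v) for _, v in pairs))


@dataclass(frozen=True)
class BaselineScr:
    """Reference creatinine against which in-stay rises are measured."""

    value: float
    provenance: str  # "most-recent-prior" | "admission"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("baseline SCr must be strictly positive")
        if self.provenance not in ("most-recent-prior", "admission"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class StageEvent:
    """First qualification of one AKI stage level.

    ``rule`` records the branch that fired on that day:
    ``ratio-7d`` (ratio vs baseline), ``abs-48h`` (rise >= 0.3 mg/dL in
    48 h), ``abs4-acute`` (SCr >= 4.0 after an acute rise), ``rrt``.
    """

    stage: int
    day: int
    rule: str

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.day < 0:
            raise ValueError("stage events must occur on nonnegative days")


def compute_baseline(
    series: ScrSeries, lookback_days: int = DEFAULT_BASELINE_LOOKBACK_DAYS
) -> BaselineScr:
    """Determine the baseline creatinine for an encounter.

    Returns the most recent pre-admission value within ``lookback_days``
    before admission if any exists, otherwise the admission (day-0)
    value.

    Raises
    ------
    ValueError
        If the series is empty or has no admission value.
    """
    if len(series.days) == 0:
        raise ValueError("no SCr available")
    prior = [
        (d, v)
        for d, v in zip(series.days, series.values)
        if -lookback_days <= d < 0
    ]
    if prior:
        return BaselineScr(value=prior[-1][1], provenance="most-recent-prior")
    if 0 not in series.days:
        raise ValueError("no SCr available at admission (day 0)")
    admission = series.values[series.days.index(0)]
    return BaselineScr(value=admission, provenance="admission")


def _stage_on_day(
    day: int,
    value: float | None,
    lookup: dict[int, float],
    baseline: float,
    rrt_days: frozenset[int],
) -> tuple[int, str]:
    """Maximum stage qualifying on one day and the branch that fired.

    ``value`` is None on RRT days without an SCr measurement.
    """
    stage, rule = 0, ""
    if day in rrt_days:
        stage, rule = 3, "rrt"
    if value is None:
        return stage, rule
    # acute rise vs the minimum over the trailing 2-day (48 h) window
    window = [lookup[e] for e in range(day - 2, day + 1) if e in lookup]
    rise = value - min(window)
    ratio = value / baseline
    if stage < 3 and value >= 4.0 - _EPS and rise >= 0.3 - _EPS:
        stage, rule = 3, "abs4-acute"
    if stage < 3 and ratio >= 3.0 - _EPS:
        stage, rule = 3, "ratio-7d"
    if stage < 2 and ratio >= 2.0 - _EPS:
        stage, rule = 2, "ratio-7d"
    if stage < 1:
        if ratio >= 1.5 - _EPS:
            stage, rule = 1, "ratio-7d"
        elif rise >= 0.3 - _EPS:
            stage, rule = 1, "abs-48h"
    return stage, rule


def daily_stages(
    series: ScrSeries,
    baseline: BaselineScr,
    rrt_days: Iterable[int] = (),
) -> dict[int, int]:
    """Maximum qualifying stage per post-admission day.

    Days evaluated are the union of measurement days >= 0 and RRT days;
    a day absent from the result did not qualify for any stage.
    """
    if baseline.value <= 0:
        raise ValueError("baseline SCr must be strictly positive")
    rrt = frozenset(int(d) for d in rrt_days)
    lookup = dict(zip(series.days, series.values))
    out: dict[int, int] = {}
    eval_days = sorted({d for d in series.days if d >= 0} | rrt)
    for d in eval_days:
        stage, _ = _stage_on_day(d, lookup.get(d), lookup, baseline.value, rrt)
        if stage:
            out[d] = stage
    return out


def stage_series(
    series: ScrSeries,
    baseline: BaselineScr,
    rrt_days: Iterable[int] = (),
) -> list[StageEvent]:
    """Stage an SCr series, reporting the first day each level is reached.

    Stages are cumulative: a day qualifying for stage ``k`` also
    qualifies for every lower stage, so the returned events (ordered by
    stage level) have nonincreasing stage onset days removed — i.e. the
    stage-1 event day <= stage-2 event day <= stage-3 event day, each
    being the first day the encounter's running maximum stage reached
    that level.
    """
    if baseline.value <= 0:
        raise ValueError("baseline SCr must be strictly positive")
    rrt = frozenset(int(d) for d in rrt_days)
    lookup = dict(zip(series.days, series.values))
    eval_days = sorted({d for d in series.days if d >= 0} | rrt)
    events: list[StageEvent] = []
    reached = 0
    for d in eval_days:
        stage, rule = _stage_on_day(d, lookup.get(d), lookup, baseline.value, rrt)
        while stage > reached:
            reached += 1
            events.append(StageEvent(stage=reached, day=d, rule=rule))
    return events


def label_encounter(timeline, task) -> tuple[int | None, int]:
    """Label one encounter for a prediction task.

    ``task`` is a :class:`~driftgbm.sampler.TaskSpec` or a bare stage
    threshold in {1, 2, 3}.  Returns ``(onset_day, max_stage)`` where
    ``onset_day`` is the first day the encounter reaches the task's
    stage threshold (None if never) and ``max_stage`` is the maximum
    stage over the stay (0 if no AKI).
    """
    threshold = getattr(task, "stage_threshold", task)
    if threshold not in (1, 2, 3):
        raise ValueError(f"stage threshold must be 1, 2 or 3, got {threshold!r}")
    series = ScrSeries.from_pairs(timeline.scr_series)
    baseline = compute_baseline(series)
    events = stage_series(series, baseline, timeline.rrt_days)
    max_stage = max((e.stage for e in events), default=0)
    onset = next((e.day for e in events if e.stage == threshold), None)
    return onset, max_stage
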