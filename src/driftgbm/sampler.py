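"""Leakage-safe discrete-time survival sampling.

A hospital stay is divided into nonoverlapping windows at times
``delta_t, 2*delta_t, ...``; the sample at window time ``t`` predicts
AKI onset at ``t`` from records observed up to and including day
``t - delta_t``.  The window on the onset day is the single positive
sample; windows after onset, and windows between a lower-stage onset
and the task-stage onset, are excluded (the true task-stage status
there is unknowable once clinicians may have intervened); negative
windows beyond the censor day are excluded to limit class imbalance.
Excluded windows are materialized with a reason rather than silently
dropped, so the per-encounter bookkeeping is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from driftgbm import kdigo

__all__ = [
    "TaskSpec",
    "WindowSample",
    "SampleMatrix",
    "build_windows",
    "assign_roles",
    "label_cohort",
    "assemble_matrix",
]

ROLE_POSITIVE = "positive"
ROLE_NEGATIVE = "negative"
ROLE_EXCLUDED = "excluded"

REASON_POST_ONSET = "post-onset"
REASON_BETWEEN_STAGES = "between-stages"
REASON_POST_CENSOR = "post-censor"


@dataclass(frozen=True)
class TaskSpec:
    """A prediction task: stage threshold and prediction window.

    ``delta_t`` is the prediction horizon in days (1 = 24-hour, 2 =
    48-hour prediction); ``censor_T`` is the stay day beyond which
    negative windows are not emitted.
    """

    stage_threshold: int
    delta_t: int = 1
    censor_T: int = 7

    def __post_init__(self) -> None:
        if self.stage_threshold not in (1, 2, 3):
            raise ValueError("stage_threshold must be 1, 2 or 3")
        if self.delta_t < 1:
            raise ValueError("delta_t must be >= 1")
        if self.censor_T < self.delta_t:
            raise ValueError("censor_T must be >= delta_t")

    @classmethod
    def any_aki(cls) -> "TaskSpec":
        """Any-AKI (stage >= 1) prediction with a 48-hour window."""
        return cls(stage_threshold=1, delta_t=2)

    @classmethod
    def stage2(cls) -> "TaskSpec":
        """Moderate-to-severe (stage >= 2) prediction, 24-hour window."""
        return cls(stage_threshold=2, delta_t=1)

    @classmethod
    def stage3(cls) -> "TaskSpec":
        """Severe (stage 3) prediction, 24-hour window."""
        return cls(stage_threshold=3, delta_t=1)


@dataclass(frozen=True)
class WindowSample:
    encounter_id: str
    t: int
    cutoff_day: int
    role: str
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_POSITIVE, ROLE_NEGATIVE, ROLE_EXCLUDED):
            raise ValueError(f"unknown role {self.role!r}")
        if (self.role == ROLE_EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason must accompany exactly the excluded role")


def _positive_window(onset_day: int, delta_t: int) -> int:
    """Smallest window-grid time >= the onset day."""
    return delta_t * math.ceil(onset_day / delta_t)


def build_windows(los: int, task: TaskSpec, onset_day: int | None = None) -> list[int]:
    """Window-grid times for one encounter.

    For encounters that never reach the task stage the grid runs over
    multiples of ``delta_t`` up to ``min(los, censor_T)``.  For onset
    encounters it runs up to the onset day, plus the (grid-aligned)
    onset window itself, which is always included even past the censor
    point.  An encounter too short to fit one window yields an empty
    list.
    """
    if los < 1:
        raise ValueError("length of stay must be >= 1")
    dt = task.delta_t
    if onset_day is None:
        horizon = min(los, task.censor_T)
        return list(range(dt, horizon + 1, dt))
    t_pos = _positive_window(onset_day, dt)
    windows = list(range(dt, onset_day + 1, dt))
    if not windows or windows[-1] != t_pos:
        windows.append(t_pos)
    return windows


def assign_roles(
    windows: Sequence[int],
    onset_day: int | None,
    stage_trajectory: Mapping[int, int] | Iterable[kdigo.StageEvent],
    task: TaskSpec,
    encounter_id: str = "",
) -> list[WindowSample]:
    """Assign exactly one role to every window.

    ``stage_trajectory`` maps stage level -> first day reached (or is a
    list of :class:`~driftgbm.kdigo.StageEvent`).  ``onset_day`` is the
    first day the *task* stage is reached, or None.
    """
    if not isinstance(stage_trajectory, Mapping):
        stage_trajectory = {e.stage: e.day for e in stage_trajectory}
    lower_onset = min(
        (d for s, d in stage_trajectory.items() if s < task.stage_threshold),
        default=None,
    )
    t_pos = None if onset_day is None else _positive_window(onset_day, task.delta_t)
    out: list[WindowSample] = []
    for t in windows:
        cutoff = t - task.delta_t
        if t_pos is not None and t == t_pos:
            role, reason = ROLE_POSITIVE, None
        elif t_pos is not None and t > t_pos:
            role, reason = ROLE_EXCLUDED, REASON_POST_ONSET
        elif lower_onset is not None and t >= lower_onset:
            role, reason = ROLE_EXCLUDED, REASON_BETWEEN_STAGES
        elif t > task.censor_T:
            role, reason = ROLE_EXCLUDED, REASON_POST_CENSOR
        else:
            role, reason = ROLE_NEGATIVE, None
        out.append(WindowSample(encounter_id, t, cutoff, role, reason))
    return out


def label_cohort(cohort, task: TaskSpec) -> dict[str, dict[int, int]]:
    """Stage trajectories (stage -> first day) for every encounter."""
    out = {}
    for tl in cohort:
        series = kdigo.ScrSeries.from_pairs(tl.scr_series)
        baseline = kdigo.compute_baseline(series)
        events = kdigo.stage_series(series, baseline, tl.rrt_days)
        out[tl.encounter_id] = {e.stage: e.day for e in events}
    return out


@dataclass
class SampleMatrix:
    """Discrete-time samples ready for model fitting.

    ``X`` holds one feature row per non-excluded window, indexed in
    step with ``meta`` rows where role != excluded; ``y`` the binary
    labels; ``meta`` every window of every encounter with its role and
    exclusion reason; ``audit`` per-encounter positive/negative/
    excluded counts.
    """

    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame
    audit: pd.DataFrame
    task: TaskSpec
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have equal length")
        if not self.feature_names:
            self.feature_names = tuple(self.X.columns)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.y)) if len(self.y) else float("nan")

    def subset(self, mask: np.ndarray) -> "SampleMatrix":
        keep = self.meta[self.meta["role"] != ROLE_EXCLUDED].iloc[mask]
        return SampleMatrix(
            X=self.X.iloc[mask].reset_index(drop=True),
            y=self.y[mask],
            meta=keep.reset_index(drop=True),
            audit=self.audit,
            task=self.task,
            feature_names=self.feature_names,
        )


def assemble_matrix(
    cohort,
    labels: Mapping[str, Mapping[int, int]] | None,
    task: TaskSpec,
    feature_scheme,
) -> SampleMatrix:
    """Build the leakage-safe design matrix for a labeled cohort.

    Features for the window at time ``t`` are computed from records
    with ``day <= t - delta_t`` only; a record postdating the cutoff
    reaching the feature builder is a hard error, not a warning.
    """
    from driftgbm import features as _features

    if labels is None:
        labels = label_cohort(cohort, task)
    meta_rows: list[tuple] = []
    x_blocks: list[np.ndarray] = []
    y_vals: list[int] = []
    audit_rows: list[tuple] = []
    for tl in cohort:
        trajectory = labels[tl.encounter_id]
        onset = trajectory.get(task.stage_threshold)
        windows = build_windows(tl.los, task, onset)
        samples = assign_roles(windows, onset, trajectory, task, tl.encounter_id)
        n_pos = n_neg = n_exc = 0
        kept = [s for s in samples if s.role != ROLE_EXCLUDED]
        if kept:
            block, consumed = _features.apply_scheme_matrix(
                feature_scheme, tl.to_records(), [s.cutoff_day for s in kept]
            )
            for s, used in zip(kept, consumed):
                if used > s.cutoff_day:
                    raise RuntimeError(
                        f"leakage: record from day {used} used beyond cutoff day "
                        f"{s.cutoff_day} for encounter {s.encounter_id} window {s.t}"
                    )
            x_blocks.append(block)
        for s in samples:
            meta_rows.append((s.encounter_id, s.t, s.cutoff_day, s.role, s.exclusion_reason))
            if s.role == ROLE_EXCLUDED:
                n_exc += 1
            elif s.role == ROLE_POSITIVE:
                n_pos += 1
                y_vals.append(1)
            else:
                n_neg += 1
                y_vals.append(0)
        audit_rows.append((tl.encounter_id, n_pos, n_neg, n_exc))

    roster = list(feature_scheme.roster)
    X = pd.DataFrame(
        np.vstack(x_blocks) if x_blocks else np.empty((0, len(roster))),
        columns=roster,
        dtype=float,
    )
    meta = pd.DataFrame(
        meta_rows, columns=["encounter_id", "t", "cutoff_day", "role", "exclusion_reason"]
    )
    audit = pd.DataFrame(audit_rows, columns=["encounter_id", "n_pos", "n_neg", "n_excluded"])
    return SampleMatrix(
        X=X, y=np.asarray(y_vals, dtype=int), meta=meta, audit=audit, task=task
    )
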