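"""Study design: dosing schedules and saliva sampling grids.

The emulated protocol is a within-subject, three-condition study:

* ``caffeine``    — 150 mg caffeine three times a day (0.75, 4 and 8 h after
  waking) for 10 days; saliva sampled on day 10 from right before the first
  capsule until ~12 h after the last one.
* ``deprivation`` — same regimen but switched to placebo so that the day-10
  sampling window spans 24–43 h after the last active dose.
* ``placebo``     — mannitol capsules throughout; no active dose.

The default 11-sample grid is anchored to the final wake time: a pre-dose
baseline at wake+0.75 h, five 1.8 h steps up to wake+9.75 h (1.75 h after the
last capsule — the earliest post-dose observation the design permits), then
five 2.0 h steps to wake+19.75 h (11.75 h after the last capsule).  All
intervals sit inside the protocol's 105–120 min range, and the 19 h span is
what makes the deprivation window come out at exactly 24–43 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CONDITIONS",
    "DoseEvent",
    "DosingSchedule",
    "SamplingGrid",
    "build_schedule",
    "default_grid",
]

CONDITIONS = ("caffeine", "deprivation", "placebo")

DEFAULT_DOSE_MG = 150.0
DEFAULT_OFFSETS_H = (0.75, 4.0, 8.0)
DEFAULT_N_DAYS = 10
DEFAULT_WAKE_INTERVAL_H = 24.0
#: hours between the last active dose and the first deprivation sample
DEPRIVATION_GAP_H = 24.0


@dataclass(frozen=True)
class DoseEvent:
    """One capsule: time since study start (h), dose (mg), active flag."""

    time_h: float
    dose_mg: float
    active: bool


@dataclass(frozen=True)
class DosingSchedule:
    condition: str
    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time_h for e in self.events]
        if times != sorted(times):
            raise ValueError("dose events must be sorted by time")
        for e in self.events:
            if not e.active and e.dose_mg != 0.0:
                raise ValueError("inactive (placebo) events must carry dose 0 mg")

    @property
    def active_events(self) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.active)

    @property
    def n_active(self) -> int:
        return len(self.active_events)

    @property
    def last_active_time(self) -> float:
        active = self.active_events
        if not active:
            raise ValueError(f"{self.condition!r} schedule has no active dose")
        return active[-1].time_h

    def daily_active_dose(self, day: int, wake_interval_h: float = DEFAULT_WAKE_INTERVAL_H) -> float:
        """Total active dose (mg) administered on 0-based day ``day``."""
        lo, hi = day * wake_interval_h, (day + 1) * wake_interval_h
        return sum(e.dose_mg for e in self.active_events if lo <= e.time_h < hi)


@dataclass(frozen=True)
class SamplingGrid:
    """The 11 saliva sampling times with their last-dose reference.

    ``times`` are hours since study start; ``reference`` is the time of the
    last active dose of the condition being sampled, so that
    ``labels = times - reference`` are the hours-after-last-dose used for
    reporting (negative for pre-dose samples).
    """

    times: np.ndarray
    reference: float
    n_samples: int = 11
    spacing_bounds: tuple[float, float] = (1.75, 2.0)
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size != self.n_samples:
            raise ValueError(f"expected {self.n_samples} sample times, got {times.size}")
        dt = np.diff(times)
        lo, hi = self.spacing_bounds
        if np.any(dt < lo - 1e-9) or np.any(dt > hi + 1e-9):
            raise ValueError(
                f"sample spacing must lie within [{lo}, {hi}] h, got {dt.round(4).tolist()}"
            )
        object.__setattr__(self, "labels", times - self.reference)

    @property
    def baseline_time(self) -> float:
        return float(self.times[0])


def build_schedule(
    condition: str,
    n_days: int = DEFAULT_N_DAYS,
    dose_mg: float = DEFAULT_DOSE_MG,
    dose_offsets_h: tuple[float, ...] = DEFAULT_OFFSETS_H,
    wake_interval_h: float = DEFAULT_WAKE_INTERVAL_H,
) -> DosingSchedule:
    """Build the dosing schedule for one study condition.

    ``caffeine`` yields ``n_days * len(dose_offsets_h)`` active events
    (30 with defaults, 450 mg per full day).  ``placebo`` yields the same
    event times with zero active dose.  ``deprivation`` keeps events active
    only up to the latest event time that leaves the day-10 baseline sample
    exactly :data:`DEPRIVATION_GAP_H` hours after the last active dose; with
    default offsets that is the first capsule of day 9, and the 11-sample
    grid then spans 24–43 h after the last intake.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    offsets = tuple(sorted(dose_offsets_h))
    times = [
        day * wake_interval_h + off for day in range(n_days) for off in offsets
    ]
    if condition == "placebo":
        events = tuple(DoseEvent(t, 0.0, False) for t in times)
    elif condition == "caffeine":
        events = tuple(DoseEvent(t, dose_mg, True) for t in times)
    else:  # deprivation: active up to (final baseline sample) - gap
        baseline = (n_days - 1) * wake_interval_h + offsets[0]
        cutoff = baseline - DEPRIVATION_GAP_H
        events = tuple(
            DoseEvent(t, dose_mg if t <= cutoff + 1e-9 else 0.0, t <= cutoff + 1e-9)
            for t in times
        )
    return DosingSchedule(condition=condition, events=events)


def default_grid(
    schedule: DosingSchedule,
    n_days: int = DEFAULT_N_DAYS,
    dose_offsets_h: tuple[float, ...] = DEFAULT_OFFSETS_H,
    wake_interval_h: float = DEFAULT_WAKE_INTERVAL_H,
    pre_spacing_h: float = 1.8,
    post_spacing_h: float = 2.0,
) -> SamplingGrid:
    """Default day-10 sampling grid for ``schedule``'s condition.

    Sampling clock times are identical across conditions (as in the
    protocol); only the last-dose ``reference`` differs.  The grid is two
    even blocks: ``pre_spacing_h`` steps from the pre-dose baseline to
    1.75 h after the final capsule slot, then ``post_spacing_h`` steps for
    the remaining five samples.
    """
    offsets = tuple(sorted(dose_offsets_h))
    wake = (n_days - 1) * wake_interval_h
    first = wake + offsets[0]
    turn = wake + offsets[-1] + 1.75
    n_pre = 5
    pre = first + pre_spacing_h * np.arange(n_pre + 1)
    if abs(pre[-1] - turn) > 1e-9:
        # honour the 1.75 h earliest-post-dose constraint over even spacing
        pre = np.linspace(first, turn, n_pre + 1)
    post = turn + post_spacing_h * np.arange(1, 5 + 1)
    times = np.concatenate([pre, post])
    if schedule.condition == "placebo":
        # no active dose: reference the would-be last caffeine capsule so
        # that reporting labels align across conditions
        reference = wake + offsets[-1]
    else:
        reference = schedule.last_active_time
    return SamplingGrid(times=times, reference=reference)
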