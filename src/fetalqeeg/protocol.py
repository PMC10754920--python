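"""Occlusion-protocol timeline.

The experimental protocol is a one-hour stability (baseline) period followed by
three one-hour phases of repeated total umbilical-cord occlusions of increasing
frequency: 1-min occlusions every 5 min (phase A, mild), every 3 min (phase B,
moderate) and every 2 min (phase C, severe).  Every 20 min a 5-min
occlusion-free "pause" is observed, and the run is stopped as soon as an
arterial-blood sample shows pH < 6.90.

This module builds that timeline as an explicit, contiguous event list so that
both the signal simulator and the analysis-window selection operate on the same
ground truth.  The protocol text does not pin down how occlusion cycles and
pauses interleave within the hour; the layout used here divides each phase into
``pause_period_s`` blocks (default 20 min), each consisting of an
occlusion-cycle sub-block (default 15 min) followed by one pause (default
5 min).  Occlusion onsets are spaced by the phase's inter-occlusion period and
a cycle is scheduled only if the full cycle (occlusion + recovery gap) fits in
the sub-block, which yields 9/15/21 occlusions for phases A/B/C under the
default configuration.  No occlusion ever overlaps a pause.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

PHASES: tuple[str, ...] = ("S", "A", "B", "C")
OCCLUSION_PHASES: tuple[str, ...] = ("A", "B", "C")

#: Event labels used on the timeline.
STABILITY, OCCLUSION, INTER_OCCLUSION, PAUSE = (
    "stability",
    "occlusion",
    "inter-occlusion",
    "pause",
)


class ProtocolError(ValueError):
    """Raised for protocol configurations that cannot be scheduled."""


class Event(NamedTuple):
    label: str
    phase: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing parameters of the repeated-occlusion protocol (seconds).

    Defaults are the study protocol: 3600-s phases, 60-s occlusions every
    300/180/120 s in phases A/B/C, a 300-s pause every 1200 s, and a stop
    threshold of pH 6.90.
    """

    phase_duration_s: float = 3600.0
    occlusion_duration_s: float = 60.0
    inter_occlusion_period_s: Mapping[str, float] = field(
        default_factory=lambda: {"A": 300.0, "B": 180.0, "C": 120.0}
    )
    pause_period_s: float = 1200.0
    pause_duration_s: float = 300.0
    stability_duration_s: float = 3600.0
    ph_stop_threshold: float = 6.90

    def __post_init__(self) -> None:
        positives = {
            "phase_duration_s": self.phase_duration_s,
            "occlusion_duration_s": self.occlusion_duration_s,
            "pause_period_s": self.pause_period_s,
            "pause_duration_s": self.pause_duration_s,
            "stability_duration_s": self.stability_duration_s,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ProtocolError(f"{name} must be > 0, got {value}")
        for phase in OCCLUSION_PHASES:
            if phase not in self.inter_occlusion_period_s:
                raise ProtocolError(f"missing inter-occlusion period for phase {phase}")
            period = self.inter_occlusion_period_s[phase]
            if not self.occlusion_duration_s < period:
                raise ProtocolError(
                    f"occlusion_duration_s ({self.occlusion_duration_s}) must be "
                    f"shorter than the phase-{phase} period ({period})"
                )
        if not self.pause_duration_s < self.pause_period_s:
            raise ProtocolError("pause_duration_s must be shorter than pause_period_s")
        n_blocks = self.phase_duration_s / self.pause_period_s
        if abs(n_blocks - round(n_blocks)) > 1e-9:
            raise ProtocolError(
                "phase_duration_s must be an integer number of pause_period_s blocks"
            )
        cycle_span = self.pause_period_s - self.pause_duration_s
        for phase in OCCLUSION_PHASES:
            if self.inter_occlusion_period_s[phase] > cycle_span:
                raise ProtocolError(
                    f"phase-{phase} inter-occlusion period exceeds the "
                    f"occlusion sub-block length ({cycle_span} s)"
                )

    @property
    def n_blocks_per_phase(self) -> int:
        return round(self.phase_duration_s / self.pause_period_s)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered, contiguous list of timeline events, possibly truncated."""

    events: tuple[Event, ...]
    truncated_at_s: float | None = None

    def __post_init__(self) -> None:
        prev_end = None
        for ev in self.events:
            if ev.end_s <= ev.start_s:
                raise ProtocolError(f"empty or inverted event {ev}")
            if prev_end is not None and ev.start_s < prev_end - 1e-9:
                raise ProtocolError(f"overlapping events at {ev.start_s}")
            prev_end = ev.end_s

    @property
    def span_s(self) -> float:
        return self.events[-1].end_s if self.events else 0.0

    def events_in(self, label: str | None = None, phase: str | None = None) -> list[Event]:
        return [
            ev
            for ev in self.events
            if (label is None or ev.label == label)
            and (phase is None or ev.phase == phase)
        ]

    def phase_span(self, phase: str) -> tuple[float, float] | None:
        evs = self.events_in(phase=phase)
        if not evs:
            return None
        return evs[0].start_s, evs[-1].end_s

    def is_complete(self, ev: Event) -> bool:
        """True unless the event runs into the truncation point."""
        return self.truncated_at_s is None or ev.end_s < self.truncated_at_s

    def truncate(self, at_s: float) -> "ProtocolSchedule":
        """Drop events starting at/after ``at_s``; clip the straddling event."""
        if at_s >= self.span_s:
            return self
        kept: list[Event] = []
        for ev in self.events:
            if ev.start_s >= at_s:
                break
            if ev.end_s > at_s:
                ev = ev._replace(end_s=at_s)
            kept.append(ev)
        return ProtocolSchedule(tuple(kept), truncated_at_s=at_s)

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "truncated_at_s": self.truncated_at_s,
            "events": [
                {"label": e.label, "phase": e.phase, "start_s": e.start_s, "end_s": e.end_s}
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ProtocolSchedule":
        events = tuple(
            Event(e["label"], e["phase"], float(e["start_s"]), float(e["end_s"]))
            for e in payload["events"]
        )
        return cls(events, truncated_at_s=payload.get("truncated_at_s"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ProtocolSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_protocol(config: ProtocolConfig = ProtocolConfig()) -> ProtocolSchedule:
    """Lay out the stability hour followed by occlusion phases A, B and C."""
    events: list[Event] = [Event(STABILITY, "S", 0.0, config.stability_duration_s)]
    t = config.stability_duration_s
    sub_block = config.pause_period_s - config.pause_duration_s
    for phase in OCCLUSION_PHASES:
        period = config.inter_occlusion_period_s[phase]
        n_cycles = int((sub_block + 1e-9) // period)
        for _ in range(config.n_blocks_per_phase):
            block_start = t
            for _ in range(n_cycles):
                events.append(Event(OCCLUSION, phase, t, t + config.occlusion_duration_s))
                events.append(Event(INTER_OCCLUSION, phase, t + config.occlusion_duration_s, t + period))
                t += period
            if t < block_start + sub_block - 1e-9:
                # phase-C cycles leave a 60-s remainder before the pause
                events.append(Event(INTER_OCCLUSION, phase, t, block_start + sub_block))
                t = block_start + sub_block
            events.append(Event(PAUSE, phase, t, t + config.pause_duration_s))
            t += config.pause_duration_s
    return ProtocolSchedule(tuple(events))


def apply_stop_rule(
    schedule: ProtocolSchedule,
    gasometry_times_s: Sequence[float],
    gasometry_ph: Sequence[float],
    threshold: float = 6.90,
) -> ProtocolSchedule:
    """Truncate the schedule at the first blood sample with pH < ``threshold``.

    Idempotent: re-applying with the same samples leaves a truncated schedule
    unchanged.  Samples are expected sorted by time.
    """
    for t, ph in zip(gasometry_times_s, gasometry_ph):
        if ph < threshold:
            return schedule.truncate(float(t))
    return schedule
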