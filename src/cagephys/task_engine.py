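"""Task rules for four-corner home-cage operant programs.

An IntelliCage-style arena has four RFID-gated operant corners. Water access
during a nightly 3-h *drinking session* is made contingent on visiting the
currently "correct" corner, under one of five programs:

* three adaptation programs (free / nosepoke / time) that impose no corner
  rule and generate no labels;
* **place learning** — each animal has one fixed assigned corner;
* **place learning with corner switch** — the correct corner rotates to an
  adjacent corner every 45 min along the cycle 1 -> 3 -> 4 -> 2 (-> 1);
* **behavioral sequencing** — the animal must alternate between the two
  corners of its assigned diagonal; one nosepoke in the correct corner swaps
  correct and previously-correct within the diagonal.

This module encodes those rules as explicit schedules / state machines and
classifies every in-session visit as ``correct``, ``incorrect``,
``previously_correct`` (the opposite corner of the assigned diagonal) or
``lateral`` (either corner of the non-assigned diagonal).

Corner geometry (which corners count as adjacent vs diagonal) is derived
from the switch cycle: consecutive corners in the cycle are adjacent, so the
default cycle (1, 3, 4, 2) yields diagonals {1, 4} and {2, 3}. The geometry
is configurable for cages wired differently.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

CORNERS = (1, 2, 3, 4)

#: Printed switch cycle: every 45 min the correct corner moves to the next
#: element; consecutive elements are adjacent corners.
DEFAULT_CYCLE = (1, 3, 4, 2)

ADAPTATION_PROGRAMS = ("free_adaptation", "nosepoke_adaptation", "time_adaptation")
SCORED_PROGRAMS = ("place_learning", "corner_switch", "sequencing")
KNOWN_PROGRAMS = ADAPTATION_PROGRAMS + SCORED_PROGRAMS

#: Program -> duration in days, mirroring the published timeline table.
DEFAULT_TIMELINE = (
    ("free_adaptation", 5),
    ("nosepoke_adaptation", 2),
    ("time_adaptation", 3),
    ("place_learning", 2),
    ("corner_switch", 2),
    ("sequencing", 3),
)

DEFAULT_SESSION_WINDOW = (_dt.time(20, 0), _dt.time(23, 0))
DEFAULT_PHASE_MINUTES = 45.0


class VisitLabel(str, Enum):
    """Outcome category of one in-session corner visit."""

    CORRECT = "correct"
    INCORRECT = "incorrect"
    PREVIOUSLY_CORRECT = "previously_correct"
    LATERAL = "lateral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _validate_corner(corner: int) -> int:
    if corner not in CORNERS:
        raise ValueError(f"corner must be in 1..4, got {corner!r}")
    return int(corner)


@dataclass(frozen=True)
class CornerGeometry:
    """Adjacency/diagonal structure of the four corners.

    Derived from a switch cycle: corners adjacent in the cycle are physically
    adjacent, so the corner two steps away is the diagonal opposite.
    """

    cycle: tuple[int, int, int, int] = DEFAULT_CYCLE

    def __post_init__(self) -> None:
        if sorted(self.cycle) != [1, 2, 3, 4]:
            raise ValueError(f"cycle must be a permutation of 1..4, got {self.cycle}")

    def opposite(self, corner: int) -> int:
        """Diagonal opposite of ``corner`` (an involution)."""
        _validate_corner(corner)
        i = self.cycle.index(corner)
        return self.cycle[(i + 2) % 4]

    def diagonal(self, corner: int) -> frozenset[int]:
        """Unordered diagonal pair containing ``corner``."""
        return frozenset({corner, self.opposite(corner)})

    @property
    def diagonals(self) -> tuple[frozenset[int], frozenset[int]]:
        return self.diagonal(self.cycle[0]), self.diagonal(self.cycle[1])


DEFAULT_GEOMETRY = CornerGeometry()


@dataclass(frozen=True)
class ProgramPhase:
    name: str
    days: int


@dataclass(frozen=True)
class ProgramTimeline:
    """Ordered program phases plus the nightly drinking-session window.

    ``total_days`` is the sum of per-program durations. ``declared_total_days``
    carries a separately stated overall duration when the source config
    provides one; the two are reported side by side and never reconciled
    silently (the published table sums to 17 days while the accompanying text
    declares 18).
    """

    phases: tuple[ProgramPhase, ...]
    session_start: _dt.time = DEFAULT_SESSION_WINDOW[0]
    session_end: _dt.time = DEFAULT_SESSION_WINDOW[1]
    declared_total_days: int | None = None

    @property
    def total_days(self) -> int:
        return sum(p.days for p in self.phases)

    @property
    def session_minutes(self) -> float:
        start = _dt.datetime.combine(_dt.date(2000, 1, 1), self.session_start)
        end = _dt.datetime.combine(_dt.date(2000, 1, 1), self.session_end)
        if end <= start:
            end += _dt.timedelta(days=1)
        return (end - start).total_seconds() / 60.0

    def program_for_day(self, day: int) -> str:
        """Program active on (0-based) experiment day ``day``."""
        if day < 0:
            raise ValueError("day must be >= 0")
        cursor = 0
        for p in self.phases:
            if day < cursor + p.days:
                return p.name
            cursor += p.days
        raise ValueError(f"day {day} beyond timeline ({self.total_days} days)")

    def days_of(self, program: str) -> list[int]:
        """0-based experiment-day indices on which ``program`` runs."""
        out, cursor = [], 0
        for p in self.phases:
            if p.name == program:
                out.extend(range(cursor, cursor + p.days))
            cursor += p.days
        return out


def build_timeline(config: Mapping | None = None) -> ProgramTimeline:
    """Build a :class:`ProgramTimeline` from a structured description.

    ``config`` maps ``phases`` to an ordered list of ``{name, days}`` (or
    ``[name, days]`` pairs), with optional ``session_start`` / ``session_end``
    ("HH:MM" strings) and ``declared_total_days``. With no config the
    published default timeline is used.
    """
    if config is None:
        config = {}
    raw_phases = config.get("phases")
    if raw_phases is None:
        phases = tuple(ProgramPhase(n, d) for n, d in DEFAULT_TIMELINE)
        declared = config.get("declared_total_days", 18)
    else:
        if len(raw_phases) == 0:
            raise ValueError("timeline must contain at least one phase")
        phases_list = []
        for entry in raw_phases:
            if isinstance(entry, Mapping):
                name, days = entry["name"], entry["days"]
            else:
                name, days = entry
            if name not in KNOWN_PROGRAMS:
                raise ValueError(
                    f"unknown program {name!r}; expected one of {KNOWN_PROGRAMS}"
                )
            days = int(days)
            if days <= 0:
                raise ValueError(f"program {name!r} has non-positive duration {days}")
            phases_list.append(ProgramPhase(name, days))
        phases = tuple(phases_list)
        declared = config.get("declared_total_days")

    def _time(v, default):
        if v is None:
            return default
        if isinstance(v, _dt.time):
            return v
        h, m = str(v).split(":")
        return _dt.time(int(h), int(m))

    return ProgramTimeline(
        phases=phases,
        session_start=_time(config.get("session_start"), DEFAULT_SESSION_WINDOW[0]),
        session_end=_time(config.get("session_end"), DEFAULT_SESSION_WINDOW[1]),
        declared_total_days=declared,
    )


@dataclass(frozen=True)
class VisitEvent:
    """One corner entry by one animal.

    ``time_min`` is minutes since the start of the drinking session; visits
    are classified by their entry time (half-open phase intervals
    ``[start, end)``).
    """

    animal_id: str
    corner: int
    time_min: float
    nosepokes: int = 0
    licks: int = 0
    cage_id: str = "cage1"

    def __post_init__(self) -> None:
        _validate_corner(self.corner)
        if self.nosepokes < 0 or self.licks < 0:
            raise ValueError("nosepokes and licks must be non-negative")


@dataclass(frozen=True)
class CornerAssignment:
    """Initial correct corner per animal within one cage.

    No corner may be assigned to more than two animals in a cage (at most
    two animals share a correct corner).
    """

    cage_id: str
    corners: Mapping[str, int]
    max_per_corner: int = 2

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for animal, corner in self.corners.items():
            _validate_corner(corner)
            counts[corner] = counts.get(corner, 0) + 1
            if counts[corner] > self.max_per_corner:
                raise ValueError(
                    f"corner {corner} assigned to more than "
                    f"{self.max_per_corner} animals in cage {self.cage_id}"
                )


@dataclass(frozen=True)
class CorrectCornerSchedule:
    """Time-tiled correct-corner plan for one session (corner-switch program).

    ``entries`` is an ordered list of (start_min, end_min, corner); intervals
    tile the session without overlap and are half-open ``[start, end)``.
    """

    entries: tuple[tuple[float, float, int], ...]

    def corner_at(self, time_min: float) -> int:
        for start, end, corner in self.entries:
            if start <= time_min < end:
                return corner
        raise ValueError(f"time {time_min} min outside the scheduled session")

    @property
    def corners(self) -> list[int]:
        return [c for _, _, c in self.entries]


def corner_switch_schedule(
    initial: int,
    session_minutes: float = 180.0,
    phase_minutes: float = DEFAULT_PHASE_MINUTES,
    geometry: CornerGeometry = DEFAULT_GEOMETRY,
) -> CorrectCornerSchedule:
    """45-min rotation of the correct corner along the switch cycle.

    Phase ``k`` is correct at the k-th cycle position counted from
    ``initial``; after a full cycle the corner returns to ``initial``, so the
    first phase of the next session repeats the initial corner. A final
    partial phase is emitted when the phase length does not divide the
    session.
    """
    _validate_corner(initial)
    if phase_minutes <= 0:
        raise ValueError("phase length must be positive")
    start_idx = geometry.cycle.index(initial)
    entries = []
    t = 0.0
    k = 0
    while t < session_minutes - 1e-9:
        end = min(t + phase_minutes, session_minutes)
        corner = geometry.cycle[(start_idx + k) % 4]
        entries.append((t, end, corner))
        t = end
        k += 1
    return CorrectCornerSchedule(entries=tuple(entries))


@dataclass(frozen=True)
class SequencingState:
    """State of the diagonal-alternation (sequencing) rule for one animal."""

    correct: int
    diagonal: frozenset[int]
    previously_correct: int | None = None
    switch_count: int = 0
    geometry: CornerGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if self.correct not in self.diagonal:
            raise ValueError("correct corner must lie on the assigned diagonal")
        if self.previously_correct is not None and self.previously_correct not in self.diagonal:
            raise ValueError("previously-correct corner must lie on the assigned diagonal")


def sequencing_init(
    assigned: int, geometry: CornerGeometry = DEFAULT_GEOMETRY
) -> SequencingState:
    """Initial sequencing state: correct at the assigned corner, no
    previously-correct corner, diagonal = {assigned, opposite(assigned)}."""
    _validate_corner(assigned)
    return SequencingState(
        correct=assigned, diagonal=geometry.diagonal(assigned), geometry=geometry
    )


def sequencing_update(
    state: SequencingState,
    visit: VisitEvent,
    swap_requires_nosepoke: bool = True,
) -> tuple[VisitLabel, SequencingState]:
    """Label one visit under the sequencing rule and advance the state.

    A visit to the current correct corner is labelled ``correct``; it swaps
    correct and previously-correct within the diagonal only when it carries
    at least one nosepoke (the door switch is nosepoke-triggered; set
    ``swap_requires_nosepoke=False`` to swap on entry). A visit to the other
    diagonal corner is ``previously_correct``; visits off the diagonal are
    ``lateral``. The state changes only on a triggered swap.
    """
    corner = _validate_corner(visit.corner)
    if corner == state.correct:
        triggered = visit.nosepokes >= 1 or not swap_requires_nosepoke
        if triggered:
            new_state = replace(
                state,
                correct=state.geometry.opposite(state.correct),
                previously_correct=state.correct,
                switch_count=state.switch_count + 1,
            )
        else:
            new_state = state
        return VisitLabel.CORRECT, new_state
    if corner in state.diagonal:
        return VisitLabel.PREVIOUSLY_CORRECT, state
    return VisitLabel.LATERAL, state


def classify_visit(
    visit: VisitEvent,
    *,
    program: str,
    assigned: int | None = None,
    schedule: CorrectCornerSchedule | None = None,
    state: SequencingState | None = None,
    swap_requires_nosepoke: bool = True,
) -> tuple[VisitLabel, SequencingState | None]:
    """Classify one in-session visit under the active program.

    * ``place_learning`` — needs ``assigned``; correct iff corner == assigned.
    * ``corner_switch`` — needs ``schedule``; correct iff corner equals the
      scheduled corner at the visit's entry time.
    * ``sequencing`` — needs ``state``; delegates to
      :func:`sequencing_update` and returns the advanced state.

    Returns ``(label, new_state)``; ``new_state`` is ``None`` except for the
    sequencing program.
    """
    if program == "place_learning":
        if assigned is None:
            raise ValueError("place_learning requires an assigned corner")
        _validate_corner(assigned)
        label = VisitLabel.CORRECT if visit.corner == assigned else VisitLabel.INCORRECT
        return label, None
    if program == "corner_switch":
        if schedule is None:
            raise ValueError("corner_switch requires a CorrectCornerSchedule")
        correct = schedule.corner_at(visit.time_min)
        label = VisitLabel.CORRECT if visit.corner == correct else VisitLabel.INCORRECT
        return label, None
    if program == "sequencing":
        if state is None:
            raise ValueError("sequencing requires a SequencingState")
        label, new_state = sequencing_update(
            state, visit, swap_requires_nosepoke=swap_requires_nosepoke
        )
        return label, new_state
    if program in ADAPTATION_PROGRAMS:
        raise ValueError(f"adaptation program {program!r} generates no visit labels")
    raise ValueError(f"unknown program {program!r}")


def label_session(
    visits: Sequence[VisitEvent],
    *,
    program: str,
    assigned: int | None = None,
    geometry: CornerGeometry = DEFAULT_GEOMETRY,
    session_minutes: float = 180.0,
    phase_minutes: float = DEFAULT_PHASE_MINUTES,
    swap_requires_nosepoke: bool = True,
) -> list[VisitLabel]:
    """Label a time-ordered visit stream of one animal over one session."""
    if program == "corner_switch":
        if assigned is None:
            raise ValueError("corner_switch requires an assigned initial corner")
        schedule = corner_switch_schedule(
            assigned, session_minutes, phase_minutes, geometry
        )
        return [
            classify_visit(v, program=program, schedule=schedule)[0] for v in visits
        ]
    if program == "sequencing":
        if assigned is None:
            raise ValueError("sequencing requires an assigned corner")
        state = sequencing_init(assigned, geometry)
        labels = []
        for v in visits:
            label, state = classify_visit(
                v,
                program=program,
                state=state,
                swap_requires_nosepoke=swap_requires_nosepoke,
            )
            labels.append(label)
        return labels
    return [
        classify_visit(v, program=program, assigned=assigned)[0] for v in visits
    ]
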