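"""End-to-end orchestration: event log -> labelled sessions -> AUC table ->
factorial statistics, mirroring how the behavioral readout is produced from
raw visit records."""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Mapping, Sequence

import pandas as pd

from . import scoring, task_engine as te
from .stats import FactorialAnova

log = logging.getLogger("cagephys")


def sessions_from_log(
    events: pd.DataFrame,
    animals: pd.DataFrame,
    timeline: te.ProgramTimeline | None = None,
    geometry: te.CornerGeometry = te.DEFAULT_GEOMETRY,
    start_date: _dt.date | None = None,
    swap_requires_nosepoke: bool = True,
) -> list[scoring.SessionVisits]:
    """Label a raw event log into per-animal per-session visit streams.

    ``animals`` carries ``animal_id, sex, genotype, corner`` (the assigned
    initial corner). Visits outside the nightly drinking-session window are
    excluded from scoring; adaptation-program days generate no labelled
    sessions. Each labelled visit stream replays the active program's rule
    from the session start (the sequencing state machine resets nightly).
    """
    timeline = timeline or te.build_timeline()
    events = events.copy()
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    if start_date is None:
        start_date = events["timestamp"].min().date()
    session_minutes = timeline.session_minutes
    info = animals.set_index("animal_id")

    sessions: list[scoring.SessionVisits] = []
    n_in = len(events)
    n_out = 0
    # assign each event to an experiment day by its session start
    day_idx = (events["timestamp"].dt.date - start_date).apply(lambda d: d.days)
    events["_day"] = day_idx
    session_start_clock = timeline.session_start
    for (animal_id, day), sub in events.groupby(["animal_id", "_day"]):
        if day < 0 or day >= timeline.total_days:
            continue
        program = timeline.program_for_day(int(day))
        if program in te.ADAPTATION_PROGRAMS:
            continue
        if animal_id not in info.index:
            raise KeyError(f"event log references unknown animal {animal_id!r}")
        row = info.loc[animal_id]
        t0 = _dt.datetime.combine(
            start_date + _dt.timedelta(days=int(day)), session_start_clock
        )
        minutes = (sub["timestamp"] - t0).dt.total_seconds() / 60.0
        in_session = (minutes >= 0) & (minutes < session_minutes)
        sub = sub[in_session]
        minutes = minutes[in_session]
        order = minutes.argsort(kind="mergesort")
        visits = [
            te.VisitEvent(
                animal_id=animal_id,
                corner=int(c),
                time_min=float(m),
                nosepokes=int(np_),
                licks=int(l),
            )
            for c, m, np_, l in zip(
                sub["corner"].to_numpy()[order],
                minutes.to_numpy()[order],
                sub["nosepokes"].to_numpy()[order],
                sub["licks"].to_numpy()[order],
            )
        ]
        labels = te.label_session(
            visits,
            program=program,
            assigned=int(row["corner"]),
            geometry=geometry,
            session_minutes=session_minutes,
            swap_requires_nosepoke=swap_requires_nosepoke,
        )
        program_day = timeline.days_of(program).index(int(day))
        n_out += len(visits)
        sessions.append(
            scoring.SessionVisits(
                animal_id=animal_id,
                program=program,
                day=program_day,
                times_min=tuple(v.time_min for v in visits),
                labels=tuple(labels),
                session_minutes=session_minutes,
                sex=row.get("sex"),
                genotype=row.get("genotype"),
            )
        )
    log.info(
        "sessions_from_log stage=label n_in=%d n_out=%d n_excluded=%d",
        n_in,
        n_out,
        n_in - n_out,
    )
    return sessions


def auc_table_from_log(
    events: pd.DataFrame,
    animals: pd.DataFrame,
    timeline: te.ProgramTimeline | None = None,
    denominator: scoring.DenominatorPolicy = "whole_session",
    threshold: int = scoring.DEFAULT_EXCLUSION_THRESHOLD,
    **kwargs,
) -> pd.DataFrame:
    """Event log -> tidy AUC table (one row per included animal-session)."""
    sessions = sessions_from_log(events, animals, timeline, **kwargs)
    records = [
        scoring.score_session(s, denominator=denominator, threshold=threshold)
        for s in sessions
        if s.n_visits > 0
    ]
    table = scoring.group_auc_table(records)
    log.info(
        "auc_table stage=score n_in=%d n_out=%d n_excluded=%d",
        len(records),
        len(table),
        len(records) - len(table),
    )
    return table


def interaction_anova(
    auc_table: pd.DataFrame,
    session: str,
    ss_type: int = 3,
):
    """Sex x genotype two-way ANOVA of AUC for one session (e.g. day-2
    sequencing), as reported per session in the behavioral figures."""
    sub = auc_table[auc_table["session"] == session]
    if sub.empty:
        raise ValueError(f"no rows for session {session!r}")
    return FactorialAnova(sub, dv="auc", between=["sex", "genotype"]).fit(
        ss_type=ss_type
    )
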