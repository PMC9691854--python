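"""Learning curves and AUC performance measures from labelled visit streams.

For each animal and drinking session, the cumulative count of correct visits
is expressed as a fraction of all visits and plotted against session time
(the *fractional accumulation of correct visits*). The area under that curve
(AUC), on time normalized to [0, 1], is the per-session performance
statistic: chance-level random visiting yields ~0.25 with four corners, a
perfect performer 1.0, and early-in-session correct visits weigh more than
late ones.

Animals that did not make more than 25 visits in a session are excluded
from that session's analysis.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .task_engine import VisitLabel

#: A session needs strictly more visits than this to enter the analysis.
DEFAULT_EXCLUSION_THRESHOLD = 25

DenominatorPolicy = Literal["whole_session", "running"]


@dataclass(frozen=True)
class SessionVisits:
    """Time-ordered labelled visits of one animal in one drinking session.

    ``times_min`` are minutes from session start; ``session_minutes`` is the
    session length used to normalize time to [0, 1].
    """

    animal_id: str
    program: str
    day: int
    times_min: tuple[float, ...]
    labels: tuple[VisitLabel, ...]
    session_minutes: float = 180.0
    sex: str | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.labels):
            raise ValueError("times and labels must have equal length")
        if any(b < a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("visits must be time-ordered")
        if self.times_min and not (
            0 <= min(self.times_min) and max(self.times_min) <= self.session_minutes
        ):
            raise ValueError("visit times must lie within the session")

    @property
    def n_visits(self) -> int:
        return len(self.times_min)

    @property
    def n_correct(self) -> int:
        return sum(1 for l in self.labels if l == VisitLabel.CORRECT)

    @property
    def session_id(self) -> str:
        return f"{self.program}_day{self.day + 1}"


def apply_exclusion(
    visits: SessionVisits, threshold: int = DEFAULT_EXCLUSION_THRESHOLD
) -> bool:
    """True iff the session enters the analysis (> ``threshold`` visits)."""
    return visits.n_visits > threshold


@dataclass(frozen=True)
class LearningCurve:
    """Right-continuous step curve of cumulative correct fraction.

    ``times`` are normalized breakpoints in [0, 1]; ``values[i]`` holds on
    ``[times[i], times[i+1])`` and ``values[-1]`` up to 1. The curve starts
    at 0 at time 0. The default fractional-accumulation curve is
    nondecreasing; the running-fraction variant may decrease, flagged by
    ``monotone=False`` at construction.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]
    monotone: InitVar[bool] = True

    def __post_init__(self, monotone: bool = True) -> None:
        v = np.asarray(self.values)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if monotone and np.any(np.diff(v) < -1e-12):
            raise ValueError("curve values must be nondecreasing")
        if len(v) and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("curve values must lie in [0, 1]")

    def __call__(self, t: float) -> float:
        """Curve value at normalized time ``t`` (right-continuous)."""
        value = 0.0
        for bt, bv in zip(self.times, self.values):
            if bt <= t:
                value = bv
            else:
                break
        return value

    @property
    def final_value(self) -> float:
        return self.values[-1] if self.values else 0.0


def learning_curve(
    visits: SessionVisits,
    denominator: DenominatorPolicy = "whole_session",
) -> LearningCurve:
    """Fractional-accumulation curve of correct visits over session time.

    Under the default ``whole_session`` policy the curve steps by
    ``1/n_visits`` at each correct visit's normalized time, reaching
    ``n_correct/n_visits`` at the last correct visit. The ``running`` policy
    instead tracks cumulative-correct / cumulative-total at every visit.
    """
    if visits.n_visits == 0:
        raise ValueError("cannot build a learning curve from an empty session")
    t_norm = [t / visits.session_minutes for t in visits.times_min]
    times: list[float] = []
    values: list[float] = []
    if denominator == "whole_session":
        n = visits.n_visits
        cum = 0
        for t, label in zip(t_norm, visits.labels):
            if label == VisitLabel.CORRECT:
                cum += 1
                times.append(t)
                values.append(cum / n)
    elif denominator == "running":
        cum_correct = 0
        for i, (t, label) in enumerate(zip(t_norm, visits.labels), start=1):
            if label == VisitLabel.CORRECT:
                cum_correct += 1
            times.append(t)
            values.append(cum_correct / i)
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    return LearningCurve(
        times=tuple(times),
        values=tuple(values),
        monotone=denominator == "whole_session",
    )


def auc(curve: LearningCurve) -> float:
    """Exact integral of the step curve over normalized time [0, 1]."""
    total = 0.0
    prev_t, prev_v = 0.0, 0.0
    for t, v in zip(curve.times, curve.values):
        total += prev_v * (t - prev_t)
        prev_t, prev_v = t, v
    total += prev_v * (1.0 - prev_t)
    return total


@dataclass(frozen=True)
class AucRecord:
    """Per animal-session AUC with factor labels and inclusion flag."""

    animal_id: str
    session_id: str
    sex: str
    genotype: str
    auc: float
    n_visits: int
    included: bool


def score_session(
    visits: SessionVisits,
    denominator: DenominatorPolicy = "whole_session",
    threshold: int = DEFAULT_EXCLUSION_THRESHOLD,
) -> AucRecord:
    """Exclusion check + curve + AUC for one animal-session."""
    included = apply_exclusion(visits, threshold)
    value = auc(learning_curve(visits, denominator)) if visits.n_visits else 0.0
    if visits.sex is None or visits.genotype is None:
        raise ValueError("session must carry sex and genotype factor labels")
    return AucRecord(
        animal_id=visits.animal_id,
        session_id=visits.session_id,
        sex=visits.sex,
        genotype=visits.genotype,
        auc=value,
        n_visits=visits.n_visits,
        included=included,
    )


def group_auc_table(records: Iterable[AucRecord]) -> pd.DataFrame:
    """Tidy table of included animal-sessions keyed by sex × genotype × session.

    One row per included record; excluded sessions are dropped (they are
    excluded from the analysis of that session). Group means/SEMs are
    computable downstream with ordinary groupby operations.
    """
    rows = []
    for r in records:
        if r.sex is None or r.genotype is None:
            raise ValueError(f"record {r.animal_id}/{r.session_id} lacks factor labels")
        if r.included:
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "session": r.session_id,
                    "sex": r.sex,
                    "genotype": r.genotype,
                    "n_visits": r.n_visits,
                    "auc": r.auc,
                }
            )
    df = pd.DataFrame(
        rows, columns=["animal_id", "session", "sex", "genotype", "n_visits", "auc"]
    )
    return df.sort_values(["session", "genotype", "sex", "animal_id"]).reset_index(
        drop=True
    )
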