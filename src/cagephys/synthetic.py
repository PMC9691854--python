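"""Synthetic study data: an agent-based cohort simulator for the four-corner
operant programs, and a stimulus–response / plasticity model emitting
synthetic fEPSP sweeps.

The cohort simulator emulates the study design — four sex × genotype groups
(defaults 18 F-control, 19 M-control, 10 F-mutant, 11 M-mutant; 58 animals),
cages of eight with at most two animals sharing a correct corner, nightly
3-h drinking sessions — and a simple instrumental learner per animal: visits
arrive as a homogeneous Poisson process within each session; the corner
choice is a softmax over per-corner action values conditioned on the
outcome of the previous visit (previous corner, rewarded or not), and the
visited corner's value moves by ``alpha * (reward - value)`` where reward
is 1 iff the task engine labels the visit correct. Conditioning on the
previous outcome lets the agent learn the alternation rule of the
sequencing task (after a rewarded visit at one diagonal corner, the
opposite corner pays), not just fixed corner preferences. Group differences enter through per-group
multipliers on the learning rate (and optionally the asymptotic accuracy).
Effect sizes are calibration choices: the source experiments publish test
statistics, not raw per-animal data, so the defaults are set once to
reproduce the qualitative pattern (female controls best, a sex × genotype
interaction on the sequencing task) at a comparable strength.

The sweep synthesizer uses alpha-function kinetics for fiber volley and
fEPSP (analytic slopes available for oracles), a saturating Hill
input–output gain, a depletion–facilitation paired-pulse model

    PPR(IPI) = 1 + (1 - Pr) * F * exp(-IPI/tau_f) - Pr * exp(-IPI/tau_rec)

(monotone decreasing in release probability Pr at every interval), and a
normalized potentiation profile

    P(t) = 1 + A_stp * exp(-t/tau_stp) + A_e * exp(-t/tau_e) + A_late

so that P(t) -> 1 + A_late long after induction.

All random draws flow from one root seed via named substreams (per animal /
per sweep), so identical seeds give identical logs and sweeps end to end.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import task_engine as te
from .ephys import IO_STIMULI_UA, SweepTrace

SEXES = ("F", "M")
GENOTYPES = ("control", "mutant")
GROUPS = tuple((s, g) for g in GENOTYPES for s in SEXES)

#: published cohort: 18 F / 19 M controls, 10 F / 11 M mutants (58 rats)
DEFAULT_GROUP_SIZES = {
    ("F", "control"): 18,
    ("M", "control"): 19,
    ("F", "mutant"): 10,
    ("M", "mutant"): 11,
}


@dataclass(frozen=True)
class CohortDesign:
    """Group sizes and caging constraints for one simulated cohort."""

    group_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    cage_capacity: int = 8
    max_per_corner: int = 2

    def __post_init__(self) -> None:
        for key, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {key}")
        if self.cage_capacity > self.max_per_corner * len(te.CORNERS):
            raise ValueError(
                "cage capacity exceeds what the per-corner sharing limit allows"
            )

    @property
    def n_animals(self) -> int:
        return sum(self.group_sizes.values())


def build_cohort(design: CohortDesign) -> pd.DataFrame:
    """Animal table with cage and initial-corner assignments.

    Sexes are caged separately (as in the study housing); corners are dealt
    round-robin within each cage so no corner serves more than two animals.
    Columns: animal_id, sex, genotype, cage_id, corner.
    """
    rows = []
    for sex in SEXES:
        animals = []
        for genotype in GENOTYPES:
            n = design.group_sizes.get((sex, genotype), 0)
            for i in range(n):
                animals.append((f"{sex}{genotype[0].upper()}{i + 1:02d}", genotype))
        for j, (animal_id, genotype) in enumerate(animals):
            cage = j // design.cage_capacity
            slot = j % design.cage_capacity
            corner = te.CORNERS[slot % len(te.CORNERS)]
            rows.append(
                {
                    "animal_id": animal_id,
                    "sex": sex,
                    "genotype": genotype,
                    "cage_id": f"cage_{sex}{cage + 1}",
                    "corner": corner,
                }
            )
    animals_df = pd.DataFrame(rows)
    # validate the two-per-corner constraint cage by cage
    for cage_id, sub in animals_df.groupby("cage_id"):
        te.CornerAssignment(
            cage_id=cage_id,
            corners=dict(zip(sub["animal_id"], sub["corner"])),
            max_per_corner=design.max_per_corner,
        )
    return animals_df


@dataclass(frozen=True)
class AgentParams:
    """Learning-agent parameters for the cohort simulator.

    visit_rate_per_h : Poisson visit rate during the 3-h session (the
        default keeps every animal above the >25-visit inclusion threshold
        with near certainty, matching a study in which no animal was
        excluded).
    alpha : value-learning rate per visit.
    p_max : asymptotic probability of choosing a fully learned corner; maps
        to the softmax temperature via beta = ln(3 p_max / (1 - p_max)).
    p_floor : chance-level choice probability before learning (1/4 corners).
    alpha_multipliers / p_max_multipliers : per-(sex, genotype) multipliers;
        the default places the learning-rate advantage on female controls
        only, a pure sex × genotype interaction.
    nuisance_rate_per_h : rate of unscored out-of-session visits injected
        around the session (0 disables; used to exercise session filtering).
    """

    visit_rate_per_h: float = 20.0
    alpha: float = 0.15
    p_max: float = 0.85
    p_floor: float = 0.25
    alpha_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("F", "control"): 1.0,
            ("M", "control"): 0.3,
            ("F", "mutant"): 0.3,
            ("M", "mutant"): 0.3,
        }
    )
    p_max_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {g: 1.0 for g in GROUPS}
    )
    nuisance_rate_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.visit_rate_per_h <= 0:
            raise ValueError("visit rate must be positive")
        if self.alpha < 0:
            raise ValueError("learning rate must be non-negative")
        if not (0 <= self.p_floor <= self.p_max <= 1):
            raise ValueError("need 0 <= p_floor <= p_max <= 1")

    def softmax_beta(self, sex: str, genotype: str) -> float:
        p = min(self.p_max * self.p_max_multipliers.get((sex, genotype), 1.0), 0.999)
        p = max(p, self.p_floor)
        if p <= self.p_floor:
            return 0.0
        return float(np.log(3.0 * p / (1.0 - p)))

    def group_alpha(self, sex: str, genotype: str) -> float:
        return self.alpha * self.alpha_multipliers.get((sex, genotype), 1.0)


@dataclass
class SimulatedCohort:
    """Output of :func:`simulate_cohort`: raw event log + animal table."""

    events: pd.DataFrame
    animals: pd.DataFrame
    timeline: te.ProgramTimeline
    seed: int


def _softmax(q: np.ndarray, beta: float) -> np.ndarray:
    z = beta * (q - q.max())
    w = np.exp(z)
    return w / w.sum()


def simulate_cohort(
    design: CohortDesign | None = None,
    params: AgentParams | None = None,
    timeline: te.ProgramTimeline | None = None,
    seed: int = 0,
    programs: Sequence[str] | None = None,
    geometry: te.CornerGeometry = te.DEFAULT_GEOMETRY,
    start_date: _dt.date = _dt.date(2026, 1, 1),
) -> SimulatedCohort:
    """Simulate a full cohort's visit event log.

    Visits are Poisson within each nightly session; corners are chosen by a
    softmax over contextual action values ``Q[prev_corner, prev_rewarded,
    corner]`` (context 0 at session start), which reset at each program
    boundary (a new rule) and persist across days within a program. The
    sequencing rule state resets at each session start. ``programs``
    restricts simulation to a subset of timeline programs (adaptation
    programs produce uniform unscored visits).

    Returns a :class:`SimulatedCohort`; the event log has columns
    ``timestamp, animal_id, cage_id, corner, visit_end, nosepokes, licks``
    and is sorted by timestamp.
    """
    design = design or CohortDesign()
    params = params or AgentParams()
    timeline = timeline or te.build_timeline()
    animals = build_cohort(design)
    session_minutes = timeline.session_minutes

    root = np.random.SeedSequence(seed)
    streams = {
        a: np.random.default_rng(s)
        for a, s in zip(animals["animal_id"], root.spawn(len(animals)))
    }

    records: list[dict] = []
    for row in animals.itertuples(index=False):
        rng = streams[row.animal_id]
        alpha = params.group_alpha(row.sex, row.genotype)
        beta = params.softmax_beta(row.sex, row.genotype)
        # contextual action values: previous corner (0 = none) x previous
        # reward x next corner
        q = np.zeros((5, 2, 4))
        current_program = None
        for day in range(timeline.total_days):
            program = timeline.program_for_day(day)
            if programs is not None and program not in programs:
                continue
            if program != current_program:
                q = np.zeros((5, 2, 4))  # new rule: start from scratch
                current_program = program
            schedule = None
            state = None
            if program == "corner_switch":
                schedule = te.corner_switch_schedule(
                    row.corner, session_minutes, geometry=geometry
                )
            elif program == "sequencing":
                state = te.sequencing_init(row.corner, geometry)

            n_visits = rng.poisson(params.visit_rate_per_h * session_minutes / 60.0)
            times = np.sort(rng.uniform(0.0, session_minutes, size=n_visits))
            session_start = _dt.datetime.combine(
                start_date + _dt.timedelta(days=day), timeline.session_start
            )
            ctx = (0, 0)  # no previous visit at session start
            for t in times:
                if program in te.ADAPTATION_PROGRAMS:
                    corner = int(rng.integers(1, 5))
                    label = None
                else:
                    probs = _softmax(q[ctx], beta)
                    corner = int(rng.choice([1, 2, 3, 4], p=probs))
                # nosepokes drawn before labeling: the sequencing door switch
                # is nosepoke-triggered
                nosepokes = int(1 + rng.poisson(1.0))
                visit = te.VisitEvent(
                    animal_id=row.animal_id,
                    corner=corner,
                    time_min=float(t),
                    nosepokes=nosepokes,
                    cage_id=row.cage_id,
                )
                if program == "place_learning":
                    label, _ = te.classify_visit(
                        visit, program=program, assigned=row.corner
                    )
                elif program == "corner_switch":
                    label, _ = te.classify_visit(
                        visit, program=program, schedule=schedule
                    )
                elif program == "sequencing":
                    label, state = te.classify_visit(
                        visit, program=program, state=state
                    )
                if program not in te.ADAPTATION_PROGRAMS:
                    reward = 1.0 if label == te.VisitLabel.CORRECT else 0.0
                    q[ctx][corner - 1] += alpha * (reward - q[ctx][corner - 1])
                    ctx = (corner, int(reward))
                correct = label == te.VisitLabel.CORRECT if label else False
                licks = int(rng.poisson(25.0)) if correct else 0
                start = session_start + _dt.timedelta(minutes=float(t))
                duration_s = float(rng.exponential(20.0)) + 2.0
                records.append(
                    {
                        "timestamp": start,
                        "animal_id": row.animal_id,
                        "cage_id": row.cage_id,
                        "corner": corner,
                        "visit_end": start + _dt.timedelta(seconds=duration_s),
                        "nosepokes": nosepokes,
                        "licks": licks,
                    }
                )
            if params.nuisance_rate_per_h > 0:
                # unscored visits outside the drinking session (2 h before)
                n_out = rng.poisson(params.nuisance_rate_per_h * 2.0)
                for t in rng.uniform(-120.0, 0.0, size=n_out):
                    start = session_start + _dt.timedelta(minutes=float(t))
                    records.append(
                        {
                            "timestamp": start,
                            "animal_id": row.animal_id,
                            "cage_id": row.cage_id,
                            "corner": int(rng.integers(1, 5)),
                            "visit_end": start + _dt.timedelta(seconds=10.0),
                            "nosepokes": int(rng.poisson(0.5)),
                            "licks": 0,
                        }
                    )

    events = pd.DataFrame.from_records(
        records,
        columns=[
            "timestamp",
            "animal_id",
            "cage_id",
            "corner",
            "visit_end",
            "nosepokes",
            "licks",
        ],
    )
    events = events.sort_values(
        ["timestamp", "animal_id"], kind="mergesort"
    ).reset_index(drop=True)
    return SimulatedCohort(events=events, animals=animals, timeline=timeline, seed=seed)


# ---------------------------------------------------------------------------
# fEPSP sweep synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapseParams:
    """Parameters of the synthetic stimulus–response / plasticity model.

    Release and short-term plasticity: ``pr`` (release probability),
    ``facil_amp`` F and ``tau_f`` (facilitation, ms), ``tau_rec``
    (recovery from depletion, ms). Input–output: maximal fEPSP slope ``s0``
    (mV/ms) scaled by a Hill gain in stimulus magnitude (``i_half`` uA,
    ``hill``); fiber-volley maximal amplitude ``fv_gain`` (mV) with its own
    Hill gain. ``noise_sd`` is additive Gaussian trace noise (mV).
    Potentiation profile (minutes): ``a_stp, tau_stp`` (decaying STP
    component), ``a_e, tau_e`` (decaying early component), ``a_late``
    (persistent late component), entering
    P(t) = 1 + a_stp e^(-t/tau_stp) + a_e e^(-t/tau_e) + a_late.
    """

    pr: float = 0.35
    facil_amp: float = 1.5
    tau_f: float = 120.0
    tau_rec: float = 150.0
    s0: float = 1.5
    i_half: float = 30.0
    hill: float = 1.8
    fv_gain: float = 0.5
    fv_i_half: float = 25.0
    fv_hill: float = 2.0
    noise_sd: float = 0.0
    a_stp: float = 0.8
    tau_stp: float = 10.0
    a_e: float = 0.3
    tau_e: float = 60.0
    a_late: float = 0.25
    fepsp_tau_ms: float = 4.0
    fepsp_onset_ms: float = 3.0
    fv_onset_ms: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.pr < 1):
            raise ValueError("release probability must lie in (0, 1)")
        for name in ("tau_f", "tau_rec", "tau_stp", "tau_e", "fepsp_tau_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def io_gain(self, stimulus_uA: float) -> float:
        """Saturating input–output gain in (0, 1) for the fEPSP pathway."""
        i = abs(stimulus_uA)
        return i**self.hill / (i**self.hill + self.i_half**self.hill)

    def fv_amplitude_of(self, stimulus_uA: float) -> float:
        i = abs(stimulus_uA)
        return self.fv_gain * i**self.fv_hill / (
            i**self.fv_hill + self.fv_i_half**self.fv_hill
        )

    def potentiation(self, t_min: float | np.ndarray | None) -> float | np.ndarray:
        """Normalized potentiation P(t); 1 at baseline (``t_min`` None/<0)."""
        if t_min is None:
            return 1.0
        t = np.asarray(t_min, dtype=float)
        p = np.where(
            t < 0,
            1.0,
            1.0
            + self.a_stp * np.exp(-t / self.tau_stp)
            + self.a_e * np.exp(-t / self.tau_e)
            + self.a_late,
        )
        return float(p) if np.isscalar(t_min) or t.ndim == 0 else p

    def paired_pulse_model(self, ipi_ms: float | np.ndarray) -> float | np.ndarray:
        """Closed-form PPR: facilitation minus depletion, recovering to 1."""
        ipi = np.asarray(ipi_ms, dtype=float)
        if np.any(ipi <= 0):
            raise ValueError("interpulse interval must be positive")
        r = (
            1.0
            + (1.0 - self.pr) * self.facil_amp * np.exp(-ipi / self.tau_f)
            - self.pr * np.exp(-ipi / self.tau_rec)
        )
        return float(r) if np.isscalar(ipi_ms) else r


def _alpha_fn(s: np.ndarray, tau: float) -> np.ndarray:
    """Unit alpha function: 0 for s<0, peak 1 at s=tau."""
    out = np.zeros_like(s)
    pos = s > 0
    out[pos] = (s[pos] / tau) * np.exp(1.0 - s[pos] / tau)
    return out


def _unit_fepsp_measured_slope(
    tau: float, dt_ms: float, frac_lo: float = 0.2, frac_hi: float = 0.8
) -> float:
    """Magnitude of the least-squares slope of the unit (peak-1) alpha
    function over its 20–80% rising window.

    Sampled on the synthesis grid; used to calibrate the waveform amplitude
    so that the *programmed* slope is exactly what the standard 20–80%
    fitting policy measures on a noiseless sweep.
    """
    s = np.arange(0.0, 5.0 * tau, dt_ms)
    f = _alpha_fn(s, tau)
    i_peak = int(np.argmax(f))
    i_lo = int(np.argmax(f[: i_peak + 1] >= frac_lo))
    i_hi = int(np.argmax(f[: i_peak + 1] >= frac_hi))
    coeff = np.polyfit(s[i_lo : i_hi + 1], f[i_lo : i_hi + 1], 1)
    return float(coeff[0])


def synth_trace(
    programmed_slope: float,
    fv_amp: float,
    params: SynapseParams,
    rng: np.random.Generator | None = None,
    duration_ms: float = 50.0,
    stim_onset_ms: float = 5.0,
    sample_khz: float = 20.0,
    meta: dict | None = None,
) -> SweepTrace:
    """Compose a sweep: fiber volley + negative alpha-function fEPSP + noise.

    ``programmed_slope`` (mV/ms, magnitude) is the slope the standard 20–80%
    fitting policy recovers on the noiseless trace; the fEPSP amplitude is
    back-calculated from the alpha-function shape factor.
    """
    dt = 1.0 / sample_khz
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    s = t - stim_onset_ms
    v = np.zeros(n)

    # biphasic fiber volley in the 1-4 ms window
    fv_shape = _alpha_fn(s - params.fv_onset_ms, 0.25) - 1.2 * _alpha_fn(
        s - params.fv_onset_ms - 0.5, 0.35
    )
    v += fv_amp * 0.6 * fv_shape

    shape_slope = _unit_fepsp_measured_slope(params.fepsp_tau_ms, dt)
    amplitude = programmed_slope / shape_slope  # peak depth in mV
    v -= amplitude * _alpha_fn(s - params.fepsp_onset_ms, params.fepsp_tau_ms)

    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = v + rng.normal(0.0, params.noise_sd, size=n)
    return SweepTrace(
        voltage_mV=v, dt_ms=dt, stim_onsets_ms=(stim_onset_ms,), meta=meta or {}
    )


def simulate_fepsp_sweep(
    stimulus_uA: float,
    t_since_induction_min: float | None,
    params: SynapseParams | None = None,
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> SweepTrace:
    """One sweep at the given stimulus, at baseline (``None``) or ``t``
    minutes after induction (slope scaled by the potentiation profile)."""
    params = params or SynapseParams()
    if not (0 < abs(stimulus_uA) <= 100):
        raise ValueError(f"stimulus {stimulus_uA} uA outside the protocol range")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    slope = params.s0 * params.io_gain(stimulus_uA) * float(
        params.potentiation(t_since_induction_min)
    )
    m = {"stimulus_uA": float(stimulus_uA), "protocol": "baseline"}
    if t_since_induction_min is not None:
        m["t_min"] = float(t_since_induction_min)
    if meta:
        m.update(meta)
    return synth_trace(slope, params.fv_amplitude_of(stimulus_uA), params, rng, meta=m)


def simulate_io_series(
    params: SynapseParams | None = None,
    seed: int = 0,
    stimuli_uA: Sequence[float] = IO_STIMULI_UA,
    slice_id: str = "slice1",
) -> list[SweepTrace]:
    """I/O protocol: one sweep per stimulus from -5 to -80 uA."""
    params = params or SynapseParams()
    root = np.random.SeedSequence(seed)
    sweeps = []
    for stim, child in zip(stimuli_uA, root.spawn(len(stimuli_uA))):
        sweeps.append(
            simulate_fepsp_sweep(
                stim,
                None,
                params,
                np.random.default_rng(child),
                meta={"protocol": "IO", "slice_id": slice_id},
            )
        )
    return sweeps


def simulate_paired_pulse(
    ipi_ms: float,
    params: SynapseParams | None = None,
    seed: int = 0,
    stimulus_uA: float = -20.0,
    slice_id: str = "slice1",
) -> tuple[SweepTrace, SweepTrace]:
    """Two sweeps separated by ``ipi_ms``; the second response's slope is the
    first's times the closed-form depletion–facilitation ratio."""
    params = params or SynapseParams()
    if ipi_ms <= 0:
        raise ValueError("interpulse interval must be positive")
    root = np.random.SeedSequence(seed)
    r1, r2 = (np.random.default_rng(c) for c in root.spawn(2))
    s1 = params.s0 * params.io_gain(stimulus_uA)
    ratio = float(params.paired_pulse_model(ipi_ms))
    fv = params.fv_amplitude_of(stimulus_uA)
    meta = {
        "protocol": "paired_pulse",
        "slice_id": slice_id,
        "stimulus_uA": float(stimulus_uA),
        "ipi_ms": float(ipi_ms),
    }
    first = synth_trace(s1, fv, params, r1, meta={**meta, "pulse": 1})
    second = synth_trace(s1 * ratio, fv, params, r2, meta={**meta, "pulse": 2})
    return first, second


def simulate_ltp_experiment(
    params: SynapseParams | None = None,
    seed: int = 0,
    stimulus_uA: float = -20.0,
    baseline_min: float = 15.0,
    post_min: float = 120.0,
    cadence_min: float = 1.0,
    slice_id: str = "slice1",
) -> list[SweepTrace]:
    """Theta-burst LTP time course: 15 min of baseline sweeps, induction at
    t=0, then sweeps out to 120 min with slopes following P(t)."""
    params = params or SynapseParams()
    t_baseline = np.arange(-baseline_min, 0.0, cadence_min)
    t_post = np.arange(cadence_min, post_min + 1e-9, cadence_min)
    times = np.concatenate([t_baseline, t_post])
    root = np.random.SeedSequence(seed)
    sweeps = []
    for t, child in zip(times, root.spawn(len(times))):
        sweeps.append(
            simulate_fepsp_sweep(
                stimulus_uA,
                None if t < 0 else float(t),
                params,
                np.random.default_rng(child),
                meta={"protocol": "LTP", "slice_id": slice_id, "t_min": float(t)},
            )
        )
    return sweeps


def sweep_manifest(sweeps: Sequence[SweepTrace]) -> pd.DataFrame:
    """Manifest table (`sweep_id, slice_id, animal_id, stimulus_uA, protocol,
    t_min, ipi_ms`) describing a collection of sweeps."""
    rows = []
    for i, tr in enumerate(sweeps):
        m = tr.meta
        rows.append(
            {
                "sweep_id": f"sweep_{i:05d}",
                "slice_id": m.get("slice_id", ""),
                "animal_id": m.get("animal_id", ""),
                "stimulus_uA": m.get("stimulus_uA", np.nan),
                "protocol": m.get("protocol", ""),
                "t_min": m.get("t_min", np.nan),
                "ipi_ms": m.get("ipi_ms", np.nan),
            }
        )
    return pd.DataFrame(rows)
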