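"""Field-potential sweep measurement and LTP phase analysis.

Operates on stimulus-locked extracellular sweeps from Schaffer-collateral
CA1 recordings (real or synthetic, same format): extracts fiber-volley (FV)
amplitude and fEPSP initial slope, assembles input–output (I/O) curves,
selects the threshold stimulus (the intensity evoking 30–40% of the maximal
response), computes paired-pulse ratios, builds the theta-burst stimulation
(TBS) timetable, and summarizes baseline-normalized LTP time courses into
the three conventional phases:

* STP   — short-term potentiation, minutes 11–20 post-induction
* E-LTP — early LTP, minutes 51–60
* L-LTP — late LTP, minutes 111–120

Sign convention: fEPSP slopes are stored signed (negative-going deflection,
negative slope); magnitudes are used for ratios, I/O curves and
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: acquisition default: sweeps digitized at 20 kHz
DEFAULT_SAMPLE_KHZ = 20.0

#: LTP phase windows in minutes post-induction: (label, lo, hi), inclusive
PHASE_WINDOWS = (("stp", 11.0, 20.0), ("e_ltp", 51.0, 60.0), ("l_ltp", 111.0, 120.0))

#: paired-pulse interpulse intervals used in the protocol (ms)
PPR_INTERVALS_MS = (20.0, 40.0, 80.0, 200.0, 500.0)

#: I/O protocol: stimulation strength from -5 to -80 uA in steps of 5 uA
IO_STIMULI_UA = tuple(-5.0 * k for k in range(1, 17))


class MeasurementError(ValueError):
    """Raised when a sweep carries no measurable deflection."""


@dataclass
class SweepTrace:
    """One uniformly sampled voltage sweep with stimulus timing.

    ``voltage_mV`` is sampled every ``dt_ms`` milliseconds starting at t=0;
    ``stim_onsets_ms`` are the stimulus times within the sweep. ``meta``
    carries identifiers (slice_id, animal_id, stimulus_uA, protocol, t_min,
    ipi_ms ...).
    """

    voltage_mV: np.ndarray
    dt_ms: float = 1.0 / DEFAULT_SAMPLE_KHZ
    stim_onsets_ms: tuple[float, ...] = (5.0,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("sampling interval must be positive")
        dur = self.duration_ms
        for onset in self.stim_onsets_ms:
            if not (0 <= onset < dur):
                raise ValueError(f"stimulus onset {onset} ms outside trace (0-{dur} ms)")

    @property
    def duration_ms(self) -> float:
        return len(self.voltage_mV) * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.voltage_mV)) * self.dt_ms


@dataclass(frozen=True)
class SlopePolicy:
    """How the fEPSP initial slope is measured.

    A 1-ms post-stimulus artifact blank is applied; the fEPSP peak is sought
    from ``search_start_ms`` after the stimulus (past the fiber volley); the
    slope is a linear least-squares fit over the initial falling phase where
    the deflection lies between 20% and 80% of the peak deflection.
    """

    blank_ms: float = 1.0
    search_start_ms: float = 4.0
    search_end_ms: float = 30.0
    frac_lo: float = 0.20
    frac_hi: float = 0.80
    min_amplitude_mV: float = 0.02


DEFAULT_SLOPE_POLICY = SlopePolicy()


@dataclass(frozen=True)
class SweepMeasures:
    """Measured quantities of one sweep (per stimulus)."""

    slope_mV_per_ms: float  # signed; negative-going fEPSP
    amplitude_mV: float  # fEPSP peak deflection magnitude
    fv_amplitude_mV: float  # fiber-volley peak-to-trough
    fit_window_ms: tuple[float, float]


def _baseline(trace: SweepTrace, onset: float) -> float:
    pre = trace.voltage_mV[trace.time_ms < max(onset - 1.0, 0.0)]
    return float(pre.mean()) if len(pre) else 0.0


def fepsp_slope(
    trace: SweepTrace,
    policy: SlopePolicy = DEFAULT_SLOPE_POLICY,
    onset_index: int = 0,
) -> float:
    """fEPSP initial slope (mV/ms, signed) of one stimulus response.

    Raises :class:`MeasurementError` when no deflection exceeds the noise
    floor (``policy.min_amplitude_mV``).
    """
    onset = trace.stim_onsets_ms[onset_index]
    t = trace.time_ms
    v = trace.voltage_mV
    base = _baseline(trace, onset)

    end = onset + policy.search_end_ms
    if onset_index + 1 < len(trace.stim_onsets_ms):
        end = min(end, trace.stim_onsets_ms[onset_index + 1])
    window = (t >= onset + policy.search_start_ms) & (t <= end)
    if not window.any():
        raise MeasurementError("empty fEPSP search window")
    depth = base - v  # positive for negative-going deflection
    # peak and crossing detection run on a lightly smoothed copy (~0.25 ms)
    # so single noise samples cannot hijack the fit window; the line is
    # fitted to the raw samples
    from scipy.ndimage import uniform_filter1d

    k = max(1, int(round(0.25 / trace.dt_ms)))
    dsm = uniform_filter1d(depth, size=k)
    # the peak estimate uses ~1 ms smoothing: taking the max over hundreds
    # of noisy samples would systematically overestimate the peak depth and
    # shift both threshold crossings up the limb
    kp = max(k, int(round(1.0 / trace.dt_ms)))
    dpk = uniform_filter1d(depth, size=kp)
    i_peak = np.flatnonzero(window)[np.argmax(dpk[window])]
    peak_depth = dpk[i_peak]
    if peak_depth < policy.min_amplitude_mV:
        raise MeasurementError(
            f"no deflection beyond noise floor ({peak_depth:.4f} mV)"
        )

    # initial falling phase: the last 20% and 80% crossings of the smoothed
    # deflection before the peak (so the fiber-volley bump cannot be
    # mistaken for the fEPSP foot)
    lo, hi = policy.frac_lo * peak_depth, policy.frac_hi * peak_depth
    i_start = np.searchsorted(t, onset + policy.blank_ms)
    seg = dsm[i_start : i_peak + 1]
    if len(seg) < 2:
        raise MeasurementError("could not locate the fEPSP rising phase")
    def crossing(thr: float) -> int:
        above = np.flatnonzero(seg >= thr)
        below = np.flatnonzero(seg < thr)
        if len(above) == 0:
            return len(seg) - 1
        if len(below) == 0:
            return 0
        # noise biases the first-above index early and the last-below index
        # late by symmetric amounts; their midpoint is unbiased
        return int(round((above[0] + below[-1] + 1) / 2))

    i_lo = i_start + crossing(lo)
    i_hi = i_start + crossing(hi)
    if i_hi <= i_lo + 1:  # degenerate: too few samples, widen to the peak
        i_hi = max(i_hi, min(i_lo + 2, i_peak))
    tt, vv = t[i_lo : i_hi + 1], v[i_lo : i_hi + 1]
    slope = float(np.polyfit(tt, vv, 1)[0])
    return slope


def fv_amplitude(
    trace: SweepTrace,
    window_ms: tuple[float, float] = (1.0, 4.0),
    onset_index: int = 0,
) -> float:
    """Fiber-volley amplitude: peak-to-trough within 1–4 ms post stimulus."""
    onset = trace.stim_onsets_ms[onset_index]
    t = trace.time_ms
    mask = (t >= onset + window_ms[0]) & (t <= onset + window_ms[1])
    if not mask.any():
        raise MeasurementError("empty fiber-volley window")
    v = trace.voltage_mV[mask]
    return float(v.max() - v.min())


def fepsp_amplitude(
    trace: SweepTrace,
    policy: SlopePolicy = DEFAULT_SLOPE_POLICY,
    onset_index: int = 0,
) -> float:
    """fEPSP peak deflection magnitude (mV) relative to pre-stimulus baseline."""
    onset = trace.stim_onsets_ms[onset_index]
    t = trace.time_ms
    base = _baseline(trace, onset)
    end = onset + policy.search_end_ms
    if onset_index + 1 < len(trace.stim_onsets_ms):
        end = min(end, trace.stim_onsets_ms[onset_index + 1])
    mask = (t >= onset + policy.search_start_ms) & (t <= end)
    depth = base - trace.voltage_mV[mask]
    return float(depth.max())


def measure_sweep(
    trace: SweepTrace,
    policy: SlopePolicy = DEFAULT_SLOPE_POLICY,
    onset_index: int = 0,
) -> SweepMeasures:
    """All standard measures of one stimulus response."""
    onset = trace.stim_onsets_ms[onset_index]
    slope = fepsp_slope(trace, policy, onset_index)
    return SweepMeasures(
        slope_mV_per_ms=slope,
        amplitude_mV=fepsp_amplitude(trace, policy, onset_index),
        fv_amplitude_mV=fv_amplitude(trace, onset_index=onset_index),
        fit_window_ms=(onset + policy.blank_ms, onset + policy.search_end_ms),
    )


def io_curve(
    sweeps: Sequence[SweepTrace],
    policy: SlopePolicy = DEFAULT_SLOPE_POLICY,
) -> pd.DataFrame:
    """Input–output table: one row per stimulus intensity.

    Columns: ``stimulus_uA`` (as delivered, negative), ``slope_mV_per_ms``
    (mean magnitude), ``amplitude_mV``, ``fv_amplitude_mV``; rows ordered by
    increasing stimulus magnitude. Sweeps sharing a stimulus are averaged.
    Supports slope-vs-stimulus, FV-vs-stimulus, and slope-vs-FV views.
    """
    if len(sweeps) == 0:
        raise ValueError("io_curve needs at least one sweep")
    rows = []
    for tr in sweeps:
        m = measure_sweep(tr, policy)
        rows.append(
            {
                "stimulus_uA": float(tr.meta.get("stimulus_uA", np.nan)),
                "slope_mV_per_ms": abs(m.slope_mV_per_ms),
                "amplitude_mV": m.amplitude_mV,
                "fv_amplitude_mV": m.fv_amplitude_mV,
            }
        )
    df = pd.DataFrame(rows)
    out = df.groupby("stimulus_uA", as_index=False).mean()
    out["abs_stimulus_uA"] = out["stimulus_uA"].abs()
    return out.sort_values("abs_stimulus_uA").reset_index(drop=True)


def threshold_stimulus(
    io: pd.DataFrame,
    band: tuple[float, float] = (0.30, 0.40),
    response: str = "amplitude_mV",
) -> float:
    """Stimulus evoking a response inside ``band`` × maximal response.

    Returns the smallest-magnitude stimulus whose fractional response lies
    inside the band; when no grid point falls inside, the nearest point
    below the upper edge is returned with a warning. The response column is
    the fEPSP amplitude by default (slope selectable).
    """
    resp = io[response].to_numpy(dtype=float)
    if np.all(resp == 0):
        raise MeasurementError("all responses are zero; no threshold definable")
    frac = resp / resp.max()
    order = np.argsort(io["stimulus_uA"].abs().to_numpy())
    for i in order:
        if band[0] <= frac[i] <= band[1]:
            return float(io["stimulus_uA"].iloc[i])
    below = [i for i in order if frac[i] < band[1]]
    if not below:
        warnings.warn(
            "no stimulus below the band's upper edge; returning the smallest "
            "stimulus",
            stacklevel=2,
        )
        return float(io["stimulus_uA"].iloc[order[0]])
    i_best = max(below, key=lambda i: frac[i])
    warnings.warn(
        f"no stimulus inside the {band[0]:.0%}-{band[1]:.0%} band; returning "
        f"the nearest grid point below ({frac[i_best]:.0%} of max)",
        stacklevel=2,
    )
    return float(io["stimulus_uA"].iloc[i_best])


def paired_pulse_ratio(first: float | SweepMeasures, second: float | SweepMeasures) -> float:
    """PPR = slope of second response / slope of first response.

    Dimensionless (report ×100 when styled as % facilitation). Signs cancel
    for same-polarity responses; a zero first slope is an error.
    """
    s1 = first.slope_mV_per_ms if isinstance(first, SweepMeasures) else float(first)
    s2 = second.slope_mV_per_ms if isinstance(second, SweepMeasures) else float(second)
    if s1 == 0:
        raise ValueError("first-response slope is zero; PPR undefined")
    return s2 / s1


@dataclass(frozen=True)
class StimProtocol:
    """Ordered pulse timetable with per-pulse intensity."""

    name: str
    pulse_times_ms: tuple[float, ...]
    intensities_uA: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pulse_times_ms) != len(self.intensities_uA):
            raise ValueError("one intensity per pulse required")
        diffs = np.diff(self.pulse_times_ms)
        if len(diffs) and np.any(diffs <= 0):
            raise ValueError("pulse times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pulse_time_ms": self.pulse_times_ms, "intensity_uA": self.intensities_uA}
        )


def tbs_protocol(
    threshold_stimulus_uA: float,
    n_trains: int = 4,
    bursts_per_train: int = 10,
    pulses_per_burst: int = 4,
    intra_burst_ms: float = 10.0,
    inter_burst_ms: float = 200.0,
    inter_train_ms: float = 10_000.0,
) -> StimProtocol:
    """Theta-burst induction timetable at the threshold stimulus.

    Default structure: bursts of 4 pulses at 100 Hz (10-ms intervals), 10
    bursts per train at 5 Hz (200-ms burst intervals), 4 trains at 10-s
    intervals — 40 bursts, 160 pulses in total.
    """
    times = []
    for train in range(n_trains):
        t_train = train * inter_train_ms
        for burst in range(bursts_per_train):
            t_burst = t_train + burst * inter_burst_ms
            for pulse in range(pulses_per_burst):
                times.append(t_burst + pulse * intra_burst_ms)
    return StimProtocol(
        name="TBS",
        pulse_times_ms=tuple(times),
        intensities_uA=tuple([float(threshold_stimulus_uA)] * len(times)),
    )


@dataclass(frozen=True)
class LtpPhaseSummary:
    """Baseline-normalized slope series and its phase means for one slice.

    ``t_min`` is minutes relative to the end of induction (baseline sweeps
    negative); ``norm_pct`` is slope magnitude as percent of the baseline
    mean. Phase means are ``nan`` when the recording does not cover the
    window.
    """

    t_min: np.ndarray
    norm_pct: np.ndarray
    stp: float
    e_ltp: float
    l_ltp: float
    baseline_slope: float
    slice_id: str | None = None

    def phases(self) -> dict[str, float]:
        return {"stp": self.stp, "e_ltp": self.e_ltp, "l_ltp": self.l_ltp}


def normalize_and_phase(
    t_min: Sequence[float],
    slopes: Sequence[float],
    phase_windows: Sequence[tuple[str, float, float]] = PHASE_WINDOWS,
    baseline_minutes: float = 15.0,
    slice_id: str | None = None,
    per_minute: bool = True,
) -> LtpPhaseSummary:
    """Normalize a slope time series to its pre-induction baseline.

    Baseline sweeps are those with ``t < 0`` within ``baseline_minutes`` of
    induction; each slope magnitude is divided by the baseline mean (×100).
    The series is averaged per whole minute before phase means when
    ``per_minute`` is set. Phase windows are inclusive in minutes
    post-induction.
    """
    t = np.asarray(t_min, dtype=float)
    s = np.abs(np.asarray(slopes, dtype=float))
    if len(t) != len(s):
        raise ValueError("timestamps and slopes must align")
    base_mask = (t < 0) & (t >= -baseline_minutes)
    if not base_mask.any():
        raise ValueError("no baseline sweeps in the pre-induction window")
    baseline = float(s[base_mask].mean())
    if baseline == 0:
        raise MeasurementError("zero baseline slope; cannot normalize")
    norm = s / baseline * 100.0

    if per_minute:
        minutes = np.floor(t).astype(int)
        frame = pd.DataFrame({"minute": minutes, "norm": norm})
        binned = frame.groupby("minute", as_index=False)["norm"].mean()
        t_out = binned["minute"].to_numpy(dtype=float)
        n_out = binned["norm"].to_numpy()
    else:
        t_out, n_out = t, norm

    phase_means = {}
    for name, lo, hi in phase_windows:
        mask = (t_out >= lo) & (t_out <= hi)
        phase_means[name] = float(n_out[mask].mean()) if mask.any() else float("nan")
    return LtpPhaseSummary(
        t_min=t_out,
        norm_pct=n_out,
        stp=phase_means.get("stp", float("nan")),
        e_ltp=phase_means.get("e_ltp", float("nan")),
        l_ltp=phase_means.get("l_ltp", float("nan")),
        baseline_slope=baseline,
        slice_id=slice_id,
    )


def ltp_phase_table(summaries: Iterable[LtpPhaseSummary]) -> pd.DataFrame:
    """One row of phase means per slice (animal-level aggregation = mean of
    a subject's slices, done downstream)."""
    rows = [
        {"slice_id": s.slice_id, "stp": s.stp, "e_ltp": s.e_ltp, "l_ltp": s.l_ltp}
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["slice_id", "stp", "e_ltp", "l_ltp"])
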