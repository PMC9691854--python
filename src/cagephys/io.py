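"""File formats and configuration.

Event logs are CSV with header
``timestamp,animal_id,cage_id,corner,visit_end,nosepokes,licks`` and
ISO-8601 timestamps (timezone-naive wall-clock; drinking sessions are
defined on the local 8-11 pm window). Sweeps are two-column TSV
(``time_ms, voltage_mV``) described by a manifest CSV. Output files carry a
comment header recording the seed and a configuration hash so every
artifact is traceable to its run.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ephys import SweepTrace

log = logging.getLogger("cagephys")

EVENT_COLUMNS = [
    "timestamp",
    "animal_id",
    "cage_id",
    "corner",
    "visit_end",
    "nosepokes",
    "licks",
]


class EventLogError(ValueError):
    """Malformed event-log content, reported with line numbers."""


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(seed: int | None, cfg_hash: str | None) -> str:
    parts = []
    if seed is not None:
        parts.append(f"# seed={seed}")
    if cfg_hash is not None:
        parts.append(f"# config_hash={cfg_hash}")
    return ("\n".join(parts) + "\n") if parts else ""


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    sep: str = ",",
) -> Path:
    """Write a table with the standard comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        df.to_csv(fh, index=False, sep=sep)
    return path


def write_event_log(
    events: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> Path:
    """Write a canonical event-log CSV (ISO-8601 timestamps, sorted)."""
    df = events.copy()
    for col in ("timestamp", "visit_end"):
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df = df[EVENT_COLUMNS]
    return write_table(df, path, seed=seed, cfg_hash=cfg_hash)


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read and validate an event-log CSV.

    Rows must carry the documented columns, ISO timestamps and corners in
    1..4; malformed rows raise :class:`EventLogError` naming the offending
    line. Unsorted files are sorted by timestamp with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    unknown = [c for c in df.columns if c not in EVENT_COLUMNS]
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise EventLogError(
            f"{path}: unknown columns {unknown}, missing columns {missing}"
        )
    # data line numbers: header is line 1 (+ any leading comment lines)
    with open(path) as fh:
        n_comments = 0
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    offset = n_comments + 2
    corners = pd.to_numeric(df["corner"], errors="coerce")
    bad = df.index[~corners.isin([1, 2, 3, 4])]
    if len(bad):
        raise EventLogError(
            f"{path}: corner outside 1..4 on line {bad[0] + offset}"
        )
    df["corner"] = corners.astype(int)
    for col in ("timestamp", "visit_end"):
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            raise EventLogError(
                f"{path}: non-ISO timestamp in {col!r} on line {bad[0] + offset}"
            )
        df[col] = parsed
    for col in ("nosepokes", "licks"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if not df["timestamp"].is_monotonic_increasing:
        log.warning("event log %s is unsorted; sorting by timestamp", path)
        df = df.sort_values(["timestamp", "animal_id"], kind="mergesort")
    n = len(df)
    log.info("read_event_log stage=read n_in=%d n_out=%d n_excluded=0", n, n)
    return df.reset_index(drop=True)


def write_sweep(trace: SweepTrace, path: str | Path) -> Path:
    """Write one sweep as two-column TSV (``time_ms, voltage_mV``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_ms": trace.time_ms, "voltage_mV": trace.voltage_mV})
    df.to_csv(path, index=False, sep="\t", float_format="%.6f")
    return path


def read_sweep(
    path: str | Path,
    stim_onsets_ms: Sequence[float] = (5.0,),
    meta: Mapping | None = None,
) -> SweepTrace:
    """Read a two-column sweep TSV back into a :class:`SweepTrace`."""
    df = pd.read_csv(path, sep="\t")
    t = df["time_ms"].to_numpy(dtype=float)
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.05
    return SweepTrace(
        voltage_mV=df["voltage_mV"].to_numpy(dtype=float),
        dt_ms=dt,
        stim_onsets_ms=tuple(stim_onsets_ms),
        meta=dict(meta or {}),
    )


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "timeline": {},  # empty -> published default timeline
    "cohort": {},  # empty -> published group sizes
    "agent": {},
    "synapse": {},
    "scoring": {"denominator": "whole_session", "exclusion_threshold": 25},
    "stats": {"ss_type": 3, "gg": "always"},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration, filling defaults for absent sections."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg
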