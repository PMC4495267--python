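"""Output writers and checkpoint/restore.

Counts and snapshots go to CSV (floats at 9 significant digits, config hash
and seed embedded as a comment header so every output is reproducible from
the file alone).  A checkpoint is a single JSON archive of the full
simulation state — cells, traces, counters, event log and the RNG state —
and a resumed run reproduces an uninterrupted one bit for bit.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

from .cells import Cell
from .chemokine import TraceStore
from .config import SimulationConfig
from .engine import SimulationState
from .immune import VesselEventLog


def _header(config: Optional[SimulationConfig]) -> str:
    if config is None:
        return ""
    return f"# config_hash={config.hash()} seed={config.seed}\n"


def write_counts(counts: pd.DataFrame, path,
                 config: Optional[SimulationConfig] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        counts.to_csv(fh, index=False, float_format="%.9g")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_snapshot(state: SimulationState, path,
                   config: Optional[SimulationConfig] = None) -> None:
    dim = state.cells[0].x.shape[0] if state.cells else 2
    cols = ["t", "id", "phenotype", "x", "y"] + (["z"] if dim == 3 else []) \
        + ["R", "phase", "phase_age", "F", "birth_time"]
    rows = []
    for c in state.cells:
        rec = c.to_record()
        rec["t"] = state.t
        rows.append({k: rec.get(k) for k in cols})
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False, float_format="%.9g")


def read_snapshot(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_events(events: VesselEventLog, path,
                 config: Optional[SimulationConfig] = None) -> None:
    df = pd.DataFrame(events.to_records(),
                      columns=["time", "event", "cell_id", "vessel_index"])
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False, float_format="%.9g")


def save_checkpoint(state: SimulationState, path) -> None:
    payload = {
        "t": state.t,
        "next_id": state.next_id,
        "counters": state.counters,
        "cells": [c.to_record() for c in state.cells],
        "traces": state.traces.to_records(),
        "events": state.events.to_records(),
        "rng_state": state.rng.bit_generator.state,
        "field_cache": None if state.field_cache is None else {
            "t": float(state.field_cache["t"]),
            "c_b": [float(v) for v in state.field_cache["c_b"]],
        },
    }

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, default=default)


def load_checkpoint(path) -> SimulationState:
    from .immune import VesselEvent

    with open(path) as fh:
        payload = json.load(fh)
    rng = np.random.default_rng()
    rng.bit_generator.state = payload["rng_state"]
    state = SimulationState(
        t=float(payload["t"]),
        cells=[Cell.from_record(r) for r in payload["cells"]],
        traces=TraceStore.from_records(payload["traces"]),
        rng=rng,
        next_id=int(payload["next_id"]),
        counters={k: int(v) for k, v in payload["counters"].items()},
    )
    log = VesselEventLog()
    for r in payload["events"]:
        log.entries.append(VesselEvent(float(r["time"]), r["event"],
                                       int(r["cell_id"]),
                                       int(r["vessel_index"])))
    state.events = log
    fc = payload.get("field_cache")
    if fc is not None:
        state.field_cache = {"t": float(fc["t"]),
                             "c_b": np.asarray(fc["c_b"], dtype=float)}
    return state
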