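"""Time stepping: subprocess ordering, adaptive step control, stop criteria.

One step executes, in fixed order on the pre-move configuration:

1. refresh chemokine source traces (cadence ``dt_quad``),
2. mechanics: sensed energies, drift directions, contact pressures,
3. chemokine concentration at vessel points and gradient at T-cells,
4. position update — RK4 on the deterministic drift (chemotactic gradient
   and noise frozen across substeps) plus the Maruyama noise term,
5. cycle events: growth, S-exit, division + mutation, death,
6. immune events: extravasation sampling per vessel, engulfment,
7. intravasation checks,
8. boundary projection.

The time step adapts so no cell displaces more than a quarter of its
diameter; when a drift would demand a step below ``dt_min``, the realized
displacement is clamped to exactly the cap instead (keeping the invariant
while keeping runs finite).  Single-threaded execution order is part of the
determinism contract: same seed, same config, bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .cells import Cell, Phase, Phenotype
from .chemokine import TraceStore, evaluate_field
from .config import SimulationConfig, validate
from .cycle import phase_step, maybe_mutate
from .immune import (VesselEventLog, engulf, extravasation_prob,
                     intravasation_check, spawn_tcell, tcell_drift)
from .mechanics import compute_signals_fast

_Z_EPS = 1e-12
_CAP_TOL = 1e-9


@dataclass
class SimulationState:
    t: float
    cells: List[Cell]
    traces: TraceStore
    rng: np.random.Generator
    next_id: int
    counters: Dict[str, int] = dc_field(default_factory=lambda: {
        "divisions": 0, "mutations": 0, "deaths": 0,
        "intravasations": 0, "seedings": 0, "tcell_entries": 0,
    })
    events: VesselEventLog = dc_field(default_factory=VesselEventLog)
    # vessel-point concentrations are refreshed at the (coarser) quadrature
    # cadence, not every motion step
    field_cache: Optional[Dict[str, object]] = None

    def phenotype_counts(self) -> Dict[str, int]:
        out = {"epithelial": 0, "tumor": 0, "tcell": 0}
        for c in self.cells:
            out[c.phenotype.value] += 1
        return out

    def tumor_fraction(self) -> float:
        counts = self.phenotype_counts()
        total = sum(counts.values())
        return counts["tumor"] / total if total else 0.0


def compute_dt(drift_speeds: np.ndarray, radii: np.ndarray, dt_max: float,
               sigma: float = 0.0, dt_min: float = 0.0) -> float:
    """Quarter-diameter step rule: dt such that drift plus a 3-sigma noise
    allowance displaces no cell more than R/2, bounded to [dt_min, dt_max]."""
    if drift_speeds.size == 0:
        return dt_max
    noise_speed = 3.0 * sigma / np.sqrt(dt_max) if sigma > 0 else 0.0
    speeds = np.abs(drift_speeds) + noise_speed
    with np.errstate(divide="ignore"):
        limits = np.where(speeds > 0, 0.5 * radii / np.maximum(speeds, 1e-300),
                          np.inf)
    dt = min(dt_max, float(limits.min()))
    return max(dt, dt_min)


def _drift_matrix(X, R, F, contact_only, alpha, chemo, domain, mech):
    """Deterministic drift velocities at trial positions X; the chemotactic
    term ``chemo`` (mu * grad c per cell) is frozen across RK4 substeps."""
    sig = compute_signals_fast(X, R, F, contact_only, domain, mech)
    znorm = np.linalg.norm(sig.z, axis=1)
    with np.errstate(invalid="ignore"):
        zhat = np.where(znorm[:, None] > _Z_EPS,
                        sig.z / np.maximum(znorm, 1e-300)[:, None], 0.0)
    V = (alpha * sig.M_total)[:, None] * zhat
    return V + chemo


def step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """Advance the state by one adaptive time step (in place)."""
    dom, fld, mech, imm, eng = (config.domain, config.field, config.mech,
                                config.immune, config.engine)
    dim = dom.dim
    cells = state.cells
    if not cells:
        state.t += eng.dt_max
        return state

    # (1) trace bookkeeping at quadrature cadence
    for c in cells:
        if c.phenotype is Phenotype.TUMOR and c.id in state.traces:
            tr = state.traces[c.id]
            if not tr.closed and state.t - tr.times[-1] >= fld.dt_quad - 1e-9:
                tr.record(state.t, c.x)

    n = len(cells)
    X = np.array([c.x for c in cells])
    R = np.array([c.R for c in cells])
    F = np.array([c.F for c in cells])
    contact_only = np.array([c.phase == Phase.M for c in cells])
    alpha = np.array([
        0.0 if not c.alive else
        (c.F / mech.F_hat) ** 2 * config.phenotype[c.phenotype.value].beta
        * c.R ** 3 / mech.f
        for c in cells
    ])

    # (2) mechanics on the pre-move configuration
    sig = compute_signals_fast(X, R, F, contact_only, dom, mech)

    # (3) chemokine: gradient at T-cells, concentration at vessel points
    chemo = np.zeros((n, dim))
    have_sources = len(state.traces) > 0
    tcell_idx = [i for i, c in enumerate(cells)
                 if c.phenotype is Phenotype.TCELL]
    if have_sources and tcell_idx:
        grads = evaluate_field(X[tcell_idx], state.t, state.traces, fld, dim,
                               grad=True)
        for j, i in enumerate(tcell_idx):
            chemo[i] = tcell_drift(np.zeros(dim), grads[j], alpha[i],
                                   imm.mu_factor)
    vessel_pts = dom.vessel_points()
    cache = state.field_cache
    if (cache is None or len(cache["c_b"]) != len(vessel_pts)
            or state.t - cache["t"] >= fld.dt_quad - 1e-9):
        c_b = (evaluate_field(vessel_pts, state.t, state.traces, fld, dim)
               if have_sources and len(vessel_pts) else
               np.zeros(len(vessel_pts)))
        state.field_cache = {"t": state.t, "c_b": np.asarray(c_b, float)}
    c_b = state.field_cache["c_b"]

    # (4) motion: adaptive RK4 + Maruyama
    V1 = _drift_matrix(X, R, F, contact_only, alpha, chemo, dom, mech)
    speeds = np.linalg.norm(V1, axis=1)
    dt = compute_dt(speeds, R, eng.dt_max, eng.sigma, eng.dt_min)
    while True:
        noise = (eng.sigma * np.sqrt(dt) * state.rng.standard_normal((n, dim))
                 if eng.sigma > 0 else np.zeros((n, dim)))
        k1 = V1
        k2 = _drift_matrix(X + 0.5 * dt * k1, R, F, contact_only, alpha, chemo,
                           dom, mech)
        k3 = _drift_matrix(X + 0.5 * dt * k2, R, F, contact_only, alpha, chemo,
                           dom, mech)
        k4 = _drift_matrix(X + dt * k3, R, F, contact_only, alpha, chemo,
                           dom, mech)
        disp = dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4) + noise
        mag = np.linalg.norm(disp, axis=1)
        cap = 0.5 * R
        if np.any(mag > cap + _CAP_TOL):
            if dt > eng.dt_min * (1.0 + 1e-9):
                dt = max(0.5 * dt, eng.dt_min)
                continue
            # at the floor: clamp displacements to the quarter-diameter cap
            over = mag > cap
            disp[over] *= (cap[over] / mag[over])[:, None]
        break
    X_new = X + disp
    for i, c in enumerate(cells):
        c.x = X_new[i]
    state.t += dt
    t_now = state.t

    # (5) cycle events (pressure from the pre-move configuration)
    index_of = {c.id: i for i, c in enumerate(cells)}
    daughters: List[Cell] = []
    for c in list(cells):
        params = config.phenotype[c.phenotype.value]
        p_i = float(sig.p[index_of[c.id]])
        events = phase_step(c, dt, p_i, params, mech, state.rng,
                            sigma_g=eng.sigma_g,
                            modulated=eng.pressure_modulation,
                            next_id=state.next_id)
        for ev in events:
            if ev.kind == "died":
                state.counters["deaths"] += 1
                if c.phenotype is Phenotype.TUMOR and c.id in state.traces:
                    state.traces.close(c.id, t_now, c.x)
            elif ev.kind == "divided":
                daughter = ev.daughter
                daughter.birth_time = t_now
                state.next_id += 1
                state.counters["divisions"] += 1
                if c.phenotype is Phenotype.EPITHELIAL and params.can_mutate:
                    new_pheno = maybe_mutate(daughter, imm.P_M, state.rng,
                                             config.phenotype["tumor"])
                    if new_pheno is Phenotype.TUMOR:
                        state.counters["mutations"] += 1
                if daughter.phenotype is Phenotype.TUMOR:
                    state.traces.open(daughter.id, t_now, daughter.x)
                daughters.append(daughter)
    cells.extend(daughters)

    # (6) immune events: extravasation at each vessel point, then engulfment
    for k, b in enumerate(vessel_pts):
        p_entry = extravasation_prob(float(c_b[k]), dt, imm.A, imm.B)
        if p_entry > 0 and state.rng.random() < p_entry:
            newcell = spawn_tcell(b, k, dom, imm, config.phenotype["tcell"],
                                  [c for c in cells if c.alive],
                                  state.rng, state.next_id,
                                  overlap_tol=eng.spawn_overlap_tol)
            if newcell is not None:
                newcell.birth_time = t_now
                state.next_id += 1
                cells.append(newcell)
                state.counters["tcell_entries"] += 1
                state.events.add(t_now, "tcell_entry", newcell.id, k)
    engulfed: set = set()
    for c in cells:
        if c.phenotype is Phenotype.TCELL and c.alive:
            for cid in engulf(c, cells):
                engulfed.add(cid)
    for c in cells:
        if c.id in engulfed:
            c.alive = False
            if c.id in state.traces and not state.traces[c.id].closed:
                state.traces.close(c.id, t_now, c.x)

    # (7) intravasation checks (sensed energy from the pre-move signal)
    for c in cells:
        if (c.alive and c.phenotype is Phenotype.TUMOR
                and c.id in index_of):
            M_i = float(sig.M_total[index_of[c.id]])
            hit = intravasation_check(c, M_i, dom, mech.M_b_star, imm.P_S,
                                      state.rng)
            if hit is not None:
                vidx, seeded = hit
                c.alive = False
                if c.id in state.traces and not state.traces[c.id].closed:
                    state.traces.close(c.id, t_now, c.x)
                state.counters["intravasations"] += 1
                state.events.add(t_now, "intravasation", c.id, vidx)
                if seeded:
                    state.counters["seedings"] += 1
                    state.events.add(t_now, "seeding", c.id, vidx)

    # (8) boundary projection and cleanup
    survivors = []
    for c in cells:
        if not c.alive:
            continue
        nrm = float(np.linalg.norm(c.x))
        if nrm > dom.radius:
            c.x = c.x * ((dom.radius - c.R) / nrm)
        survivors.append(c)
    state.cells = survivors
    return state


@dataclass
class RunResult:
    counts: pd.DataFrame
    events: VesselEventLog
    state: SimulationState
    meta: Dict[str, object]


def _counts_row(state: SimulationState) -> dict:
    counts = state.phenotype_counts()
    total = sum(counts.values())
    return {
        "t": state.t,
        "n_epithelial": counts["epithelial"],
        "n_tumor": counts["tumor"],
        "n_tcell": counts["tcell"],
        "tumor_fraction": counts["tumor"] / total if total else 0.0,
        "cum_intravasated": state.counters["intravasations"],
    }


def run(config: SimulationConfig,
        initial_state: Optional[SimulationState] = None) -> RunResult:
    """Run a full simulation from a validated config.

    Steps until ``t_end`` or until the tumor fraction reaches
    ``stop_fraction`` (or the tissue empties).  Returns the counts time
    series, the vessel event log, the final state and run metadata."""
    from .initial import initialize_state  # local import avoids a cycle

    validate(config)
    eng = config.engine
    if initial_state is None:
        rng = np.random.default_rng(config.seed)
        state = initialize_state(config, rng)
    else:
        state = initial_state
    rows = [_counts_row(state)]
    next_record = state.t + eng.counts_every
    stopped = "t_end"
    while state.t < eng.t_end - 1e-12:
        step(state, config)
        if state.t >= next_record - 1e-9:
            rows.append(_counts_row(state))
            while next_record <= state.t + 1e-9:
                next_record += eng.counts_every
        if state.tumor_fraction() >= eng.stop_fraction:
            stopped = "stop_fraction"
            break
        if not state.cells:
            stopped = "extinct"
            break
    rows.append(_counts_row(state))
    counts = pd.DataFrame(rows).drop_duplicates(subset="t", keep="last")
    counts = counts.reset_index(drop=True)
    meta = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "stopped": stopped,
        "final_t": state.t,
        **{f"cum_{k}": v for k, v in state.counters.items()},
    }
    return RunResult(counts=counts, events=state.events, state=state, meta=meta)
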