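"""Initial condition: a disc/ball of tissue packed with epithelial cells.

Cells of radius R0 are placed by random sequential position draws at a
target packing fraction and then relaxed by contact sweeps (each overlapping
pair moves apart, wall violations are projected inward) until the largest
pair penetration is below 1e-3 R0.  Cells start in G1 with phase ages drawn
uniformly over [0, T_G1] so divisions do not arrive in artificial waves
(``synchronized_start`` restores the in-phase start).  Optionally, every
cell within ``tumor_seed_radius`` of the centre starts as a tumor cell with
an open chemokine trace — a pre-initiated microtumor.
"""

from __future__ import annotations

import numpy as np

from .cells import Cell, Phase, Phenotype
from .chemokine import TraceStore
from .config import SimulationConfig
from .engine import SimulationState


class PackingError(RuntimeError):
    pass


def _sample_positions(n: int, dim: int, r_max: float,
                      rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n) ** (1.0 / dim)
    v = rng.standard_normal((n, dim))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return r_max * u[:, None] * v


def relax_packing(X: np.ndarray, R: np.ndarray, domain_radius: float,
                  tol: float, max_sweeps: int) -> np.ndarray:
    """Contact-relaxation sweeps: push overlapping pairs apart (half the
    overlap each, under-relaxed) and project wall violators inward."""
    n = X.shape[0]
    if n < 2:
        return X
    relax = 0.6
    for _ in range(max_sweeps):
        diff = X[None, :, :] - X[:, None, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        overlap = np.maximum(0.0, R[:, None] + R[None, :] - dist)
        pen = 0.5 * overlap.max()
        nrm = np.linalg.norm(X, axis=1)
        wall_violation = np.maximum(0.0, nrm + R - domain_radius).max()
        if pen < tol and wall_violation < tol:
            return X
        with np.errstate(invalid="ignore"):
            unit = diff / np.maximum(dist, 1e-300)[:, :, None]
        X = X - relax * 0.5 * np.einsum("ij,ijk->ik", overlap, unit)
        nrm = np.linalg.norm(X, axis=1)
        outside = nrm + R > domain_radius
        if np.any(outside):
            scale = (domain_radius - R[outside]) / np.maximum(nrm[outside], 1e-300)
            X[outside] *= scale[:, None]
    raise PackingError(
        "contact relaxation did not converge; lower engine.packing_fraction"
    )


def initialize_state(config: SimulationConfig,
                     rng: np.random.Generator) -> SimulationState:
    dom, eng = config.domain, config.engine
    dim = dom.dim
    epi = config.phenotype["epithelial"]
    tum = config.phenotype["tumor"]
    R0 = epi.R0
    n_cells = int(eng.packing(dim) * (dom.radius / R0) ** dim)
    X = _sample_positions(n_cells, dim, dom.radius - R0, rng)
    R = np.full(n_cells, R0)
    X = relax_packing(X, R, dom.radius, tol=1e-3 * R0,
                      max_sweeps=eng.max_pack_sweeps)

    traces = TraceStore()
    cells = []
    for i in range(n_cells):
        is_tumor = (eng.tumor_seed_radius > 0
                    and np.linalg.norm(X[i]) < eng.tumor_seed_radius)
        params = tum if is_tumor else epi
        age = 0.0
        if not eng.synchronized_start and params.T_G1 > 0:
            age = float(rng.uniform(0.0, params.T_G1))
        cell = Cell(
            id=i,
            phenotype=Phenotype.TUMOR if is_tumor else Phenotype.EPITHELIAL,
            x=X[i].copy(),
            R=params.R0,
            phase=Phase.G1,
            phase_age=age,
            F=params.F,
            birth_time=0.0,
        )
        cells.append(cell)
        if is_tumor:
            # a pre-initiated microtumor has been secreting during its
            # growth history: open the trace in the past (stationary there)
            tr = traces.open(cell.id, -eng.tumor_seed_age, cell.x)
            if eng.tumor_seed_age > 0:
                tr.record(0.0, cell.x)
    return SimulationState(t=0.0, cells=cells, traces=traces, rng=rng,
                           next_id=n_cells)
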