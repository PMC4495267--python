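"""Immune response and vessel traffic.

T-cells extravasate from vessel points on the boundary with a probability
that saturates in the local chemokine concentration,

    P_T(dt) = 1 - (1 - A c^2 / (B + c^2))^dt,

chase tumor cells up the chemokine gradient (sensitivity mu = mu_factor *
alpha), and engulf every tumor cell they touch.  Tumor cells in contact with
a vessel whose sensed strain energy exceeds M_b* intravasate: they leave the
domain through the blood stream and, with probability P_S, are tagged as a
seeding event (possible distant spread; no downstream dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cells import Cell, Phase, Phenotype
from .config import DomainParams, ImmuneParams, PhenotypeParams


@dataclass
class VesselEvent:
    time: float
    event: str  # "tcell_entry" | "intravasation" | "seeding"
    cell_id: int
    vessel_index: int


@dataclass
class VesselEventLog:
    entries: List[VesselEvent] = field(default_factory=list)

    def add(self, time: float, event: str, cell_id: int, vessel_index: int) -> None:
        if self.entries and time < self.entries[-1].time - 1e-9:
            raise ValueError("vessel events must be appended in time order")
        self.entries.append(VesselEvent(time, event, cell_id, vessel_index))

    def to_records(self) -> list:
        return [
            {"time": e.time, "event": e.event, "cell_id": e.cell_id,
             "vessel_index": e.vessel_index}
            for e in self.entries
        ]


def extravasation_prob(c_b: float, dt: float, A: float, B: float) -> float:
    """Per-interval T-cell entry probability at a vessel point with local
    chemokine concentration c_b; saturates at 1 - (1-A)^dt as c_b -> inf."""
    if c_b < 0:
        raise ValueError("concentration must be non-negative")
    hazard = A * c_b * c_b / (B + c_b * c_b)
    return 1.0 - (1.0 - hazard) ** dt


def spawn_tcell(vessel_point: np.ndarray, vessel_index: int,
                domain: DomainParams, immune: ImmuneParams,
                tcell_params: PhenotypeParams, cells: Sequence[Cell],
                rng: np.random.Generator, next_id: int,
                overlap_tol: float = 3.0, max_tries: int = 16) -> Optional[Cell]:
    """Place a new T-cell just inside the boundary at a vessel point.

    Candidates are the tangent position plus jittered variants; the least
    overlapping one is taken, provided no existing cell is penetrated deeper
    than ``overlap_tol`` (transmigration squeezes between resident cells and
    contact repulsion resolves the residual overlap within a few steps).
    Returns None (event skipped, logged by the caller) when even the best
    candidate exceeds the tolerance — a strict no-overlap rule in a
    confluent tissue would starve the immune response entirely.
    """
    R_t = immune.R_tcell
    vp = np.asarray(vessel_point, dtype=float)
    inward = -vp / np.linalg.norm(vp)
    base = vp + inward * R_t
    if cells:
        X = np.array([c.x for c in cells])
        R = np.array([c.R for c in cells])
    else:
        X = np.zeros((0, vp.shape[0]))
        R = np.zeros(0)
    best_x, best_pen = None, np.inf
    for attempt in range(max_tries):
        jitter = rng.normal(scale=0.5 * R_t, size=vp.shape[0]) if attempt else 0.0
        x = base + jitter
        nrm = np.linalg.norm(x)
        if nrm > domain.radius - R_t:
            x = x * (domain.radius - R_t) / nrm
        pen = 0.0
        if X.shape[0]:
            dist = np.linalg.norm(X - x[None, :], axis=1)
            pen = float((0.5 * np.maximum(0.0, R + R_t - dist)).max())
        if pen < best_pen:
            best_x, best_pen = x, pen
        if pen == 0.0:
            break
    if best_x is None or best_pen > overlap_tol:
        return None
    return Cell(
        id=next_id,
        phenotype=Phenotype.TCELL,
        x=np.asarray(best_x, dtype=float),
        R=R_t,
        phase=Phase.NONE,
        F=tcell_params.F,
    )


def engulf(tcell: Cell, cells: Sequence[Cell]) -> List[int]:
    """Ids of tumor cells in contact with the T-cell (centre distance below
    the radius sum).  Only the tumor phenotype is ever engulfed; the caller
    removes the cells and closes their traces."""
    removed = []
    for c in cells:
        if c.phenotype is not Phenotype.TUMOR or not c.alive:
            continue
        if np.linalg.norm(c.x - tcell.x) < tcell.R + c.R:
            removed.append(c.id)
    return removed


def intravasation_check(cell: Cell, M_at_cell: float, domain: DomainParams,
                        M_b_star: float, P_S: float,
                        rng: np.random.Generator) -> Optional[Tuple[int, bool]]:
    """Intravasation of one tumor cell: requires geometric contact with a
    vessel sphere (distance to a vessel point below R_b + R) AND sensed
    strain energy above the threshold M_b*.  Returns (vessel_index, seeded)
    where ``seeded`` is True with probability P_S, or None if the criterion
    is not met."""
    if cell.phenotype is not Phenotype.TUMOR:
        return None
    if M_at_cell <= M_b_star:
        return None
    for idx, b in enumerate(domain.vessel_points()):
        if np.linalg.norm(cell.x - b) < domain.R_b + cell.R:
            seeded = P_S > 0 and rng.random() < P_S
            return (idx, seeded)
    return None


def tcell_drift(mech_drift: np.ndarray, grad_c: np.ndarray, alpha: float,
                mu_factor: float) -> np.ndarray:
    """Total deterministic T-cell drift velocity: mechanical part plus
    chemotaxis mu * grad c with mu = mu_factor * alpha."""
    return mech_drift + mu_factor * alpha * np.asarray(grad_c, dtype=float)
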