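"""Cell agents and their discrete labels.

Every cell is a disc (2D) or sphere (3D) with a phenotype, a position in
micrometres, a radius, a cell-cycle phase and a traction force.  Internal
units throughout the package: length um, time s, pressure / energy density
kPa, force nN (1 nN = 1 kPa * um^2, which is what makes the strain-energy
expressions come out in kPa without conversion factors).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Phenotype(str, enum.Enum):
    EPITHELIAL = "epithelial"
    TUMOR = "tumor"
    TCELL = "tcell"


class Phase(str, enum.Enum):
    G1 = "G1"
    S = "S"
    G2 = "G2"
    M = "M"
    NONE = "none"  # non-cycling cells (T-cells)


@dataclass
class Cell:
    """One agent.

    ``x`` is the centre position (um), ``R`` the current radius (um),
    ``F`` the traction force the cell exerts on the matrix (nN),
    ``phase_age`` the time spent in the current cycle phase (s).
    """

    id: int
    phenotype: Phenotype
    x: np.ndarray
    R: float
    phase: Phase = Phase.G1
    phase_age: float = 0.0
    F: float = 1.0
    alive: bool = True
    birth_time: float = 0.0

    def copy(self) -> "Cell":
        return Cell(
            id=self.id,
            phenotype=self.phenotype,
            x=self.x.copy(),
            R=self.R,
            phase=self.phase,
            phase_age=self.phase_age,
            F=self.F,
            alive=self.alive,
            birth_time=self.birth_time,
        )

    def to_record(self) -> dict:
        rec = {
            "id": self.id,
            "phenotype": self.phenotype.value,
            "x": float(self.x[0]),
            "y": float(self.x[1]),
            "R": self.R,
            "phase": self.phase.value,
            "phase_age": self.phase_age,
            "F": self.F,
            "alive": self.alive,
            "birth_time": self.birth_time,
        }
        if self.x.shape[0] == 3:
            rec["z"] = float(self.x[2])
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Cell":
        coords = [rec["x"], rec["y"]]
        if "z" in rec and rec["z"] is not None:
            coords.append(rec["z"])
        return cls(
            id=int(rec["id"]),
            phenotype=Phenotype(rec["phenotype"]),
            x=np.asarray(coords, dtype=float),
            R=float(rec["R"]),
            phase=Phase(rec["phase"]),
            phase_age=float(rec.get("phase_age", 0.0)),
            F=float(rec.get("F", 1.0)),
            alive=bool(rec.get("alive", True)),
            birth_time=float(rec.get("birth_time", 0.0)),
        )
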