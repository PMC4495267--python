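"""Parameter containers, defaults, validation and config-file round trip.

Unit system (fixed, conversions happen only at config load):

====================  ==========
quantity              unit
====================  ==========
length                um
time                  s
pressure / energy     kPa
force                 nN
concentration         scaled nmol um^-3
====================  ==========

The defaults reproduce the model's standard parameter set: a soft matrix
(E_s = 5 kPa), compliant cells (E_c = 0.5 kPa), chemokine diffusivity
D = 100 um^2/s, and two cycling phenotypes — slow epithelial cells
(cycle 1001 s, observed doubling 1e7 s, i.e. a homeostatic tissue) and
fast tumor cells (cycle 21 s, doubling 4000 s).  T-cells do not cycle;
their death keeps the epithelial calibration.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

CUBE_ROOT_2 = 2.0 ** (1.0 / 3.0)

_VESSEL_CACHE: dict = {}


class ConfigError(ValueError):
    """A configuration invariant is violated; the message names it."""


class PhenotypeParams(BaseModel):
    """Cycle timings, geometry and traction of one phenotype (durations s, radii um)."""

    model_config = ConfigDict(validate_assignment=True)

    name: str
    T_G1: float = 300.0
    T_S: float = 400.0
    T_G2: float = 300.0
    T_M: float = 1.0
    T_C: float = 1001.0
    T_2: float = 1.0e7
    R0: float = 3.0
    R_max: float = 3.0 * CUBE_ROOT_2
    F: float = 1.0  # traction force, nN
    beta: float = 10.0  # mobility rate, 1/s
    can_divide: bool = True
    can_mutate: bool = False


class MechanicsParams(BaseModel):
    """Matrix/cell elasticity, mechanosensing and pressure-response constants."""

    model_config = ConfigDict(validate_assignment=True)

    E_s: float = 5.0  # matrix elastic modulus, kPa
    E_c: float = 0.5  # cell elastic modulus, kPa
    F_hat: float = 1.0  # reference traction force, nN
    lambda_attenuation: float = 10.0  # strain-energy decay per cell radius
    L: float = 30.0  # mechanosensing cutoff, um
    f: float = 0.2  # cell-substrate friction, dimensionless
    M_b_star: float = 0.1  # intravasation energy threshold, kPa
    M_min: float = 0.0  # optional sensing threshold on energy magnitude, kPa
    c1: float = 11.0
    c2: float = 9.0
    c3: float = 1.0
    c4: float = 9.0
    c5: float = 10.0


class FieldParams(BaseModel):
    """Chemokine transport: diffusivity, secretion and quadrature control."""

    model_config = ConfigDict(validate_assignment=True)

    D: float = 100.0  # um^2/s
    gamma: float = 2.0  # secretion rate, scaled nmol um^-3 s^-1
    t_tilde: float = 80.0  # drop dead sources older than this, s
    t_star: float = 80.0  # switch to the long-time tail beyond this lag, s
    dt_quad: float = 5.0  # trace sampling / quadrature step, s
    eps_r: float = 0.1  # minimum source-evaluation distance, um


class ImmuneParams(BaseModel):
    """Extravasation response, T-cell geometry, mutation and seeding odds."""

    model_config = ConfigDict(validate_assignment=True)

    A: float = 0.05  # extravasation saturation level
    B: float = 200.0  # half-saturation scale, concentration^2
    mu_factor: float = 1.0e4  # chemotactic sensitivity, mu = mu_factor * alpha_i
    R_tcell: float = 4.5  # um
    P_M: float = 0.25  # mutation probability per epithelial division
    P_S: float = 0.01  # seeding probability per intravasated tumor cell


class DomainParams(BaseModel):
    """Bounded disc/ball of tissue with vessel points on its boundary."""

    model_config = ConfigDict(validate_assignment=True)

    dim: int = 2
    radius: float = 40.0  # um
    R_b: float = 4.0  # blood-vessel radius, um
    n_vessels: Optional[int] = None  # default: 4 in 2D, 6 in 3D

    def vessel_count(self) -> int:
        if self.n_vessels is not None:
            return self.n_vessels
        return 4 if self.dim == 2 else 6

    def vessel_points(self) -> np.ndarray:
        """Vessel points on the boundary: equally spaced on the circle (2D),
        octahedral on the sphere (3D).  Cached on the field values."""
        n = self.vessel_count()
        key = (self.dim, self.radius, n)
        cached = _VESSEL_CACHE.get(key)
        if cached is not None:
            return cached
        pts = self._vessel_points_uncached(n)
        _VESSEL_CACHE[key] = pts
        return pts

    def _vessel_points_uncached(self, n: int) -> np.ndarray:
        if self.dim == 2:
            ang = 2.0 * np.pi * np.arange(n) / n
            return self.radius * np.column_stack([np.cos(ang), np.sin(ang)])
        if n == 6:
            pts = np.array(
                [
                    [1, 0, 0], [-1, 0, 0],
                    [0, 1, 0], [0, -1, 0],
                    [0, 0, 1], [0, 0, -1],
                ],
                dtype=float,
            )
            return self.radius * pts
        # generic: golden-spiral points on the sphere
        k = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)
        theta = np.pi * (1.0 + 5.0 ** 0.5) * k
        pts = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        return self.radius * pts


class EngineParams(BaseModel):
    """Time stepping, noise, run length and initial-condition knobs."""

    model_config = ConfigDict(validate_assignment=True)

    dt_max: float = 1.0  # s
    dt_min: float = 0.1  # s; below this the displacement cap clamps instead
    sigma: float = 0.1  # random-walk magnitude, um s^-1/2
    sigma_g: float = 0.01  # growth noise, um s^-1/2
    t_end: float = 600.0  # s
    stop_fraction: float = 0.5  # halt when tumor fraction reaches this
    counts_every: float = 5.0  # s between counts records
    packing_fraction: Optional[float] = None  # default 0.7 (2D) / 0.5 (3D)
    synchronized_start: bool = False  # if True, all cells start at phase_age 0
    pressure_modulation: bool = True  # apply F(p), G(p) to cycle and death
    tumor_seed_radius: float = 0.0  # um; cells inside start as tumor
    tumor_seed_age: float = 0.0  # s; seeded tumor has secreted this long already
    spawn_overlap_tol: float = 3.0  # um; max penetration allowed at T-cell spawn
    max_pack_sweeps: int = 2000

    def packing(self, dim: int) -> float:
        if self.packing_fraction is not None:
            return self.packing_fraction
        return 0.7 if dim == 2 else 0.5


class SimulationConfig(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    seed: int = 0
    domain: DomainParams = Field(default_factory=DomainParams)
    field: FieldParams = Field(default_factory=FieldParams)
    mech: MechanicsParams = Field(default_factory=MechanicsParams)
    immune: ImmuneParams = Field(default_factory=ImmuneParams)
    engine: EngineParams = Field(default_factory=EngineParams)
    phenotype: Dict[str, PhenotypeParams] = Field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> SimulationConfig:
    """The standard parameter set (see module docstring)."""
    phenos = {
        "epithelial": PhenotypeParams(
            name="epithelial",
            T_G1=300.0, T_S=400.0, T_G2=300.0, T_M=1.0,
            T_C=1001.0, T_2=1.0e7,
            can_divide=True, can_mutate=True,
        ),
        "tumor": PhenotypeParams(
            name="tumor",
            T_G1=10.0, T_S=0.0, T_G2=10.0, T_M=1.0,
            T_C=21.0, T_2=4000.0,
            can_divide=True, can_mutate=False,
        ),
        "tcell": PhenotypeParams(
            name="tcell",
            T_G1=0.0, T_S=0.0, T_G2=0.0, T_M=0.0,
            # non-cycling; T_C/T_2 only calibrate death, kept at the
            # epithelial values (minimal consistent choice)
            T_C=1001.0, T_2=1.0e7,
            R0=4.5, R_max=4.5,
            can_divide=False, can_mutate=False,
        ),
    }
    return SimulationConfig(phenotype=phenos)


def validate(config: SimulationConfig) -> SimulationConfig:
    """Check cross-field invariants; raise :class:`ConfigError` naming the
    violated one.  Returns the config unchanged on success."""
    dom, fld, mech, imm, eng = (
        config.domain, config.field, config.mech, config.immune, config.engine
    )
    if dom.dim not in (2, 3):
        raise ConfigError(f"domain.dim must be 2 or 3, got {dom.dim}")
    if dom.radius <= 0:
        raise ConfigError("domain.radius must be positive")
    if dom.R_b <= 0:
        raise ConfigError("domain.R_b must be positive")
    if fld.D <= 0:
        raise ConfigError(f"field.D must be positive, got {fld.D}")
    if fld.t_tilde <= 0 or fld.dt_quad <= 0 or fld.t_star <= 0:
        raise ConfigError("field.t_tilde, t_star and dt_quad must be positive")
    if fld.eps_r <= 0:
        raise ConfigError("field.eps_r must be positive")
    for name in ("E_s", "E_c", "F_hat", "lambda_attenuation", "L", "f",
                 "M_b_star", "c1", "c2", "c3", "c4", "c5"):
        if getattr(mech, name) <= 0:
            raise ConfigError(f"mech.{name} must be strictly positive")
    if not 0.0 <= imm.A <= 1.0:
        raise ConfigError(f"immune.A must lie in [0, 1], got {imm.A}")
    if imm.B <= 0:
        raise ConfigError("immune.B must be positive")
    if not 0.0 <= imm.P_M <= 1.0:
        raise ConfigError(f"immune.P_M must lie in [0, 1], got {imm.P_M}")
    if not 0.0 <= imm.P_S <= 1.0:
        raise ConfigError(f"immune.P_S must lie in [0, 1], got {imm.P_S}")
    if eng.dt_max <= 0 or eng.dt_min <= 0 or eng.dt_min > eng.dt_max:
        raise ConfigError("engine requires 0 < dt_min <= dt_max")
    if eng.sigma < 0 or eng.sigma_g < 0:
        raise ConfigError("noise magnitudes sigma and sigma_g must be >= 0")
    for name, ph in config.phenotype.items():
        if ph.R0 <= 0 or ph.R_max < ph.R0:
            raise ConfigError(f"phenotype {name}: need 0 < R0 <= R_max")
        if ph.can_divide:
            total = ph.T_G1 + ph.T_S + ph.T_G2 + ph.T_M
            if not np.isclose(total, ph.T_C, rtol=0, atol=1e-9):
                raise ConfigError(
                    f"phenotype {name}: T_C ({ph.T_C}) != sum of phase times ({total})"
                )
        if ph.T_2 <= ph.T_C:
            raise ConfigError(
                f"phenotype {name}: T_2 ({ph.T_2}) must exceed T_C ({ph.T_C}); "
                "T_2 = T_C makes the death calibration degenerate (immortal)"
            )
    vessels = dom.vessel_points()
    if not np.allclose(np.linalg.norm(vessels, axis=1), dom.radius, rtol=1e-9):
        raise ConfigError("vessel points must lie on the domain boundary")
    return config


def to_yaml(config: SimulationConfig, path=None) -> str:
    """Serialize to YAML (floats round-trip exactly via repr)."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_yaml(source) -> SimulationConfig:
    """Load a config from a YAML string or file path and validate it."""
    import os

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    cfg = SimulationConfig.model_validate(data)
    return validate(cfg)
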