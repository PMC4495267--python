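"""Cell cycle: growth, phase transitions, division with mutation, and death.

Phases G1 (growth), S (DNA synthesis), G2 (growth) and M (mitosis).  G1, G2
and M have fixed durations; the S phase exits each step with probability
(dt/T_S) * F(p), giving a geometric residence with mean T_S / F(p).  The
radius grows linearly at kappa = (R_max - R0)/(T_G1 + T_G2) during G1/G2
(plus optional noise).  Death is sampled every step with

    P_D(dt) = 1 - 2^{(1/T_2 - 1/T_C) dt G(p)},

calibrated so that, at G = 1, a colony dividing every T_C doubles in the
experimentally observed time T_2.  The pressure responses
F(p) = c1/(1 + c2 exp(c3 p)) (proliferation shut-down) and
G(p) = c4/(1 + exp(-c5 p)) (pressure-enhanced death) can be switched off
(`modulated=False`) to recover the bare calibration.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .cells import Cell, Phase, Phenotype
from .config import MechanicsParams, PhenotypeParams


@dataclass
class CycleEvent:
    kind: str  # "died" | "divided" | "mutated"
    cell: Cell
    daughter: Optional[Cell] = None


def pressure_response(p: float, c1: float = 11.0, c2: float = 9.0,
                      c3: float = 1.0) -> float:
    """F(p) = c1 / (1 + c2 exp(c3 p)); F(0) = 1.1 with the defaults."""
    return c1 / (1.0 + c2 * math.exp(c3 * p))


def death_modulation(p: float, c4: float = 9.0, c5: float = 10.0) -> float:
    """G(p) = c4 / (1 + exp(-c5 p)); G(0) = c4/2."""
    return c4 / (1.0 + math.exp(-c5 * p))


def growth_constant(params: PhenotypeParams) -> float:
    """kappa = (R_max - R0) / (T_G1 + T_G2), um/s."""
    denom = params.T_G1 + params.T_G2
    if denom <= 0:
        raise ValueError("growth constant undefined: T_G1 + T_G2 must be > 0")
    return (params.R_max - params.R0) / denom


def grow_radius(cell: Cell, dt: float, params: PhenotypeParams, sigma_g: float,
                rng: np.random.Generator) -> float:
    """One growth increment dR = gamma_phase * kappa * dt + sigma_g dW,
    clamped to [R0, R_max].  gamma_phase is 1 in G1/G2, else 0."""
    gamma_phase = 1.0 if cell.phase in (Phase.G1, Phase.G2) else 0.0
    dR = gamma_phase * growth_constant(params) * dt
    if sigma_g > 0:
        dR += sigma_g * math.sqrt(dt) * rng.standard_normal()
    cell.R = min(max(cell.R + dR, params.R0), params.R_max)
    return cell.R


def transition_prob_S_to_G2(dt: float, T_S: float, p: float = 0.0,
                            c1: float = 11.0, c2: float = 9.0, c3: float = 1.0,
                            modulated: bool = True) -> float:
    """Per-step S -> G2 exit probability (dt/T_S) * F(p), capped at 1.
    T_S = 0 means the phase is skipped (probability 1)."""
    if T_S <= 0:
        return 1.0
    base = dt / T_S
    if modulated:
        base *= pressure_response(p, c1, c2, c3)
    return min(1.0, base)


def death_prob(dt: float, T_C: float, T_2: float, p: float = 0.0,
               c4: float = 9.0, c5: float = 10.0, modulated: bool = True) -> float:
    """Per-step death probability 1 - 2^{(1/T_2 - 1/T_C) dt G(p)};
    with modulated=False this is the bare doubling-time calibration."""
    G = death_modulation(p, c4, c5) if modulated else 1.0
    expo = (1.0 / T_2 - 1.0 / T_C) * dt * G
    return 1.0 - 2.0 ** expo


def _random_unit(dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(dim)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(dim)
        n = np.linalg.norm(v)
    return v / n


def divide(mother: Cell, params: PhenotypeParams, rng: np.random.Generator,
           next_id: int) -> Tuple[Cell, Cell]:
    """Mitosis: mother and daughter get radius R0 and are displaced to
    x +/- R0 u along a uniformly random unit direction, so they touch exactly
    at the former mother centre.  Both enter G1 at phase_age 0."""
    dim = mother.x.shape[0]
    u = _random_unit(dim, rng)
    centre = mother.x.copy()
    mother.x = centre + params.R0 * u
    mother.R = params.R0
    mother.phase = Phase.G1
    mother.phase_age = 0.0
    daughter = Cell(
        id=next_id,
        phenotype=mother.phenotype,
        x=centre - params.R0 * u,
        R=params.R0,
        phase=Phase.G1,
        phase_age=0.0,
        F=mother.F,
        birth_time=0.0,  # engine stamps the clock
    )
    return mother, daughter


def maybe_mutate(daughter: Cell, P_M: float, rng: np.random.Generator,
                 tumor_params: Optional[PhenotypeParams] = None) -> Phenotype:
    """Mutation decision at the end of mitosis: with probability P_M the
    daughter of an epithelial division becomes a tumor cell."""
    if rng.random() < P_M:
        daughter.phenotype = Phenotype.TUMOR
        if tumor_params is not None:
            daughter.F = tumor_params.F
            daughter.R = min(daughter.R, tumor_params.R_max)
    return daughter.phenotype


def phase_step(cell: Cell, dt: float, p: float, params: PhenotypeParams,
               mech: MechanicsParams, rng: np.random.Generator,
               sigma_g: float = 0.0, modulated: bool = True,
               next_id: Optional[int] = None) -> List[CycleEvent]:
    """Advance one cell's cycle by dt under contact pressure p.

    Order: death sample first (all phenotypes, all phases), then growth,
    then phase bookkeeping.  G1/G2/M end deterministically at their mean
    durations (remainders carry over); S exits geometrically.  Returns the
    events produced (death, division, mutation decided by the caller).
    """
    events: List[CycleEvent] = []
    if rng.random() < death_prob(dt, params.T_C, params.T_2, p,
                                 mech.c4, mech.c5, modulated):
        cell.alive = False
        events.append(CycleEvent("died", cell))
        return events
    if not params.can_divide:
        return events
    grow_radius(cell, dt, params, sigma_g, rng)
    cell.phase_age += dt
    # phase boundaries carry their overshoot (and tolerate float round-off)
    # so the realized cycle length stays T_C on average: the death
    # calibration against T_2 sits on a knife edge for fast phenotypes and
    # a systematic stretch of even one step per cycle would bias it
    eps = 1e-9
    if cell.phase == Phase.G1 and cell.phase_age >= params.T_G1 - eps:
        cell.phase_age = max(0.0, cell.phase_age - params.T_G1)
        cell.phase = Phase.S
    if cell.phase == Phase.S:
        if params.T_S <= 0:
            cell.phase = Phase.G2
        elif rng.random() < transition_prob_S_to_G2(dt, params.T_S, p,
                                                    mech.c1, mech.c2, mech.c3,
                                                    modulated):
            cell.phase = Phase.G2
            cell.phase_age = 0.0
            return events
        else:
            return events
    if cell.phase == Phase.G2 and cell.phase_age >= params.T_G2 - eps:
        cell.phase_age = max(0.0, cell.phase_age - params.T_G2)
        cell.phase = Phase.M
    if cell.phase == Phase.M and cell.phase_age >= params.T_M - eps:
        if next_id is None:
            raise ValueError("phase_step needs next_id to perform a division")
        overshoot = max(0.0, cell.phase_age - params.T_M)
        mother, daughter = divide(cell, params, rng, next_id)
        mother.phase_age = daughter.phase_age = overshoot
        events.append(CycleEvent("divided", mother, daughter))
    return events


def mean_s_residence(n_cells: int, dt: float, T_S: float,
                     rng: np.random.Generator, modulated: bool = False,
                     p: float = 0.0) -> float:
    """Simulated mean S-phase residence time of a cohort: every cell runs
    the per-step Bernoulli exit trial until it leaves (vectorized)."""
    prob = transition_prob_S_to_G2(dt, T_S, p=p, modulated=modulated)
    remaining = np.arange(n_cells)
    steps = np.zeros(n_cells, dtype=np.int64)
    k = 0
    while remaining.size:
        k += 1
        exit_mask = rng.random(remaining.size) < prob
        steps[remaining[exit_mask]] = k
        remaining = remaining[~exit_mask]
    return float(steps.mean() * dt)


def branching_doubling_time(n0: int, params: PhenotypeParams, dt: float,
                            rng: np.random.Generator,
                            max_t: float = 1.0e5) -> float:
    """Doubling time of a non-spatial branching colony: each step every cell
    dies with the bare P_D(dt) (G == 1); survivors divide into two on
    completing a cycle of length T_C.  Cohort ages start from the stable age
    profile of a steadily doubling colony, f(a) ~ 2^(-a/T_C), so the
    division flux starts at its long-run level instead of in an artificial
    wave.  Returns the first time the population reaches 2 * n0."""
    n_bins = max(1, int(round(params.T_C / dt)))
    ages = dt * np.arange(n_bins)
    weights = np.exp2(-ages / params.T_C)
    counts = rng.multinomial(n0, weights / weights.sum())
    pd = death_prob(dt, params.T_C, params.T_2, modulated=False)
    t = 0.0
    total = n0
    while total < 2 * n0:
        t += dt
        if t > max_t:
            raise RuntimeError("population failed to double within max_t")
        deaths = rng.binomial(counts, pd)
        counts = counts - deaths
        dividing = counts[-1]
        counts = np.roll(counts, 1)
        counts[0] = 2 * dividing
        total = int(counts.sum())
        if total == 0:
            raise RuntimeError("population went extinct before doubling")
    return t
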