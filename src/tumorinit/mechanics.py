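"""Mechanical signalling: strain-energy haptotaxis and Hertz contact repulsion.

A cell pulling on the matrix with traction force F induces a strain energy
density M0 = F^2 / (2 pi^2 E_s R^4) at its centre, attenuated exponentially
with distance (decay rate ``lambda`` per cell radius) and sensed only within
a cutoff L.  Overlapping cells additionally store Hertzian contact energy,
which repels them.  The migration direction of a cell sums unit vectors to
its neighbours weighted by these energies: long-range (haptotactic) terms
attract, contact terms repel; the drift magnitude is alpha * M_total where
alpha = (F/F_hat)^2 beta R^3 / f is the phenomenological mobility.

Walls are handled as contact with a virtual mirror cell of equal radius
across the boundary; vessel points as spheres of radius R_b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cells import Cell, Phase
from .config import DomainParams, MechanicsParams, PhenotypeParams

_Z_EPS = 1e-12


@dataclass
class MechanicalSignal:
    """Per-cell mechanical state for one step."""

    M_total: np.ndarray  # kPa, sensed energy density (haptotactic + contact)
    z: np.ndarray  # unnormalized drift direction
    p: np.ndarray  # kPa, contact pressure proxy (contact terms only)


def source_strength(F: float, E_s: float, R: float) -> float:
    """Strain energy density a cell induces at its own centre,
    F^2 / (2 pi^2 E_s R^4), in kPa."""
    return F * F / (2.0 * np.pi ** 2 * E_s * R ** 4)


def sensed_energy(x, cells: Sequence[Cell], mech: MechanicsParams) -> float:
    """Haptotactic strain energy density at an arbitrary point: attenuated
    source strengths of all cells within the sensing cutoff L (additive)."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for c in cells:
        d = float(np.linalg.norm(x - c.x))
        if d >= mech.L:
            continue
        M0 = source_strength(c.F, mech.E_s, c.R)
        val = M0 * np.exp(-mech.lambda_attenuation * d / c.R)
        if val >= mech.M_min:
            total += val
    return total


def penetration_depth(x_i, x_j, R_i: float, R_j: float) -> float:
    """h = max(0, R_i + R_j - ||x_j - x_i||) / 2."""
    d = float(np.linalg.norm(np.asarray(x_j, float) - np.asarray(x_i, float)))
    if d == 0.0:
        raise ValueError("coincident cell centres: penetration depth undefined")
    return 0.5 * max(0.0, R_i + R_j - d)


def contact_energy(h: float, R_i: float, E_c: float, dim: int) -> float:
    """Hertz contact strain energy density of a cell of radius R_i pushing
    with penetration h: prefactor 16/25 (2D) or 2/5 (3D) times
    E_c/(sqrt(2) pi) * (h/R_i)^(5/2)."""
    if h <= 0.0:
        return 0.0
    pref = 16.0 / 25.0 if dim == 2 else 2.0 / 5.0
    return pref * E_c / (np.sqrt(2.0) * np.pi) * (h / R_i) ** 2.5


def mobility_alpha(cell: Cell, mech: MechanicsParams, beta: float) -> float:
    """alpha = (F/F_hat)^2 beta R^3 / f; zero for dead cells, which cannot
    migrate actively."""
    if not cell.alive:
        return 0.0
    return (cell.F / mech.F_hat) ** 2 * beta * cell.R ** 3 / mech.f


def _wall_contact(X: np.ndarray, R: np.ndarray, domain: DomainParams,
                  mech: MechanicsParams):
    """Mirror-cell contact with the outer boundary.

    A cell at distance d from the centre faces its mirror image across the
    boundary sphere at centre distance 2*radius - d; the pair penetration is
    h = max(0, R - (radius - d)).  Returns (energy, inward unit vectors)."""
    d = np.linalg.norm(X, axis=1)
    gap = domain.radius - d
    h = np.maximum(0.0, R - gap)
    dim = X.shape[1]
    pref = 16.0 / 25.0 if dim == 2 else 2.0 / 5.0
    M = np.where(h > 0, pref * mech.E_c / (np.sqrt(2.0) * np.pi)
                 * (h / R) ** 2.5, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        outward = np.where(d[:, None] > 0, X / np.maximum(d, 1e-300)[:, None], 0.0)
    return M, outward


def _vessel_contact(X: np.ndarray, R: np.ndarray, domain: DomainParams,
                    mech: MechanicsParams):
    """Contact with vessel spheres of radius R_b at the vessel points.
    Returns (total energy per cell, summed -v_ib * M_ib direction term)."""
    n, dim = X.shape
    E = np.zeros(n)
    Zrep = np.zeros_like(X)
    pref = 16.0 / 25.0 if dim == 2 else 2.0 / 5.0
    for b in domain.vessel_points():
        diff = b[None, :] - X
        dist = np.linalg.norm(diff, axis=1)
        h = 0.5 * np.maximum(0.0, R + domain.R_b - dist)
        mask = h > 0
        if not np.any(mask):
            continue
        # pushing body is the vessel (radius R_b)
        Mv = pref * mech.E_c / (np.sqrt(2.0) * np.pi) * (h[mask] / domain.R_b) ** 2.5
        unit = diff[mask] / np.maximum(dist[mask], 1e-300)[:, None]
        E[mask] += Mv
        Zrep[mask] -= Mv[:, None] * unit
    return E, Zrep


def compute_signals(X: np.ndarray, R: np.ndarray, F: np.ndarray,
                    contact_only: np.ndarray, domain: DomainParams,
                    mech: MechanicsParams) -> MechanicalSignal:
    """Vectorized per-cell mechanical signal for the whole population.

    ``contact_only`` marks cells (M-phase) that ignore remote haptotaxis and
    move only under contact repulsion.  Pairs in physical contact contribute
    only their (negative-signed) Hertz term; separated pairs within L
    contribute their (positive-signed) attenuated source strength.
    """
    n, dim = X.shape
    if n == 0:
        return MechanicalSignal(np.zeros(0), np.zeros((0, dim)), np.zeros(0))
    diff = X[None, :, :] - X[:, None, :]  # diff[i, j] = x_j - x_i
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    with np.errstate(invalid="ignore"):
        unit = diff / np.maximum(dist, 1e-300)[:, :, None]

    h = 0.5 * np.maximum(0.0, R[:, None] + R[None, :] - dist)
    in_contact = h > 0.0

    # remote haptotaxis: M_j evaluated at x_i, cutoff L, contacts excluded
    M0 = F ** 2 / (2.0 * np.pi ** 2 * mech.E_s * R ** 4)
    attn = M0[None, :] * np.exp(-mech.lambda_attenuation * dist / R[None, :])
    remote = (dist < mech.L) & (~in_contact) & (attn >= mech.M_min)
    attn = np.where(remote, attn, 0.0)

    # contact energy experienced by i from pusher j (radius R_j, Eq. asym.)
    pref = 16.0 / 25.0 if dim == 2 else 2.0 / 5.0
    with np.errstate(invalid="ignore"):
        Mc = np.where(in_contact,
                      pref * mech.E_c / (np.sqrt(2.0) * np.pi)
                      * (h / R[None, :]) ** 2.5, 0.0)

    attn_eff = np.where(contact_only[:, None], 0.0, attn)
    z = np.einsum("ij,ijk->ik", attn_eff - Mc, unit)
    M_total = attn_eff.sum(axis=1) + Mc.sum(axis=1)
    p = Mc.sum(axis=1)

    Mw, outward = _wall_contact(X, R, domain, mech)
    z -= Mw[:, None] * outward
    M_total += Mw
    p += Mw

    Ev, Zv = _vessel_contact(X, R, domain, mech)
    z += Zv
    M_total += Ev
    p += Ev

    return MechanicalSignal(M_total=M_total, z=z, p=p)


try:  # jitted pair loop for the engine's inner RK4 evaluations
    from numba import njit as _njit

    @_njit(cache=True)
    def _pair_signals(X, R, F, contact_only, E_s, E_c, lam, L, M_min, pref,
                      domain_radius, vessels, R_b):  # pragma: no cover
        n, dim = X.shape
        M_total = np.zeros(n)
        z = np.zeros((n, dim))
        p = np.zeros(n)
        sq2pi = np.sqrt(2.0) * np.pi
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d2 = 0.0
                for k in range(dim):
                    dd = X[j, k] - X[i, k]
                    d2 += dd * dd
                d = np.sqrt(d2)
                sumR = R[i] + R[j]
                if d < sumR:
                    h = 0.5 * (sumR - d)
                    Mc = pref * E_c / sq2pi * (h / R[j]) ** 2.5
                    M_total[i] += Mc
                    p[i] += Mc
                    for k in range(dim):
                        z[i, k] -= Mc * (X[j, k] - X[i, k]) / d
                elif d < L and not contact_only[i]:
                    a = (F[j] * F[j] / (2.0 * np.pi ** 2 * E_s * R[j] ** 4)
                         * np.exp(-lam * d / R[j]))
                    if a >= M_min:
                        M_total[i] += a
                        for k in range(dim):
                            z[i, k] += a * (X[j, k] - X[i, k]) / d
            nrm = 0.0
            for k in range(dim):
                nrm += X[i, k] * X[i, k]
            nrm = np.sqrt(nrm)
            hw = R[i] - (domain_radius - nrm)
            if hw > 0.0 and nrm > 0.0:
                Mw = pref * E_c / sq2pi * (hw / R[i]) ** 2.5
                M_total[i] += Mw
                p[i] += Mw
                for k in range(dim):
                    z[i, k] -= Mw * X[i, k] / nrm
            for v in range(vessels.shape[0]):
                d2 = 0.0
                for k in range(dim):
                    dd = vessels[v, k] - X[i, k]
                    d2 += dd * dd
                d = np.sqrt(d2)
                hv = 0.5 * (R[i] + R_b - d)
                if hv > 0.0 and d > 0.0:
                    Mv = pref * E_c / sq2pi * (hv / R_b) ** 2.5
                    M_total[i] += Mv
                    p[i] += Mv
                    for k in range(dim):
                        z[i, k] -= Mv * (vessels[v, k] - X[i, k]) / d
        return M_total, z, p

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def compute_signals_fast(X, R, F, contact_only, domain: DomainParams,
                         mech: MechanicsParams) -> MechanicalSignal:
    """Same contract as :func:`compute_signals`, via the jitted pair loop
    when numba is importable (falls back to the vectorized path)."""
    if not _HAVE_NUMBA or X.shape[0] == 0:
        return compute_signals(X, R, F, contact_only, domain, mech)
    dim = X.shape[1]
    pref = 16.0 / 25.0 if dim == 2 else 2.0 / 5.0
    vessels = np.ascontiguousarray(domain.vessel_points(), dtype=float)
    M_total, z, p = _pair_signals(
        np.ascontiguousarray(X, dtype=float),
        np.ascontiguousarray(R, dtype=float),
        np.ascontiguousarray(F, dtype=float),
        np.ascontiguousarray(contact_only, dtype=np.bool_),
        mech.E_s, mech.E_c, mech.lambda_attenuation, mech.L, mech.M_min,
        pref, domain.radius, vessels, domain.R_b,
    )
    return MechanicalSignal(M_total=M_total, z=z, p=p)


def pressure(cell: Cell, cells: Sequence[Cell], domain: DomainParams,
             mech: MechanicsParams) -> float:
    """Contact pressure proxy of one cell: summed Hertz energies with
    overlapping neighbours plus wall and vessel contacts (kPa)."""
    dim = cell.x.shape[0]
    total = 0.0
    for other in cells:
        if other.id == cell.id:
            continue
        h = penetration_depth(cell.x, other.x, cell.R, other.R)
        if h > 0:
            total += contact_energy(h, other.R, mech.E_c, dim)
    d = float(np.linalg.norm(cell.x))
    h_wall = max(0.0, cell.R - (domain.radius - d))
    total += contact_energy(h_wall, cell.R, mech.E_c, dim)
    for b in domain.vessel_points():
        hv = 0.5 * max(0.0, cell.R + domain.R_b - float(np.linalg.norm(b - cell.x)))
        total += contact_energy(hv, domain.R_b, mech.E_c, dim)
    return total


def migration_direction(cell: Cell, cells: Sequence[Cell],
                        mech: MechanicsParams,
                        domain: Optional[DomainParams] = None) -> Optional[np.ndarray]:
    """Unit drift direction of ``cell`` among ``cells`` (positive toward
    remote strain-energy sources, negative away from contacts and walls);
    None when the signals cancel below tolerance."""
    others = [c for c in cells if c.id != cell.id]
    all_cells = [cell] + others
    X = np.array([c.x for c in all_cells])
    R = np.array([c.R for c in all_cells])
    F = np.array([c.F for c in all_cells])
    contact_only = np.array([c.phase == Phase.M for c in all_cells])
    dom = domain if domain is not None else DomainParams(
        dim=X.shape[1], radius=1e9, n_vessels=0)
    sig = compute_signals(X, R, F, contact_only, dom, mech)
    z = sig.z[0]
    nz = float(np.linalg.norm(z))
    if nz < _Z_EPS:
        return None
    return z / nz
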