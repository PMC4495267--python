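"""Chemokine concentration from moving point sources, without a mesh.

Each tumor cell secretes chemokine at rate ``gamma`` from its centre while it
lives.  Because free-space diffusion is linear, the concentration anywhere is
the superposition, over every tumor cell that ever lived, of the heat kernel
convolved along that cell's trajectory (Duhamel principle).  Traces of dead
cells are retained: their chemokine is still dispersing.  Numerics:

* trapezoidal quadrature over each trace's recorded samples (cadence
  ``dt_quad``);
* contributions from a dead source are dropped once ``t - tau_D >= t_tilde``
  (they decay monotonically to zero);
* the part of a trace older than ``t - t_star`` is replaced by a closed-form
  long-time tail that ignores the spatial factor of the kernel (valid once
  ``r^2/(4 D t_star)`` is small).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .config import FieldParams

log = logging.getLogger(__name__)


_warned_clamped = False


def _warn_clamped() -> None:
    """Warn once at WARNING level about eps_r clamping, then at DEBUG (the
    situation recurs every step while a T-cell sits on a source)."""
    global _warned_clamped
    if _warned_clamped:
        log.debug("chemokine evaluation within eps_r of a source; clamped")
    else:
        log.warning("chemokine evaluation within eps_r of a source; clamped")
        _warned_clamped = True


class SingularKernelError(ZeroDivisionError):
    """kernel_value requested at r = 0, tau = 0 where the kernel is singular."""


def kernel_value(r, tau, D: float, dim: int):
    """Free-space heat kernel exp(-r^2/(4 D tau)) / (4 pi D tau)^(dim/2).

    Accepts scalars or arrays; at tau -> 0 with r > 0 the value is 0.
    """
    r = np.asarray(r, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any((tau <= 0) & (r <= 0)):
        raise SingularKernelError("heat kernel is singular at r = 0, tau = 0")
    out = np.zeros(np.broadcast_shapes(r.shape, tau.shape))
    pos = tau > 0
    with np.errstate(divide="ignore", over="ignore"):
        rb = np.broadcast_to(r, out.shape)[pos]
        tb = np.broadcast_to(tau, out.shape)[pos]
        out[pos] = np.exp(-rb * rb / (4.0 * D * tb)) / (4.0 * np.pi * D * tb) ** (dim / 2.0)
    if out.ndim == 0 or (np.isscalar(r) and np.isscalar(tau)):
        return float(out)
    return out


def tail_integral(t: float, tau_B: float, params: FieldParams, dim: int) -> float:
    """Closed-form long-time contribution of a source born at ``tau_B``,
    integrated over [tau_B, t - t_star] with the spatial factor dropped:
    (gamma/4piD) log((t - tau_B)/t*) in 2D and
    (gamma/2piD) (1/sqrt(t*) - 1/sqrt(t - tau_B)) in 3D.
    """
    age = t - tau_B
    if age < params.t_star:
        raise ValueError("tail_integral requires t - tau_B >= t_star")
    g, D, ts = params.gamma, params.D, params.t_star
    if dim == 2:
        return g / (4.0 * np.pi * D) * math.log(age / ts)
    return g / (2.0 * np.pi * D) * (1.0 / math.sqrt(ts) - 1.0 / math.sqrt(age))


def _tail_segment(t: float, tau_B: float, upper: float, params: FieldParams, dim: int) -> float:
    """Tail closed form over [tau_B, upper] for upper <= t - t_star."""
    g, D = params.gamma, params.D
    if upper <= tau_B:
        return 0.0
    if dim == 2:
        return g / (4.0 * np.pi * D) * math.log((t - tau_B) / (t - upper))
    return g / (2.0 * np.pi * D) * (
        1.0 / math.sqrt(t - upper) - 1.0 / math.sqrt(t - tau_B)
    )


@dataclass
class SourceTrace:
    """Time-stamped position history of one tumor cell.

    ``samples`` span [tau_B, min(tau_D, now)] at quadrature resolution;
    traces of dead cells are never deleted (their contribution only expires
    from the *evaluation* once older than ``t_tilde``).
    """

    cell_id: int
    tau_B: float
    tau_D: Optional[float] = None
    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)

    def record(self, t: float, x: np.ndarray) -> None:
        if self.tau_D is not None:
            raise ValueError("cannot record on a closed (dead) trace")
        if self.times and t < self.times[-1]:
            raise ValueError("trace samples must be non-decreasing in time")
        if self.times and t == self.times[-1]:
            self.positions[-1] = np.array(x, dtype=float)
            return
        self.times.append(float(t))
        self.positions.append(np.array(x, dtype=float))

    def close(self, t: float, x: Optional[np.ndarray] = None) -> None:
        if x is not None:
            self.record(t, x)
        self.tau_D = float(t)

    @property
    def closed(self) -> bool:
        return self.tau_D is not None

    def arrays(self):
        return np.asarray(self.times), np.asarray(self.positions)


def _trace_nodes(trace: SourceTrace, lo: float, hi: float):
    """Sample times/positions restricted to [lo, hi], with interpolated
    boundary nodes so truncation does not lose half a panel."""
    s, X = trace.arrays()
    if len(s) == 0 or hi <= lo:
        return None
    inside = (s >= lo) & (s <= hi)
    s_in = s[inside]
    X_in = X[inside]
    def interp_at(q):
        pos = np.array([np.interp(q, s, X[:, k]) for k in range(X.shape[1])])
        return pos
    ss = list(s_in)
    XX = list(X_in)
    if len(ss) == 0 or ss[0] > lo:
        if s[0] < lo:
            ss.insert(0, lo)
            XX.insert(0, interp_at(lo))
    if len(ss) == 0 or ss[-1] < hi:
        if s[-1] > hi or np.isclose(s[-1], hi):
            ss.append(hi)
            XX.append(interp_at(hi))
    if len(ss) < 2:
        return None
    return np.asarray(ss), np.asarray(XX)


def _gather_nodes(t: float, traces, params: FieldParams, dim: int):
    """Collect quadrature nodes of every contributing trace into flat arrays.

    Returns (tail_total, s_nodes, X_nodes, weights) where ``weights`` are the
    per-node trapezoid weights (panels never span trace boundaries), or
    (tail_total, None, ...) when no trace has an integrable recent segment.
    """
    tail_total = 0.0
    s_parts, X_parts, w_parts = [], [], []
    for trace in traces:
        if trace.closed and t - trace.tau_D >= params.t_tilde:
            continue
        end_live = min(t, trace.tau_D) if trace.closed else t
        if end_live <= trace.tau_B:
            continue
        tail_hi = t - params.t_star
        if tail_hi > trace.tau_B:
            upper = min(tail_hi, end_live)
            tail_total += _tail_segment(t, trace.tau_B, upper, params, dim)
        lo = max(trace.tau_B, tail_hi)
        # never evaluate at s = t (kernel 0/0 at the source itself): stop one
        # quadrature step short of now for live traces
        hi = (min(end_live, t - params.dt_quad) if not trace.closed
              else min(end_live, t - 1e-12))
        nodes = _trace_nodes(trace, lo, hi)
        if nodes is None:
            continue
        s, X = nodes
        ds = np.diff(s)
        w = np.zeros_like(s)
        w[:-1] += 0.5 * ds
        w[1:] += 0.5 * ds
        s_parts.append(s)
        X_parts.append(X)
        w_parts.append(w)
    if not s_parts:
        return tail_total, None, None, None
    return (tail_total, np.concatenate(s_parts), np.vstack(X_parts),
            np.concatenate(w_parts))


def evaluate_field(points, t: float, traces: Iterable[SourceTrace],
                   params: FieldParams, dim: int, grad: bool = False):
    """Concentration (or its gradient) at several points at once.

    ``points`` is (m, dim); returns (m,) concentrations or (m, dim)
    gradients.  The spatially-flat long-time tail contributes to the
    concentration only."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    m = P.shape[0]
    tail_total, s, X, w = _gather_nodes(t, traces, params, dim)
    if grad:
        out = np.zeros((m, dim))
    else:
        out = np.full(m, tail_total)
    if s is None or m == 0:
        return out
    tau = t - s  # (N,)
    diff = P[:, None, :] - X[None, :, :]  # (m, N, dim)
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r < params.eps_r):
        _warn_clamped()
        r = np.maximum(r, params.eps_r)
    with np.errstate(divide="ignore", over="ignore"):
        K = np.exp(-r * r / (4.0 * params.D * tau[None, :])) \
            / (4.0 * np.pi * params.D * tau[None, :]) ** (dim / 2.0)
    K = np.where(tau[None, :] > 0, K, 0.0)
    if grad:
        wk = params.gamma * w[None, :] * K / (2.0 * params.D
                                              * np.maximum(tau, 1e-300)[None, :])
        out -= np.einsum("ij,ijk->ik", wk, diff)
    else:
        out += params.gamma * (K * w[None, :]).sum(axis=1)
    return out


def concentration(x, t: float, traces: Iterable[SourceTrace], params: FieldParams,
                  dim: int) -> float:
    """Chemokine concentration at point ``x`` and time ``t``."""
    return float(evaluate_field(np.asarray(x, float)[None, :], t, traces,
                                params, dim)[0])


def concentration_gradient(x, t: float, traces: Iterable[SourceTrace],
                           params: FieldParams, dim: int) -> np.ndarray:
    """Spatial gradient of the concentration at (t, x), by analytic
    differentiation of the kernel under the same quadrature and truncation
    rules (the spatially-flat tail contributes no gradient)."""
    return evaluate_field(np.asarray(x, float)[None, :], t, traces, params,
                          dim, grad=True)[0]


class TraceStore:
    """All source traces of a run, live and dead, keyed by cell id."""

    def __init__(self):
        self._traces: Dict[int, SourceTrace] = {}

    def open(self, cell_id: int, t: float, x: np.ndarray) -> SourceTrace:
        if cell_id in self._traces:
            raise ValueError(f"trace for cell {cell_id} already exists")
        tr = SourceTrace(cell_id=cell_id, tau_B=t)
        tr.record(t, x)
        self._traces[cell_id] = tr
        return tr

    def close(self, cell_id: int, t: float, x: Optional[np.ndarray] = None) -> None:
        self._traces[cell_id].close(t, x)

    def record(self, cell_id: int, t: float, x: np.ndarray) -> None:
        self._traces[cell_id].record(t, x)

    def __getitem__(self, cell_id: int) -> SourceTrace:
        return self._traces[cell_id]

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self._traces

    def __iter__(self):
        return iter(self._traces.values())

    def __len__(self):
        return len(self._traces)

    def live(self):
        return [tr for tr in self._traces.values() if not tr.closed]

    def to_records(self) -> list:
        return [
            {
                "cell_id": tr.cell_id,
                "tau_B": tr.tau_B,
                "tau_D": tr.tau_D,
                "times": [float(v) for v in tr.times],
                "positions": [list(map(float, p)) for p in tr.positions],
            }
            for tr in self._traces.values()
        ]

    @classmethod
    def from_records(cls, records: list) -> "TraceStore":
        store = cls()
        for rec in records:
            tr = SourceTrace(cell_id=int(rec["cell_id"]), tau_B=float(rec["tau_B"]))
            tr.times = [float(v) for v in rec["times"]]
            tr.positions = [np.asarray(p, dtype=float) for p in rec["positions"]]
            tr.tau_D = None if rec["tau_D"] is None else float(rec["tau_D"])
            store._traces[tr.cell_id] = tr
        return store
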