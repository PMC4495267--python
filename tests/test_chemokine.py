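"""Heat-kernel field: quadrature, truncation rules and closed forms."""

import numpy as np
import pytest
from scipy import integrate

from tumorinit import concentration, concentration_gradient, kernel_value, tail_integral
from tumorinit.chemokine import SingularKernelError, SourceTrace, TraceStore
from tumorinit.config import FieldParams


def stationary_trace(dim, t_end, spacing=None, taus=None, origin=None):
    """Trace of a motionless source born at t = 0."""
    tr = SourceTrace(cell_id=0, tau_B=0.0)
    if taus is not None:  # node times given as lags before t_end
        s = np.sort(t_end - np.asarray(taus))
        s = np.concatenate([[0.0], s[s > 0]])
    else:
        s = np.arange(0.0, t_end + 1e-9, spacing)
    x0 = np.zeros(dim) if origin is None else np.asarray(origin, float)
    tr.times = list(s)
    tr.positions = [x0.copy() for _ in s]
    return tr


class TestKernel:
    def test_point_value_2d(self):
        assert kernel_value(0.0, 1.0, 100.0, 2) == pytest.approx(
            1.0 / (400.0 * np.pi))

    def test_vanishes_at_zero_lag_away_from_source(self):
        assert kernel_value(5.0, 1e-12, 100.0, 2) == pytest.approx(0.0, abs=1e-30)
        assert kernel_value(5.0, 0.0, 100.0, 2) == 0.0

    def test_singular_at_origin(self):
        with pytest.raises(SingularKernelError):
            kernel_value(0.0, 0.0, 100.0, 2)

    @pytest.mark.parametrize("dim,tau", [(2, 0.5), (2, 3.0), (3, 1.0)])
    def test_mass_normalization(self, dim, tau):
        # integrate the kernel over all space by radial quadrature
        D = 100.0
        surf = 2 * np.pi if dim == 2 else 4 * np.pi

        def f(r):
            return surf * r ** (dim - 1) * kernel_value(r, tau, D, dim)

        mass, _ = integrate.quad(f, 0, np.inf, limit=200)
        assert mass == pytest.approx(1.0, rel=1e-8)


class TestTail:
    def test_2d_zero_at_switch(self):
        p = FieldParams(t_star=1.0)
        assert tail_integral(1.0, 0.0, p, 2) == 0.0

    def test_2d_log_value(self):
        p = FieldParams(t_star=1.0)
        assert tail_integral(np.e, 0.0, p, 2) == pytest.approx(
            2.0 / (400.0 * np.pi))

    def test_3d_long_time_limit(self):
        p = FieldParams(t_star=1.0)
        assert tail_integral(1e14, 0.0, p, 3) == pytest.approx(
            2.0 / (200.0 * np.pi), rel=1e-6)

    def test_contract_violation(self):
        p = FieldParams(t_star=10.0)
        with pytest.raises(ValueError):
            tail_integral(5.0, 0.0, p, 2)


class TestConcentration:
    def test_no_traces_is_zero(self):
        p = FieldParams()
        assert concentration(np.zeros(2), 10.0, [], p, 2) == 0.0

    def test_3d_stationary_source_steady_state(self):
        # gamma/(4 pi D r) for a long-lived motionless source
        p = FieldParams(dt_quad=1e-4, t_star=1e9, t_tilde=1e9)
        t = 1.0e4
        tr = stationary_trace(3, t, taus=np.geomspace(1e-4, t, 6000))
        c = concentration(np.array([10.0, 0.0, 0.0]), t, [tr], p, 3)
        assert c == pytest.approx(2.0 / (4.0 * np.pi * 100.0 * 10.0), rel=0.01)

    def test_gradient_points_at_source_with_steady_magnitude(self):
        p = FieldParams(dt_quad=1e-4, t_star=1e9, t_tilde=1e9)
        t = 1.0e4
        tr = stationary_trace(3, t, taus=np.geomspace(1e-4, t, 6000))
        g = concentration_gradient(np.array([10.0, 0.0, 0.0]), t, [tr], p, 3)
        # toward the source (negative x) with magnitude gamma/(4 pi D r^2)
        assert g[0] < 0
        assert np.linalg.norm(g) == pytest.approx(
            2.0 / (4.0 * np.pi * 100.0 * 100.0), rel=0.02)

    def test_midpoint_of_two_identical_sources_has_zero_gradient(self):
        p = FieldParams(dt_quad=0.5, t_star=1e9, t_tilde=1e9)
        a = stationary_trace(2, 50.0, spacing=0.5, origin=[-8.0, 0.0])
        a.cell_id = 1
        b = stationary_trace(2, 50.0, spacing=0.5, origin=[8.0, 0.0])
        b.cell_id = 2
        g = concentration_gradient(np.zeros(2), 50.0, [a, b], p, 2)
        assert np.linalg.norm(g) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        # two moving sources kept away from the probe point
        p = FieldParams(dt_quad=0.5, t_star=1e9, t_tilde=1e9)
        rng = np.random.default_rng(7)
        traces = []
        for k, x0 in enumerate(([12.0, 0.0], [0.0, 14.0])):
            tr = SourceTrace(cell_id=k, tau_B=0.0)
            s = np.arange(0.0, 40.001, 0.5)
            wiggle = np.cumsum(rng.normal(0, 0.05, (len(s), 2)), axis=0)
            tr.times = list(s)
            tr.positions = list(np.asarray(x0) + wiggle)
            traces.append(tr)
        x = np.array([-5.0, -4.0])
        g = concentration_gradient(x, 40.0, traces, p, 2)
        eps = 1e-3
        fd = np.array([
            (concentration(x + eps * e, 40.0, traces, p, 2)
             - concentration(x - eps * e, 40.0, traces, p, 2)) / (2 * eps)
            for e in np.eye(2)
        ])
        assert np.abs(g - fd).max() <= 1e-6 * np.abs(fd).max()

    def test_dead_source_contribution_decreases_monotonically(self):
        p = FieldParams(dt_quad=0.25, t_star=1e9, t_tilde=1e9)
        tr = stationary_trace(2, 20.0, spacing=0.25)
        tr.tau_D = 20.0
        x = np.array([5.0, 0.0])
        times = np.arange(21.0, 60.0, 2.0)
        vals = [concentration(x, t, [tr], p, 2) for t in times]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v > 0 for v in vals)

    def test_dead_source_dropped_after_t_tilde(self):
        p = FieldParams(dt_quad=0.25, t_star=1e9, t_tilde=80.0)
        tr = stationary_trace(2, 20.0, spacing=0.25)
        tr.tau_D = 20.0
        x = np.array([5.0, 0.0])
        assert concentration(x, 99.9, [tr], p, 2) > 0
        assert concentration(x, 100.1, [tr], p, 2) == 0.0

    def test_trapezoid_close_to_fine_quadrature_oracle(self):
        # 2-leg piecewise trace vs scipy.quad on the interpolated path
        p = FieldParams(dt_quad=0.1, t_star=1e9, t_tilde=1e9)
        tr = SourceTrace(cell_id=0, tau_B=0.0)
        s = np.arange(0.0, 20.001, 0.1)
        pos = np.where(s[:, None] < 10.0,
                       np.array([[0.0, 0.0]]), np.array([[6.0, 0.0]]))
        tr.times = list(s)
        tr.positions = list(pos.astype(float))
        x = np.array([0.0, 9.0])
        t = 20.0
        D = p.D

        def integrand(sv):
            xs = np.array([np.interp(sv, s, pos[:, 0]), 0.0])
            r = np.linalg.norm(x - xs)
            tau = t - sv
            return p.gamma * np.exp(-r * r / (4 * D * tau)) / (4 * np.pi * D * tau)

        oracle, _ = integrate.quad(integrand, 0.0, t - 1e-9, limit=500,
                                   points=[10.0])
        ours = concentration(x, t, [tr], p, 2)
        assert ours == pytest.approx(oracle, rel=0.01)

    def test_refinement_convergence_second_order(self):
        # halving the node spacing shrinks the error ~4x on a smooth
        # (closed) trace, where no moving-endpoint cutoff interferes
        t_dead = 30.0
        t_eval = 31.0
        x = np.array([9.0, 2.0])

        def value(spacing):
            p = FieldParams(dt_quad=spacing, t_star=1e9, t_tilde=1e9)
            tr = SourceTrace(cell_id=0, tau_B=0.0)
            s = np.arange(0.0, t_dead + 1e-9, spacing)
            tr.times = list(s)
            tr.positions = [np.array([np.sin(0.1 * v), 0.0]) for v in s]
            tr.tau_D = t_dead
            return concentration(x, t_eval, [tr], p, 2)

        ref = value(0.0125)
        e1 = abs(value(0.4) - ref)
        e2 = abs(value(0.2) - ref)
        assert e2 < e1 / 3.0

    def test_mass_accounting_single_source(self):
        # spatial integral of the field equals gamma * (time alive)
        t = 1.0
        p = FieldParams(dt_quad=1e-6, t_star=1e9, t_tilde=1e9)
        tr = stationary_trace(2, t, taus=np.geomspace(1e-6, t, 3000))
        rr = np.linspace(1e-3, 60.0, 800)
        cv = np.array([concentration(np.array([r, 0.0]), t, [tr], p, 2)
                       for r in rr])
        mass = np.trapezoid(2 * np.pi * rr * cv, rr)
        assert mass == pytest.approx(p.gamma * t, rel=0.01)

    def test_positivity(self):
        p = FieldParams()
        tr = stationary_trace(2, 100.0, spacing=5.0)
        for pt in ([3.0, 4.0], [-20.0, 1.0], [0.3, 0.0]):
            assert concentration(np.asarray(pt), 100.0, [tr], p, 2) >= 0.0


class TestTraces:
    def test_samples_monotone_and_closed_traces_immutable(self):
        tr = SourceTrace(cell_id=5, tau_B=0.0)
        tr.record(0.0, np.zeros(2))
        tr.record(1.0, np.ones(2))
        with pytest.raises(ValueError):
            tr.record(0.5, np.zeros(2))
        tr.close(2.0, np.ones(2))
        with pytest.raises(ValueError):
            tr.record(3.0, np.zeros(2))

    def test_store_round_trip(self):
        store = TraceStore()
        store.open(1, 0.0, np.zeros(2))
        store.record(1, 5.0, np.ones(2))
        store.open(2, 3.0, np.array([1.0, -1.0]))
        store.close(2, 4.0, np.array([1.5, -1.0]))
        back = TraceStore.from_records(store.to_records())
        assert len(back) == 2
        assert back[2].closed and back[2].tau_D == 4.0
        assert not back[1].closed
        np.testing.assert_allclose(back[1].positions, store[1].positions)
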