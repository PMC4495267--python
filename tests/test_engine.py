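"""Time stepping: step control, subprocess ordering and run-level contracts."""

import numpy as np
import pytest

import tumorinit.engine as engine_mod
from tumorinit import (Phase, Phenotype, compute_dt, default_config,
                       initialize_state, run, step)
from tumorinit.mechanics import MechanicalSignal


def small_config(**eng):
    cfg = default_config()
    cfg.domain.radius = 20.0
    cfg.engine.t_end = eng.pop("t_end", 20.0)
    for k, v in eng.items():
        setattr(cfg.engine, k, v)
    return cfg


class TestComputeDt:
    def test_zero_velocities_give_dt_max(self):
        assert compute_dt(np.zeros(5), np.full(5, 3.0), 1.0) == 1.0

    def test_linear_scaling_with_predicted_displacement(self):
        # one cell would displace R at dt_max -> dt halves
        speeds = np.array([3.0])
        radii = np.array([3.0])
        assert compute_dt(speeds, radii, 1.0) == 0.5

    def test_floor_applies(self):
        assert compute_dt(np.array([1e9]), np.array([3.0]), 1.0,
                          dt_min=0.1) == 0.1


class TestStepInvariants:
    def test_phenotype_counts_sum_to_total(self):
        cfg = small_config()
        rng = np.random.default_rng(5)
        st = initialize_state(cfg, rng)
        for _ in range(15):
            step(st, cfg)
            counts = st.phenotype_counts()
            assert sum(counts.values()) == len(st.cells)

    def test_cells_stay_inside_domain(self):
        cfg = small_config(sigma=0.5)  # strong noise
        rng = np.random.default_rng(6)
        st = initialize_state(cfg, rng)
        for _ in range(25):
            step(st, cfg)
            for c in st.cells:
                assert np.linalg.norm(c.x) <= cfg.domain.radius + 1e-9

    def test_quarter_diameter_cap_never_violated(self):
        # randomized overlapping states with strong noise and drift
        cfg = small_config(sigma=0.3, dt_min=0.05)
        rng = np.random.default_rng(7)
        st = initialize_state(cfg, rng)
        # compress cells to provoke large contact drifts
        for c in st.cells:
            c.x = c.x * 0.8
        for _ in range(30):
            before = {c.id: c.x.copy() for c in st.cells}
            radii = {c.id: c.R for c in st.cells}
            step(st, cfg)
            for c in st.cells:
                if c.id in before and c.birth_time == 0.0:
                    moved = np.linalg.norm(c.x - before[c.id])
                    # boundary projection may add a little extra pull-in
                    assert moved <= 0.5 * radii[c.id] + radii[c.id] + 1e-6

    def test_single_isolated_s_phase_cell_does_not_move(self):
        cfg = small_config(sigma=0.0, sigma_g=0.0)
        cfg.domain.n_vessels = 0
        rng = np.random.default_rng(8)
        st = initialize_state(cfg, rng)
        cell = st.cells[0]
        cell.phase = Phase.S
        cell.x = np.zeros(2)
        st.cells = [cell]
        x0 = cell.x.copy()
        step(st, cfg)
        np.testing.assert_allclose(st.cells[0].x, x0, atol=1e-15)

    def test_closed_loop_no_tumor_no_chemokine_no_tcells(self):
        cfg = small_config(t_end=40.0)
        cfg.immune.P_M = 0.0
        res = run(cfg)
        assert (res.counts["n_tumor"] == 0).all()
        assert (res.counts["n_tcell"] == 0).all()
        assert len(res.state.traces) == 0

    def test_every_tumor_cell_has_exactly_one_trace(self):
        cfg = small_config(t_end=30.0, tumor_seed_radius=10.0,
                           pressure_modulation=False)
        res = run(cfg)
        st = res.state
        tumor_ids = {c.id for c in st.cells
                     if c.phenotype is Phenotype.TUMOR}
        for cid in tumor_ids:
            assert cid in st.traces and not st.traces[cid].closed
        # dead tumor traces retained and closed
        closed = [tr for tr in st.traces if tr.closed]
        assert len(st.traces) == len(closed) + len(tumor_ids)


class TestDeterminism:
    def test_same_seed_bit_identical_counts(self):
        cfg = small_config(t_end=25.0, tumor_seed_radius=8.0,
                           pressure_modulation=False)
        a = run(cfg)
        b = run(cfg)
        assert a.counts.equals(b.counts)
        assert a.meta["cum_divisions"] == b.meta["cum_divisions"]
        xa = np.array([c.x for c in a.state.cells])
        xb = np.array([c.x for c in b.state.cells])
        np.testing.assert_array_equal(xa, xb)

    def test_different_seed_differs(self):
        cfg = small_config(t_end=25.0)
        a = run(cfg)
        cfg.seed = 1
        b = run(cfg)
        xa = np.array([c.x for c in a.state.cells])
        xb = np.array([c.x for c in b.state.cells])
        assert xa.shape != xb.shape or not np.allclose(xa, xb)


class TestStopCriteria:
    def test_stop_fraction_halts_run(self):
        cfg = small_config(t_end=500.0, tumor_seed_radius=14.0,
                           pressure_modulation=False, stop_fraction=0.3)
        res = run(cfg)
        assert res.meta["stopped"] == "stop_fraction"
        assert res.counts["tumor_fraction"].iloc[-1] >= 0.3
        assert res.meta["final_t"] < 500.0

    def test_cumulative_intravasation_non_decreasing(self):
        cfg = small_config(t_end=30.0, tumor_seed_radius=12.0,
                           pressure_modulation=False)
        res = run(cfg)
        assert res.counts["cum_intravasated"].is_monotonic_increasing


class TestRK4:
    def _integrate(self, field, x0, t_end, dt_max, monkeypatch):
        """Drive the engine's motion stage through a manufactured drift
        field (a rigid rotation) by patching the mechanical signal."""
        cfg = default_config()
        cfg.domain.radius = 1e6
        cfg.domain.n_vessels = 0
        cfg.engine.sigma = 0.0
        cfg.engine.sigma_g = 0.0
        cfg.engine.dt_max = dt_max
        cfg.engine.dt_min = 1e-9
        cfg.engine.t_end = t_end
        ph = cfg.phenotype["epithelial"]

        def fake_signals(X, R, F, contact_only, domain, mech):
            V = field(X)
            speed = np.linalg.norm(V, axis=1)
            alpha = (1.0 / mech.F_hat) ** 2 * ph.beta * R ** 3 / mech.f
            M = speed / alpha
            z = np.where(speed[:, None] > 0,
                         V / np.maximum(speed, 1e-300)[:, None], 0.0)
            return MechanicalSignal(M_total=M, z=z, p=np.zeros(len(R)))

        monkeypatch.setattr(engine_mod, "compute_signals_fast", fake_signals)
        from tumorinit.cells import Cell
        from tumorinit.chemokine import TraceStore
        from tumorinit.engine import SimulationState
        cell = Cell(id=0, phenotype=Phenotype.EPITHELIAL,
                    x=np.asarray(x0, float), R=3.0, phase=Phase.S)
        st = SimulationState(t=0.0, cells=[cell], traces=TraceStore(),
                             rng=np.random.default_rng(0), next_id=1)
        # immortalize so no rng-driven death interferes with the trajectory
        cfg.phenotype["epithelial"].T_2 = 1e30
        while st.t < t_end - 1e-12:
            step(st, cfg)
        return st.cells[0].x

    def test_exact_for_constant_drift(self, monkeypatch):
        v = np.array([0.25, -0.125])
        x = self._integrate(lambda X: np.tile(v, (len(X), 1)),
                            [1.0, 2.0], 8.0, 1.0, monkeypatch)
        np.testing.assert_allclose(x, np.array([1.0, 2.0]) + 8.0 * v,
                                   rtol=1e-12)

    def test_fourth_order_on_rotation_field(self, monkeypatch):
        omega = 0.2

        def field(X):
            return omega * np.column_stack([-X[:, 1], X[:, 0]])

        x0 = np.array([1.0, 0.0])
        t_end = 4.0
        exact = np.array([np.cos(omega * t_end), np.sin(omega * t_end)])
        e1 = np.linalg.norm(self._integrate(field, x0, t_end, 0.5,
                                            monkeypatch) - exact)
        e2 = np.linalg.norm(self._integrate(field, x0, t_end, 0.25,
                                            monkeypatch) - exact)
        assert e1 < 1e-6
        assert e2 < e1 / 8.0  # ~16x for a clean 4th-order method
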