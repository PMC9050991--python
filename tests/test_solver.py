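"""Electro-thermal solver against closed-form oracles and physical invariants."""

import numpy as np
import pytest

from rfablate import (
    AblationProtocol,
    ElectroThermalSolver,
    PIController,
    SolverConfig,
    build_annulus_mesh,
    build_block_mesh,
    default_material_table,
)

TABLE = default_material_table()


@pytest.fixture(scope="module")
def annulus():
    mesh = build_annulus_mesh(1.0, 50.0, 10.0, edge_mm=1.0, grade_inner_mm=0.1)
    return mesh, ElectroThermalSolver(mesh)


class TestPotential:
    V0 = 20.0
    A_M, B_M, L_M = 1e-3, 50e-3, 10e-3

    def test_matches_log_potential(self, annulus):
        """Concentric-cylinder oracle: V(r) = V0 ln(b/r) / ln(b/a)."""
        mesh, solver = annulus
        sigma = np.full(mesh.n_cells, 0.5)
        V = solver.solve_potential(sigma, self.V0)
        exact = self.V0 * np.log(self.B_M / mesh.points[:, 0]) / np.log(self.B_M / self.A_M)
        assert np.max(np.abs(V - exact)) / self.V0 < 0.01

    def test_zero_voltage_gives_zero_field(self, annulus):
        mesh, solver = annulus
        V = solver.solve_potential(np.full(mesh.n_cells, 0.5), 0.0)
        assert np.all(V == 0.0)

    def test_scale_invariance_in_conductivity(self, annulus):
        mesh, solver = annulus
        V1 = solver.solve_potential(np.full(mesh.n_cells, 0.5), self.V0)
        V2 = solver.solve_potential(np.full(mesh.n_cells, 1.0), self.V0)
        assert np.allclose(V1, V2, atol=1e-10)

    def test_discrete_maximum_principle(self, annulus):
        mesh, solver = annulus
        V = solver.solve_potential(np.full(mesh.n_cells, 0.5), self.V0)
        assert V.min() >= -1e-9 and V.max() <= self.V0 + 1e-9

    def test_joule_power_matches_closed_form(self, annulus):
        """P = 2 pi L sigma V0^2 / ln(b/a)."""
        mesh, solver = annulus
        sigma = np.full(mesh.n_cells, 0.5)
        V = solver.solve_potential(sigma, self.V0)
        q = solver.joule_heating(V, sigma)
        exact = 2 * np.pi * self.L_M * 0.5 * self.V0**2 / np.log(self.B_M / self.A_M)
        assert solver.total_power(q) == pytest.approx(exact, rel=0.01)
        assert np.all(q >= 0.0)

    def test_joule_quadratic_in_voltage(self, annulus):
        mesh, solver = annulus
        sigma = np.full(mesh.n_cells, 0.5)
        V = solver.solve_potential(sigma, self.V0)
        q1 = solver.joule_heating(V, sigma)
        q2 = solver.joule_heating(2.0 * V, sigma)
        assert np.allclose(q2, 4.0 * q1, rtol=1e-12)

    def test_zero_potential_gives_zero_heating(self, annulus):
        mesh, solver = annulus
        q = solver.joule_heating(np.zeros(mesh.n_nodes), np.full(mesh.n_cells, 0.5))
        assert np.all(q == 0.0)


class TestThermalStep:
    def test_equilibrium_preserved(self):
        """No source, uniform 37 C: the state must not drift at all."""
        mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=1.0, region="tumour")
        solver = ElectroThermalSolver(mesh, TABLE)
        T = np.full(mesh.n_nodes, 37.0)
        T_new, audit = solver.advance_temperature(
            T, np.zeros(mesh.n_nodes), np.zeros(mesh.n_cells), 0.5
        )
        assert np.allclose(T_new, 37.0, atol=1e-12)
        assert abs(audit["dH_J"]) < 1e-9

    @pytest.mark.parametrize("mode", ["axisymmetric_2d", "full_3d"])
    def test_uniform_heating_of_insulated_block(self, mode):
        """Lumped ODE oracle: dT/dt = Q / (rho c) for an insulated block."""
        mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=2.0, region="tumour", mode=mode)
        solver = ElectroThermalSolver(mesh, TABLE)
        Q = 1e6
        T = np.full(mesh.n_nodes, 37.0)
        omega = np.zeros(mesh.n_nodes)
        for _ in range(10):
            T, _ = solver.advance_temperature(T, omega, np.full(mesh.n_cells, Q), 0.5)
        rho_c = 1150.0 * 3664.0
        expected = 37.0 + Q * 5.0 / rho_c
        assert np.max(np.abs(T - expected)) / (expected - 37.0) < 0.005

    # perfusion decay rate of muscle: omega rho_b c_b / (rho c), about 1/148 s
    MUSCLE_RATE = 6.6167e-3 * 1050.0 * 3617.0 / (1090.0 * 3421.0)

    def test_perfused_block_relaxes_to_body_temperature(self):
        """No source, perfusion on: uniform decay matches the scalar
        backward-Euler recurrence T_n = 37 + 10 / (1 + rate dt)^n."""
        mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=2.0, region="muscle")
        solver = ElectroThermalSolver(mesh, TABLE)
        T = np.full(mesh.n_nodes, 47.0)
        omega = np.zeros(mesh.n_nodes)
        dt, n = 4.0, 20
        prev_max = T.max()
        for _ in range(n):
            T, _ = solver.advance_temperature(T, omega, np.zeros(mesh.n_cells), dt)
            assert T.max() <= prev_max + 1e-12
            assert T.min() >= 37.0 - 1e-9
            prev_max = T.max()
        expected = 37.0 + 10.0 / (1.0 + self.MUSCLE_RATE * dt) ** n
        assert T.max() == pytest.approx(expected, rel=1e-6)

    def test_dead_tissue_stops_cooling(self):
        """Perfusion shuts off where Omega exceeds the death threshold."""
        mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=2.0, region="muscle")
        solver = ElectroThermalSolver(mesh, TABLE)
        T0 = np.full(mesh.n_nodes, 47.0)
        dead = np.full(mesh.n_nodes, 5.0)
        alive = np.zeros(mesh.n_nodes)
        T_dead, _ = solver.advance_temperature(T0.copy(), dead, np.zeros(mesh.n_cells), 1.0)
        T_alive, _ = solver.advance_temperature(T0.copy(), alive, np.zeros(mesh.n_cells), 1.0)
        assert np.allclose(T_dead, 47.0, atol=1e-9)   # insulated + no sink
        expected = 37.0 + 10.0 / (1.0 + self.MUSCLE_RATE)
        assert T_alive.max() == pytest.approx(expected, rel=1e-6)


class TestClosedLoopInvariants:
    def test_energy_bookkeeping_within_one_percent(self, short_coarse_run):
        """Per step: dH = dt (sum Q_RF - sum Q_p - boundary outflux) to 1 %."""
        audits = short_coarse_run["result"].energy_audits
        assert len(audits) > 50
        for a in audits:
            scale = max(abs(a["dH_J"]), abs(a["source_J"]), 1e-9)
            assert abs(a["imbalance_J"]) / scale < 0.01

    def test_damage_and_lesion_volume_monotone(self, short_coarse_run):
        df = short_coarse_run["result"].summary
        assert (np.diff(df["lesion_volume_mm3"].to_numpy()) >= -1e-9).all()
        snaps = short_coarse_run["result"].snapshots
        for s0, s1 in zip(snaps[:-1], snaps[1:]):
            assert np.all(s1.omega >= s0.omega - 1e-12)

    def test_potential_bounded_by_electrode_voltage(self, short_coarse_run):
        df = short_coarse_run["result"].summary
        final = short_coarse_run["result"].final
        v_applied = df["v_rms_V"].iloc[-1]
        assert final.V.min() >= -1e-6
        assert final.V.max() <= v_applied * (1 + 1e-6)

    def test_hottest_point_near_electrode_not_outer_boundary(self, short_coarse_run):
        mesh = short_coarse_run["result"].mesh
        T = short_coarse_run["result"].final.T_C
        hot = mesh.points[np.argmax(T)]
        assert hot[0] < 5e-3  # within 5 mm of the axis
        outer = mesh.boundary_nodes("outer_muscle")
        assert np.argmax(T) not in outer
        assert np.allclose(T[outer], 37.0, atol=1e-9)

    def test_temperature_never_below_body(self, short_coarse_run):
        assert short_coarse_run["result"].final.T_C.min() >= 37.0 - 1e-6

    def test_zero_duration_protocol_returns_initial_state(self, coarse_mesh):
        solver = ElectroThermalSolver(coarse_mesh)
        res = solver.simulate(AblationProtocol(30.0, 0.0, 0.0))
        assert len(res.summary) == 0
        assert res.final.t_s == 0.0
        assert np.all(res.final.T_C == 37.0)

    def test_simulation_is_deterministic(self, coarse_mesh):
        proto = AblationProtocol.from_minutes(3, 1.0, 0.75)
        r1 = ElectroThermalSolver(coarse_mesh).simulate(proto, PIController())
        r2 = ElectroThermalSolver(coarse_mesh).simulate(proto, PIController())
        assert np.array_equal(r1.final.omega, r2.final.omega)
        assert np.array_equal(r1.final.T_C, r2.final.T_C)
        assert r1.summary.equals(r2.summary)


def test_substepping_respects_temperature_increment_limit():
    """A violent source is integrated through automatic sub-stepping."""
    mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=2.0, region="tumour")
    solver = ElectroThermalSolver(
        mesh, TABLE, SolverConfig(dt_s=0.5, max_dT_per_step_C=5.0)
    )
    rho_c = 1150.0 * 3664.0
    Q = 40.0 * rho_c  # 40 K/s adiabatic heating rate
    T = np.full(mesh.n_nodes, 37.0)
    T_new, audit = solver.advance_temperature(
        T, np.zeros(mesh.n_nodes), np.full(mesh.n_cells, Q), 0.5
    )
    assert np.max(T_new) == pytest.approx(57.0, rel=0.005)  # 20 K in one control step
    scale = max(abs(audit["dH_J"]), abs(audit["source_J"]))
    assert abs(audit["imbalance_J"]) / scale < 0.01
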