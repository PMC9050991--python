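"""Coupled quasi-static electrical / enthalpy-form bioheat solver.

Each control step runs a staggered update on the labelled mesh:

1. the PI controller turns the tip-temperature error into the RMS electrode
   voltage;
2. the quasi-static potential ``div(sigma(T) grad V) = 0`` is solved with
   Dirichlet values on the electrode surface and the grounded outer muscle
   boundary (Galerkin P1, axisymmetric 2*pi*r weighting where applicable);
3. the Joule source ``Q_RF = sigma |grad V|^2`` is evaluated per element;
4. one backward-Euler step of the enthalpy-form Pennes equation
   ``dh/dt = div(k(T) grad T) + Q_RF - Q_p`` advances the temperature, with
   the phase change handled through a secant (chord) apparent heat capacity
   iterated to consistency, the perfusion sink gated by the local damage,
   and automatic sub-stepping when a step moves any node more than a
   configured temperature increment;
5. the Arrhenius damage integral accumulates nodally.

Coefficients are evaluated element-wise at the element-mean temperature
(one-point quadrature, piecewise-constant Q_RF), lagged within the Picard
iteration.  Everything is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import tissues as tis
from .control import AblationProtocol, PIController
from .damage import ArrheniusParams, damage_increment
from .geometry import Mesh

MM = 1e-3


class SolverError(RuntimeError):
    """Linear-solver or time-stepping failure."""


@dataclass
class SolverConfig:
    """Numerical knobs of the time integrator (seconds / °C)."""

    dt_s: float = 0.5
    max_dT_per_step_C: float = 5.0
    picard_tol_C: float = 1e-3
    max_picard_iter: int = 30
    max_substep_depth: int = 10
    output_every_s: float = 30.0
    reach_60_timeout_s: float = 600.0
    initial_T_C: float = 37.0

    def validate(self) -> None:
        if self.dt_s <= 0 or self.picard_tol_C <= 0:
            raise ValueError("dt_s and picard_tol_C must be positive")
        if self.max_dT_per_step_C <= 0:
            raise ValueError("max_dT_per_step_C must be positive")


@dataclass
class FieldState:
    """Nodal and element fields at one time instant."""

    t_s: float
    V: np.ndarray          # nodal RMS potential, volts
    T_C: np.ndarray        # nodal temperature
    h: np.ndarray          # nodal lumped enthalpy density surrogate (J)
    omega: np.ndarray      # nodal Arrhenius damage
    q_rf: np.ndarray       # element Joule source, W/m^3
    q_p: np.ndarray        # element perfusion sink, W/m^3


@dataclass
class SimulationResult:
    """Per-step summary, snapshots at the output cadence, and the final state."""

    mesh: Mesh
    summary: pd.DataFrame
    snapshots: list
    final: FieldState
    protocol: AblationProtocol
    reached_60_at_s: float | None
    energy_audits: list = field(default_factory=list)


class ElectroThermalSolver:
    """Assembles and advances the coupled problem on one labelled mesh."""

    def __init__(
        self,
        mesh: Mesh,
        materials: tis.MaterialTable | None = None,
        config: SolverConfig | None = None,
        damage_params: ArrheniusParams | None = None,
    ):
        self.mesh = mesh
        self.materials = materials or tis.default_material_table()
        self.materials.validate(required=tuple(mesh.present_regions()))
        self.config = config or SolverConfig()
        self.config.validate()
        self.damage = damage_params or ArrheniusParams()
        self._precompute()

    # ------------------------------------------------------------------ setup
    def _precompute(self) -> None:
        mesh = self.mesh
        pts, cells = mesh.points, mesh.cells
        npc = cells.shape[1]
        p = pts[cells]

        if mesh.dim == 2:
            meas = 0.5 * np.abs(
                (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
            )
            # P1 gradients: grad phi_i constant per triangle
            b = np.stack(
                [p[:, 1, 1] - p[:, 2, 1], p[:, 2, 1] - p[:, 0, 1], p[:, 0, 1] - p[:, 1, 1]],
                axis=1,
            )
            cc = np.stack(
                [p[:, 2, 0] - p[:, 1, 0], p[:, 0, 0] - p[:, 2, 0], p[:, 1, 0] - p[:, 0, 0]],
                axis=1,
            )
            grads = np.stack([b, cc], axis=2) / (2 * meas)[:, None, None]
        else:
            d = p[:, 1:] - p[:, :1]
            meas = np.abs(np.einsum("ij,ij->i", np.cross(d[:, 0], d[:, 1]), d[:, 2])) / 6.0
            grads = np.empty((len(cells), 4, 3))
            for i in range(4):
                others = [j for j in range(4) if j != i]
                e1 = p[:, others[1]] - p[:, others[0]]
                e2 = p[:, others[2]] - p[:, others[0]]
                n = np.cross(e1, e2)
                # orient towards node i, scale so grad phi_i . (x_i - x_o) = 1
                dot = np.einsum("ij,ij->i", n, p[:, i] - p[:, others[0]])
                grads[:, i] = n / dot[:, None]

        self.cell_weight = mesh.cell_volumes()          # physical volume per cell
        self.node_weight = mesh.node_cell_weights()     # (ne, npc) lumped shares
        self.grads = grads
        # stiffness scatter pattern: G[e, i, j] = grad_i . grad_j * weight_e
        self.G = np.einsum("eid,ejd->eij", grads, grads) * self.cell_weight[:, None, None]
        self.Krow = np.repeat(cells, npc, axis=1).ravel()
        self.Kcol = np.tile(cells, npc).ravel()

        n = mesh.n_nodes
        self.n_nodes = n
        self.Mvec = np.zeros(n)
        np.add.at(self.Mvec, cells.ravel(), self.node_weight.ravel())
        # per-node region-resolved lumped volumes (shared interface nodes split
        # their control volume between the adjacent regions)
        n_reg = len(mesh.region_names)
        self.Wreg = np.zeros((n, n_reg))
        for r in range(n_reg):
            sel = mesh.cell_regions == r
            if sel.any():
                np.add.at(
                    self.Wreg[:, r], cells[sel].ravel(), self.node_weight[sel].ravel()
                )
        gc = self.materials.constants
        self.pvec = np.zeros(n)  # W/K per node while alive
        for r, name in enumerate(mesh.region_names):
            if name in self.materials.tissues:
                w = self.materials[name].perfusion_per_s
                self.pvec += self.Wreg[:, r] * w * gc.rho_blood_kg_per_m3 * gc.c_blood_J_per_kgK

        self.electrode_nodes = mesh.boundary_nodes("electrode_surface")
        self.outer_nodes = mesh.boundary_nodes("outer_muscle")
        self._pot_dirichlet = np.union1d(self.electrode_nodes, self.outer_nodes)
        self._pot_free = np.setdiff1d(np.arange(n), self._pot_dirichlet)
        self._th_dirichlet = self.outer_nodes
        self._th_free = np.setdiff1d(np.arange(n), self._th_dirichlet)
        self.region_of_cell = mesh.cell_regions

    # ------------------------------------------------------- small utilities
    def element_mean(self, nodal: np.ndarray) -> np.ndarray:
        return nodal[self.mesh.cells].mean(axis=1)

    def _assemble(self, coef_e: np.ndarray) -> sp.csr_matrix:
        data = (coef_e[:, None, None] * self.G).ravel()
        return sp.coo_matrix((data, (self.Krow, self.Kcol)), shape=(self.n_nodes,) * 2).tocsr()

    def _solve_dirichlet(self, A: sp.csr_matrix, b: np.ndarray, dir_nodes, dir_vals, free):
        vals = np.broadcast_to(np.asarray(dir_vals, dtype=float), (len(dir_nodes),))
        x = np.zeros(self.n_nodes)
        x[dir_nodes] = vals
        Afd = A[free]
        rhs = b[free] - Afd[:, dir_nodes] @ vals
        Aff = Afd[:, free].tocsc()
        try:
            x[free] = spla.spsolve(Aff, rhs)
        except Exception as exc:  # pragma: no cover
            raise SolverError(f"sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(x)):
            raise SolverError("singular or ill-conditioned system (non-finite solution)")
        return x

    def sigma_elements(self, T_nodal: np.ndarray) -> np.ndarray:
        """Element electrical conductivity at the element-mean temperature."""
        Te = self.element_mean(T_nodal)
        out = np.empty(len(Te))
        for r, name in enumerate(self.mesh.region_names):
            sel = self.region_of_cell == r
            if sel.any():
                out[sel] = tis.electrical_conductivity(
                    self.materials[name], Te[sel], self.materials.constants
                )
        return out

    def k_elements(self, T_nodal: np.ndarray) -> np.ndarray:
        Te = self.element_mean(T_nodal)
        out = np.empty(len(Te))
        for r, name in enumerate(self.mesh.region_names):
            sel = self.region_of_cell == r
            if sel.any():
                out[sel] = tis.thermal_conductivity(self.materials[name], Te[sel])
        return out

    def _nodal_enthalpy(self, T: np.ndarray) -> np.ndarray:
        """Lumped enthalpy per node in joules: sum_r W[:, r] * h_r(T)."""
        H = np.zeros(self.n_nodes)
        for r, name in enumerate(self.mesh.region_names):
            if name in self.materials.tissues and self.Wreg[:, r].any():
                H += self.Wreg[:, r] * self.materials.h(name, T)
        return H

    def _nodal_capacity(self, T: np.ndarray) -> np.ndarray:
        C = np.zeros(self.n_nodes)
        for r, name in enumerate(self.mesh.region_names):
            if name in self.materials.tissues and self.Wreg[:, r].any():
                C += self.Wreg[:, r] * self.materials.dh_dT(name, T)
        return C

    # --------------------------------------------------------------- physics
    def solve_potential(self, sigma_e: np.ndarray, v_electrode: float) -> np.ndarray:
        """Quasi-static potential with V = v_electrode on the electrode surface."""
        if np.any(sigma_e <= 0):
            raise SolverError("element conductivities must be positive")
        if len(self.electrode_nodes) == 0 or len(self.outer_nodes) == 0:
            raise SolverError("potential problem needs electrode_surface and outer_muscle tags")
        if v_electrode == 0.0:
            return np.zeros(self.n_nodes)
        A = self._assemble(sigma_e)
        b = np.zeros(self.n_nodes)
        vals = np.zeros(len(self._pot_dirichlet))
        vals[np.isin(self._pot_dirichlet, self.electrode_nodes)] = v_electrode
        return self._solve_dirichlet(A, b, self._pot_dirichlet, vals, self._pot_free)

    def joule_heating(self, V: np.ndarray, sigma_e: np.ndarray) -> np.ndarray:
        """Element Q_RF = sigma |grad V|^2 (W/m^3)."""
        E = np.einsum("eid,ei->ed", self.grads, V[self.mesh.cells])
        return sigma_e * np.einsum("ed,ed->e", E, E)

    def total_power(self, q_rf: np.ndarray) -> float:
        return float((q_rf * self.cell_weight).sum())

    def advance_temperature(
        self,
        T: np.ndarray,
        omega: np.ndarray,
        q_rf: np.ndarray,
        dt: float,
        _depth: int = 0,
    ):
        """One backward-Euler step; returns (T_new, audit dict).

        Sub-steps recursively when the Picard iteration stalls or the step
        exceeds ``max_dT_per_step_C`` at any node.
        """
        cfg = self.config
        if dt <= 0:
            raise ValueError("dt must be positive")
        f = np.zeros(self.n_nodes)
        np.add.at(f, self.mesh.cells.ravel(), (q_rf[:, None] * self.node_weight).ravel())
        alive = omega < self.damage.omega_death
        pvec = self.pvec * alive
        Tb = self.materials.constants.T_blood_C
        H_old = self._nodal_enthalpy(T)

        T_star = T.copy()
        converged = False
        for _ in range(cfg.max_picard_iter):
            K = self._assemble(self.k_elements(T_star))
            dT = T_star - T
            C = np.where(
                np.abs(dT) > 1e-9,
                (self._nodal_enthalpy(T_star) - H_old) / np.where(np.abs(dT) > 1e-9, dT, 1.0),
                self._nodal_capacity(T_star),
            )
            C = np.maximum(C, 1e-12)
            A = K + sp.diags(C / dt + pvec)
            b = (C / dt) * T + pvec * Tb + f
            if len(self._th_dirichlet):
                T_new = self._solve_dirichlet(
                    A, b, self._th_dirichlet, cfg.initial_T_C, self._th_free
                )
            else:
                T_new = spla.spsolve(A.tocsc(), b)
                if not np.all(np.isfinite(T_new)):
                    raise SolverError("thermal solve produced non-finite values")
            if np.max(np.abs(T_new - T_star)) < cfg.picard_tol_C:
                T_star = T_new
                converged = True
                break
            T_star = T_new

        too_big = np.max(np.abs(T_star - T)) > cfg.max_dT_per_step_C
        if (not converged or too_big) and _depth < cfg.max_substep_depth:
            T_half, a1 = self.advance_temperature(T, omega, q_rf, dt / 2, _depth + 1)
            T_full, a2 = self.advance_temperature(T_half, omega, q_rf, dt / 2, _depth + 1)
            audit = _merge_audits(a1, a2)
            return T_full, audit
        if not converged:
            raise SolverError(
                f"thermal step did not converge at dt={dt:g}s "
                f"(max |dT| = {np.max(np.abs(T_star - T)):.2f} C)"
            )

        T_new = T_star
        # energy bookkeeping: dH = dt * (sources - perfusion - boundary outflux)
        dH = float((self._nodal_enthalpy(T_new) - H_old).sum())
        source = float(f.sum()) * dt
        perf = float((pvec * (T_new - Tb)).sum()) * dt
        K = self._assemble(self.k_elements(T_new))
        C = np.where(
            np.abs(T_new - T) > 1e-9,
            (self._nodal_enthalpy(T_new) - H_old) / np.where(np.abs(T_new - T) > 1e-9, T_new - T, 1.0),
            self._nodal_capacity(T_new),
        )
        resid = (K @ T_new) + (C / dt + pvec) * T_new - ((C / dt) * T + pvec * Tb + f)
        # Dirichlet-row reactions are the discrete boundary conduction flux;
        # the remaining imbalance is exactly the free-row (Picard) residual.
        outflux = -float(resid[self._th_dirichlet].sum()) * dt
        audit = {
            "dH_J": dH,
            "source_J": source,
            "perfusion_J": perf,
            "boundary_outflux_J": outflux,
            "imbalance_J": dH - (source - perf - outflux),
        }
        return T_new, audit

    # ------------------------------------------------------------ simulation
    def simulate(
        self,
        protocol: AblationProtocol,
        controller: PIController | None = None,
        tip_point=None,
        electrode=None,
        progress: bool = False,
    ) -> SimulationResult:
        """Run the full temperature-controlled protocol.

        ``tip_point`` overrides the temperature-sensing location (defaults
        to the node nearest the axial apex of the electrode tip).  With an
        :class:`~rfablate.geometry.ElectrodeInfo` passed as ``electrode``
        the per-step summary additionally logs the three lesion diameters.
        """
        mesh = self.mesh
        cfg = self.config
        ctrl = controller or PIController()
        dt = cfg.dt_s
        samplers = None
        if electrode is not None:
            from .lesion import make_measurement_samplers

            samplers = make_measurement_samplers(mesh, electrode)

        if tip_point is None:
            tip_point = self._default_tip_point()
        tip_node = int(np.argmin(np.linalg.norm(mesh.points - np.asarray(tip_point), axis=1)))

        T = np.full(self.n_nodes, cfg.initial_T_C)
        omega = np.zeros(self.n_nodes)
        V = np.zeros(self.n_nodes)
        q_rf = np.zeros(self.mesh.n_cells)
        q_p = np.zeros(self.mesh.n_cells)
        t = 0.0
        reached_60 = None

        def make_state(t):
            return FieldState(t, V.copy(), T.copy(), self._nodal_enthalpy(T), omega.copy(),
                              q_rf.copy(), q_p.copy())

        rows: list[dict] = []
        audits: list[dict] = []
        snapshots = [make_state(0.0)]
        if protocol.schedule_end_s <= 0:
            final = snapshots[0]
            return SimulationResult(mesh, pd.DataFrame(rows), snapshots, final, protocol, None)

        next_output = cfg.output_every_s
        dead_vol_mm3 = 0.0
        while True:
            if reached_60 is None:
                target = protocol.start_target_C
                if T[tip_node] >= protocol.start_target_C:
                    reached_60 = t
                elif t > cfg.reach_60_timeout_s:
                    raise SolverError(
                        f"tip failed to reach {protocol.start_target_C} C within "
                        f"{cfg.reach_60_timeout_s} s (tip T = {T[tip_node]:.1f} C)"
                    )
            if reached_60 is not None:
                target = protocol.target_temperature(t - reached_60)
                if target is None:
                    break

            v_el = ctrl.update(float(T[tip_node]), target, dt)
            sigma_e = self.sigma_elements(T)
            V = self.solve_potential(sigma_e, v_el) if v_el > 0 else np.zeros(self.n_nodes)
            q_rf = self.joule_heating(V, sigma_e)
            T, audit = self.advance_temperature(T, omega, q_rf, dt)
            omega = omega + damage_increment(T, dt, self.damage)
            q_p = self._element_perfusion(T, omega)
            t += dt

            dead = omega >= self.damage.omega_death
            dead_vol_mm3 = float(self.Mvec[dead].sum() / MM**3)
            audits.append(audit)
            row = {
                "t_s": t,
                "phase": "reach" if reached_60 is None else (
                    "ramp" if (t - reached_60) < protocol.ramp_s else "hold"
                ),
                "target_C": target,
                "v_rms_V": v_el,
                "tip_T_C": float(T[tip_node]),
                "max_T_C": float(T.max()),
                "power_W": self.total_power(q_rf),
                "lesion_volume_mm3": dead_vol_mm3,
            }
            if samplers is not None:
                from .lesion import measure_diameters

                m = measure_diameters(
                    mesh, omega, electrode, threshold=self.damage.omega_death,
                    samplers=samplers, volume_mm3=dead_vol_mm3,
                )
                row["d_longest_mm"] = m.longest_mm
                row["d_shortest_mm"] = m.shortest_mm
                row["d_other_mm"] = m.other_mm
            rows.append(row)
            if progress and len(rows) % 100 == 0:
                print(f"  t={t:7.1f}s target={target:5.1f}C tip={T[tip_node]:5.1f}C "
                      f"V={v_el:5.1f}V lesion={dead_vol_mm3:8.0f}mm3")
            if t >= next_output - 1e-9:
                snapshots.append(make_state(t))
                next_output += cfg.output_every_s

        final = make_state(t)
        if not snapshots or snapshots[-1].t_s < t:
            snapshots.append(final)
        return SimulationResult(
            mesh, pd.DataFrame(rows), snapshots, final, protocol, reached_60, audits
        )

    def _default_tip_point(self):
        """Axial apex of the electrode tip: lowest electrode node on the axis."""
        el_cells = self.mesh.cells_of("electrode")
        if len(el_cells) == 0:
            raise SolverError("mesh has no electrode region; pass tip_point explicitly")
        nodes = np.unique(self.mesh.cells[el_cells])
        pts = self.mesh.points[nodes]
        radial = pts[:, 0] if self.mesh.dim == 2 else np.hypot(pts[:, 0], pts[:, 1])
        score = radial / MM + (pts[:, -1] - pts[:, -1].min()) / MM * 1.0
        # prefer on-axis, lowest-z electrode nodes
        best = nodes[np.argmin(score)]
        return self.mesh.points[best]

    def _element_perfusion(self, T: np.ndarray, omega: np.ndarray) -> np.ndarray:
        gc = self.materials.constants
        Te = self.element_mean(T)
        alive_frac = (omega < self.damage.omega_death)[self.mesh.cells].mean(axis=1)
        out = np.zeros(self.mesh.n_cells)
        for r, name in enumerate(self.mesh.region_names):
            sel = self.region_of_cell == r
            if sel.any() and name in self.materials.tissues:
                w = self.materials[name].perfusion_per_s
                out[sel] = (
                    w * gc.rho_blood_kg_per_m3 * gc.c_blood_J_per_kgK
                    * (Te[sel] - gc.T_blood_C) * alive_frac[sel]
                )
        return out


def _merge_audits(a1: dict, a2: dict) -> dict:
    out = {k: a1[k] + a2[k] for k in a1}
    return out


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def solve_potential(mesh, sigma_field, v_electrode, materials=None):
    s = ElectroThermalSolver(mesh, materials)
    return s.solve_potential(np.asarray(sigma_field, dtype=float), v_electrode)


def joule_heating(mesh, V, sigma_field, materials=None):
    s = ElectroThermalSolver(mesh, materials)
    return s.joule_heating(np.asarray(V, dtype=float), np.asarray(sigma_field, dtype=float))


def simulate(mesh, materials, protocol, config=None, controller=None,
             damage_params=None, electrode=None):
    solver = ElectroThermalSolver(mesh, materials, config, damage_params)
    return solver.simulate(protocol, controller=controller, electrode=electrode)
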