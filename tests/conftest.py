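"""Shared fixtures: meshes and (expensive) closed-loop simulation runs."""

from __future__ import annotations

import numpy as np
import pytest

from rfablate import (
    AblationProtocol,
    ElectroThermalSolver,
    GeometrySpec,
    PIController,
    SolverConfig,
    build_synthetic_geometry,
    measure_diameters,
)

#: Coarse sizing for tests that only need topology/physics, not accuracy.
COARSE_EDGES = {
    "electrode": 0.5,
    "tumour": 3.0,
    "trabecular": 3.0,
    "cortical": 2.5,
    "muscle": 10.0,
}

#: Reduced convergence-study sizing (between coarse and default).
STUDY_EDGES = {
    "electrode": 0.5,
    "tumour": 3.0,
    "trabecular": 3.0,
    "cortical": 2.5,
    "muscle": 10.0,
}

#: Short protocol for the discretisation study: 2 min over 60 C, 1.5 min at 90 C.
STUDY_PROTOCOL = AblationProtocol.from_minutes(3, 2.0, 1.5)


@pytest.fixture(scope="session")
def default_spec() -> GeometrySpec:
    return GeometrySpec()


@pytest.fixture(scope="session")
def default_mesh(default_spec):
    return build_synthetic_geometry(default_spec)


@pytest.fixture(scope="session")
def coarse_spec() -> GeometrySpec:
    return GeometrySpec(target_edge_lengths_mm=dict(COARSE_EDGES))


@pytest.fixture(scope="session")
def coarse_mesh(coarse_spec):
    return build_synthetic_geometry(coarse_spec)


@pytest.fixture(scope="session")
def reference_run(default_spec, default_mesh):
    """The reference closed-loop case: 3 cm electrode, 1 min ramp, 9 min hold."""
    protocol = AblationProtocol.from_minutes(3, 10, 9)
    solver = ElectroThermalSolver(default_mesh)
    result = solver.simulate(
        protocol, PIController(), electrode=default_spec.electrode_info()
    )
    measurement = measure_diameters(
        default_mesh, result.final.omega, default_spec.electrode_info()
    )
    return {"spec": default_spec, "result": result, "measurement": measurement}


def _study_run(edges: dict, dt: float):
    spec = GeometrySpec(target_edge_lengths_mm=edges)
    mesh = build_synthetic_geometry(spec)
    solver = ElectroThermalSolver(mesh, config=SolverConfig(dt_s=dt))
    result = solver.simulate(STUDY_PROTOCOL, PIController())
    return measure_diameters(mesh, result.final.omega, spec.electrode_info())


@pytest.fixture(scope="session")
def discretisation_study():
    """Base / half-dt / half-mesh-spacing runs of the reduced reference case."""
    base = _study_run(dict(STUDY_EDGES), dt=0.5)
    half_dt = _study_run(dict(STUDY_EDGES), dt=0.25)
    half_h = _study_run({k: v / 2 for k, v in STUDY_EDGES.items()}, dt=0.5)
    return {"base": base, "half_dt": half_dt, "half_h": half_h}


@pytest.fixture(scope="session")
def short_coarse_run(coarse_spec, coarse_mesh):
    """A short heated run used by invariant checks (45 s ramp, 45 s hold)."""
    protocol = AblationProtocol.from_minutes(3, 1.5, 0.75)
    solver = ElectroThermalSolver(coarse_mesh)
    result = solver.simulate(
        protocol, PIController(), electrode=coarse_spec.electrode_info()
    )
    return {"spec": coarse_spec, "result": result}
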