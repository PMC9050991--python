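"""Run configuration: YAML schema, validation and the end-to-end pipeline.

A run config names either a synthetic geometry spec or an external labelled
MSH mesh, the material table (defaults are the published property table),
the ablation protocol in its clinical units (electrode length in cm, both
durations in minutes), controller gains, solver knobs and damage
parameters.  ``run_simulation`` executes the whole pipeline and writes a
VTU snapshot series, a per-step summary CSV, the final lesion measurement
as JSON and a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .control import AblationProtocol, PIController
from .damage import ArrheniusParams
from .geometry import ElectrodeInfo, GeometrySpec, build_synthetic_geometry
from .lesion import extract_lesion, measure_diameters
from .solver import ElectroThermalSolver, SolverConfig
from .tissues import MaterialTable

log = logging.getLogger("rfablate")


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one ablation simulation."""

    geometry: GeometrySpec | None = None
    mesh_path: str | None = None
    mesh_name_map: dict = field(default_factory=dict)
    electrode: ElectrodeInfo | None = None  # required with mesh_path
    materials: MaterialTable = field(default_factory=MaterialTable)
    protocol: AblationProtocol = field(
        default_factory=lambda: AblationProtocol.from_minutes(3, 10, 9)
    )
    controller: PIController = field(default_factory=PIController)
    solver: SolverConfig = field(default_factory=SolverConfig)
    damage: ArrheniusParams = field(default_factory=ArrheniusParams)
    output_dir: str = "results"
    log_level: str = "INFO"

    def validate(self) -> None:
        problems = []
        if (self.geometry is None) == (self.mesh_path is None):
            problems.append("exactly one of 'geometry' and 'mesh' must be given")
        if self.geometry is not None:
            try:
                self.geometry.validate()
            except ValueError as exc:
                problems.append(f"geometry: {exc}")
        if self.mesh_path is not None and self.electrode is None:
            problems.append("mesh: an 'electrode' block (radius/tip/top) is required "
                            "with an external mesh")
        try:
            self.materials.validate()
        except ValueError as exc:
            problems.append(f"materials: {exc}")
        try:
            self.solver.validate()
        except ValueError as exc:
            problems.append(f"solver: {exc}")
        if problems:
            raise ConfigError("; ".join(problems))

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        d: dict = {
            "protocol": {
                "electrode_length_cm": self.protocol.electrode_length_mm / 10.0,
                "time_over_60_min": self.protocol.time_over_60_s / 60.0,
                "time_at_90_min": self.protocol.time_at_90_s / 60.0,
            },
            "controller": {
                "kp_V_per_K": self.controller.kp_V_per_K,
                "ki_V_per_Ks": self.controller.ki_V_per_Ks,
                "v_max_V": self.controller.v_max_V,
            },
            "solver": asdict(self.solver),
            "damage": {
                "frequency_factor_per_s": self.damage.frequency_factor_per_s,
                "activation_energy_J_per_mol": self.damage.activation_energy_J_per_mol,
                "omega_death": self.damage.omega_death,
                "rule": self.damage.rule,
            },
            "materials": self.materials.to_dict(),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        if self.geometry is not None:
            d["geometry"] = self.geometry.to_dict()
        if self.mesh_path is not None:
            d["mesh"] = {
                "path": self.mesh_path,
                "name_map": self.mesh_name_map,
                "electrode": {
                    "radius_mm": self.electrode.radius_m * 1e3,
                    "tip_z_mm": self.electrode.tip_z_m * 1e3,
                    "top_z_mm": self.electrode.top_z_m * 1e3,
                },
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs: dict = {}
        if "geometry" in d:
            kwargs["geometry"] = GeometrySpec.from_dict(d["geometry"])
        if "mesh" in d:
            m = d["mesh"]
            kwargs["mesh_path"] = m["path"]
            kwargs["mesh_name_map"] = m.get("name_map", {})
            el = m.get("electrode")
            if el:
                mode = "full_3d" if "mode" not in m else m["mode"]
                kwargs["electrode"] = ElectrodeInfo(
                    radius_m=el["radius_mm"] * 1e-3,
                    tip_z_m=el["tip_z_mm"] * 1e-3,
                    top_z_m=el["top_z_mm"] * 1e-3,
                    axis_point=(0.0, 0.0),
                    mode=mode,
                )
        if "protocol" in d:
            p = d["protocol"]
            kwargs["protocol"] = AblationProtocol.from_minutes(
                p["electrode_length_cm"], p["time_over_60_min"], p["time_at_90_min"]
            )
        if "controller" in d:
            kwargs["controller"] = PIController(**d["controller"])
        if "solver" in d:
            kwargs["solver"] = SolverConfig(**d["solver"])
        if "damage" in d:
            kwargs["damage"] = ArrheniusParams(
                frequency_factor_per_s=d["damage"].get("frequency_factor_per_s", 8.99e133),
                activation_energy_J_per_mol=d["damage"].get("activation_energy_J_per_mol", 8.38e5),
                omega_death=d["damage"].get("omega_death", 4.6),
                rule=d["damage"].get("rule", "rectangle"),
            )
        if "materials" in d:
            kwargs["materials"] = MaterialTable.from_dict(d["materials"])
        for key in ("output_dir", "log_level"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def load_config(path) -> RunConfig:
    cfg = RunConfig.from_yaml(Path(path).read_text())
    cfg.validate()
    return cfg


def run_simulation(cfg: RunConfig, progress: bool = False):
    """Execute one configured run end-to-end; returns (result, measurement).

    Writes, under ``cfg.output_dir``: a VTU snapshot series plus ``.pvd``
    index, ``summary.csv`` (one row per control step), ``lesion.json`` with
    the final diameters, and ``provenance.json``.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    if cfg.geometry is not None:
        log.info("building synthetic geometry (%s)", cfg.geometry.mode)
        mesh = build_synthetic_geometry(cfg.geometry)
        electrode = cfg.geometry.electrode_info()
    else:
        from .mshio import read_msh

        log.info("reading mesh %s", cfg.mesh_path)
        mesh = read_msh(cfg.mesh_path, name_map=cfg.mesh_name_map)
        electrode = cfg.electrode
    log.info("mesh: %d nodes, %d cells", mesh.n_nodes, mesh.n_cells)

    solver = ElectroThermalSolver(mesh, cfg.materials, cfg.solver, cfg.damage)
    result = solver.simulate(
        cfg.protocol, controller=cfg.controller, electrode=electrode, progress=progress
    )
    region = extract_lesion(mesh, result.final.omega, cfg.damage.omega_death)
    measurement = measure_diameters(
        mesh, result.final.omega, electrode,
        threshold=cfg.damage.omega_death, volume_mm3=region.volume_mm3,
    )

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .vtu import write_series

    write_series(out, "fields", mesh, result.snapshots)
    result.summary.to_csv(out / "summary.csv", index=False)
    (out / "lesion.json").write_text(json.dumps(measurement.as_dict(), indent=2))
    config_yaml = cfg.to_yaml()
    provenance = {
        "rfablate_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "reached_60_at_s": result.reached_60_at_s,
        "n_nodes": mesh.n_nodes,
        "n_cells": mesh.n_cells,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "config.yaml").write_text(config_yaml)
    log.info(
        "lesion: longest %.1f mm, shortest %.1f mm, other %.1f mm, volume %.0f mm3",
        measurement.longest_mm, measurement.shortest_mm,
        measurement.other_mm, measurement.volume_mm3,
    )
    return result, measurement
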