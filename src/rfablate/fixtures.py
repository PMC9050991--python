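"""Named fixtures: small meshes, configs and the clinical tables.

Used by tests and demos; ``rfablate fixtures <name>`` writes them to disk.
"""

from __future__ import annotations

from pathlib import Path

from .clinical import clinical_cases
from .config import RunConfig
from .geometry import GeometrySpec, build_annulus_mesh, build_block_mesh

FIXTURES = ("annulus", "lumped-block", "reference-femur", "table23")


def make_fixture(name: str, out_dir) -> list:
    """Write the named fixture; returns the list of created paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "annulus":
        mesh = build_annulus_mesh(1.0, 50.0, 10.0, edge_mm=1.0, grade_inner_mm=0.1)
        path = out / "annulus.msh"
        mesh.write_msh(path)
        note = out / "annulus.md"
        note.write_text(
            "Concentric-cylinder oracle: uniform sigma, V0 on the inner wall "
            "(r = 1 mm), ground at r = 50 mm, insulated ends.\n"
            "Closed form: V(r) = V0 ln(b/r)/ln(b/a); "
            "P = 2 pi L sigma V0^2 / ln(b/a).\n"
        )
        return [path, note]
    if name == "lumped-block":
        mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=1.0, region="tumour")
        path = out / "lumped_block.msh"
        mesh.write_msh(path)
        note = out / "lumped_block.md"
        note.write_text(
            "Insulated homogeneous block (tumour tissue, no perfusion): uniform "
            "volumetric heating obeys dT/dt = Q / (rho c) exactly.\n"
        )
        return [path, note]
    if name == "reference-femur":
        cfg = RunConfig(geometry=GeometrySpec())
        path = out / "reference_femur.yaml"
        path.write_text(cfg.to_yaml())
        return [path]
    if name == "table23":
        path = out / "clinical_cases.csv"
        clinical_cases().to_csv(path, index=False)
        return [path]
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
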