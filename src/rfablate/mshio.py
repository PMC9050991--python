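"""Gmsh MSH v2.2 ASCII reader/writer for labelled meshes.

Region tags are carried as physical groups of the cell dimension (triangles
in axisymmetric meshes, tetrahedra in 3D) and boundary/interface tags as
physical groups one dimension lower.  ``read_msh`` maps physical-group
names onto the canonical region/boundary tags through a user-supplied
dictionary (identity by default) and verifies the mesh invariants.

Only MSH v2 ASCII is supported; v4 files raise a clear error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Mesh, MeshingError, validate_mesh
from .tissues import REGIONS, BOUNDARIES

# Gmsh element type codes
_LINE, _TRIANGLE, _TETRA = 1, 2, 4


class MshFormatError(MeshingError):
    """Malformed or unsupported MSH content."""


def write_msh(path, mesh: Mesh) -> None:
    """Write a labelled mesh as MSH v2.2 ASCII.

    Region groups get physical ids 1..len(region_names); boundary groups
    101..; 2D points are embedded with z = 0.
    """
    path = Path(path)
    dim = mesh.dim
    cell_type = _TRIANGLE if dim == 2 else _TETRA
    facet_type = _LINE if dim == 2 else _TRIANGLE

    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]

    used_regions = sorted(set(int(r) for r in mesh.cell_regions))
    used_bounds = sorted(set(int(t) for t in mesh.facet_tags))
    lines.append("$PhysicalNames")
    lines.append(str(len(used_regions) + len(used_bounds)))
    for t in used_bounds:
        lines.append(f'{dim - 1} {101 + t} "{mesh.boundary_names[t]}"')
    for r in used_regions:
        lines.append(f'{dim} {1 + r} "{mesh.region_names[r]}"')
    lines.append("$EndPhysicalNames")

    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    pts = mesh.points if dim == 3 else np.column_stack([mesh.points, np.zeros(mesh.n_nodes)])
    for i, (x, y, z) in enumerate(pts, start=1):
        lines.append(f"{i} {x:.16g} {y:.16g} {z:.16g}")
    lines.append("$EndNodes")

    lines.append("$Elements")
    lines.append(str(len(mesh.facets) + mesh.n_cells))
    eid = 1
    for f, t in zip(mesh.facets, mesh.facet_tags):
        nodes = " ".join(str(n + 1) for n in f)
        lines.append(f"{eid} {facet_type} 2 {101 + int(t)} {101 + int(t)} {nodes}")
        eid += 1
    for cell, r in zip(mesh.cells, mesh.cell_regions):
        nodes = " ".join(str(n + 1) for n in cell)
        lines.append(f"{eid} {cell_type} 2 {1 + int(r)} {1 + int(r)} {nodes}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(
    path,
    name_map: dict | None = None,
    mode: str | None = None,
    required_regions: tuple = REGIONS,
) -> Mesh:
    """Read an MSH v2 ASCII file into a labelled :class:`Mesh`.

    ``name_map`` maps physical-group names in the file onto the canonical
    region/boundary names; unmapped names raise, as does a missing required
    region.  ``mode`` defaults to ``axisymmetric_2d`` for triangle meshes
    and ``full_3d`` for tetrahedral meshes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    sections = _split_sections(text)
    if "MeshFormat" not in sections:
        raise MshFormatError("not an MSH file (missing $MeshFormat)")
    version = sections["MeshFormat"][0].split()[0]
    if not version.startswith("2"):
        raise MshFormatError(
            f"unsupported MSH version {version}; only v2 ASCII is supported"
        )

    phys_names: dict[int, str] = {}
    if "PhysicalNames" in sections:
        body = sections["PhysicalNames"]
        for line in body[1 : 1 + int(body[0])]:
            parts = line.split(maxsplit=2)
            phys_names[int(parts[1])] = parts[2].strip().strip('"')

    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=np.int64)
    xyz = np.empty((n_nodes, 3), dtype=float)
    for row, line in enumerate(node_lines[1 : 1 + n_nodes]):
        parts = line.split()
        ids[row] = int(parts[0])
        xyz[row] = [float(parts[1]), float(parts[2]), float(parts[3])]
    id_to_row = {int(i): r for r, i in enumerate(ids)}

    elem_lines = sections["Elements"]
    n_elem = int(elem_lines[0])
    tris, tri_phys, tets, tet_phys, facets1, facet_phys1, facets2, facet_phys2 = (
        [], [], [], [], [], [], [], [],
    )
    for line in elem_lines[1 : 1 + n_elem]:
        parts = [int(p) for p in line.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else 0
        nodes = parts[3 + ntags :]
        if etype == _TRIANGLE:
            tris.append(nodes)
            tri_phys.append(phys)
        elif etype == _TETRA:
            tets.append(nodes)
            tet_phys.append(phys)
        elif etype == _LINE:
            facets1.append(nodes)
            facet_phys1.append(phys)
        # other element types (points, quads...) are ignored

    if tets:
        dim, cells_raw, cell_phys = 3, tets, tet_phys
        facets_raw, fphys = tris, tri_phys
        mode = mode or "full_3d"
        points = xyz
    elif tris:
        dim, cells_raw, cell_phys = 2, tris, tri_phys
        facets_raw, fphys = facets1, facet_phys1
        mode = mode or "axisymmetric_2d"
        points = xyz[:, :2]
    else:
        raise MshFormatError("no triangles or tetrahedra found")

    name_map = dict(name_map or {})
    known = set(REGIONS) | set(BOUNDARIES)

    def canonical(phys: int) -> str:
        name = phys_names.get(phys, str(phys))
        mapped = name_map.get(name, name)
        if mapped not in known:
            unmapped = sorted(
                {phys_names.get(p, str(p)) for p in set(cell_phys) | set(fphys)}
                - known - set(name_map)
            )
            raise MshFormatError(
                f"physical group {name!r} has no mapping to a canonical tag; "
                f"unmapped names: {unmapped}"
            )
        return mapped

    remap = np.vectorize(lambda i: id_to_row[i])
    cells = remap(np.asarray(cells_raw, dtype=np.int64) )
    cell_regions = np.array([REGIONS.index(canonical(p)) for p in cell_phys], dtype=np.int32)
    if facets_raw:
        facets = remap(np.asarray(facets_raw, dtype=np.int64))
        facet_tags = np.array([BOUNDARIES.index(canonical(p)) for p in fphys], dtype=np.int32)
    else:
        facets = np.empty((0, dim), dtype=np.int64)
        facet_tags = np.empty(0, dtype=np.int32)

    present = {REGIONS[i] for i in np.unique(cell_regions)}
    missing = sorted(set(required_regions) - present)
    if missing:
        raise MshFormatError(f"mesh is missing required regions: {missing}")

    mesh = Mesh(points, cells, cell_regions, REGIONS, facets, facet_tags, BOUNDARIES, mode)
    validate_mesh(mesh, strict=True)
    return mesh


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            body = []
            i += 1
            while i < len(lines) and lines[i].strip() != f"$End{name}":
                body.append(lines[i])
                i += 1
            sections[name] = body
        i += 1
    return sections
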