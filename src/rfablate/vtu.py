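"""Minimal VTU (XML ASCII UnstructuredGrid) time-series writer.

One ``.vtu`` file per output instant with point data (V, T, Omega) and cell
data (Q_RF, region id), plus a ``.pvd`` collection index for time-aware
viewers (ParaView and friends).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_VTK_TRIANGLE, _VTK_TETRA = 5, 10


def _data_array(name: str, values: np.ndarray, components: int = 1) -> str:
    flat = np.asarray(values).ravel()
    body = " ".join(f"{v:.9g}" for v in flat)
    return (
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{components}" format="ascii">{body}</DataArray>'
    )


def write_vtu(path, mesh, point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Write one labelled mesh plus fields as an ASCII .vtu file."""
    path = Path(path)
    pts = mesh.points
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    cells = mesh.cells
    npc = cells.shape[1]
    ctype = _VTK_TRIANGLE if npc == 3 else _VTK_TETRA

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(pts)}" NumberOfCells="{len(cells)}">',
        "<Points>",
        _data_array("Points", pts, components=3),
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">'
        + " ".join(map(str, cells.ravel()))
        + "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">'
        + " ".join(str(npc * (i + 1)) for i in range(len(cells)))
        + "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">'
        + " ".join([str(ctype)] * len(cells))
        + "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        parts.extend(_data_array(k, v) for k, v in point_data.items())
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        parts.extend(_data_array(k, v) for k, v in cell_data.items())
        parts.append("</CellData>")
    parts.extend(["</Piece>", "</UnstructuredGrid>", "</VTKFile>"])
    path.write_text("\n".join(parts) + "\n")


def write_series(directory, basename: str, mesh, states) -> Path:
    """Write a snapshot series and the .pvd collection; returns the index path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, st in enumerate(states):
        fname = f"{basename}_{i:04d}.vtu"
        write_vtu(
            directory / fname,
            mesh,
            point_data={"V": st.V, "T": st.T_C, "Omega": st.omega},
            cell_data={"Q_RF": st.q_rf, "Q_p": st.q_p, "region": mesh.cell_regions},
        )
        entries.append(f'<DataSet timestep="{st.t_s}" group="" part="0" file="{fname}"/>')
    pvd = directory / f"{basename}.pvd"
    pvd.write_text(
        '<?xml version="1.0"?>\n<VTKFile type="Collection" version="0.1">\n<Collection>\n'
        + "\n".join(entries)
        + "\n</Collection>\n</VTKFile>\n"
    )
    return pvd
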