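"""Synthetic patient-like geometries and labelled simplicial meshes.

The model domain mirrors the segmented anatomy of an RF ablation of a bone
tumour: a needle electrode with a hemispherical tip, the tumour (ellipsoid),
trabecular bone, a cortical shell (trabecular surface = cortical surface
offset inward by 2.5 mm), and a large muscle box carrying the outer
boundary conditions.  The insulated electrode shaft is not meshed; a
cylindrical channel above the active electrode is carved out and its walls
carry the zero-flux ``electrode_bottom`` tag.

Two modes are supported:

* ``axisymmetric_2d`` — an (r, z) half-plane with the electrode on the
  symmetry axis and the cortical wall represented as a cylindrical shell
  around it.  This breaks the true geometry of a long bone (the shell wraps
  the electrode instead of being pierced by it) but is cheap and captures
  the radial physics; all integrals are 2*pi*r weighted.
* ``full_3d`` — the bone is a cylinder along the x axis, pierced from above
  by the vertical electrode, with the tumour inside; tetrahedral mesh.

Meshing strategy: graded tensor-product grids (fine near the electrode,
coarsening outward) split into simplices, with exact grid coordinates at
every cylindrical/planar interface and node snapping onto curved interfaces
(tumour ellipsoid, bone cylinders in 3D).  Element regions are assigned by
centroid classification.  Coordinates are metres internally; every user
interface is in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .tissues import REGIONS, BOUNDARIES

MM = 1e-3


class GeometryError(ValueError):
    """Infeasible geometry specification."""


class MeshingError(RuntimeError):
    """Mesh generation or validation failure."""


DEFAULT_EDGE_LENGTHS_MM = {
    "electrode": 0.25,
    "tumour": 1.5,
    "trabecular": 1.5,
    "cortical": 1.25,
    "muscle": 6.0,
}

# 3D tetrahedral meshes cannot afford the 2D electrode sizing; these are the
# documented full_3d defaults.
DEFAULT_EDGE_LENGTHS_3D_MM = {
    "electrode": 0.75,
    "tumour": 3.0,
    "trabecular": 3.0,
    "cortical": 3.0,
    "muscle": 10.0,
}


@dataclass
class ElectrodeInfo:
    """Electrode placement used by the controller and lesion measurement (SI)."""

    radius_m: float
    tip_z_m: float          # lowest point of the hemispherical tip
    top_z_m: float          # proximal end of the active part (insulation start)
    axis_point: tuple       # a point on the axis (origin of the axis line)
    mode: str

    @property
    def active_length_m(self) -> float:
        return self.top_z_m - self.tip_z_m

    @property
    def mid_z_m(self) -> float:
        return 0.5 * (self.tip_z_m + self.top_z_m)


@dataclass
class GeometrySpec:
    """Parameters of the synthetic layered bone/tumour/muscle model (mm).

    ``cortical_thickness_mm=None`` uses ``trabecular_offset_mm`` (the
    trabecular surface is the cortical surface offset inward, so the offset
    *is* the default shell thickness).
    """

    mode: str = "axisymmetric_2d"
    electrode_active_length_mm: float = 30.0
    electrode_radius_mm: float = 0.75
    electrode_tip_position_mm: tuple = (0.0, 0.0, -15.0)
    bone_outer_radius_mm: float = 15.0
    trabecular_offset_mm: float = 2.5
    cortical_thickness_mm: float | None = None
    tumour_center_mm: tuple = (0.0, 0.0, 0.0)
    tumour_semiaxes_mm: tuple = (10.0, 10.0, 10.0)
    muscle_box_halfwidth_mm: float = 60.0
    target_edge_lengths_mm: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.target_edge_lengths_mm:
            base = DEFAULT_EDGE_LENGTHS_MM if self.mode == "axisymmetric_2d" else DEFAULT_EDGE_LENGTHS_3D_MM
            self.target_edge_lengths_mm = dict(base)

    # -- derived quantities --------------------------------------------------
    @property
    def cortical_shell_mm(self) -> float:
        return self.cortical_thickness_mm if self.cortical_thickness_mm is not None else self.trabecular_offset_mm

    @property
    def tip_z_mm(self) -> float:
        return float(self.electrode_tip_position_mm[2])

    @property
    def top_z_mm(self) -> float:
        return self.tip_z_mm + self.electrode_active_length_mm

    @property
    def cap_center_z_mm(self) -> float:
        return self.tip_z_mm + self.electrode_radius_mm

    def electrode_info(self) -> ElectrodeInfo:
        return ElectrodeInfo(
            radius_m=self.electrode_radius_mm * MM,
            tip_z_m=self.tip_z_mm * MM,
            top_z_m=self.top_z_mm * MM,
            axis_point=(0.0, 0.0),
            mode=self.mode,
        )

    def validate(self) -> None:
        if self.mode not in ("axisymmetric_2d", "full_3d"):
            raise GeometryError(f"unknown mode {self.mode!r}")
        for name in (
            "electrode_active_length_mm",
            "electrode_radius_mm",
            "bone_outer_radius_mm",
            "trabecular_offset_mm",
            "muscle_box_halfwidth_mm",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.cortical_shell_mm <= 0 or self.cortical_shell_mm >= self.bone_outer_radius_mm:
            raise GeometryError("cortical shell thickness must be in (0, bone_outer_radius)")
        a, b, c = self.tumour_semiaxes_mm
        if min(a, b, c) <= 0:
            raise GeometryError("tumour semi-axes must be positive")
        hw = self.muscle_box_halfwidth_mm
        cx, cy, cz = self.tumour_center_mm
        if max(abs(cx) + a, abs(cy) + b, abs(cz) + c) >= hw:
            raise GeometryError("tumour must lie fully inside the muscle box")
        if not (-hw < self.tip_z_mm and self.top_z_mm < hw):
            raise GeometryError("electrode must lie inside the domain")
        if self.mode == "axisymmetric_2d":
            if abs(cx) > 1e-9 or abs(cy) > 1e-9:
                raise GeometryError("axisymmetric mode requires the tumour centre on the axis")
            if abs(a - b) > 1e-9:
                raise GeometryError("axisymmetric mode requires equal transverse tumour semi-axes")
            if a > self.bone_outer_radius_mm:
                raise GeometryError("tumour extends outside the bone envelope")
        else:
            # electrode axis (x = y = 0) must intersect the tumour ellipsoid
            if (cx / a) ** 2 + (cy / b) ** 2 >= 1.0:
                raise GeometryError("electrode axis does not intersect the tumour")
        if abs(self.electrode_tip_position_mm[0]) > 1e-9 or abs(self.electrode_tip_position_mm[1]) > 1e-9:
            raise GeometryError("electrode axis is the z axis; tip x/y must be 0")
        for region, h in self.target_edge_lengths_mm.items():
            if region not in REGIONS:
                raise GeometryError(f"unknown region in target_edge_lengths_mm: {region!r}")
            if h <= 0:
                raise GeometryError("target edge lengths must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["electrode_tip_position_mm"] = list(self.electrode_tip_position_mm)
        d["tumour_center_mm"] = list(self.tumour_center_mm)
        d["tumour_semiaxes_mm"] = list(self.tumour_semiaxes_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometrySpec":
        d = dict(d)
        for key in ("electrode_tip_position_mm", "tumour_center_mm", "tumour_semiaxes_mm"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Labelled mesh container
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Labelled simplicial mesh (triangles in (r, z), tetrahedra in 3D), SI units.

    ``facets``/``facet_tags`` cover the exterior boundary plus the internal
    electrode-tissue interface (``electrode_surface``).
    """

    points: np.ndarray          # (n_nodes, 2|3), metres
    cells: np.ndarray           # (n_cells, 3|4) node indices
    cell_regions: np.ndarray    # (n_cells,) indices into region_names
    region_names: tuple
    facets: np.ndarray          # (n_facets, 2|3) node indices
    facet_tags: np.ndarray      # (n_facets,) indices into boundary_names
    boundary_names: tuple
    mode: str                   # "axisymmetric_2d" | "full_3d"

    # -- basics --------------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def region_id(self, name: str) -> int:
        return self.region_names.index(name)

    def cells_of(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.cell_regions == self.region_id(name))

    def present_regions(self) -> set:
        return {self.region_names[i] for i in np.unique(self.cell_regions) if i >= 0}

    # -- measures ------------------------------------------------------------
    def cell_measures(self) -> np.ndarray:
        """Signed areas (2D) or signed volumes (3D)."""
        p = self.points[self.cells]
        if self.dim == 2:
            d1 = p[:, 1] - p[:, 0]
            d2 = p[:, 2] - p[:, 0]
            return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        d3 = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def cell_volumes(self) -> np.ndarray:
        """Physical volumes: 2*pi*r_centroid*area in axisymmetric mode, else |V|."""
        meas = np.abs(self.cell_measures())
        if self.mode == "axisymmetric_2d":
            r_c = self.points[self.cells, 0].mean(axis=1)
            return 2.0 * math.pi * r_c * meas
        return meas

    def node_cell_weights(self) -> np.ndarray:
        """(n_cells, nodes_per_cell) lumped volume shares; rows sum to cell_volumes.

        Axisymmetric rows use the exact linear-density integral
        ``2*pi*A*(2 r_i + r_j + r_k)/12``.
        """
        meas = np.abs(self.cell_measures())
        if self.mode == "axisymmetric_2d":
            r = self.points[self.cells, 0]
            w = (r + r.sum(axis=1, keepdims=True)) / 12.0
            return 2.0 * math.pi * meas[:, None] * w
        npc = self.cells.shape[1]
        return np.repeat(meas[:, None] / npc, npc, axis=1)

    def region_volume(self, name: str) -> float:
        return float(self.cell_volumes()[self.cells_of(name)].sum())

    # -- boundaries ----------------------------------------------------------
    def boundary_id(self, name: str) -> int:
        return self.boundary_names.index(name)

    def facets_of(self, name: str) -> np.ndarray:
        return self.facets[self.facet_tags == self.boundary_id(name)]

    def boundary_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.facets_of(name))

    # -- quality -------------------------------------------------------------
    def edge_lengths(self) -> np.ndarray:
        """Lengths of all unique cell edges."""
        edges = _cell_edges(self.cells)
        uniq = np.unique(np.sort(edges, axis=1), axis=0)
        d = self.points[uniq[:, 0]] - self.points[uniq[:, 1]]
        return np.linalg.norm(d, axis=1)

    def write_msh(self, path) -> None:
        from . import mshio

        mshio.write_msh(path, self)


def _cell_edges(cells: np.ndarray) -> np.ndarray:
    npc = cells.shape[1]
    pairs = [(i, j) for i in range(npc) for j in range(i + 1, npc)]
    return np.concatenate([cells[:, [i, j]] for i, j in pairs], axis=0)


def _cell_facets(cells: np.ndarray) -> np.ndarray:
    """All facets (edges of triangles / faces of tets), one row per cell-facet."""
    npc = cells.shape[1]
    combos = [[j for j in range(npc) if j != i] for i in range(npc)]
    return np.concatenate([cells[:, c] for c in combos], axis=0)


# ---------------------------------------------------------------------------
# Graded 1D point distributions
# ---------------------------------------------------------------------------

def _sizing_function(zones: Sequence[tuple], h_base: float, slope: float = 0.45) -> Callable:
    """h(x) = min(h_base, min_z (h_z + slope * distance to zone z))."""

    def size(x: float) -> float:
        h = h_base
        for lo, hi, hz in zones:
            d = 0.0 if lo <= x <= hi else (lo - x if x < lo else x - hi)
            h = min(h, hz + slope * d)
        return h

    return size


def graded_points(x0: float, x1: float, size: Callable, mandatory: Sequence[float] = ()) -> np.ndarray:
    """March a graded point set over [x0, x1] hitting ``mandatory`` coordinates exactly."""
    brk = sorted({x0, x1, *(m for m in mandatory if x0 < m < x1)})
    pts = [x0]
    for a, b in zip(brk[:-1], brk[1:]):
        sub = [a]
        x = a
        while x < b - 1e-12:
            x = min(x + max(size(x), 1e-9), b)
            sub.append(x)
        if len(sub) < 2:
            sub = [a, b]
        sub = np.asarray(sub)
        sub = a + (sub - a) * (b - a) / (sub[-1] - a)  # land exactly on b
        pts.extend(sub[1:].tolist())
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# Synthetic geometry builders
# ---------------------------------------------------------------------------

def build_synthetic_geometry(spec: GeometrySpec) -> Mesh:
    """Generate the labelled synthetic femur-like mesh for ``spec``."""
    spec.validate()
    if spec.mode == "axisymmetric_2d":
        return _build_axisymmetric(spec)
    return _build_3d(spec)


def _repair_snapping(points, cells, original_points, snapped, dim) -> np.ndarray:
    """Revert snapped nodes that degenerate or invert any incident cell."""
    for _ in range(10):
        meas = _signed_measures(points, cells, dim)
        ref = _signed_measures(original_points, cells, dim)
        bad = np.abs(meas) < 0.2 * np.abs(ref)
        bad |= np.sign(meas) != np.sign(ref)
        if not bad.any():
            break
        bad_nodes = np.unique(cells[bad])
        revert = np.intersect1d(bad_nodes, np.flatnonzero(snapped))
        if revert.size == 0:
            break
        points[revert] = original_points[revert]
        snapped[revert] = False
    return points


def _signed_measures(points, cells, dim):
    p = points[cells]
    if dim == 2:
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    d3 = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0


def _local_spacing(coords: np.ndarray) -> np.ndarray:
    """Per-grid-coordinate local spacing (min of adjacent intervals)."""
    d = np.diff(coords)
    return np.minimum(np.r_[d[0], d], np.r_[d, d[-1]])


def _build_axisymmetric(spec: GeometrySpec) -> Mesh:
    h = spec.target_edge_lengths_mm
    r_el = spec.electrode_radius_mm
    R = spec.bone_outer_radius_mm
    R_in = R - spec.cortical_shell_mm
    hw = spec.muscle_box_halfwidth_mm
    a, _, c = spec.tumour_semiaxes_mm
    cz = spec.tumour_center_mm[2]
    h_bone = min(h["tumour"], h["trabecular"], h["cortical"])

    r_size = _sizing_function(
        [(0.0, r_el + 0.6, h["electrode"]), (0.0, R + 2.0, h_bone)], h["muscle"]
    )
    z_size = _sizing_function(
        [(spec.tip_z_mm - 0.6, spec.top_z_mm + 0.6, h["electrode"]),
         (cz - c - 2.0, cz + c + 2.0, h_bone)],
        h["muscle"],
    )
    r_pts = graded_points(0.0, hw, r_size, mandatory=[r_el, R_in, R])
    z_pts = graded_points(-hw, hw, z_size,
                          mandatory=[spec.tip_z_mm, spec.cap_center_z_mm, spec.top_z_mm, cz])

    rr, zz = np.meshgrid(r_pts, z_pts, indexing="ij")
    points = np.column_stack([rr.ravel(), zz.ravel()]) * MM
    nr, nz = len(r_pts), len(z_pts)

    def nid(i, j):
        return i * nz + j

    # two triangles per quad with alternating diagonals
    i, j = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1), indexing="ij")
    i, j = i.ravel(), j.ravel()
    n00, n10, n01, n11 = nid(i, j), nid(i + 1, j), nid(i, j + 1), nid(i + 1, j + 1)
    alt = ((i + j) % 2).astype(bool)
    t1 = np.where(alt[:, None], np.column_stack([n00, n10, n11]), np.column_stack([n00, n10, n01]))
    t2 = np.where(alt[:, None], np.column_stack([n00, n11, n01]), np.column_stack([n10, n11, n01]))
    cells = np.concatenate([t1, t2], axis=0)

    # --- snap nodes onto the tumour ellipsoid -------------------------------
    hr = _local_spacing(r_pts)[:, None] * np.ones((1, nz))
    hz = _local_spacing(z_pts)[None, :] * np.ones((nr, 1))
    h_loc = np.minimum(hr, hz).ravel() * MM
    original = points.copy()
    snapped = np.zeros(len(points), dtype=bool)
    pr, pz = points[:, 0], points[:, 1]
    am, cm, czm = a * MM, c * MM, cz * MM
    phi = np.sqrt((pr / am) ** 2 + ((pz - czm) / cm) ** 2)
    grad = np.column_stack([pr / am**2, (pz - czm) / cm**2])
    gnorm = np.linalg.norm(grad, axis=1)
    ok = (gnorm > 1e-12) & (pr > (r_el + 0.5) * MM)
    dist = np.where(ok, (phi - 1.0) / np.where(gnorm > 1e-12, gnorm, 1.0), np.inf)
    sel = ok & (np.abs(dist) < 0.45 * h_loc)
    points[sel] -= dist[sel, None] * grad[sel] / gnorm[sel, None]
    snapped[sel] = True
    points = _repair_snapping(points, cells, original, snapped, dim=2)

    # --- carve the insulated-shaft channel, classify, orient ----------------
    cent = points[cells].mean(axis=1)
    r_c, z_c = cent[:, 0] / MM, cent[:, 1] / MM
    keep = ~((r_c < r_el) & (z_c > spec.top_z_mm))
    cells, r_c, z_c = cells[keep], r_c[keep], z_c[keep]

    in_shaft = (r_c <= r_el) & (z_c >= spec.cap_center_z_mm) & (z_c <= spec.top_z_mm)
    in_cap = (r_c**2 + (z_c - spec.cap_center_z_mm) ** 2 <= r_el**2) & (z_c < spec.cap_center_z_mm)
    in_tum = (r_c / a) ** 2 + ((z_c - cz) / c) ** 2 <= 1.0
    region = np.full(len(cells), -1, dtype=np.int32)
    names = REGIONS
    region[r_c > R] = names.index("muscle")
    region[(r_c <= R) & (r_c >= R_in)] = names.index("cortical")
    region[r_c < R_in] = names.index("trabecular")
    region[in_tum & (region != names.index("muscle"))] = names.index("tumour")
    region[in_shaft | in_cap] = names.index("electrode")

    points, cells = _compress_nodes(points, cells)
    meas = _signed_measures(points, cells, 2)
    flip = meas < 0
    cells[flip] = cells[flip][:, [0, 2, 1]]

    facets, tags = _tag_facets(
        points, cells, region, spec, mode="axisymmetric_2d"
    )
    mesh = Mesh(points, cells, region, names, facets, tags, BOUNDARIES, "axisymmetric_2d")
    _check_build(mesh, spec)
    return mesh


_KUHN_TETS = (
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 4, 5, 7), (0, 4, 6, 7), (0, 2, 6, 7), (0, 2, 3, 7),
)


def _build_3d(spec: GeometrySpec) -> Mesh:
    h = spec.target_edge_lengths_mm
    r_el = spec.electrode_radius_mm
    R = spec.bone_outer_radius_mm
    R_in = R - spec.cortical_shell_mm
    hw = spec.muscle_box_halfwidth_mm
    a, b, c = spec.tumour_semiaxes_mm
    cx, cy, cz = spec.tumour_center_mm
    h_bone = min(h["tumour"], h["trabecular"], h["cortical"])

    x_size = _sizing_function(
        [(-r_el - 0.6, r_el + 0.6, h["electrode"]), (cx - a - 2, cx + a + 2, h_bone)], h["muscle"]
    )
    y_size = _sizing_function(
        [(-r_el - 0.6, r_el + 0.6, h["electrode"]),
         (cy - b - 2, cy + b + 2, h_bone), (-R - 2, R + 2, min(h_bone * 2, h["muscle"]))],
        h["muscle"],
    )
    z_size = _sizing_function(
        [(spec.tip_z_mm - 0.6, spec.top_z_mm + 0.6, h["electrode"]),
         (cz - c - 2, cz + c + 2, h_bone), (-R - 2, R + 2, min(h_bone * 2, h["muscle"]))],
        h["muscle"],
    )
    x_pts = graded_points(-hw, hw, x_size, mandatory=[-r_el, 0.0, r_el])
    y_pts = graded_points(-hw, hw, y_size, mandatory=[-r_el, 0.0, r_el])
    z_pts = graded_points(-hw, hw, z_size,
                          mandatory=[spec.tip_z_mm, spec.cap_center_z_mm, spec.top_z_mm, cz])

    nx, ny, nz = len(x_pts), len(y_pts), len(z_pts)
    X, Y, Z = np.meshgrid(x_pts, y_pts, z_pts, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) * MM

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corner = [nid(i + di, j + dj, k + dk) for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]
    corner = np.column_stack(corner)  # ordering: bit0=z, bit1=y, bit2=x
    cells = np.concatenate([corner[:, list(t)] for t in _KUHN_TETS], axis=0)

    # --- node snapping to curved interfaces ---------------------------------
    hx = _local_spacing(x_pts)
    hy = _local_spacing(y_pts)
    hz = _local_spacing(z_pts)
    HL = np.minimum(np.minimum(hx[:, None, None], hy[None, :, None]), hz[None, None, :])
    h_loc = HL.ravel() * MM
    original = points.copy()
    snapped = np.zeros(len(points), dtype=bool)
    px, py, pz = points[:, 0], points[:, 1], points[:, 2]
    xyr = np.hypot(px, py)

    candidates = []  # (distance, displacement) per interface
    # electrode cylinder (above the cap centre)
    d_el = xyr - r_el * MM
    ok = (xyr > 1e-12) & (pz > spec.cap_center_z_mm * MM)
    disp = np.zeros_like(points)
    disp[:, 0] = -np.where(ok, d_el, 0.0) * px / np.where(xyr > 1e-12, xyr, 1.0)
    disp[:, 1] = -np.where(ok, d_el, 0.0) * py / np.where(xyr > 1e-12, xyr, 1.0)
    candidates.append((np.where(ok, np.abs(d_el), np.inf), disp))
    # bone cylinders (axis along x at y=0, z=cz), keep clear of the electrode
    br = np.hypot(py, pz - cz * MM)
    clear = xyr > (r_el + 1.0) * MM
    for radius in (R, R_in):
        d = br - radius * MM
        ok = clear & (br > 1e-12)
        disp = np.zeros_like(points)
        disp[:, 1] = -np.where(ok, d, 0.0) * py / np.where(br > 1e-12, br, 1.0)
        disp[:, 2] = -np.where(ok, d, 0.0) * (pz - cz * MM) / np.where(br > 1e-12, br, 1.0)
        candidates.append((np.where(ok, np.abs(d), np.inf), disp))
    # tumour ellipsoid
    ax_, by_, cz_ = a * MM, b * MM, c * MM
    u = np.column_stack([(px - cx * MM) / ax_, (py - cy * MM) / by_, (pz - cz * MM) / cz_])
    phi = np.linalg.norm(u, axis=1)
    grad = np.column_stack([u[:, 0] / ax_, u[:, 1] / by_, u[:, 2] / cz_])
    gnorm = np.linalg.norm(grad, axis=1)
    ok = (gnorm > 1e-12) & clear
    d = np.where(ok, (phi - 1.0) / np.where(gnorm > 1e-12, gnorm, 1.0), np.inf)
    disp = -np.where(np.isfinite(d), d, 0.0)[:, None] * grad / np.where(gnorm > 1e-12, gnorm, 1.0)[:, None]
    candidates.append((np.abs(d), disp))

    dists = np.column_stack([cd[0] for cd in candidates])
    best = np.argmin(dists, axis=1)
    best_d = dists[np.arange(len(points)), best]
    sel = best_d < 0.45 * h_loc
    for m, (_, disp) in enumerate(candidates):
        use = sel & (best == m)
        points[use] += disp[use]
        snapped[use] = True
    points = _repair_snapping(points, cells, original, snapped, dim=3)

    # --- carve channel, classify --------------------------------------------
    cent = points[cells].mean(axis=1) / MM
    xc, yc, zc = cent[:, 0], cent[:, 1], cent[:, 2]
    rc = np.hypot(xc, yc)
    keep = ~((rc < r_el) & (zc > spec.top_z_mm))
    cells, xc, yc, zc, rc = cells[keep], xc[keep], yc[keep], zc[keep], rc[keep]

    in_shaft = (rc <= r_el) & (zc >= spec.cap_center_z_mm) & (zc <= spec.top_z_mm)
    in_cap = (xc**2 + yc**2 + (zc - spec.cap_center_z_mm) ** 2 <= r_el**2) & (zc < spec.cap_center_z_mm)
    brc = np.hypot(yc, zc - cz)
    in_tum = ((xc - cx) / a) ** 2 + ((yc - cy) / b) ** 2 + ((zc - cz) / c) ** 2 <= 1.0
    region = np.full(len(cells), -1, dtype=np.int32)
    names = REGIONS
    region[brc > R] = names.index("muscle")
    region[(brc <= R) & (brc >= R_in)] = names.index("cortical")
    region[brc < R_in] = names.index("trabecular")
    region[in_tum & (region != names.index("muscle"))] = names.index("tumour")
    region[in_shaft | in_cap] = names.index("electrode")

    points, cells = _compress_nodes(points, cells)
    meas = _signed_measures(points, cells, 3)
    flip = meas < 0
    cells[flip] = cells[flip][:, [0, 1, 3, 2]]

    facets, tags = _tag_facets(points, cells, region, spec, mode="full_3d")
    mesh = Mesh(points, cells, region, names, facets, tags, BOUNDARIES, "full_3d")
    _check_build(mesh, spec)
    return mesh


def _compress_nodes(points, cells):
    used = np.unique(cells)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return points[used], remap[cells]


def _tag_facets(points, cells, region, spec: GeometrySpec, mode: str):
    """Boundary facets (count == 1) plus electrode-tissue interface facets."""
    dim = points.shape[1]
    facets_all = _cell_facets(cells)
    npc = cells.shape[1]
    owner = np.tile(np.arange(len(cells)), npc)
    key = np.sort(facets_all, axis=1)
    order = np.lexsort(key.T[::-1])
    key_s, owner_s, raw_s = key[order], owner[order], facets_all[order]
    uniq, start, count = np.unique(key_s, axis=0, return_index=True, return_counts=True)

    if count.max(initial=0) > 2:  # pragma: no cover - broken topology
        raise MeshingError("facet shared by more than two cells")

    tol = 1e-6 * MM
    hw = spec.muscle_box_halfwidth_mm * MM
    r_el = spec.electrode_radius_mm * MM
    z_top = spec.top_z_mm * MM
    el_id = REGIONS.index("electrode")
    b = BOUNDARIES

    # exterior boundary facets -------------------------------------------------
    bdry = raw_s[start[count == 1]]
    p = points[bdry]  # (F, nodes_per_facet, dim)
    tags = np.full(len(bdry), -1, dtype=np.int32)
    if mode == "axisymmetric_2d":
        radial = p[:, :, 0]
        on_axis = np.all(radial < tol, axis=1)
        tags[on_axis] = b.index("symmetry_axis")
    else:
        radial = np.hypot(p[:, :, 0], p[:, :, 1])
    outer = np.zeros(len(bdry), dtype=bool)
    if mode == "axisymmetric_2d":
        outer |= np.all(p[:, :, 0] > hw - tol, axis=1)
        outer |= np.all(p[:, :, 1] > hw - tol, axis=1)
        outer |= np.all(p[:, :, 1] < -hw + tol, axis=1)
    else:
        for axis in range(p.shape[2]):
            outer |= np.all(p[:, :, axis] > hw - tol, axis=1)
            outer |= np.all(p[:, :, axis] < -hw + tol, axis=1)
    tags[(tags < 0) & outer] = b.index("outer_muscle")
    # carved-channel walls are a staircase in 3D; nodes lie within r_el*sqrt(2)
    shaft = np.all(radial <= 1.5 * r_el + 10 * tol, axis=1) & np.all(
        p[:, :, -1] >= z_top - 10 * tol, axis=1
    )
    tags[(tags < 0) & shaft] = b.index("electrode_bottom")
    if np.any(tags < 0):
        where = p[tags < 0].mean(axis=1)[0] / MM
        raise MeshingError(f"untaggable boundary facet at {where} mm")

    # internal electrode-tissue interface -------------------------------------
    s2 = start[count == 2]
    is_el0 = region[owner_s[s2]] == el_id
    is_el1 = region[owner_s[s2 + 1]] == el_id
    iface = raw_s[s2[is_el0 != is_el1]]

    facets = np.concatenate([bdry, iface], axis=0)
    facet_tags = np.concatenate(
        [tags, np.full(len(iface), b.index("electrode_surface"), dtype=np.int32)]
    )
    return facets.astype(np.int64), facet_tags


def _check_build(mesh: Mesh, spec: GeometrySpec) -> None:
    present = mesh.present_regions()
    if present != set(REGIONS):
        raise MeshingError(f"synthetic mesh missing regions: {sorted(set(REGIONS) - present)}")
    report = validate_mesh(mesh)
    if report.violations:
        raise MeshingError(f"generated mesh violates invariants: {report.violations}")


# ---------------------------------------------------------------------------
# Simple test-domain meshes (analytic oracles)
# ---------------------------------------------------------------------------

def build_annulus_mesh(
    inner_radius_mm: float,
    outer_radius_mm: float,
    length_mm: float,
    edge_mm: float = 0.5,
    region: str = "muscle",
    grade_inner_mm: float | None = None,
) -> Mesh:
    """Axisymmetric annulus r in [a, b], z in [0, L].

    Inner wall tagged ``electrode_surface``, outer wall ``outer_muscle``,
    both ends ``electrode_bottom`` (zero flux).  With a uniform conductivity
    this is the closed-form concentric-cylinder (log-potential) oracle.
    """
    a, bb, L = inner_radius_mm, outer_radius_mm, length_mm
    if not 0 < a < bb or L <= 0:
        raise GeometryError("need 0 < inner < outer radius and positive length")
    r_pts = graded_points(a, bb, _sizing_function([(a, a + 0.5, grade_inner_mm or edge_mm / 4)], edge_mm))
    z_pts = graded_points(0.0, L, lambda x: edge_mm)
    return _structured_rect_mesh(r_pts, z_pts, region, inner_tag="electrode_surface")


def build_block_mesh(
    r0_mm: float,
    r1_mm: float,
    length_mm: float,
    edge_mm: float = 1.0,
    region: str = "muscle",
    mode: str = "axisymmetric_2d",
    dirichlet_outer: bool = False,
) -> Mesh:
    """Homogeneous block, fully insulated by default (all facets ``electrode_bottom``).

    With ``dirichlet_outer=True`` the outer-radius wall is tagged
    ``outer_muscle`` instead.  In ``full_3d`` mode the block is the box
    [r0, r1]^3 shifted to positive coordinates.
    """
    if mode == "full_3d":
        pts = graded_points(r0_mm, r1_mm, lambda x: edge_mm)
        return _structured_box_mesh(pts, region, dirichlet_outer)
    r_pts = graded_points(r0_mm, r1_mm, lambda x: edge_mm)
    z_pts = graded_points(0.0, length_mm, lambda x: edge_mm)
    return _structured_rect_mesh(
        r_pts, z_pts, region,
        inner_tag="electrode_bottom",
        outer_tag="outer_muscle" if dirichlet_outer else "electrode_bottom",
        end_tag="electrode_bottom",
    )


def _structured_rect_mesh(
    r_pts, z_pts, region,
    inner_tag="electrode_surface", outer_tag="outer_muscle", end_tag="electrode_bottom",
) -> Mesh:
    nr, nz = len(r_pts), len(z_pts)
    rr, zz = np.meshgrid(r_pts, z_pts, indexing="ij")
    points = np.column_stack([rr.ravel(), zz.ravel()]) * MM

    def nid(i, j):
        return i * nz + j

    i, j = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1), indexing="ij")
    i, j = i.ravel(), j.ravel()
    n00, n10, n01, n11 = nid(i, j), nid(i + 1, j), nid(i, j + 1), nid(i + 1, j + 1)
    alt = ((i + j) % 2).astype(bool)
    t1 = np.where(alt[:, None], np.column_stack([n00, n10, n11]), np.column_stack([n00, n10, n01]))
    t2 = np.where(alt[:, None], np.column_stack([n00, n11, n01]), np.column_stack([n10, n11, n01]))
    cells = np.concatenate([t1, t2], axis=0)
    meas = _signed_measures(points, cells, 2)
    cells[meas < 0] = cells[meas < 0][:, [0, 2, 1]]
    regions = np.full(len(cells), REGIONS.index(region), dtype=np.int32)

    tol = 1e-9
    a_m, b_m = r_pts[0] * MM, r_pts[-1] * MM
    facets_all = _cell_facets(cells)
    key = np.sort(facets_all, axis=1)
    uniq, count = np.unique(key, axis=0, return_counts=True)
    bdry = uniq[count == 1]
    p = points[bdry]
    tags = np.full(len(bdry), BOUNDARIES.index(end_tag), dtype=np.int32)
    inner = np.all(np.abs(p[:, :, 0] - a_m) < tol, axis=1)
    outer = np.all(np.abs(p[:, :, 0] - b_m) < tol, axis=1)
    tags[inner] = BOUNDARIES.index(inner_tag)
    tags[outer] = BOUNDARIES.index(outer_tag)
    return Mesh(points, cells, regions, REGIONS, bdry, tags, BOUNDARIES, "axisymmetric_2d")


def _structured_box_mesh(pts, region, dirichlet_outer: bool) -> Mesh:
    n = len(pts)
    X, Y, Z = np.meshgrid(pts, pts, pts, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) * MM

    def nid(i, j, k):
        return (i * n + j) * n + k

    i, j, k = np.meshgrid(np.arange(n - 1), np.arange(n - 1), np.arange(n - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corner = [nid(i + di, j + dj, k + dk) for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]
    corner = np.column_stack(corner)
    cells = np.concatenate([corner[:, list(t)] for t in _KUHN_TETS], axis=0)
    meas = _signed_measures(points, cells, 3)
    cells[meas < 0] = cells[meas < 0][:, [0, 1, 3, 2]]
    regions = np.full(len(cells), REGIONS.index(region), dtype=np.int32)

    facets_all = _cell_facets(cells)
    key = np.sort(facets_all, axis=1)
    uniq, count = np.unique(key, axis=0, return_counts=True)
    bdry = uniq[count == 1]
    tag_name = "outer_muscle" if dirichlet_outer else "electrode_bottom"
    tags = np.full(len(bdry), BOUNDARIES.index(tag_name), dtype=np.int32)
    return Mesh(points, cells, regions, REGIONS, bdry, tags, BOUNDARIES, "full_3d")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class MeshReport:
    """Per-region statistics and invariant violations of a labelled mesh."""

    n_nodes: int
    n_cells: int
    region_cell_counts: dict
    min_edge_mm: float
    max_edge_mm: float
    worst_quality: float  # min over cells of (inradius / circumradius) * dim
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_mesh(mesh: Mesh, strict: bool = False) -> MeshReport:
    """Check mesh invariants; with ``strict=True`` raise on any violation."""
    violations: list[str] = []
    counts = {
        name: int((mesh.cell_regions == i).sum()) for i, name in enumerate(mesh.region_names)
    }
    n_untagged = int((mesh.cell_regions < 0).sum()) + int(
        (mesh.cell_regions >= len(mesh.region_names)).sum()
    )
    if n_untagged:
        violations.append(f"untagged element ({n_untagged} cells without a region tag)")
    if mesh.mode == "axisymmetric_2d":
        min_r = float(mesh.points[:, 0].min())
        if min_r < -1e-12:
            violations.append(f"negative radius (min r = {min_r:.3e} m)")
    meas = mesh.cell_measures()
    n_bad = int((meas <= 0).sum())
    if n_bad:
        violations.append(f"inverted or degenerate element ({n_bad} cells)")
    bad_tags = int((mesh.facet_tags < 0).sum()) + int(
        (mesh.facet_tags >= len(mesh.boundary_names)).sum()
    )
    if bad_tags:
        violations.append(f"facet with unknown boundary tag ({bad_tags})")

    lengths = mesh.edge_lengths() / MM
    quality = _radius_ratio(mesh)
    report = MeshReport(
        n_nodes=mesh.n_nodes,
        n_cells=mesh.n_cells,
        region_cell_counts=counts,
        min_edge_mm=float(lengths.min()),
        max_edge_mm=float(lengths.max()),
        worst_quality=float(quality.min()),
        violations=violations,
    )
    if strict and violations:
        raise MeshingError("; ".join(violations))
    return report


def _radius_ratio(mesh: Mesh) -> np.ndarray:
    """Normalised inradius/circumradius quality in (0, 1], 1 for regular simplices."""
    p = mesh.points[mesh.cells]
    meas = np.abs(mesh.cell_measures())
    if mesh.dim == 2:
        e = np.stack(
            [np.linalg.norm(p[:, 1] - p[:, 2], axis=1),
             np.linalg.norm(p[:, 2] - p[:, 0], axis=1),
             np.linalg.norm(p[:, 0] - p[:, 1], axis=1)],
            axis=1,
        )
        s = e.sum(axis=1) / 2
        inr = meas / np.maximum(s, 1e-300)
        circ = e.prod(axis=1) / np.maximum(4 * meas, 1e-300)
        return 2.0 * inr / np.maximum(circ, 1e-300)
    # tetrahedra: inradius = 3V / total face area; circumradius via Cayley formula
    faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    area = sum(
        0.5 * np.linalg.norm(np.cross(p[:, f[1]] - p[:, f[0]], p[:, f[2]] - p[:, f[0]]), axis=1)
        for f in faces
    )
    inr = 3 * meas / np.maximum(area, 1e-300)
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1) * np.linalg.norm(p[:, 2] - p[:, 3], axis=1)
    b = np.linalg.norm(p[:, 0] - p[:, 2], axis=1) * np.linalg.norm(p[:, 1] - p[:, 3], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 3], axis=1) * np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    # Crelle's formula: R = sqrt((a+b+c)(-a+b+c)(a-b+c)(a+b-c)) / (24 V)
    prod = np.maximum((a + b + c) * (-a + b + c) * (a - b + c) * (a + b - c), 0.0)
    circ = np.sqrt(prod) / np.maximum(24 * meas, 1e-300)
    return 3.0 * inr / np.maximum(circ, 1e-300)


# ---------------------------------------------------------------------------
# Optional STL surface import
# ---------------------------------------------------------------------------

def load_stl_surface(path):
    """Load an STL surface (vertices, faces); volumetric meshing is out of scope."""
    try:
        import trimesh
    except ImportError as exc:  # pragma: no cover
        raise ImportError("STL import requires the optional 'trimesh' dependency") from exc
    surf = trimesh.load_mesh(str(path))
    return np.asarray(surf.vertices, dtype=float), np.asarray(surf.faces, dtype=np.int64)
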