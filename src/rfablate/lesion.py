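"""Ablation-zone extraction, diameter measurement and error statistics.

The lesion is the region where the Arrhenius damage integral exceeds the
99 %-cell-death threshold (Omega >= 4.6).  Its volume is computed by
clipping each element against the linearly interpolated iso-contour (exact
for P1 fields), and its size is reported the way radiologists measure it:
three orthogonal diameters through the centre of the active electrode —
"longest" along the electrode axis and "shortest"/"other" perpendicular to
it.  Comparison against radiological measurements mirrors the clinical
evaluation: per-direction absolute errors (simulated minus radiological, the
convention of the published per-case table), relative percentages, and
median/Tukey-hinge summaries per direction plus pooled over all
case-direction pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ElectrodeInfo, Mesh

MM = 1e-3


# ---------------------------------------------------------------------------
# Iso-region extraction
# ---------------------------------------------------------------------------

@dataclass
class LesionRegion:
    """The Omega >= threshold iso-region of a nodal damage field."""

    threshold: float
    node_mask: np.ndarray       # nodes at/above threshold
    cell_fraction: np.ndarray   # per-cell volume fraction above threshold
    volume_m3: float

    @property
    def volume_mm3(self) -> float:
        return self.volume_m3 / MM**3

    @property
    def empty(self) -> bool:
        return self.volume_m3 == 0.0


def extract_lesion(mesh: Mesh, omega: np.ndarray, threshold: float = 4.6) -> LesionRegion:
    """Extract the damage iso-region with sub-element interpolation."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (mesh.n_nodes,):
        raise ValueError("omega must be a nodal field")
    frac = _cell_fractions(mesh, omega, threshold)
    if mesh.mode == "axisymmetric_2d":
        vol = _axisym_clipped_volume(mesh, omega, threshold, frac)
    else:
        vol = float((frac * mesh.cell_volumes()).sum())
    return LesionRegion(threshold, omega >= threshold, frac, vol)


def lesion_volume(mesh: Mesh, omega: np.ndarray, threshold: float = 4.6) -> float:
    """Volume (m^3) of the Omega >= threshold region."""
    return extract_lesion(mesh, omega, threshold).volume_m3


def nodal_lesion_volume(mesh: Mesh, omega: np.ndarray, threshold: float = 4.6) -> float:
    """Fast lumped (node-control-volume) lesion volume used in per-step logs."""
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, mesh.cells.ravel(), mesh.node_cell_weights().ravel())
    return float(w[np.asarray(omega) >= threshold].sum())


def _cell_fractions(mesh: Mesh, omega: np.ndarray, thr: float) -> np.ndarray:
    """Per-cell measure fraction of {omega >= thr} for the P1 interpolant.

    Uses the truncated-power identity for a linear function on a simplex:
    frac{f <= t} = sum_i (t - v_i)_+^d / prod_{j != i} (v_j - v_i).
    """
    v = omega[mesh.cells].astype(float)
    d = v.shape[1] - 1
    lo = v.min(axis=1)
    hi = v.max(axis=1)
    frac = np.zeros(len(v))
    frac[lo >= thr] = 1.0
    cut = (lo < thr) & (hi > thr)
    if cut.any():
        vc = v[cut]
        # break ties deterministically; the identity needs distinct values
        span = (vc.max(axis=1) - vc.min(axis=1))[:, None]
        vc = vc + np.arange(1, d + 2) * 1e-9 * span
        below = np.zeros(len(vc))
        for i in range(d + 1):
            num = np.maximum(thr - vc[:, i], 0.0) ** d
            den = np.ones(len(vc))
            for j in range(d + 1):
                if j != i:
                    den *= vc[:, j] - vc[:, i]
            below += num / den
        frac[cut] = np.clip(1.0 - below, 0.0, 1.0)
    return frac


def _axisym_clipped_volume(mesh: Mesh, omega: np.ndarray, thr: float, frac: np.ndarray) -> float:
    """Exact 2*pi*r-weighted volume of the clipped region (polygon clipping)."""
    vols = mesh.cell_volumes()
    total = float(vols[frac >= 1.0].sum())
    cut = np.flatnonzero((frac > 0.0) & (frac < 1.0))
    pts = mesh.points
    cells = mesh.cells
    vals = omega[cells]
    for e in cut:
        poly = _clip_triangle(pts[cells[e]], vals[e], thr)
        if len(poly) >= 3:
            area, cr = _polygon_area_centroid_r(poly)
            total += 2.0 * math.pi * cr * area
    return total


def _clip_triangle(p: np.ndarray, v: np.ndarray, thr: float) -> list:
    """Vertices of the {linear field >= thr} sub-polygon of a triangle."""
    poly = []
    for i in range(3):
        j = (i + 1) % 3
        if v[i] >= thr:
            poly.append(p[i])
        if (v[i] - thr) * (v[j] - thr) < 0:
            t = (thr - v[i]) / (v[j] - v[i])
            poly.append(p[i] + t * (p[j] - p[i]))
    return poly


def _polygon_area_centroid_r(poly: list) -> tuple:
    """Shoelace area and area-weighted mean r of a planar polygon."""
    a = 0.0
    cr = 0.0
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        w = x1 * y2 - x2 * y1
        a += w
        cr += (x1 + x2) * w
    a *= 0.5
    if a == 0.0:
        return 0.0, 0.0
    cr /= 6.0 * a
    return abs(a), cr


# ---------------------------------------------------------------------------
# Field sampling along lines
# ---------------------------------------------------------------------------

class LineSampler:
    """Barycentric interpolation of nodal fields at fixed sample points.

    Point location is done once at construction; sampling any nodal field is
    then a cheap gather.  Points outside the mesh (e.g. inside the carved
    electrode-shaft channel) sample as NaN.
    """

    def __init__(self, mesh: Mesh, points: np.ndarray):
        self.mesh = mesh
        points = np.asarray(points, dtype=float)
        self.points = points
        n = len(points)
        self.cell_idx = np.full(n, -1, dtype=np.int64)
        self.weights = np.zeros((n, mesh.dim + 1))
        if mesh.dim == 2:
            self._locate_2d()
        else:
            self._locate_3d()

    def _locate_2d(self) -> None:
        import matplotlib.tri as mtri

        tri = mtri.Triangulation(
            self.mesh.points[:, 0], self.mesh.points[:, 1], self.mesh.cells
        )
        finder = tri.get_trifinder()
        idx = finder(self.points[:, 0], self.points[:, 1])
        self.cell_idx = np.asarray(idx, dtype=np.int64)
        ok = self.cell_idx >= 0
        self.weights[ok] = _barycentric(
            self.mesh.points, self.mesh.cells[self.cell_idx[ok]], self.points[ok]
        )

    def _locate_3d(self) -> None:
        from scipy.spatial import cKDTree

        cent = self.mesh.cell_centroids()
        tree = cKDTree(cent)
        k = min(64, self.mesh.n_cells)
        _, cand = tree.query(self.points, k=k)
        cand = np.atleast_2d(cand)
        for i, pt in enumerate(self.points):
            w = _barycentric(self.mesh.points, self.mesh.cells[cand[i]], pt[None, :])
            inside = np.all(w >= -1e-9, axis=1)
            hits = np.flatnonzero(inside)
            if len(hits):
                self.cell_idx[i] = cand[i][hits[0]]
                self.weights[i] = w[hits[0]]

    def sample(self, nodal: np.ndarray) -> np.ndarray:
        out = np.full(len(self.points), np.nan)
        ok = self.cell_idx >= 0
        conn = self.mesh.cells[self.cell_idx[ok]]
        out[ok] = np.einsum("ij,ij->i", nodal[conn], self.weights[ok])
        return out


def _barycentric(points: np.ndarray, cells: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of query points in the given simplices."""
    p = points[cells]  # (n, npc, dim)
    if query.shape[0] == 1 and p.shape[0] > 1:
        query = np.broadcast_to(query, (p.shape[0], query.shape[1]))
    d = p.shape[2]
    T = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))  # (n, dim, dim)
    rhs = (query - p[:, 0])[:, :, None]
    try:
        lam = np.linalg.solve(T, rhs)[:, :, 0]
    except np.linalg.LinAlgError:
        lam = np.full((p.shape[0], d), np.inf)
    return np.column_stack([1.0 - lam.sum(axis=1), lam])


# ---------------------------------------------------------------------------
# Diameter measurement
# ---------------------------------------------------------------------------

@dataclass
class LesionMeasurement:
    """Three orthogonal ablation diameters (mm) and the lesion volume."""

    longest_mm: float
    shortest_mm: float
    other_mm: float
    volume_mm3: float = 0.0
    equal_transverse: bool = False      # axisymmetric: both transverse equal
    labels_by_magnitude: bool = False   # a transverse chord exceeded the axial one

    def as_dict(self) -> dict:
        return {
            "longest_mm": self.longest_mm,
            "shortest_mm": self.shortest_mm,
            "other_mm": self.other_mm,
            "volume_mm3": self.volume_mm3,
            "equal_transverse": self.equal_transverse,
            "labels_by_magnitude": self.labels_by_magnitude,
        }


def make_measurement_samplers(
    mesh: Mesh, electrode: ElectrodeInfo, step_mm: float = 0.2
) -> dict:
    """Pre-locate the axial and transverse measurement lines on a mesh.

    The axial profile follows the symmetry axis up to the electrode's
    proximal face and continues just outside the carved shaft channel above
    it; transverse chords pass through the midpoint of the active electrode.
    """
    zmin = float(mesh.points[:, -1].min())
    zmax = float(mesh.points[:, -1].max())
    step = step_mm * MM
    z = np.arange(zmin + step / 2, zmax - step / 4, step)
    off = electrode.radius_m + 0.25 * MM if mesh.dim == 2 else 1.6 * electrode.radius_m
    if mesh.dim == 2:
        r_line = np.where(z <= electrode.top_z_m, 0.0, off)
        axial_pts = np.column_stack([r_line, z])
        rmax = float(mesh.points[:, 0].max())
        r = np.arange(0.0, rmax, step)
        trans_pts = np.column_stack([r, np.full_like(r, electrode.mid_z_m)])
        return {
            "axial": (LineSampler(mesh, axial_pts), z),
            "transverse": [(LineSampler(mesh, trans_pts), r)],
        }
    x_line = np.where(z <= electrode.top_z_m, 0.0, off)
    axial_pts = np.column_stack([x_line, np.zeros_like(z), z])
    lim = float(np.abs(mesh.points[:, 0]).max())
    s = np.arange(-lim, lim, step)
    tx = np.column_stack([s, np.zeros_like(s), np.full_like(s, electrode.mid_z_m)])
    ty = np.column_stack([np.zeros_like(s), s, np.full_like(s, electrode.mid_z_m)])
    return {
        "axial": (LineSampler(mesh, axial_pts), z),
        "transverse": [(LineSampler(mesh, tx), s), (LineSampler(mesh, ty), s)],
    }


def _extent(coord: np.ndarray, values: np.ndarray, thr: float) -> float:
    """Length of the outermost super-threshold span along a sampled line."""
    above = np.nan_to_num(values, nan=-np.inf) >= thr
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return 0.0
    lo, hi = idx[0], idx[-1]
    x_lo = coord[lo]
    if lo > 0 and np.isfinite(values[lo - 1]):
        t = (thr - values[lo - 1]) / (values[lo] - values[lo - 1])
        x_lo = coord[lo - 1] + t * (coord[lo] - coord[lo - 1])
    x_hi = coord[hi]
    if hi < len(coord) - 1 and np.isfinite(values[hi + 1]):
        t = (thr - values[hi]) / (values[hi + 1] - values[hi])
        x_hi = coord[hi] + t * (coord[hi + 1] - coord[hi])
    return float(x_hi - x_lo)


def measure_diameters(
    mesh: Mesh,
    omega: np.ndarray,
    electrode: ElectrodeInfo,
    threshold: float = 4.6,
    samplers: dict | None = None,
    volume_mm3: float | None = None,
) -> LesionMeasurement:
    """Measure the three orthogonal ablation diameters of the damage field.

    The longest diameter is the lesion extent along the electrode axis; the
    two transverse diameters are chords through the active-electrode
    midpoint.  Of the transverse chords the smaller is labelled "shortest"
    and the larger "other"; should a transverse chord exceed the axial
    extent, the labels follow magnitude order and the measurement is
    flagged.  In axisymmetric mode both transverse chords coincide.
    """
    omega = np.asarray(omega, dtype=float)
    if samplers is None:
        samplers = make_measurement_samplers(mesh, electrode)
    ax_sampler, z = samplers["axial"]
    d_axial = _extent(z, ax_sampler.sample(omega), threshold) / MM

    trans = []
    for sampler, coord in samplers["transverse"]:
        vals = sampler.sample(omega)
        if mesh.dim == 2:
            # radial profile: chord = 2 * outermost crossing radius
            trans.append(2.0 * _outer_radius(coord, vals, threshold) / MM)
        else:
            trans.append(_extent(coord, vals, threshold) / MM)
    equal_transverse = mesh.dim == 2
    if len(trans) == 1:
        trans = [trans[0], trans[0]]

    t_small, t_large = sorted(trans)
    if volume_mm3 is None:
        volume_mm3 = extract_lesion(mesh, omega, threshold).volume_mm3
    if t_large > d_axial:
        ordered = sorted([d_axial, t_small, t_large], reverse=True)
        return LesionMeasurement(
            ordered[0], ordered[2], ordered[1], volume_mm3, equal_transverse, True
        )
    return LesionMeasurement(d_axial, t_small, t_large, volume_mm3, equal_transverse, False)


def _outer_radius(r: np.ndarray, values: np.ndarray, thr: float) -> float:
    above = np.nan_to_num(values, nan=-np.inf) >= thr
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return 0.0
    hi = idx[-1]
    if hi < len(r) - 1 and np.isfinite(values[hi + 1]):
        t = (thr - values[hi]) / (values[hi + 1] - values[hi])
        return float(r[hi] + t * (r[hi + 1] - r[hi]))
    return float(r[hi])


# ---------------------------------------------------------------------------
# Error statistics (clinical-style evaluation)
# ---------------------------------------------------------------------------

DIRECTIONS = ("shortest", "other", "longest")


def tukey_hinges(values) -> tuple:
    """(lower hinge, median, upper hinge) with inclusive halves (Tukey)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        return (math.nan,) * 3
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x)), float(np.median(x[-half:]))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _to_frame(measurements, prefix: str) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        cols = {}
        for d in DIRECTIONS:
            for cand in (f"{prefix}_{d}_mm", f"{d}_mm", d):
                if cand in measurements.columns:
                    cols[d] = measurements[cand].to_numpy(dtype=float)
                    break
            else:
                raise ValueError(f"missing column for direction {d!r}")
        return pd.DataFrame(cols)
    rows = []
    for m in measurements:
        if isinstance(m, LesionMeasurement):
            rows.append({d: getattr(m, f"{d}_mm") for d in DIRECTIONS})
        else:
            rows.append(dict(zip(DIRECTIONS, m)))
    return pd.DataFrame(rows)


def compare_and_summarize(
    radiological,
    simulated,
    sign: str = "simulated_minus_radiological",
):
    """Per-case error table and median/IQR summary of paired diameter sets.

    ``radiological`` and ``simulated`` are equal-length sequences of
    measurements (``LesionMeasurement``, 3-tuples, or DataFrames with
    shortest/other/longest columns).  Absolute errors follow the printed
    per-case evaluation convention, simulated minus radiological
    (``sign="radiological_minus_simulated"`` flips it); relative errors are
    percentages 100 * simulated / radiological rounded half-up.  The summary
    carries per-direction Tukey hinges and medians plus the pooled ("total")
    statistics over every case-direction pair.
    """
    rad = _to_frame(radiological, "radiological")
    sim = _to_frame(simulated, "simulated")
    if len(rad) != len(sim):
        raise ValueError(f"paired lists must have equal length ({len(rad)} vs {len(sim)})")
    if sign not in ("simulated_minus_radiological", "radiological_minus_simulated"):
        raise ValueError(f"unknown sign convention {sign!r}")
    flip = -1.0 if sign == "radiological_minus_simulated" else 1.0

    errors = pd.DataFrame({"case": np.arange(1, len(rad) + 1)})
    for d in DIRECTIONS:
        errors[f"error_{d}_mm"] = flip * (sim[d] - rad[d])
        errors[f"relative_{d}_pct"] = [
            _round_half_up(100.0 * s / r) for s, r in zip(sim[d], rad[d])
        ]

    summary_rows = []
    pooled = []
    for d in DIRECTIONS:
        e = errors[f"error_{d}_mm"].to_numpy()
        pooled.extend(e.tolist())
        lo, med, hi = tukey_hinges(e)
        summary_rows.append({"direction": d, "iqr1_mm": lo, "median_mm": med, "iqr3_mm": hi})
    lo, med, hi = tukey_hinges(pooled)
    summary_rows.append({"direction": "total", "iqr1_mm": lo, "median_mm": med, "iqr3_mm": hi})
    return errors, pd.DataFrame(summary_rows)
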