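"""Lesion extraction, diameter measurement and the clinical error tables."""

import numpy as np
import pandas as pd
import pytest

from rfablate import (
    ElectrodeInfo,
    build_block_mesh,
    clinical_cases,
    compare_and_summarize,
    extract_lesion,
    lesion_volume,
    measure_diameters,
    tukey_hinges,
)
from rfablate.lesion import DIRECTIONS, LesionMeasurement

MM3 = 1e-9


@pytest.fixture(scope="module")
def fine_block():
    """Axisymmetric block r in [0, 40] mm, z in [0, 40] mm."""
    return build_block_mesh(0.0, 40.0, 40.0, edge_mm=0.8, region="tumour")


class TestExtraction:
    def test_zero_field_gives_empty_lesion(self, fine_block):
        region = extract_lesion(fine_block, np.zeros(fine_block.n_nodes))
        assert region.empty
        assert region.volume_m3 == 0.0

    def test_saturated_field_covers_whole_domain(self, fine_block):
        region = extract_lesion(fine_block, np.full(fine_block.n_nodes, 10.0))
        assert region.volume_m3 == pytest.approx(fine_block.cell_volumes().sum(), rel=1e-12)

    def test_cone_field_iso_surface_is_half_radius_sphere(self, fine_block):
        """Omega = 9.2 max(0, 1 - d/R): the 4.6 level set is the d = R/2 sphere."""
        center = np.array([0.0, 0.02])
        R = 0.015
        d = np.linalg.norm(fine_block.points - center, axis=1)
        omega = 9.2 * np.maximum(0.0, 1.0 - d / R)
        vol = lesion_volume(fine_block, omega) / MM3
        exact = 4.0 / 3.0 * np.pi * 7.5**3
        assert vol == pytest.approx(exact, rel=0.02)

    def test_volume_converges_under_refinement(self):
        center = np.array([0.0, 0.02])
        R = 0.015
        errs = []
        for h in (2.0, 1.0, 0.5):
            mesh = build_block_mesh(0.0, 40.0, 40.0, edge_mm=h, region="tumour")
            d = np.linalg.norm(mesh.points - center, axis=1)
            omega = 9.2 * np.maximum(0.0, 1.0 - d / R)
            vol = lesion_volume(mesh, omega) / MM3
            errs.append(abs(vol - 4.0 / 3.0 * np.pi * 7.5**3))
        assert errs[2] < errs[0]

    def test_3d_fraction_formula(self):
        """Tetrahedral sub-volume fractions against the same analytic sphere."""
        mesh = build_block_mesh(-25.0, 25.0, 0.0, edge_mm=1.5, region="tumour", mode="full_3d")
        d = np.linalg.norm(mesh.points, axis=1)
        omega = 9.2 * np.maximum(0.0, 1.0 - d / 0.020)
        vol = lesion_volume(mesh, omega) / MM3
        exact = 4.0 / 3.0 * np.pi * 10.0**3
        assert vol == pytest.approx(exact, rel=0.02)


class TestDiameters:
    def test_ellipsoid_chords(self):
        """Semi-axes (20, 15, 12) mm along (z, x, y) give diameters 40/30/24."""
        mesh = build_block_mesh(-30.0, 30.0, 0.0, edge_mm=2.0, region="tumour", mode="full_3d")
        el = ElectrodeInfo(0.00075, -0.005, 0.005, (0.0, 0.0), "full_3d")
        p = mesh.points
        # linear-in-distance field along every ray: iso-surface at half scale
        rho = np.sqrt((p[:, 2] / 0.040) ** 2 + (p[:, 0] / 0.030) ** 2 + (p[:, 1] / 0.024) ** 2)
        omega = 9.2 * np.maximum(0.0, 1.0 - rho)
        m = measure_diameters(mesh, omega, el)
        assert m.longest_mm == pytest.approx(40.0, rel=0.01)
        assert m.other_mm == pytest.approx(30.0, rel=0.01)
        assert m.shortest_mm == pytest.approx(24.0, rel=0.01)
        assert not m.labels_by_magnitude

    def test_sphere_gives_equal_diameters(self, fine_block):
        el = ElectrodeInfo(0.00075, 0.012, 0.028, (0.0, 0.0), "axisymmetric_2d")
        center = np.array([0.0, 0.02])
        d = np.linalg.norm(fine_block.points - center, axis=1)
        omega = 9.2 * np.maximum(0.0, 1.0 - d / 0.020)  # iso at 10 mm radius
        m = measure_diameters(fine_block, omega, el)
        assert m.longest_mm == pytest.approx(20.0, rel=0.01)
        assert m.shortest_mm == pytest.approx(20.0, rel=0.01)
        assert m.other_mm == pytest.approx(20.0, rel=0.01)
        assert m.equal_transverse

    def test_transverse_dominant_lesion_relabelled(self, fine_block):
        """A pancake lesion flags magnitude-ordered labels."""
        el = ElectrodeInfo(0.00075, 0.012, 0.028, (0.0, 0.0), "axisymmetric_2d")
        p = fine_block.points
        rho = np.sqrt((p[:, 0] / 0.030) ** 2 + ((p[:, 1] - 0.02) / 0.010) ** 2)
        omega = 9.2 * np.maximum(0.0, 1.0 - rho)  # radius 15 mm, half-height 5 mm
        m = measure_diameters(fine_block, omega, el)
        assert m.labels_by_magnitude
        assert m.longest_mm == pytest.approx(30.0, rel=0.02)
        assert m.shortest_mm == pytest.approx(10.0, rel=0.02)

    def test_empty_lesion_measures_zero(self, fine_block):
        el = ElectrodeInfo(0.00075, 0.012, 0.028, (0.0, 0.0), "axisymmetric_2d")
        m = measure_diameters(fine_block, np.zeros(fine_block.n_nodes), el)
        assert m.longest_mm == m.shortest_mm == m.other_mm == 0.0


@pytest.fixture(scope="module")
def tables():
    df = clinical_cases()
    rad = df[[f"radiological_{d}_mm" for d in DIRECTIONS]]
    sim = df[[f"simulated_{d}_mm" for d in DIRECTIONS]]
    return compare_and_summarize(rad, sim)


class TestErrorStatistics:
    """Reproduction of the published per-case evaluation tables."""

    # absolute errors (simulated - radiological) per case and direction,
    # exactly as printed in the per-case error table
    PRINTED_ERRORS = {
        "shortest": [10, 1, 8, -1, -1, 8, 3],
        "other": [-1, -10, -3, -2, -6, 4, -1],
        "longest": [-1, -9, 0, 0, -6, -5, 7],
    }
    PRINTED_RELATIVE = {
        "shortest": [138, 102, 129, 98, 98, 122, 113],
        "other": [98, 81, 92, 95, 88, 112, 97],
        "longest": [98, 86, 100, 100, 88, 89, 123],
    }

    def test_every_absolute_error_cell(self, tables):
        errors, _ = tables
        for d in DIRECTIONS:
            assert errors[f"error_{d}_mm"].tolist() == self.PRINTED_ERRORS[d]

    def test_every_relative_error_cell(self, tables):
        errors, _ = tables
        for d in DIRECTIONS:
            assert errors[f"relative_{d}_pct"].tolist() == self.PRINTED_RELATIVE[d]

    def test_per_direction_medians(self, tables):
        _, summary = tables
        med = dict(zip(summary["direction"], summary["median_mm"]))
        assert med["shortest"] == 3.0
        assert med["other"] == -2.0
        assert med["longest"] == -1.0

    def test_pooled_median_and_iqr(self, tables):
        _, summary = tables
        total = summary[summary["direction"] == "total"].iloc[0]
        assert total["median_mm"] == -1.0
        assert total["iqr1_mm"] == -3.0
        assert total["iqr3_mm"] == 3.0

    def test_per_direction_hinges(self, tables):
        _, summary = tables
        rows = {r["direction"]: r for _, r in summary.iterrows()}
        assert (rows["shortest"]["iqr1_mm"], rows["shortest"]["iqr3_mm"]) == (0.0, 8.0)
        assert (rows["other"]["iqr1_mm"], rows["other"]["iqr3_mm"]) == (-4.5, -1.0)
        assert (rows["longest"]["iqr1_mm"], rows["longest"]["iqr3_mm"]) == (-5.5, 0.0)

    def test_identical_lists_give_zero_errors(self):
        m = [LesionMeasurement(40.0, 25.0, 30.0)] * 3
        errors, summary = compare_and_summarize(m, m)
        assert (errors.filter(like="error_") == 0).all().all()
        assert (summary["median_mm"] == 0).all()

    def test_sign_convention_flip(self):
        df = clinical_cases()
        rad = df[[f"radiological_{d}_mm" for d in DIRECTIONS]]
        sim = df[[f"simulated_{d}_mm" for d in DIRECTIONS]]
        flipped, _ = compare_and_summarize(rad, sim, sign="radiological_minus_simulated")
        assert flipped["error_shortest_mm"].tolist() == [-e for e in self.PRINTED_ERRORS["shortest"]]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_and_summarize(
                [LesionMeasurement(40, 25, 30)], [LesionMeasurement(40, 25, 30)] * 2
            )


def test_tukey_hinges_odd_sample():
    lo, med, hi = tukey_hinges([-1, -1, 1, 3, 8, 8, 10])
    assert (lo, med, hi) == (0.0, 3.0, 8.0)


def test_diameters_nondecreasing_through_simulation(short_coarse_run):
    """Damage monotonicity makes every reported diameter non-decreasing."""
    df = short_coarse_run["result"].summary
    for col in ("d_longest_mm", "d_shortest_mm", "d_other_mm"):
        assert (np.diff(df[col].to_numpy()) >= -1e-9).all()
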