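"""Synthetic geometry generation, MSH round trips and mesh validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfablate import (
    GeometryError,
    GeometrySpec,
    MeshingError,
    build_annulus_mesh,
    build_block_mesh,
    build_synthetic_geometry,
    read_msh,
    validate_mesh,
    write_msh,
)
from rfablate.geometry import DEFAULT_EDGE_LENGTHS_MM
from rfablate.tissues import BOUNDARIES, REGIONS

from conftest import COARSE_EDGES

MM3 = 1e-9


class TestSpecValidation:
    def test_default_spec_is_valid(self):
        GeometrySpec().validate()

    def test_tumour_outside_muscle_box(self):
        with pytest.raises(GeometryError, match="muscle box"):
            GeometrySpec(tumour_center_mm=(0, 0, 55), tumour_semiaxes_mm=(10, 10, 10)).validate()

    def test_tumour_outside_bone_envelope(self):
        with pytest.raises(GeometryError, match="bone"):
            GeometrySpec(tumour_semiaxes_mm=(20, 20, 20)).validate()

    def test_electrode_outside_domain(self):
        with pytest.raises(GeometryError, match="electrode"):
            GeometrySpec(electrode_tip_position_mm=(0, 0, 50)).validate()

    def test_axis_must_hit_tumour_in_3d(self):
        with pytest.raises(GeometryError, match="axis"):
            GeometrySpec(
                mode="full_3d", tumour_center_mm=(30, 0, 0), tumour_semiaxes_mm=(10, 10, 10)
            ).validate()


class TestSyntheticMesh:
    def test_all_five_regions_present_and_partitioning(self, default_mesh):
        assert default_mesh.present_regions() == set(REGIONS)
        assert np.all(default_mesh.cell_regions >= 0)

    def test_tumour_volume_matches_sphere(self, default_mesh):
        vol = default_mesh.region_volume("tumour") / MM3
        exact = 4.0 / 3.0 * np.pi * 10.0**3
        assert vol == pytest.approx(exact, rel=0.02)

    def test_halving_edge_lengths_triples_cell_count(self, default_mesh):
        half = {k: v / 2 for k, v in DEFAULT_EDGE_LENGTHS_MM.items()}
        fine = build_synthetic_geometry(GeometrySpec(target_edge_lengths_mm=half))
        assert fine.n_cells >= 3 * default_mesh.n_cells

    def test_electrode_sizing_band(self, default_mesh):
        """Edges of electrode-surface facets stay inside the configured band."""
        surf = default_mesh.facets_of("electrode_surface")
        d = default_mesh.points[surf[:, 0]] - default_mesh.points[surf[:, 1]]
        lengths_mm = np.linalg.norm(d, axis=1) / 1e-3
        assert lengths_mm.max() <= 2.0 * DEFAULT_EDGE_LENGTHS_MM["electrode"]

    def test_all_boundary_tags_present(self, default_mesh):
        for name in BOUNDARIES:
            assert len(default_mesh.facets_of(name)) > 0

    def test_no_negative_radius(self, default_mesh):
        assert default_mesh.points[:, 0].min() >= -1e-12

    def test_validation_clean(self, default_mesh):
        report = validate_mesh(default_mesh, strict=True)
        assert report.ok
        assert report.region_cell_counts["electrode"] > 0

    def test_coarse_3d_mesh(self):
        mesh = build_synthetic_geometry(
            GeometrySpec(
                mode="full_3d",
                target_edge_lengths_mm={
                    "electrode": 1.5, "tumour": 4.0, "trabecular": 4.0,
                    "cortical": 4.0, "muscle": 12.0,
                },
            )
        )
        assert mesh.present_regions() == set(REGIONS)
        assert validate_mesh(mesh, strict=True).ok
        vol = mesh.region_volume("tumour") / MM3
        exact = 4.0 / 3.0 * np.pi * 10.0**3
        assert vol == pytest.approx(exact, rel=0.08)


@settings(max_examples=6, deadline=None, derandomize=True)
@given(
    length=st.sampled_from([20.0, 30.0]),
    bone_r=st.floats(min_value=13.0, max_value=18.0),
    tum_r=st.floats(min_value=6.0, max_value=11.0),
    tip_z=st.floats(min_value=-18.0, max_value=-12.0),
)
def test_randomised_specs_build_valid_meshes(length, bone_r, tum_r, tip_z):
    tum_r = min(tum_r, bone_r - 2.0)
    spec = GeometrySpec(
        electrode_active_length_mm=length,
        bone_outer_radius_mm=bone_r,
        tumour_semiaxes_mm=(tum_r, tum_r, tum_r),
        electrode_tip_position_mm=(0.0, 0.0, tip_z),
        target_edge_lengths_mm=dict(COARSE_EDGES),
    )
    mesh = build_synthetic_geometry(spec)
    assert mesh.present_regions() == set(REGIONS)
    assert validate_mesh(mesh, strict=True).ok


class TestMshRoundTrip:
    def test_build_write_read_identical(self, coarse_mesh, tmp_path):
        path = tmp_path / "femur.msh"
        write_msh(path, coarse_mesh)
        again = read_msh(path)
        assert again.n_nodes == coarse_mesh.n_nodes
        assert np.array_equal(again.cells, coarse_mesh.cells)
        assert np.array_equal(again.cell_regions, coarse_mesh.cell_regions)
        assert np.array_equal(again.facet_tags, coarse_mesh.facet_tags)
        assert np.allclose(again.points, coarse_mesh.points)

    def test_unmapped_physical_group_errors(self, tmp_path):
        mesh = build_block_mesh(5.0, 15.0, 10.0, edge_mm=5.0)
        path = tmp_path / "renamed.msh"
        write_msh(path, mesh)
        path.write_text(path.read_text().replace('"muscle"', '"fat"'))
        with pytest.raises(MeshingError, match="fat"):
            read_msh(path, required_regions=("muscle",))

    def test_name_map_resolves_foreign_names(self, tmp_path):
        mesh = build_block_mesh(5.0, 15.0, 10.0, edge_mm=5.0)
        path = tmp_path / "renamed.msh"
        write_msh(path, mesh)
        path.write_text(path.read_text().replace('"muscle"', '"fat"'))
        again = read_msh(path, name_map={"fat": "muscle"}, required_regions=("muscle",))
        assert again.present_regions() == {"muscle"}

    def test_missing_region_errors(self, tmp_path):
        mesh = build_block_mesh(5.0, 15.0, 10.0, edge_mm=5.0)  # muscle only
        path = tmp_path / "block.msh"
        write_msh(path, mesh)
        with pytest.raises(MeshingError, match="electrode"):
            read_msh(path)

    def test_msh4_rejected(self, tmp_path):
        path = tmp_path / "v4.msh"
        path.write_text("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        with pytest.raises(MeshingError, match="version"):
            read_msh(path)


class TestValidateMesh:
    def test_negative_radius_detected(self):
        mesh = build_block_mesh(0.0, 10.0, 10.0, edge_mm=2.0)
        mesh.points[0, 0] = -1e-9
        report = validate_mesh(mesh)
        assert any("negative radius" in v for v in report.violations)

    def test_untagged_element_detected(self):
        mesh = build_block_mesh(0.0, 10.0, 10.0, edge_mm=2.0)
        mesh.cell_regions[0] = -1
        report = validate_mesh(mesh)
        assert any("untagged" in v for v in report.violations)
        with pytest.raises(MeshingError):
            validate_mesh(mesh, strict=True)

    def test_inverted_element_detected(self):
        mesh = build_block_mesh(0.0, 10.0, 10.0, edge_mm=2.0)
        mesh.cells[0] = mesh.cells[0][[0, 2, 1]]
        report = validate_mesh(mesh)
        assert any("inverted" in v for v in report.violations)


class TestOracleMeshes:
    def test_annulus_tags(self):
        mesh = build_annulus_mesh(1.0, 20.0, 5.0, edge_mm=1.0)
        assert len(mesh.boundary_nodes("electrode_surface")) > 0
        assert len(mesh.boundary_nodes("outer_muscle")) > 0
        a = mesh.points[mesh.boundary_nodes("electrode_surface"), 0]
        assert np.allclose(a, 1e-3)

    def test_annulus_volume(self):
        mesh = build_annulus_mesh(5.0, 10.0, 4.0, edge_mm=0.5)
        vol = mesh.cell_volumes().sum() / MM3
        exact = np.pi * (10.0**2 - 5.0**2) * 4.0
        assert vol == pytest.approx(exact, rel=1e-9)  # exact for polygonal annulus

    def test_block_is_fully_insulated_by_default(self):
        mesh = build_block_mesh(10.0, 20.0, 10.0, edge_mm=2.0)
        assert set(mesh.facet_tags) == {mesh.boundary_id("electrode_bottom")}
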