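import numpy as np
import pytest

from sinuflow.config import GeometryParams, StenosisSpec
from sinuflow.geometry import build_geometry
from sinuflow.meshing import (generate_mesh, refine_mesh, mesh_quality,
                              rectangle_mesh, write_msh, read_msh, write_vtk)


@pytest.fixture(scope="module")
def full_mesh(scenario_mesh):
    return scenario_mesh[1]


class TestGenerateMesh:
    @pytest.mark.parametrize("h_mm", [0.3, 0.8, 2.0])
    def test_element_size_and_angle_contracts(self, scenario_mesh, h_mm):
        geom, _ = scenario_mesh
        mesh = generate_mesh(geom, h_mm * 1e-3)
        q = mesh_quality(mesh)
        assert q["max_circumdiameter"] <= h_mm * 1e-3 * (1 + 1e-9)
        assert q["min_angle_deg"] > 15.0

    def test_rectangle_markers_sum_to_perimeter(self):
        geo = GeometryParams(ts_length=8.0, bend_angle_deg=0.0, ss_length=2.0,
                             half_width=1.0, stenosis=StenosisSpec(rate=100.0),
                             diverticulum=None, cavity_enabled=False)
        g = build_geometry(geo, stented=False)
        mesh = generate_mesh(g, 5e-4)
        lengths = {}
        for name in ("inlet", "outlet", "lateral", "interface"):
            lengths[name] = mesh.edge_lengths(mesh.marker_edges(name)).sum()
        assert lengths["inlet"] == pytest.approx(2e-3)
        assert lengths["lateral"] == pytest.approx(10e-3)
        # lumen loop perimeter: rectangle 10 mm x 2 mm
        assert sum(lengths.values()) == pytest.approx(24e-3)

    def test_all_four_regions_present(self, full_mesh):
        counts = mesh_quality(full_mesh)["region_counts"]
        assert set(counts) == {"lumen", "wall", "bone", "air"}
        assert all(c > 0 for c in counts.values())

    def test_every_marked_edge_has_one_marker(self, full_mesh):
        # each edge appears once in the marked set
        key = np.sort(full_mesh.edges, axis=1)
        uniq = np.unique(key, axis=0)
        assert len(uniq) == len(full_mesh.edges)

    def test_halving_h_grows_elements_3_to_5x(self, scenario_mesh):
        geom, _ = scenario_mesh
        n1 = len(generate_mesh(geom, 2.0e-3).triangles)
        n2 = len(generate_mesh(geom, 1.0e-3).triangles)
        assert 3.0 <= n2 / n1 <= 5.0

    def test_infeasible_h_rejected(self, scenario_mesh):
        geom, _ = scenario_mesh
        with pytest.raises(ValueError, match="cap"):
            generate_mesh(geom, 1.0e-5)

    def test_interface_nodes_shared_between_regions(self, full_mesh):
        lumen = set(np.unique(full_mesh.region_tris("lumen")).tolist())
        wall = set(np.unique(full_mesh.region_tris("wall")).tolist())
        itf = set(np.unique(full_mesh.marker_edges("interface")).tolist())
        assert itf <= (lumen & wall)


class TestRefineMesh:
    def test_midpoint_subdivision_counts_and_area(self, full_mesh):
        fine = refine_mesh(full_mesh)
        assert len(fine.triangles) == 4 * len(full_mesh.triangles)
        for region in full_mesh.regions:
            assert fine.region_area(region) == pytest.approx(
                full_mesh.region_area(region), abs=1e-15)

    def test_nesting_node_superset(self, full_mesh):
        fine = refine_mesh(full_mesh)
        finer = refine_mesh(fine)
        pts = {tuple(p) for p in finer.points.round(12)}
        assert all(tuple(p) in pts for p in fine.points.round(12))

    def test_markers_inherited_with_length(self, full_mesh):
        fine = refine_mesh(full_mesh)
        for name in full_mesh.markers:
            l0 = full_mesh.edge_lengths(full_mesh.marker_edges(name)).sum()
            l1 = fine.edge_lengths(fine.marker_edges(name)).sum()
            assert l1 == pytest.approx(l0, rel=1e-12)

    def test_quality_preserved(self, full_mesh):
        q0 = mesh_quality(full_mesh)
        q1 = mesh_quality(refine_mesh(full_mesh))
        assert q1["min_angle_deg"] >= q0["min_angle_deg"] - 1e-9


class TestMeshQuality:
    def test_equilateral_reference(self):
        import sinuflow.meshing as M

        tri = M.Mesh(
            points=np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]),
            triangles=np.array([[0, 1, 2]]),
            tri_region=np.array([0], dtype=np.int32), regions={"lumen": 0},
            edges=np.zeros((0, 2), dtype=np.int64),
            edge_marker=np.zeros(0, dtype=np.int32), markers={}, h=1.0)
        q = mesh_quality(tri)
        assert q["min_angle_deg"] == pytest.approx(60.0)
        assert q["max_aspect"] == pytest.approx(1.0)


def test_msh_round_trip(tmp_path, full_mesh):
    path = tmp_path / "mesh.msh"
    write_msh(full_mesh, path)
    back = read_msh(path)
    assert np.allclose(back.points, full_mesh.points)
    assert np.array_equal(back.triangles, full_mesh.triangles)
    assert np.array_equal(back.tri_region, full_mesh.tri_region)
    assert back.regions == full_mesh.regions
    assert np.array_equal(back.edge_marker, full_mesh.edge_marker)


def test_vtk_writer_emits_valid_header(tmp_path, full_mesh):
    path = tmp_path / "mesh.vtk"
    write_vtk(full_mesh, path,
              point_data={"p": np.zeros(full_mesh.num_nodes)})
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert f"POINTS {full_mesh.num_nodes} double" in text
    assert "SCALARS p double 1" in text
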