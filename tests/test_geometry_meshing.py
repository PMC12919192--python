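"""Geometry validation and labeled-mesh quality/volume checks."""

import numpy as np
import pytest

from cellstretch import (
    CellGeometry,
    GeometryError,
    InvalidParameterError,
    MeshSizing,
    build_geometry,
    mesh_geometry,
    region_volume,
)
from cellstretch.meshing import CYTOPLASM, NUCLEUS, LabeledMesh, box_mesh


class TestGeometry:
    def test_default_geometry_is_valid(self):
        with pytest.warns(UserWarning, match="tangent"):
            g = build_geometry({})
        assert g.cell_semi_axes == (25.0, 15.0, 6.0)
        assert g.cell_volume == pytest.approx(2 / 3 * np.pi * 25 * 15 * 6)

    def test_nucleus_taller_than_cell_rejected(self):
        with pytest.raises(GeometryError, match="outside"):
            build_geometry(
                {"nucleus_semi_axes_um": (8, 6, 10), "nucleus_center_um": (0, 0, 3)}
            )

    def test_nucleus_below_substrate_rejected(self):
        with pytest.raises(GeometryError, match="basal"):
            build_geometry({"nucleus_center_um": (0.0, 0.0, 2.0)})

    def test_round_cell_allowed_with_degeneracy_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            build_geometry(
                {
                    "cell_semi_axes_um": (10, 10, 5),
                    "nucleus_semi_axes_um": (4, 4, 2),
                    "nucleus_center_um": (0, 0, 2.2),
                }
            )

    def test_long_axis_convention_enforced(self):
        with pytest.raises(GeometryError, match="long axis"):
            CellGeometry(cell_semi_axes=(10, 15, 6))

    def test_unknown_config_key_rejected(self):
        with pytest.raises(InvalidParameterError, match="wobble"):
            build_geometry({"wobble": 3})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h_max": 0.0},
            {"h_refined": 1.2, "h_max": 1.0},
            {"growth_rate": 1.0},
        ],
    )
    def test_sizing_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            MeshSizing(**{"h_max": 2.0, "growth_rate": 1.4, "h_refined": 0.5, **kwargs})


class TestLabeledMesh:
    def test_cell_volume_matches_analytic(self, default_geometry, ci_mesh):
        assert ci_mesh.total_volume() == pytest.approx(
            default_geometry.cell_volume, rel=0.02
        )

    def test_nucleus_volume_matches_analytic(self, default_geometry, ci_mesh):
        assert region_volume(ci_mesh, "nucleus") == pytest.approx(
            default_geometry.nucleus_volume, rel=0.02
        )

    def test_region_partition(self, ci_mesh):
        total = region_volume(ci_mesh, "cytoplasm") + region_volume(ci_mesh, "nucleus")
        assert total == pytest.approx(ci_mesh.total_volume(), rel=1e-12)
        assert set(np.unique(ci_mesh.region)) == {CYTOPLASM, NUCLEUS}

    def test_all_tets_positive(self, ci_mesh):
        assert ci_mesh.tet_volumes.min() > 0

    def test_basal_facets_on_substrate_plane(self, ci_mesh):
        z = ci_mesh.vertices[ci_mesh.basal_facets, 2]
        assert np.abs(z).max() < 1e-9

    def test_membrane_facets_off_substrate(self, ci_mesh):
        z = ci_mesh.vertices[ci_mesh.membrane_facets, 2]
        assert np.all(z.max(axis=1) > 1e-6)

    def test_interface_facets_shared_pairwise(self, ci_mesh):
        """Each interior facet belongs to exactly two tets; nucleus/cytoplasm
        interface facets pair one tet of each region."""
        tets = ci_mesh.tets
        faces = np.concatenate(
            [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
        )
        owner = np.tile(np.arange(len(tets)), 4)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        assert counts.max() == 2
        order = np.argsort(inv, kind="stable")
        inv_sorted, owner_sorted = inv[order], owner[order]
        starts = np.searchsorted(inv_sorted, np.arange(counts.size))
        pair_mask = counts == 2
        a = owner_sorted[starts[pair_mask]]
        b = owner_sorted[starts[pair_mask] + 1]
        cross = ci_mesh.region[a] != ci_mesh.region[b]
        assert cross.sum() > 0  # the interface exists and is shared

    def test_coarse_sizing_still_valid(self, default_geometry):
        m = mesh_geometry(default_geometry, MeshSizing(3.0, 1.4, 1.2))
        assert m.tet_volumes.min() > 0
        assert set(np.unique(m.region)) <= {CYTOPLASM, NUCLEUS}
        assert region_volume(m, "nucleus") > 0

    def test_unknown_region_rejected(self, ci_mesh):
        with pytest.raises(InvalidParameterError):
            region_volume(ci_mesh, "mitochondria")


class TestRegionVolume:
    def test_regular_tetrahedron_volume(self):
        """A single regular tet of edge a has volume a^3 / (6 sqrt(2))."""
        a = 2.0
        verts = a * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
        ) / np.sqrt(8)  # regular tet with edge a
        tets = np.array([[0, 1, 2, 3]])
        from cellstretch.meshing import _tet_volumes

        vol = abs(_tet_volumes(verts, tets)[0])
        mesh = LabeledMesh(
            vertices=verts,
            tets=tets if _tet_volumes(verts, tets)[0] > 0 else tets[:, [0, 1, 3, 2]],
            region=np.array([NUCLEUS], dtype=np.int8),
        )
        assert region_volume(mesh, "nucleus") == pytest.approx(a**3 / (6 * np.sqrt(2)))
        assert vol == pytest.approx(a**3 / (6 * np.sqrt(2)))


class TestBoxMesh:
    def test_volume_exact(self):
        m = box_mesh((2.0, 3.0, 1.5), (3, 2, 2))
        assert m.total_volume() == pytest.approx(2.0 * 3.0 * 1.5, rel=1e-12)
        assert m.tet_volumes.min() > 0

    def test_boundary_labels(self):
        m = box_mesh((1, 1, 1), (2, 2, 2), with_membrane=True)
        assert np.abs(m.vertices[m.basal_facets, 2]).max() == 0.0
        assert len(m.membrane_facets) > 0
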