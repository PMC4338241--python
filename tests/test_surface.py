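import numpy as np
import pytest

from cranioreg.geometry import Ball
from cranioreg.phantom import PhantomSpec, build_phantom, build_sphere_volume
from cranioreg.surface import (
    NoSurfaceError,
    RegionMissError,
    StlParseError,
    TriMesh,
    Volume,
    circular_patch,
    clean_components,
    decimate_to_budget,
    extract_isosurface,
    load_volume,
    read_stl,
    save_volume,
    select_region,
    write_stl,
)

from conftest import COARSE_KW, make_plate


class TestIsosurface:
    def test_sphere_area_within_two_percent(self):
        vol = build_sphere_volume(radius_mm=20.0, voxel_size_mm=0.8)
        mesh = extract_isosurface(vol, 500.0)
        analytic = 4 * np.pi * 20.0**2
        assert abs(mesh.area() - analytic) / analytic < 0.02

    def test_any_bone_threshold_cuts_same_interface_on_binary_volume(self):
        # on a binary volume every bone-range threshold crosses the same set
        # of voxel edges: identical topology, vertices within half a voxel
        # (linear interpolation shifts crossings along the edge)
        vol = build_sphere_volume(radius_mm=10.0, voxel_size_mm=1.0, partial_volume=False)
        m300 = extract_isosurface(vol, 300.0)
        m500 = extract_isosurface(vol, 500.0)
        assert m300.n_faces == m500.n_faces
        np.testing.assert_array_equal(m300.faces, m500.faces)
        assert np.abs(m300.vertices - m500.vertices).max() < 0.5

    def test_empty_volume_raises(self):
        vol = Volume(np.zeros((8, 8, 8)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(NoSurfaceError):
            extract_isosurface(vol, 500.0)

    def test_convex_mesh_is_closed(self):
        vol = build_sphere_volume(radius_mm=10.0, voxel_size_mm=1.0)
        tm = extract_isosurface(vol, 500.0).to_trimesh()
        assert tm.is_watertight
        assert tm.euler_number == 2

    def test_isosurface_position_converges_with_voxel_size(self):
        errs = []
        for h in (1.0, 0.5):
            vol = build_sphere_volume(radius_mm=10.0, voxel_size_mm=h)
            mesh = extract_isosurface(vol, 500.0)
            center = (np.array(vol.shape) - 1) * h / 2
            r = np.linalg.norm(mesh.vertices - center, axis=1)
            errs.append(np.abs(r - 10.0).max())
        # first-order convergence: the ratio sits at ~0.5 up to
        # discretisation jitter on the max statistic
        assert errs[1] <= 0.55 * errs[0]


class TestCleanComponents:
    def test_single_component_unchanged(self, icosphere_mesh):
        out = clean_components(icosphere_mesh, 0.01)
        assert out.n_faces == icosphere_mesh.n_faces
        assert len(out.vertices) == len(icosphere_mesh.vertices)

    def test_floater_removed_sphere_kept(self, icosphere_mesh):
        # append a 10-triangle floater far away
        rng = np.random.default_rng(0)
        base = np.array([100.0, 100.0, 100.0])
        fverts, ffaces = [], []
        for i in range(10):
            tri = base + rng.normal(0, 1, (3, 3)) + i * 5
            ffaces.append([3 * i, 3 * i + 1, 3 * i + 2])
            fverts.append(tri)
        fverts = np.concatenate(fverts)
        mesh = TriMesh(
            np.vstack([icosphere_mesh.vertices, fverts]),
            np.vstack(
                [icosphere_mesh.faces, np.array(ffaces) + len(icosphere_mesh.vertices)]
            ),
        )
        out = clean_components(mesh, 0.01)
        assert out.n_faces == icosphere_mesh.n_faces

    def test_equal_components_both_retained(self, icosphere_mesh):
        shifted = TriMesh(icosphere_mesh.vertices + 100.0, icosphere_mesh.faces.copy())
        both = TriMesh(
            np.vstack([icosphere_mesh.vertices, shifted.vertices]),
            np.vstack(
                [icosphere_mesh.faces, shifted.faces + len(icosphere_mesh.vertices)]
            ),
        )
        out = clean_components(both, 0.5)
        assert out.n_faces == 2 * icosphere_mesh.n_faces


class TestDecimation:
    def test_within_budget_is_identity(self, icosphere_mesh):
        out = decimate_to_budget(icosphere_mesh, 100_000)
        assert out is icosphere_mesh

    def test_area_preserved_to_five_percent(self):
        vol = build_sphere_volume(radius_mm=20.0, voxel_size_mm=0.5)
        dense = extract_isosurface(vol, 500.0)
        out = decimate_to_budget(dense, 2000)
        assert out.n_faces <= 2000
        assert abs(out.area() - dense.area()) / dense.area() < 0.05
        assert np.isfinite(out.metadata["decimation_drift_mm"])

    def test_tiny_budget_contract(self, icosphere_mesh):
        out = decimate_to_budget(icosphere_mesh, 4)
        assert out.n_faces <= 4


class TestRegions:
    def test_ball_membership_contract(self, icosphere_mesh):
        center = icosphere_mesh.vertices[0]
        mask = select_region(icosphere_mesh, Ball(center, 5.0))
        centroids = icosphere_mesh.face_centroids()[mask.face_ids]
        assert np.all(np.linalg.norm(centroids - center, axis=1) <= 5.0)

    def test_bounding_descriptor_selects_all_faces(self, icosphere_mesh):
        mask = select_region(icosphere_mesh, Ball([0, 0, 0], 100.0))
        assert len(mask) == icosphere_mesh.n_faces

    def test_region_miss_raises(self, icosphere_mesh):
        with pytest.raises(RegionMissError):
            select_region(icosphere_mesh, Ball([500, 500, 500], 1.0))

    def test_foramen_rim_selection_matches_documented_extent(
        self, fine_phantom, fine_mesh
    ):
        # the posterior foramen rim reference is ~1.0 cm x 1.5 cm
        _, _, _, atlas = fine_phantom
        mask = select_region(fine_mesh, atlas["ForamenMagnumRim"])
        assert abs(mask.achieved_area_mm2 - 150.0) / 150.0 < 0.30

    def test_selection_is_deterministic(self, fine_phantom, fine_mesh):
        _, _, _, atlas = fine_phantom
        m1 = select_region(fine_mesh, atlas["AnteriorCranialBase"])
        m2 = select_region(fine_mesh, atlas["AnteriorCranialBase"])
        np.testing.assert_array_equal(m1.face_ids, m2.face_ids)


class TestCircularPatch:
    def test_growth_stopping_rule_on_plate(self, plate):
        mask = circular_patch(plate, [10.0, 10.0, 0.0], 5.0)
        max_face = plate.face_areas().max()
        assert 5.0 <= mask.achieved_area_mm2 < 5.0 + max_face

    def test_monotone_growth(self, plate):
        small = circular_patch(plate, [10.0, 10.0, 0.0], 5.0)
        large = circular_patch(plate, [10.0, 10.0, 0.0], 15.0)
        assert set(small.face_ids) <= set(large.face_ids)

    def test_geodesic_radius_on_sphere(self, icosphere_mesh):
        seed_pt = np.array([0.0, 0.0, 20.0])
        mask = circular_patch(icosphere_mesh, seed_pt, 5.0)
        centroids = icosphere_mesh.face_centroids()[mask.face_ids]
        # geodesic distance on the sphere = r * angle from the pole
        angles = np.arccos(
            np.clip(centroids[:, 2] / np.linalg.norm(centroids, axis=1), -1, 1)
        )
        geodesic = 20.0 * angles
        edge = icosphere_mesh.vertices[icosphere_mesh.faces[:, 0]] - (
            icosphere_mesh.vertices[icosphere_mesh.faces[:, 1]]
        )
        face_diam = 2.0 * np.linalg.norm(edge, axis=1).max()
        assert np.all(geodesic <= np.sqrt(5.0 / np.pi) + face_diam)

    def test_far_center_rejected(self, plate):
        with pytest.raises(RegionMissError):
            circular_patch(plate, [10.0, 10.0, 50.0], 5.0)


class TestStlRoundTrip:
    def test_binary_round_trip_float32(self, tmp_path, icosphere_mesh):
        path = tmp_path / "m.stl"
        write_stl(icosphere_mesh, path, "binary")
        back = read_stl(path)
        assert back.n_faces == icosphere_mesh.n_faces
        orig32 = np.unique(
            icosphere_mesh.vertices.astype(np.float32).astype(float), axis=0
        )
        np.testing.assert_allclose(np.unique(back.vertices, axis=0), orig32, atol=0)

    def test_ascii_and_binary_agree(self, tmp_path, icosphere_mesh):
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        write_stl(icosphere_mesh, pa, "ascii")
        write_stl(icosphere_mesh, pb, "binary")
        ma, mb = read_stl(pa), read_stl(pb)

        def tri_multiset(m):
            tris = np.sort(m.vertices[m.faces].reshape(len(m.faces), -1), axis=1)
            return np.sort(tris.round(4), axis=0)

        np.testing.assert_allclose(tri_multiset(ma), tri_multiset(mb), atol=1e-3)

    def test_truncated_binary_raises_with_offset(self, tmp_path, icosphere_mesh):
        path = tmp_path / "m.stl"
        write_stl(icosphere_mesh, path, "binary")
        raw = path.read_bytes()
        trunc = tmp_path / "t.stl"
        trunc.write_bytes(raw[:-37])
        with pytest.raises(StlParseError) as err:
            read_stl(trunc)
        assert err.value.byte_offset == len(raw) - 37


class TestVolumeIO:
    def test_round_trip(self, tmp_path):
        vol = build_sphere_volume(radius_mm=5.0, voxel_size_mm=1.0, noise_sd_hu=10.0)
        path = tmp_path / "v.npz"
        save_volume(vol, path)
        back = load_volume(path)
        np.testing.assert_array_equal(back.intensities, vol.intensities)
        np.testing.assert_array_equal(back.spacing_mm, vol.spacing_mm)
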