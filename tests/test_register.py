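import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cranioreg.geometry import LandmarkSet, RigidTransform
from cranioreg.phantom import jitter_operator
from cranioreg.proximity import ClosestPointQuery, closest_point_on_triangles
from cranioreg.register import (
    Bundle,
    DegenerateLandmarkError,
    IcpParams,
    InsufficientOverlapError,
    closest_point,
    coarse_align,
    icp_point_to_plane,
    kabsch,
    kabsch_3p,
    superimpose,
)
from cranioreg.surface import RegionMask, TriMesh

from conftest import make_plate


def _exhaustive_closest(mesh, pts):
    tri = mesh.vertices[mesh.faces]
    best_d = np.full(len(pts), np.inf)
    best_f = np.zeros(len(pts), dtype=int)
    for i in range(len(tri)):
        cp = closest_point_on_triangles(
            pts,
            np.tile(tri[i, 0], (len(pts), 1)),
            np.tile(tri[i, 1], (len(pts), 1)),
            np.tile(tri[i, 2], (len(pts), 1)),
        )
        d = np.linalg.norm(pts - cp, axis=1)
        upd = d < best_d  # lowest face id wins exact ties
        best_d[upd] = d[upd]
        best_f[upd] = i
    return best_f, best_d


class TestKabsch:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_exact_recovery_on_congruent_triples(self, seed):
        rng = np.random.default_rng(seed)
        tf = RigidTransform.from_rotvec(rng.uniform(-90, 90, 3), rng.uniform(-20, 20, 3))
        src = rng.uniform(-30, 30, (3, 3))
        rec = kabsch_3p(src, tf.apply(src))
        assert rec.almost_equal(tf, atol=1e-9)

    def test_identity_for_identical_points(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        assert kabsch_3p(pts, pts).is_identity(atol=1e-12)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(DegenerateLandmarkError):
            kabsch_3p(pts, pts)

    def test_least_squares_optimality_vs_random_search(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-30, 30, (3, 3))
        tgt = src + rng.normal(0, 0.5, (3, 3))
        best = kabsch(src, tgt)
        rms_best = np.sqrt(np.mean((best.apply(src) - tgt) ** 2))
        for _ in range(10_000):
            cand = RigidTransform.random(rng, 180.0, 10.0)
            rms = np.sqrt(np.mean((cand.apply(src) - tgt) ** 2))
            assert rms_best <= rms + 1e-12


class TestCoarseAlign:
    def _lm(self):
        return LandmarkSet(
            {
                "InfraorbitalL": [28, 82, 50],
                "InfraorbitalR": [80, 82, 50],
                "MastoidL": [25, 48, 26],
            }
        )

    def test_already_aligned_gives_identity(self):
        lm = self._lm()
        assert coarse_align(lm, lm).is_identity(atol=1e-9)

    def test_recovers_pure_rotation_exactly(self):
        lm = self._lm()
        tf = RigidTransform.from_rotvec([0, 0, 30.0])
        rec = coarse_align(lm.transformed(tf), lm)
        assert rec.compose(tf).rotation_angle_deg() < 1e-6

    def test_missing_landmark_raises(self):
        lm = self._lm()
        incomplete = LandmarkSet({k: v for k, v in lm.items() if k != "MastoidL"})
        with pytest.raises(KeyError):
            coarse_align(incomplete, lm)

    def test_phantom_rescan_residual_below_1mm(self, coarse_phantom):
        _, truth, _ = coarse_phantom
        rng = np.random.default_rng(3)
        for _ in range(5):
            tf = RigidTransform.random(rng, 5.0, 4.0)
            moved = truth.landmarks_t0.transformed(tf)
            # jittered picks emulate the operator
            picks = LandmarkSet(
                {k: v + rng.normal(0, 0.3, 3) for k, v in moved.items()}
            )
            rec = coarse_align(picks, truth.landmarks_t0)
            names = list(truth.landmarks_t0)
            resid = rec.apply(moved.as_array(names)) - truth.landmarks_t0.as_array(names)
            assert np.sqrt(np.mean(resid**2)) < 1.0


class TestClosestPoint:
    def test_vertex_query_returns_zero(self, icosphere_mesh):
        v = icosphere_mesh.vertices[17]
        pt, fid, dist, boundary = closest_point(icosphere_mesh, v)
        assert dist < 1e-12
        np.testing.assert_allclose(pt, v, atol=1e-12)
        assert not boundary  # watertight sphere has no boundary faces

    def test_analytic_plane_distance(self, plate):
        pt, _, dist, _ = closest_point(plate, [5.0, 5.0, 3.0])
        assert dist == pytest.approx(3.0, abs=1e-12)
        np.testing.assert_allclose(pt, [5.0, 5.0, 0.0], atol=1e-12)

    def test_matches_exhaustive_scan(self, icosphere_mesh):
        # small mesh (<=200 faces) for the exhaustive oracle
        sub = TriMesh(icosphere_mesh.vertices, icosphere_mesh.faces[:180])
        engine = ClosestPointQuery(sub.vertices, sub.faces)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-30, 30, (1000, 3))
        cp, fid, d = engine.query(pts)
        of, od = _exhaustive_closest(sub, pts)
        np.testing.assert_array_equal(fid, of)
        np.testing.assert_allclose(d, od, atol=1e-12)

    def test_mask_marks_outside_faces_boundary(self, plate):
        mask = RegionMask(np.array([0, 1]), "patch")
        _, _, _, boundary = closest_point(plate, [15.0, 15.0, 1.0], region_mask=mask)
        assert boundary


def _duplicate_pair(coarse_mesh, coarse_phantom, seed):
    _, truth, atlas = coarse_phantom
    rng = np.random.default_rng(seed)
    base = RigidTransform.random(rng, 5.0, 4.0)
    c = coarse_mesh.vertices.mean(axis=0)
    tf = RigidTransform(base.rotation, c - base.rotation @ c + base.translation)
    return coarse_mesh.transformed(tf), truth.landmarks_t0.transformed(tf), atlas.transformed(tf), tf


class TestIcp:
    def test_recovers_rigid_displacement(self, coarse_mesh, coarse_phantom):
        _, truth, atlas = coarse_phantom
        dup, lm_dup, atlas_dup, tf_true = _duplicate_pair(coarse_mesh, coarse_phantom, 1)
        # perturbed init from jittered landmark picks
        rng = np.random.default_rng(2)
        picks = LandmarkSet({k: v + rng.normal(0, 0.5, 3) for k, v in lm_dup.items()})
        init = coarse_align(picks, truth.landmarks_t0)
        params = IcpParams(sample_count=3000, seed=0)
        rec, report = icp_point_to_plane(dup, None, coarse_mesh, None, init, params)
        comp = rec.compose(tf_true)
        assert comp.rotation_angle_deg() < 0.05
        c = coarse_mesh.vertices.mean(axis=0)
        assert np.linalg.norm(comp.apply(c) - c) < 0.02
        assert report.converged

    def test_truth_init_is_a_fixed_point(self, coarse_mesh, coarse_phantom):
        dup, _, _, tf_true = _duplicate_pair(coarse_mesh, coarse_phantom, 3)
        params = IcpParams(sample_count=2000, seed=0)
        rec, report = icp_point_to_plane(
            dup, None, coarse_mesh, None, tf_true.inverse(), params
        )
        assert report.iterations_run <= 2
        assert rec.almost_equal(tf_true.inverse(), atol=1e-9)

    def test_trimmed_rms_is_monotone(self, coarse_mesh, coarse_phantom):
        dup, lm_dup, _, tf_true = _duplicate_pair(coarse_mesh, coarse_phantom, 4)
        rng = np.random.default_rng(5)
        _, truth, _ = coarse_phantom
        picks = LandmarkSet({k: v + rng.normal(0, 1.0, 3) for k, v in lm_dup.items()})
        init = coarse_align(picks, truth.landmarks_t0)
        _, report = icp_point_to_plane(
            dup, None, coarse_mesh, None, init, IcpParams(sample_count=2000, seed=1)
        )
        rms = np.array(report.rms_history)
        assert np.all(np.diff(rms) <= 1e-9)

    def test_insufficient_overlap_raises(self, coarse_mesh, coarse_phantom):
        dup, _, _, _ = _duplicate_pair(coarse_mesh, coarse_phantom, 6)
        params = IcpParams(sample_count=500, min_pairs=5000, seed=0)
        with pytest.raises(InsufficientOverlapError):
            icp_point_to_plane(
                dup, None, coarse_mesh, None, RigidTransform.identity(), params
            )

    def test_equivariance_under_common_rotation(self, coarse_mesh, coarse_phantom):
        dup, lm_dup, _, tf_true = _duplicate_pair(coarse_mesh, coarse_phantom, 7)
        params = IcpParams(sample_count=2000, seed=2)
        init = tf_true.inverse()
        rec, _ = icp_point_to_plane(dup, None, coarse_mesh, None, init, params)
        Q = RigidTransform.from_rotvec([10, -5, 20], [3, 1, -2])
        rec_q, _ = icp_point_to_plane(
            dup.transformed(Q), None, coarse_mesh.transformed(Q), None,
            Q.compose(init).compose(Q.inverse()), params,
        )
        conj = Q.compose(rec).compose(Q.inverse())
        assert conj.compose(rec_q.inverse()).rotation_angle_deg() < 0.05
        c = Q.apply(coarse_mesh.vertices.mean(axis=0))
        assert np.linalg.norm(conj.apply(c) - rec_q.apply(c)) < 0.05

    def test_robust_to_outlier_spikes(self, coarse_mesh):
        rng = np.random.default_rng(8)
        tf = RigidTransform.from_rotvec([1, 2, 1], [1, -1, 0.5])
        moving = coarse_mesh.transformed(tf)
        nspike = int(0.05 * moving.n_faces)
        pick = rng.choice(moving.n_faces, nspike, replace=False)
        spikes = moving.vertices[moving.faces[pick]] + rng.normal(0, 4.0, (nspike, 1, 3))
        spiked = TriMesh(
            np.vstack([moving.vertices, spikes.reshape(-1, 3)]),
            np.vstack(
                [moving.faces,
                 (np.arange(nspike * 3) + len(moving.vertices)).reshape(-1, 3)]
            ),
        )
        params = IcpParams(sample_count=3000, trim_fraction=0.1, seed=3)
        clean_tf, _ = icp_point_to_plane(
            moving, None, coarse_mesh, None, RigidTransform.identity(), params
        )
        spike_tf, _ = icp_point_to_plane(
            spiked, None, coarse_mesh, None, RigidTransform.identity(), params
        )
        assert np.linalg.norm(clean_tf.translation - spike_tf.translation) < 0.05


class TestSuperimpose:
    def test_3p_exact_on_duplicate_without_jitter(self, coarse_mesh, coarse_phantom):
        _, truth, atlas = coarse_phantom
        dup, lm_dup, atlas_dup, tf_true = _duplicate_pair(coarse_mesh, coarse_phantom, 9)
        tf, report = superimpose(
            "3P",
            Bundle(coarse_mesh, truth.landmarks_t0, atlas),
            Bundle(dup, lm_dup, atlas_dup),
        )
        assert report is None
        err = [
            np.linalg.norm(tf.apply(lm_dup[k]) - truth.landmarks_t0[k])
            for k in lm_dup
        ]
        assert max(err) < 1e-6

    def test_unknown_technique_rejected(self, coarse_mesh, coarse_phantom):
        _, truth, atlas = coarse_phantom
        b = Bundle(coarse_mesh, truth.landmarks_t0, atlas)
        with pytest.raises(ValueError, match="technique"):
            superimpose("XY", b, b)

    def test_acf_alias_accepted(self, coarse_mesh, coarse_phantom):
        _, truth, atlas = coarse_phantom
        dup, lm_dup, atlas_dup, _ = _duplicate_pair(coarse_mesh, coarse_phantom, 10)
        tf, report = superimpose(
            "AC+F",
            Bundle(coarse_mesh, truth.landmarks_t0, atlas),
            Bundle(dup, lm_dup, atlas_dup),
            IcpParams(sample_count=1500, seed=0),
        )
        assert report is not None and report.converged
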