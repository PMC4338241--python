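"""Rigid superimposition: landmark registration and region-masked robust ICP.

Five techniques are dispatched by :func:`superimpose`:

* ``3P``  — least-squares rigid registration of three anatomical landmarks;
* ``1Z``  — robust ICP on the left zygomatic arch region;
* ``BZ``  — robust ICP on both zygomatic arches;
* ``AC``  — robust ICP on the anterior cranial base;
* ``ACF`` — robust ICP on the anterior cranial base + foramen magnum rim
  (the gold-standard reference).

All ICP routes are preceded by a coarse landmark alignment (an FH-plane-like
orientation from the infraorbital pair and a third inferior landmark). The
ICP engine is a trimmed point-to-plane iteration: seeded area-weighted
samples on the moving region, exact closest points on the (masked) fixed
surface, rejection of pairs that hit the mask/mesh boundary, trimming of the
worst fraction by distance, and a damped Gauss-Newton update of the rigid
transform. Step halving guarantees the trimmed RMS never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import LandmarkSet, RigidTransform
from .proximity import ClosestPointQuery
from .surface import RegionMask, TriMesh, select_region

__all__ = [
    "IcpParams",
    "IcpReport",
    "Bundle",
    "DegenerateLandmarkError",
    "InsufficientOverlapError",
    "TECHNIQUES",
    "kabsch",
    "kabsch_3p",
    "coarse_align",
    "closest_point",
    "icp_point_to_plane",
    "superimpose",
]

TECHNIQUES = ("3P", "1Z", "BZ", "AC", "ACF")

THREE_POINT_NAMES = ("InfraorbitalL", "InfraorbitalR", "MastoidL")


class DegenerateLandmarkError(ValueError):
    pass


class InsufficientOverlapError(RuntimeError):
    pass


@dataclass(frozen=True)
class IcpParams:
    """Tuning of the robust ICP engine.

    ``tolerance_mm`` is the deviation level at which a registration is
    certified converged (the engine itself iterates to stationarity:
    |ΔRMS| < ``delta_rms_stop`` or RMS < ``rms_stop``). ``trim_fraction``
    of the accepted pairs (worst by distance) is discarded each iteration;
    boundary pairs are rejected when ``boundary_reject`` is on.
    """

    tolerance_mm: float = 0.3
    max_iterations: int = 100
    sample_count: int = 20000
    boundary_reject: bool = True
    trim_fraction: float = 0.1
    min_pairs: int = 100
    seed: int = 0
    delta_rms_stop: float = 1e-6
    rms_stop: float = 1e-7

    def __post_init__(self):
        if self.tolerance_mm <= 0:
            raise ValueError("tolerance_mm must be positive")
        if not (0 <= self.trim_fraction < 1):
            raise ValueError("trim_fraction must be in [0, 1)")


@dataclass
class IcpReport:
    iterations_run: int
    rms_history: list
    pairs_used_final: int
    converged: bool


@dataclass
class Bundle:
    """One scan's registration inputs: mesh + picked landmarks + region atlas."""

    mesh: TriMesh
    landmarks: LandmarkSet
    atlas: object  # RegionAtlas


# ---------------------------------------------------------------------------
# landmark registration
# ---------------------------------------------------------------------------


def kabsch(source_pts, target_pts) -> RigidTransform:
    """Least-squares rigid transform (no scaling, no reflection) mapping
    source points onto target points (SVD / Kabsch)."""
    src = np.asarray(source_pts, float)
    tgt = np.asarray(target_pts, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ct - R @ cs)


def _triple(landmarks, names) -> np.ndarray:
    try:
        return np.array([landmarks[n] for n in names], float)
    except KeyError as exc:
        raise KeyError(f"missing landmark {exc} (need {names})") from exc


def kabsch_3p(source_pts, target_pts) -> RigidTransform:
    """Three-point rigid registration; exact when the triples are congruent.

    Accepts (3, 3) arrays or mappings containing the three-point landmark
    names (infraorbital L/R + left mastoid)."""
    if isinstance(source_pts, dict):
        source_pts = _triple(source_pts, THREE_POINT_NAMES)
    if isinstance(target_pts, dict):
        target_pts = _triple(target_pts, THREE_POINT_NAMES)
    src = np.asarray(source_pts, float)
    tgt = np.asarray(target_pts, float)
    if src.shape != (3, 3) or tgt.shape != (3, 3):
        raise ValueError("three labeled points required on each side")
    for pts in (src, tgt):
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if area <= 1e-6:
            raise DegenerateLandmarkError(
                f"landmark triple is (near-)collinear: triangle area {area:.2e} mm²"
            )
    return kabsch(src, tgt)


def _frame(landmarks) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame from the infraorbital line and the plane through
    the triple (infraorbital L/R + mastoid); returns (frame, centroid)."""
    tri = _triple(landmarks, THREE_POINT_NAMES)
    infl, infr, mast = tri
    e1 = infr - infl
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        raise DegenerateLandmarkError("infraorbital landmarks coincide")
    e1 = e1 / n1
    v = mast - 0.5 * (infl + infr)
    e3 = np.cross(e1, v)
    n3 = np.linalg.norm(e3)
    if n3 < 1e-9:
        raise DegenerateLandmarkError("coarse-alignment landmarks are collinear")
    e3 = e3 / n3
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3]), tri.mean(axis=0)


def coarse_align(landmarks_src: LandmarkSet, landmarks_ref: LandmarkSet) -> RigidTransform:
    """Initial orientation: align the plane spanned by the landmark triple
    and the infraorbital line direction, then translate the triple midpoints
    together. Exact for congruent noiseless landmark sets."""
    Fs, cs = _frame(landmarks_src)
    Fr, cr = _frame(landmarks_ref)
    R = Fr @ Fs.T
    return RigidTransform(R, cr - R @ cs)


# ---------------------------------------------------------------------------
# closest point
# ---------------------------------------------------------------------------


def closest_point(mesh: TriMesh, query, region_mask: RegionMask | None = None):
    """Exact nearest point on the mesh to ``query``.

    Returns ``(point, face_id, distance_mm, is_boundary)`` where
    ``is_boundary`` is true when the hit face has a boundary edge or falls
    outside ``region_mask``. Convenience wrapper; batch callers should hold a
    :class:`~cranioreg.proximity.ClosestPointQuery`.
    """
    if mesh.is_empty:
        raise ValueError("mesh has no faces")
    engine = ClosestPointQuery(mesh.vertices, mesh.faces)
    pt, fid, dist = engine.query(np.asarray(query, float))
    boundary = bool(engine.boundary_faces[fid])
    if region_mask is not None and fid not in set(region_mask.face_ids.tolist()):
        boundary = True
    return pt, fid, dist, boundary


# ---------------------------------------------------------------------------
# robust ICP (trimmed point-to-plane)
# ---------------------------------------------------------------------------


def _sample_on_faces(mesh: TriMesh, face_ids, count: int, rng) -> np.ndarray:
    areas = mesh.face_areas()[face_ids]
    probs = areas / areas.sum()
    chosen = rng.choice(len(face_ids), size=count, p=probs)
    tri = mesh.vertices[mesh.faces[face_ids[chosen]]]
    r1 = np.sqrt(rng.uniform(size=count))
    r2 = rng.uniform(size=count)
    a = 1.0 - r1
    b = r1 * (1.0 - r2)
    c = r1 * r2
    return (
        tri[:, 0] * a[:, None] + tri[:, 1] * b[:, None] + tri[:, 2] * c[:, None]
    )


class _Correspondences:
    __slots__ = ("points", "closest", "normals", "distances", "rms", "n_used")


def icp_point_to_plane(
    moving: TriMesh,
    moving_mask: RegionMask | None,
    fixed: TriMesh,
    fixed_mask: RegionMask | None,
    init: RigidTransform,
    params: IcpParams = IcpParams(),
):
    """Region-masked trimmed point-to-plane ICP.

    Returns ``(RigidTransform, IcpReport)`` where the transform maps the
    moving mesh's frame onto the fixed mesh's frame (composed with ``init``).
    """
    move_faces = (
        moving_mask.face_ids if moving_mask is not None else np.arange(moving.n_faces)
    )
    if len(move_faces) == 0:
        raise ValueError("moving mask is empty")
    fixed_sub = fixed.submesh(fixed_mask.face_ids) if fixed_mask is not None else fixed
    if fixed_sub.is_empty:
        raise ValueError("fixed mask is empty")
    engine = ClosestPointQuery(fixed_sub.vertices, fixed_sub.faces)
    normals = fixed_sub.face_normals()
    boundary = engine.boundary_faces

    rng = np.random.default_rng(int(params.seed) % (2**31))
    n_samples = min(params.sample_count, max(4 * len(move_faces), 64))
    samples = _sample_on_faces(moving, np.asarray(move_faces, int), n_samples, rng)

    def correspond(tf: RigidTransform) -> _Correspondences:
        p = tf.apply(samples)
        cp, fid, d = engine.query(p)
        keep = np.ones(len(p), dtype=bool)
        if params.boundary_reject:
            keep &= ~boundary[fid]
        if params.trim_fraction > 0 and keep.sum() > 0:
            kept_d = d[keep]
            cut = np.quantile(kept_d, 1.0 - params.trim_fraction)
            keep &= d <= cut
        if keep.sum() < params.min_pairs:
            raise InsufficientOverlapError(
                f"only {int(keep.sum())} usable pairs "
                f"(min_pairs={params.min_pairs}); insufficient region overlap"
            )
        c = _Correspondences()
        c.points = p[keep]
        c.closest = cp[keep]
        c.normals = normals[fid[keep]]
        c.distances = d[keep]
        c.rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        c.n_used = int(keep.sum())
        return c

    tf = init
    data = correspond(tf)
    history = [data.rms]
    iterations = 0
    converged_flag = False

    for it in range(params.max_iterations):
        if data.rms < params.rms_stop:
            break
        # linearised point-to-plane least squares around the centroid
        centroid = data.points.mean(axis=0)
        q = data.points - centroid
        n = data.normals
        b = np.einsum("ij,ij->i", data.closest - data.points, n)
        A = np.hstack([np.cross(q, n), n])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError(f"non-finite ICP solve at iteration {it}")
        omega, trans = sol[:3], sol[3:]

        accepted = None
        scale = 1.0
        for _ in range(8):
            rot = RigidTransform.from_rotvec(np.degrees(omega * scale))
            inc = RigidTransform(
                rot.rotation,
                centroid - rot.rotation @ centroid + trans * scale,
            )
            cand_tf = inc.compose(tf)
            cand = correspond(cand_tf)
            if cand.rms <= data.rms + 1e-12:
                accepted = (cand_tf, cand)
                break
            scale *= 0.5
        iterations = it + 1
        if accepted is None:
            break  # no descent step exists: stationary
        delta = data.rms - accepted[1].rms
        tf, data = accepted
        history.append(data.rms)
        if abs(delta) < params.delta_rms_stop:
            break

    converged_flag = data.rms <= params.tolerance_mm and data.n_used >= params.min_pairs
    report = IcpReport(
        iterations_run=iterations,
        rms_history=history,
        pairs_used_final=data.n_used,
        converged=converged_flag,
    )
    return tf, report


# ---------------------------------------------------------------------------
# technique dispatch
# ---------------------------------------------------------------------------


def _union_mask(mesh: TriMesh, atlas, names) -> RegionMask:
    ids = np.concatenate(
        [select_region(mesh, atlas[name]).face_ids for name in names]
    )
    return RegionMask(ids, label="+".join(names))


_TECHNIQUE_REGIONS = {
    "1Z": ("ZygomaticArchL",),
    "BZ": ("ZygomaticArchL", "ZygomaticArchR"),
    "AC": ("AnteriorCranialBase",),
    "ACF": ("AnteriorCranialBase", "ForamenMagnumRim"),
}


def superimpose(
    technique: str,
    t0_bundle: Bundle,
    t1_bundle: Bundle,
    params: IcpParams = IcpParams(),
    operator_context: dict | None = None,
):
    """Register the T1 bundle onto the T0 bundle with the given technique.

    ``operator_context`` may override the picked landmarks / selected
    regions (keys ``landmarks_t0``, ``landmarks_t1``, ``atlas_t0``,
    ``atlas_t1``). Returns ``(RigidTransform, IcpReport | None)``; the
    report is None for the landmark-only 3P technique.
    """
    technique = technique.upper().replace("+", "").replace(" ", "")
    if technique == "AC F":
        technique = "ACF"
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; expected {TECHNIQUES}")
    ctx = operator_context or {}
    lm0 = ctx.get("landmarks_t0", t0_bundle.landmarks)
    lm1 = ctx.get("landmarks_t1", t1_bundle.landmarks)
    atlas0 = ctx.get("atlas_t0", t0_bundle.atlas)
    atlas1 = ctx.get("atlas_t1", t1_bundle.atlas)

    if technique == "3P":
        return kabsch_3p(lm1, lm0), None

    names = _TECHNIQUE_REGIONS[technique]
    init = coarse_align(lm1, lm0)
    moving_mask = _union_mask(t1_bundle.mesh, atlas1, names)
    fixed_mask = _union_mask(t0_bundle.mesh, atlas0, names)
    return icp_point_to_plane(
        t1_bundle.mesh, moving_mask, t0_bundle.mesh, fixed_mask, init, params
    )
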