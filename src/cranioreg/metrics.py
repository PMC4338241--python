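"""Superimposition accuracy and precision metrics.

Accuracy is the overall deviation D — the mean Euclidean closest-point
distance between the superimposed models — evaluated on small circular
patches at form-stable sites (anterior sella surface, posterior left/right
foramen magnum rim) and averaged over the three patches. Precision is the
displacement measured at clinical landmarks (piriform aperture and incisor
points) after superimposition.

Per-axis values Dx/Dy/Dz are *signed means* of the displacement components
(direction of bias is preserved); D is the mean of the Euclidean norms, so
D <= |Dx|+|Dy|+|Dz| need not hold. Sign convention: positive = result mesh
outside the reference surface (along the reference face normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform
from .proximity import ClosestPointQuery
from .surface import RegionMask, TriMesh

__all__ = [
    "DeviationRecord",
    "AccuracyResult",
    "CorrespondenceError",
    "patch_deviation",
    "accuracy_D",
    "landmark_displacement",
    "deviation_field",
    "trim_to_roi",
    "CORRESPONDENCE_CUTOFF_MM",
]

CORRESPONDENCE_CUTOFF_MM = 10.0  # beyond this, surfaces are deemed non-corresponding


class CorrespondenceError(RuntimeError):
    """No corresponding surface within the cutoff (the grey-zone analogue)."""


@dataclass
class DeviationRecord:
    patch_or_point: str
    D: float
    Dx: float
    Dy: float
    Dz: float
    n_samples: int

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("D must be nonnegative")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class AccuracyResult:
    patch_deviations: list
    D_accuracy: float


def _sample_patch(mesh: TriMesh, patch: RegionMask, n_samples: int, seed: int):
    rng = np.random.default_rng(int(seed) % (2**31))
    areas = mesh.face_areas()[patch.face_ids]
    total = areas.sum()
    if total <= 0:
        raise ValueError("patch has zero area")
    probs = areas / total
    chosen = rng.choice(len(patch.face_ids), size=n_samples, p=probs)
    tri = mesh.vertices[mesh.faces[patch.face_ids[chosen]]]
    r1 = np.sqrt(rng.uniform(size=n_samples))
    r2 = rng.uniform(size=n_samples)
    w = np.column_stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2])
    return np.einsum("nkd,nk->nd", tri, w)


def patch_deviation(
    result_mesh: TriMesh,
    reference_mesh: TriMesh,
    patch: RegionMask,
    n_samples: int | None = None,
    seed: int = 0,
) -> DeviationRecord:
    """Deviation of a patch on the (already superimposed) result mesh from
    the reference mesh: D = mean closest-point distance, Dx/Dy/Dz = mean
    signed components of (closest reference point - sample point).

    Samples with no reference surface within 10 mm are dropped; if none
    remain the patch is deemed non-corresponding and an error is raised.
    """
    if n_samples is None:
        area = float(result_mesh.face_areas()[patch.face_ids].sum())
        n_samples = max(200, int(40 * area))
    pts = _sample_patch(result_mesh, patch, n_samples, seed)
    engine = ClosestPointQuery(reference_mesh.vertices, reference_mesh.faces)
    cp, _, d = engine.query(pts)
    ok = d <= CORRESPONDENCE_CUTOFF_MM
    if not np.any(ok):
        raise CorrespondenceError(
            f"patch {patch.label!r}: no reference surface within "
            f"{CORRESPONDENCE_CUTOFF_MM} mm"
        )
    vec = cp[ok] - pts[ok]
    return DeviationRecord(
        patch_or_point=patch.label,
        D=float(np.mean(d[ok])),
        Dx=float(np.mean(vec[:, 0])),
        Dy=float(np.mean(vec[:, 1])),
        Dz=float(np.mean(vec[:, 2])),
        n_samples=int(ok.sum()),
    )


def accuracy_D(
    result_mesh: TriMesh,
    reference_mesh: TriMesh,
    fiducial_patches,
    n_samples: int | None = None,
    seed: int = 0,
) -> AccuracyResult:
    """Accuracy statistic: deviations of the three fiducial patches summed
    and divided by three (i.e. their mean)."""
    patches = list(fiducial_patches)
    if len(patches) != 3:
        raise ValueError("exactly three fiducial patches expected")
    records = []
    for patch in patches:
        try:
            records.append(
                patch_deviation(result_mesh, reference_mesh, patch, n_samples, seed)
            )
        except CorrespondenceError as exc:
            raise CorrespondenceError(f"fiducial patch failed: {exc}") from exc
    return AccuracyResult(
        patch_deviations=records,
        D_accuracy=float(np.mean([r.D for r in records])),
    )


def landmark_displacement(
    landmark_t0, landmark_t1, superimposition: RigidTransform, label: str = "point"
) -> DeviationRecord:
    """Structural change measured at a landmark: the T1 point is mapped into
    the T0 frame by the recovered superimposition and compared with the T0
    point."""
    p0 = np.asarray(landmark_t0, float)
    vec = superimposition.apply(np.asarray(landmark_t1, float)) - p0
    return DeviationRecord(
        patch_or_point=label,
        D=float(np.linalg.norm(vec)),
        Dx=float(vec[0]),
        Dy=float(vec[1]),
        Dz=float(vec[2]),
        n_samples=1,
    )


def deviation_field(
    result_mesh: TriMesh, reference_mesh: TriMesh, cap_mm: float
) -> TriMesh:
    """Colour-map export: per-vertex signed distance of the result mesh from
    the reference surface, clamped to +-cap_mm. Positive = outside the
    reference (along its face normal); vertices with no correspondence
    within 10 mm are NaN (rendered grey)."""
    if cap_mm <= 0:
        raise ValueError("cap_mm must be positive")
    engine = ClosestPointQuery(reference_mesh.vertices, reference_mesh.faces)
    normals = reference_mesh.face_normals()
    cp, fid, d = engine.query(result_mesh.vertices)
    side = np.einsum("ij,ij->i", result_mesh.vertices - cp, normals[fid])
    signed = np.where(side >= 0, d, -d)
    signed = np.clip(signed, -cap_mm, cap_mm)
    signed[d > CORRESPONDENCE_CUTOFF_MM] = np.nan
    out = TriMesh(
        result_mesh.vertices.copy(), result_mesh.faces.copy(), signed,
        dict(result_mesh.metadata),
    )
    return out


def trim_to_roi(mesh: TriMesh, box) -> TriMesh:
    """Keep faces fully inside an axis-aligned box ``(lo, hi)`` (report
    plumbing; an empty result carries ``metadata['empty'] = True``)."""
    lo, hi = (np.asarray(b, float).reshape(3) for b in box)
    v_in = np.all((mesh.vertices >= lo) & (mesh.vertices <= hi), axis=1)
    keep = np.nonzero(v_in[mesh.faces].all(axis=1))[0]
    if len(keep) == 0:
        out = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        out.metadata["empty"] = True
        return out
    if len(keep) == mesh.n_faces:
        return mesh
    return mesh.submesh(keep)
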