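"""Seeded synthetic skull phantoms with exact ground truth.

A phantom stands in for a patient CT pair: a T0 volume rasterised from a
union of analytic primitives, a treatment deformation (rapid maxillary
expansion: the two hemimaxillae translate apart, the zygomatic arches bend
outward, the cranial base and foramen magnum stay form-stable), and a random
rigid repositioning between scans. Because every deformed piece moves
rigidly and volumes are re-rasterised from the analytic solids (never
resampled), landmark ground truth is exact to machine precision.

Stylised anatomy (mm, origin at the volume corner, x left->right,
y posterior->anterior, z inferior->superior):

* a cranial-base shelf: two joined plates with a sella depression and
  hemispherical relief bumps (the relief makes in-plane sliding of a
  registration detectable);
* a thick-walled ring standing in for the foramen magnum rim;
* two slender tapered arc tubes with bulges = zygomatic arches;
* an anterior U-shaped maxilla in two halves bearing incisor prongs and a
  piriform notch;
* two orbital-rim bars and a mastoid prong carrying the landmarks used for
  three-point and coarse (FH-plane-like) registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Ball, CappedCylinder, LandmarkSet, RigidTransform
from .surface import Volume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "RegionAtlas",
    "build_phantom",
    "apply_treatment",
    "simulate_rescan",
    "compose_rescan",
    "jitter_operator",
    "build_sphere_volume",
    "PhantomError",
]

TREATED_LANDMARKS = ("PiriformL", "PiriformR", "IncisorL", "IncisorR")
STABLE_LANDMARKS = (
    "InfraorbitalL",
    "InfraorbitalR",
    "MastoidL",
    "SellaPatchCenter",
    "ForamenPatchCenterR",
    "ForamenPatchCenterL",
)
MEASUREMENT_POINTS = TREATED_LANDMARKS  # the four clinical outcome points
FIDUCIAL_PATCH_CENTERS = (
    "SellaPatchCenter",
    "ForamenPatchCenterR",
    "ForamenPatchCenterL",
)


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# primitives (canonical frame; pieces carry the rigid pose)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Box:
    center: np.ndarray
    half: np.ndarray

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        q = np.abs(pts - self.center) - self.half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(q.max(axis=1), 0.0)
        return outside + inside

    def bounding_points(self) -> np.ndarray:
        signs = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            dtype=float,
        )
        return self.center + signs * self.half


@dataclass(frozen=True)
class _Ring:
    """Annular ring, axis along z: r_inner <= radial <= r_outer, |z - z0| <= half_h."""

    center: np.ndarray
    r_outer: float
    r_inner: float
    half_h: float

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        radial = np.hypot(d[:, 0], d[:, 1])
        mid = 0.5 * (self.r_outer + self.r_inner)
        qx = np.abs(radial - mid) - 0.5 * (self.r_outer - self.r_inner)
        qz = np.abs(d[:, 2]) - self.half_h
        q = np.column_stack([qx, qz])
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(q.max(axis=1), 0.0)
        return outside + inside

    def bounding_points(self) -> np.ndarray:
        r, h = self.r_outer, self.half_h
        return _Box(self.center, np.array([r, r, h])).bounding_points()


@dataclass(frozen=True)
class _ArcTube:
    """Tapered tube around a horizontal circular arc (plus end balls).

    The arc lies in the plane z = center[2], centred at center[:2] with the
    given radius; azimuth runs from theta0 to theta1 (degrees, ccw, theta1 >
    theta0). The tube radius tapers linearly from r0 at theta0 to r1 at
    theta1 — the taper (and bulges layered on top) breaks the torus sliding
    symmetry so registration on an arch is well posed.
    """

    center: np.ndarray
    radius: float
    theta0_deg: float
    theta1_deg: float
    r0: float
    r1: float
    wobble_amp: float = 0.0  # signed; integer cycles keep the ends at z = 0
    wobble_cycles: int = 3

    def _axis_z(self, frac):
        return self.wobble_amp * np.sin(2.0 * np.pi * self.wobble_cycles * frac)

    def _point_at(self, theta_deg: float) -> np.ndarray:
        th = np.radians(theta_deg)
        frac = (theta_deg - self.theta0_deg) / (self.theta1_deg - self.theta0_deg)
        return self.center + np.array(
            [
                self.radius * np.cos(th),
                self.radius * np.sin(th),
                float(self._axis_z(frac)),
            ]
        )

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        rho = np.hypot(d[:, 0], d[:, 1])
        theta = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        span = self.theta1_deg - self.theta0_deg
        rel = np.mod(theta - self.theta0_deg, 360.0)
        frac = np.clip(rel / span, 0.0, 1.0)
        tube_r = self.r0 + (self.r1 - self.r0) * frac
        dist_arc = np.hypot(rho - self.radius, d[:, 2] - self._axis_z(frac)) - tube_r
        out = np.where(rel <= span, dist_arc, np.inf)
        for th, rr in ((self.theta0_deg, self.r0), (self.theta1_deg, self.r1)):
            end = self._point_at(th)
            out = np.minimum(out, np.linalg.norm(pts - end, axis=1) - rr)
        return out

    def bounding_points(self) -> np.ndarray:
        r = self.radius + max(self.r0, self.r1)
        z = max(self.r0, self.r1) + abs(self.wobble_amp)
        return _Box(self.center, np.array([r, r, z])).bounding_points()


def _sdf(prim, pts: np.ndarray) -> np.ndarray:
    """Signed distance of any primitive (negative inside)."""
    if isinstance(prim, Ball):
        return np.linalg.norm(pts - prim.center, axis=1) - prim.radius
    if isinstance(prim, CappedCylinder):
        axis = prim.p1 - prim.p0
        L = np.linalg.norm(axis)
        a = axis / L
        rel = pts - 0.5 * (prim.p0 + prim.p1)
        along = rel @ a
        radial = np.linalg.norm(rel - np.outer(along, a), axis=1)
        qx = radial - prim.radius
        qz = np.abs(along) - 0.5 * L
        q = np.column_stack([qx, qz])
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(q.max(axis=1), 0.0)
        return outside + inside
    return prim.sdf(pts)


def _ball_prim(center, radius):
    return Ball(np.asarray(center, float), radius)


# Ball and CappedCylinder already expose contains(); add bounding points ad hoc.
def _bounding_points(prim) -> np.ndarray:
    if isinstance(prim, Ball):
        return _Box(prim.center, np.full(3, prim.radius)).bounding_points()
    if isinstance(prim, CappedCylinder):
        lo = np.minimum(prim.p0, prim.p1) - prim.radius
        hi = np.maximum(prim.p0, prim.p1) + prim.radius
        return _Box((lo + hi) / 2, (hi - lo) / 2).bounding_points()
    return prim.bounding_points()


@dataclass
class _Piece:
    """A rigid anatomical piece: union of solids minus cuts, under a pose."""

    name: str
    solids: list
    cuts: list = field(default_factory=list)
    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        local = self.pose.inverse().apply(pts)
        d = np.full(len(local), np.inf)
        for s in self.solids:
            d = np.minimum(d, _sdf(s, local))
        for c in self.cuts:
            d = np.maximum(d, -_sdf(c, local))
        return d

    def bounding_points(self) -> np.ndarray:
        pts = np.concatenate([_bounding_points(s) for s in self.solids])
        return self.pose.apply(pts)

    def with_pose(self, pose: RigidTransform) -> "_Piece":
        return _Piece(self.name, self.solids, self.cuts, pose)


# ---------------------------------------------------------------------------
# spec / ground truth / atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic patient.

    Defaults emulate the acquisition and treatment of the emulated study:
    0.8 mm isotropic voxels, ~9 mm total maxillary expansion
    (0.6 mm/day x 15 days), a moderate outward bend of the zygomatic
    arches, and a bounded random repositioning between scans.
    """

    voxel_size_mm: float = 0.8
    grid_shape: tuple = (136, 141, 106)
    bone_hu: float = 1200.0
    background_hu: float = 0.0
    noise_sd_hu: float = 25.0
    bias_field_amp_hu: float = 120.0
    bias_field_corr_mm: float = 60.0
    expansion_total_mm: float = 9.0
    zygoma_bend_deg: float = 2.0
    rescan_rotation_max_deg: float = 5.0
    rescan_translation_max_mm: float = 4.0
    partial_volume: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise PhantomError("voxel_size_mm must be positive")
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise PhantomError("grid_shape must be 3 positive integers")
        if self.noise_sd_hu < 0 or self.expansion_total_mm < 0:
            raise PhantomError("noise_sd_hu and expansion_total_mm must be >= 0")
        if self.bias_field_amp_hu < 0 or self.bias_field_corr_mm <= 0:
            raise PhantomError("bias field amplitude must be >= 0, length > 0")
        if self.zygoma_bend_deg < 0:
            raise PhantomError("zygoma_bend_deg must be >= 0")
        if self.rescan_rotation_max_deg < 0 or self.rescan_translation_max_mm < 0:
            raise PhantomError("rescan bounds must be >= 0")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, float) - 1.0) * self.voxel_size_mm

    @property
    def margin_mm(self) -> float:
        return 2.0 * self.voxel_size_mm


@dataclass
class GroundTruth:
    """Exact landmark truth. ``landmarks_t1 = rescan(treatment(landmarks_t0))``
    by construction; ``true_displacements`` is the treatment effect expressed
    in the T0 frame (zero vectors for form-stable landmarks)."""

    rescan_transform: RigidTransform
    landmarks_t0: LandmarkSet
    landmarks_t1: LandmarkSet
    true_displacements: dict

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.rescan_transform,
            self.landmarks_t0.copy(),
            self.landmarks_t1.copy(),
            {k: np.array(v) for k, v in self.true_displacements.items()},
        )


@dataclass
class RegionAtlas:
    """Named analytic reference-region descriptors, in the frame of the
    volume they accompany."""

    regions: dict

    def __getitem__(self, key):
        return self.regions[key]

    def keys(self):
        return self.regions.keys()

    def transformed(self, transform: RigidTransform) -> "RegionAtlas":
        return RegionAtlas(
            {k: v.transformed(transform) for k, v in self.regions.items()}
        )

    def copy(self) -> "RegionAtlas":
        return RegionAtlas(dict(self.regions))


# ---------------------------------------------------------------------------
# geometry layout (offsets from the grid centre C, in mm)
# ---------------------------------------------------------------------------


_ARCH_SPAN_R = (-20.0, 75.0)
_ARCH_SPAN_L = (105.0, 200.0)
_ARCH_WOBBLE = 1.5  # mm, vertical undulation amplitude of the arch axis


def _arc_point(C: np.ndarray, theta_deg: float) -> np.ndarray:
    """Point on the (wobbled) arch axis; mirror-symmetric between sides."""
    th = np.radians(theta_deg)
    if theta_deg <= 90.0:
        t0, t1 = _ARCH_SPAN_R
        amp = _ARCH_WOBBLE
    else:
        t0, t1 = _ARCH_SPAN_L
        amp = -_ARCH_WOBBLE
    frac = (theta_deg - t0) / (t1 - t0)
    z = amp * np.sin(2.0 * np.pi * 3 * frac)
    return C + np.array([30.0 * np.cos(th), 30.0 * np.sin(th), -2.0 + z])




def _build_pieces(C: np.ndarray) -> list[_Piece]:
    off = lambda dx, dy, dz: C + np.array([dx, dy, dz], float)

    cranial_base = _Piece(
        "cranial_base",
        solids=[
            _Box(off(0, 18, 21), np.array([28.0, 11.0, 3.0])),  # anterior plate
            _Box(off(0, -5, 19), np.array([22.0, 12.0, 3.0])),  # posterior plate
            _ball_prim(off(-16, 22, 24), 4.0),  # relief bumps
            _ball_prim(off(16, 22, 24), 4.0),
            _ball_prim(off(0, -10, 22), 4.0),
            _ball_prim(off(-14, -4, 22), 3.5),
            _ball_prim(off(14, -4, 22), 3.5),
        ],
        cuts=[_ball_prim(off(0, 18, 25.5), 4.5)],  # sella depression
    )
    orbital_bars = _Piece(
        "orbital_rims",
        solids=[
            _Box(off(-26, 26, 5), np.array([4.5, 4.0, 3.0])),
            _Box(off(26, 26, 5), np.array([4.5, 4.0, 3.0])),
        ],
    )
    mastoid = _Piece("mastoid", solids=[_Box(off(-29, -8, -10), np.array([3.0, 4.0, 6.0]))])
    foramen = _Piece(
        "foramen_ring",
        solids=[_Ring(off(0, -22, -22), r_outer=15.0, r_inner=6.0, half_h=6.0)],
    )
    arch_r = _Piece(
        "zygomatic_arch_R",
        solids=[
            _ArcTube(
                off(0, 0, -2), 30.0, *_ARCH_SPAN_R, r0=4.0, r1=2.5,
                wobble_amp=_ARCH_WOBBLE,
            ),
            # bulges (zygomatic-process analogues); with the vertical
            # undulation they make sliding along the arch detectable
            _ball_prim(_arc_point(C, 8.0), 4.3),
            _ball_prim(_arc_point(C, 22.0), 4.0),
        ],
    )
    arch_l = _Piece(
        "zygomatic_arch_L",
        solids=[
            _ArcTube(
                off(0, 0, -2), 30.0, *_ARCH_SPAN_L, r0=2.5, r1=4.0,
                wobble_amp=-_ARCH_WOBBLE,
            ),
            _ball_prim(_arc_point(C, 172.0), 4.3),
            _ball_prim(_arc_point(C, 158.0), 4.0),
        ],
    )
    notch = CappedCylinder(off(0, 14, -16), off(0, 38, -16), 6.0)
    maxilla_l = _Piece(
        "maxilla_L",
        solids=[
            _Box(off(-9, 27, -21), np.array([9.0, 9.0, 9.0])),
            _Box(off(-2.5, 38, -26), np.array([2.5, 4.0, 4.0])),  # incisor prong
        ],
        cuts=[notch],
    )
    maxilla_r = _Piece(
        "maxilla_R",
        solids=[
            _Box(off(9, 27, -21), np.array([9.0, 9.0, 9.0])),
            _Box(off(2.5, 38, -26), np.array([2.5, 4.0, 4.0])),
        ],
        cuts=[notch],
    )
    return [
        cranial_base,
        orbital_bars,
        mastoid,
        foramen,
        arch_r,
        arch_l,
        maxilla_l,
        maxilla_r,
    ]


def _arch_root(C: np.ndarray, side: str) -> np.ndarray:
    return _arc_point(C, -20.0 if side == "R" else 200.0)


def _landmarks(C: np.ndarray) -> LandmarkSet:
    off = lambda dx, dy, dz: C + np.array([dx, dy, dz], float)
    return LandmarkSet(
        {
            "PiriformL": off(-6, 36, -16),
            "PiriformR": off(6, 36, -16),
            "IncisorL": off(-5, 42, -26),
            "IncisorR": off(5, 42, -26),
            "InfraorbitalL": off(-26, 26, 8),
            "InfraorbitalR": off(26, 26, 8),
            "MastoidL": off(-29, -8, -16),
            "SellaPatchCenter": off(0, 18, 21),
            "ForamenPatchCenterR": off(7.5, -34.99, -22),
            "ForamenPatchCenterL": off(-7.5, -34.99, -22),
        }
    )


def _atlas(C: np.ndarray) -> RegionAtlas:
    off = lambda dx, dy, dz: C + np.array([dx, dy, dz], float)
    return RegionAtlas(
        {
            "AnteriorCranialBase": CappedCylinder(
                off(0, 8, 12), off(0, 8, 30), 30.0, label="AC"
            ),
            "ForamenMagnumRim": CappedCylinder(
                off(-7.5, -37, -22), off(7.5, -37, -22), 5.5, label="F"
            ),
            "ZygomaticArchR": Ball(_arc_point(C, 15.0), 13.0, label="ZygR"),
            "ZygomaticArchL": Ball(_arc_point(C, 165.0), 13.0, label="ZygL"),
            "Maxilla": Ball(off(0, 27, -21), 24.0, label="Maxilla"),
        }
    )


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------


def _rasterize(pieces, spec: PhantomSpec, rng: np.random.Generator) -> Volume:
    """Rasterise the analytic solid onto the voxel grid.

    With ``partial_volume`` (the default) each voxel's intensity follows a
    one-voxel linear ramp of the exact signed distance — the CT
    partial-volume effect — which lets marching cubes place the isosurface
    sub-voxel. Binary mode assigns pure bone/background values.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    h = spec.voxel_size_mm
    dist = np.full(shape, np.inf)
    axes = [np.arange(n) * h for n in shape]
    for piece in pieces:
        bp = piece.bounding_points()
        lo = np.maximum(np.floor(bp.min(axis=0) / h).astype(int) - 2, 0)
        hi = np.minimum(
            np.ceil(bp.max(axis=0) / h).astype(int) + 2, np.array(shape) - 1
        )
        if np.any(lo > hi):
            continue
        gx, gy, gz = np.meshgrid(
            axes[0][lo[0] : hi[0] + 1],
            axes[1][lo[1] : hi[1] + 1],
            axes[2][lo[2] : hi[2] + 1],
            indexing="ij",
        )
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d = piece.signed_distance(pts).reshape(gx.shape)
        block = dist[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        np.minimum(block, d, out=block)
    span = spec.bone_hu - spec.background_hu
    if spec.partial_volume:
        # two-voxel ramp: sub-voxel isosurface placement with low orientation
        # dependence of the reconstruction error
        frac = np.clip(0.5 - dist / (2.0 * h), 0.0, 1.0)
        intensities = spec.background_hu + span * frac
    else:
        intensities = np.where(dist <= 0.0, spec.bone_hu, spec.background_hu)
    if spec.bias_field_amp_hu > 0:
        intensities = intensities + _bias_field(spec, rng)
    if spec.noise_sd_hu > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd_hu, size=shape)
    vol = Volume(intensities, np.full(3, h), np.zeros(3))
    vol.pieces = list(pieces)  # analytic model rides along (not serialised)
    return vol


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth scan-specific intensity bias (beam-hardening / calibration
    analogue): a Gaussian random field with the given correlation length,
    scaled to the given amplitude (sd, in HU). Drawn anew for every scan, it
    perturbs each reconstruction's surfaces coherently over ~corr_mm — the
    dominant error source real region-based registrations contend with."""
    from scipy import ndimage

    shape = np.array(spec.grid_shape, dtype=int)
    step = max(int(round(spec.bias_field_corr_mm / spec.voxel_size_mm)), 2)
    coarse = rng.normal(size=tuple(shape // step + 3))
    field = ndimage.zoom(
        coarse,
        [shape[i] / coarse.shape[i] for i in range(3)],
        order=3,
        mode="nearest",
    )
    sd = field.std()
    if sd > 0:
        field = field * (spec.bias_field_amp_hu / sd)
    return field


def _check_margin(pieces, spec: PhantomSpec, what: str) -> None:
    lo_lim = spec.margin_mm
    hi_lim = spec.extent_mm - spec.margin_mm
    for piece in pieces:
        bp = piece.bounding_points()
        if np.any(bp.min(axis=0) < lo_lim) or np.any(bp.max(axis=0) > hi_lim):
            raise PhantomError(
                f"{what}: piece {piece.name!r} violates the 2-voxel grid margin; "
                f"increase grid_shape (extent {spec.extent_mm} mm)"
            )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def build_phantom(spec: PhantomSpec):
    """Rasterise the T0 phantom. Returns ``(Volume, GroundTruth, RegionAtlas)``."""
    C = spec.extent_mm / 2.0
    pieces = _build_pieces(C)
    _check_margin(pieces, spec, "grid too small")
    rng = np.random.default_rng([int(spec.seed) % (2**31), 0])
    vol = _rasterize(pieces, spec, rng)
    lm = _landmarks(C)
    truth = GroundTruth(
        rescan_transform=RigidTransform.identity(),
        landmarks_t0=lm,
        landmarks_t1=lm.copy(),
        true_displacements={k: np.zeros(3) for k in lm},
    )
    return vol, truth, _atlas(C)


def apply_treatment(volume_t0: Volume, truth: GroundTruth, atlas: RegionAtlas, spec: PhantomSpec):
    """Deform the analytic solid (pre-rescan T1): hemimaxillae translate
    laterally by +-expansion/2, zygomatic arches rotate outward about their
    posterior roots, the cranial base and foramen ring stay put. Returns
    ``(Volume, GroundTruth, RegionAtlas)`` in the (unmoved) T0 frame."""
    pieces = getattr(volume_t0, "pieces", None)
    if pieces is None:
        raise PhantomError("volume does not carry an analytic phantom model")
    C = spec.extent_mm / 2.0
    e = spec.expansion_total_mm
    shift_l = RigidTransform(np.eye(3), np.array([-e / 2, 0.0, 0.0]))
    shift_r = RigidTransform(np.eye(3), np.array([e / 2, 0.0, 0.0]))

    def bend(side: str) -> RigidTransform:
        # outward bend about a vertical axis through the arch's posterior root
        sign = -1.0 if side == "R" else 1.0
        root = _arch_root(C, side)
        rot = RigidTransform.from_rotvec([0.0, 0.0, sign * spec.zygoma_bend_deg])
        return RigidTransform(
            rot.rotation, root - rot.rotation @ root
        )

    piece_tf = {
        "maxilla_L": shift_l,
        "maxilla_R": shift_r,
        "zygomatic_arch_R": bend("R"),
        "zygomatic_arch_L": bend("L"),
    }
    new_pieces = [
        p.with_pose(piece_tf[p.name].compose(p.pose)) if p.name in piece_tf else p
        for p in pieces
    ]
    _check_margin(
        [p for p in new_pieces if p.name in piece_tf], spec, "treatment exits grid"
    )
    rng = np.random.default_rng([int(spec.seed) % (2**31), 1])
    vol = _rasterize(new_pieces, spec, rng)

    new_truth = truth.copy()
    for name in TREATED_LANDMARKS:
        tf = shift_l if name.endswith("L") else shift_r
        moved = tf.apply(truth.landmarks_t0[name])
        new_truth.landmarks_t1[name] = moved
        new_truth.true_displacements[name] = moved - truth.landmarks_t0[name]
    for name in STABLE_LANDMARKS:
        new_truth.landmarks_t1[name] = np.array(truth.landmarks_t0[name])
        new_truth.true_displacements[name] = np.zeros(3)

    new_atlas = atlas.copy()
    new_atlas.regions["ZygomaticArchR"] = atlas["ZygomaticArchR"].transformed(
        piece_tf["zygomatic_arch_R"]
    )
    new_atlas.regions["ZygomaticArchL"] = atlas["ZygomaticArchL"].transformed(
        piece_tf["zygomatic_arch_L"]
    )
    return vol, new_truth, new_atlas


def simulate_rescan(volume: Volume, spec: PhantomSpec, rng: np.random.Generator):
    """Sample a rigid repositioning (rotation about the solid's centroid)
    within the spec bounds, apply it to the analytic solid *before*
    rasterisation, and return ``(Volume, RigidTransform)``.

    Samples violating the grid margin are rejected and redrawn (up to 50
    draws) so the emitted transform always keeps the solid inside the grid.
    """
    pieces = getattr(volume, "pieces", None)
    if pieces is None:
        raise PhantomError("volume does not carry an analytic phantom model")
    centroid = np.concatenate([p.bounding_points() for p in pieces]).mean(axis=0)
    last_err = None
    for _ in range(50):
        base = RigidTransform.random(
            rng, spec.rescan_rotation_max_deg, spec.rescan_translation_max_mm
        )
        # rotate about the centroid, then translate
        tf = RigidTransform(
            base.rotation,
            centroid - base.rotation @ centroid + base.translation,
        )
        moved = [p.with_pose(tf.compose(p.pose)) for p in pieces]
        try:
            _check_margin(moved, spec, "rescan exits grid")
        except PhantomError as exc:
            last_err = exc
            continue
        vol = _rasterize(moved, spec, rng)
        return vol, tf
    raise PhantomError(f"could not sample an in-grid rescan transform: {last_err}")


def compose_rescan(truth: GroundTruth, atlas: RegionAtlas, transform: RigidTransform):
    """Fold a rescan transform into the ground truth: T1 landmarks and the
    T1-frame atlas become ``transform`` applied to the treated geometry."""
    new_truth = truth.copy()
    new_truth.rescan_transform = transform
    new_truth.landmarks_t1 = truth.landmarks_t1.transformed(transform)
    return new_truth, atlas.transformed(transform)


def jitter_operator(
    landmarks: LandmarkSet,
    atlas: RegionAtlas,
    sd_mm: float,
    rng: np.random.Generator,
    mesh=None,
    region_fraction: float = 0.2,
):
    """Operator variability model: isotropic Gaussian jitter on picked
    landmarks (re-projected onto the mesh surface when one is given) and a
    bounded multiplicative perturbation of region descriptor radii."""
    if sd_mm < 0:
        raise ValueError("sd_mm must be >= 0")
    if sd_mm == 0:
        return landmarks.copy(), atlas.copy()
    new_lm = LandmarkSet()
    query = None
    if mesh is not None:
        from .proximity import ClosestPointQuery

        query = ClosestPointQuery(mesh.vertices, mesh.faces)
    for name, p in landmarks.items():
        q = p + rng.normal(0.0, sd_mm, size=3)
        if query is not None:
            q, _, _ = query.query(q)
        new_lm[name] = q
    new_regions = {}
    for name, desc in atlas.regions.items():
        if region_fraction > 0:
            scale = 1.0 + rng.uniform(-region_fraction, region_fraction)
            new_regions[name] = desc.with_radius_scale(scale)
        else:
            new_regions[name] = desc
    return new_lm, RegionAtlas(new_regions)


def build_sphere_volume(
    radius_mm: float = 20.0,
    voxel_size_mm: float = 0.8,
    bone_hu: float = 1200.0,
    background_hu: float = 0.0,
    noise_sd_hu: float = 0.0,
    partial_volume: bool = True,
    seed: int = 0,
) -> Volume:
    """Single-ball debug volume with an analytic oracle (volume 4/3 pi r^3,
    area 4 pi r^2); used to validate rasterisation and surface extraction."""
    margin = 4 * voxel_size_mm
    n = int(np.ceil((2 * radius_mm + 2 * margin) / voxel_size_mm)) + 1
    spec = PhantomSpec(
        voxel_size_mm=voxel_size_mm,
        grid_shape=(n, n, n),
        bone_hu=bone_hu,
        background_hu=background_hu,
        noise_sd_hu=noise_sd_hu,
        bias_field_amp_hu=0.0,
        partial_volume=partial_volume,
        seed=seed,
    )
    C = spec.extent_mm / 2.0
    piece = _Piece("ball", solids=[_ball_prim(C, radius_mm)])
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    return _rasterize([piece], spec, rng)
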