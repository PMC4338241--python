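"""Voxel volumes, triangle meshes and reference-region face masks.

A :class:`Volume` is a regular grid of HU-like radiodensities with
anisotropy-capable spacing; :func:`extract_isosurface` turns it into a
triangle mesh in mm via marching cubes with linear interpolation along cell
edges (sub-voxel isosurface placement, no smoothing by default). Region
masks name subsets of faces used as registration references or as
measurement patches.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np
import trimesh as _trimesh
from skimage import measure as _measure

from .geometry import Ball, CappedCylinder, RigidTransform
from .proximity import ClosestPointQuery

__all__ = [
    "Volume",
    "TriMesh",
    "RegionMask",
    "NoSurfaceError",
    "RegionMissError",
    "StlParseError",
    "extract_isosurface",
    "clean_components",
    "decimate_to_budget",
    "select_region",
    "circular_patch",
    "read_stl",
    "write_stl",
    "save_volume",
    "load_volume",
    "read_dicom_series",
]


class NoSurfaceError(ValueError):
    """The requested isosurface does not exist in the volume."""


class RegionMissError(ValueError):
    """A region descriptor selected no faces."""


class StlParseError(ValueError):
    """Malformed STL file; carries the byte offset of the failure."""

    def __init__(self, message: str, byte_offset: int | None = None):
        self.byte_offset = byte_offset
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """Regular voxel grid of HU intensities. Grid sample ``(i, j, k)`` sits at
    ``origin_mm + (i, j, k) * spacing_mm``."""

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D grid")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class TriMesh:
    """Indexed triangle surface with vertex positions in mm.

    ``vertex_scalars`` optionally carries a per-vertex channel (e.g. signed
    deviations for colour-map export); ``metadata`` carries provenance such
    as decimation drift.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalars: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces) and self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face index out of range")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex positions must be finite")

    # -- derived quantities -------------------------------------------
    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def transformed(self, transform: RigidTransform) -> "TriMesh":
        return TriMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            None if self.vertex_scalars is None else self.vertex_scalars.copy(),
            dict(self.metadata),
        )

    def submesh(self, face_ids) -> "TriMesh":
        """Reindexed mesh containing only the given faces."""
        face_ids = np.asarray(face_ids, int)
        f = self.faces[face_ids]
        used, inv = np.unique(f, return_inverse=True)
        return TriMesh(self.vertices[used], inv.reshape(-1, 3))

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))


@dataclass
class RegionMask:
    """Subset of mesh faces naming a reference structure or measurement patch."""

    face_ids: np.ndarray
    label: str = ""
    achieved_area_mm2: float | None = None

    def __post_init__(self):
        self.face_ids = np.unique(np.asarray(self.face_ids, dtype=int))
        if len(self.face_ids) == 0:
            raise ValueError("region mask must be non-empty")

    def __len__(self) -> int:
        return len(self.face_ids)


# ---------------------------------------------------------------------------
# isosurface extraction and mesh hygiene
# ---------------------------------------------------------------------------


def extract_isosurface(
    volume: Volume, threshold_hu: float, smooth_iterations: int = 0
) -> TriMesh:
    """Marching-cubes isosurface at ``threshold_hu``, in mm coordinates.

    Linear interpolation along cell edges places the surface sub-voxel;
    orientation is fixed to point outward (away from high intensities).
    Optional Laplacian smoothing is off by default (matching a
    surface-rendering pipeline with noise reduction not selected).
    """
    lo = float(volume.intensities.min())
    hi = float(volume.intensities.max())
    if not (lo < threshold_hu < hi):
        raise NoSurfaceError(
            f"threshold {threshold_hu} HU outside intensity range ({lo}, {hi})"
        )
    verts, faces, _, _ = _measure.marching_cubes(
        volume.intensities,
        level=threshold_hu,
        spacing=tuple(volume.spacing_mm),
        gradient_direction="descent",
    )
    mesh = TriMesh(verts + volume.origin_mm, faces)
    tm = mesh.to_trimesh()
    if tm.is_watertight and tm.volume < 0:
        mesh.faces = mesh.faces[:, ::-1]
    if smooth_iterations > 0:
        tm = mesh.to_trimesh()
        _trimesh.smoothing.filter_laplacian(tm, iterations=smooth_iterations)
        mesh = TriMesh.from_trimesh(tm)
    return mesh


def clean_components(mesh: TriMesh, min_fraction: float = 0.01) -> TriMesh:
    """Drop connected components with fewer than ``min_fraction`` times the
    largest component's face count (floating artifact removal). The largest
    component is preserved exactly; vertices are reindexed."""
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    if mesh.is_empty:
        return mesh
    tm = mesh.to_trimesh()
    comps = _trimesh.graph.connected_components(
        tm.face_adjacency, nodes=np.arange(len(mesh.faces))
    )
    sizes = np.array([len(c) for c in comps])
    largest = sizes.max()
    keep = np.concatenate([c for c, s in zip(comps, sizes) if s >= min_fraction * largest])
    if len(keep) == len(mesh.faces):
        return mesh
    return mesh.submesh(np.sort(keep))


def _cluster_decimate(mesh: TriMesh, pitch: float) -> TriMesh:
    lo = mesh.vertices.min(axis=0)
    cell = np.floor((mesh.vertices - lo) / pitch).astype(np.int64)
    key, cluster_id = np.unique(cell, axis=0, return_inverse=True)
    n_clusters = len(key)
    # representative: mean of the vertices in each cluster
    reps = np.zeros((n_clusters, 3))
    counts = np.bincount(cluster_id, minlength=n_clusters).astype(float)
    for d in range(3):
        reps[:, d] = np.bincount(
            cluster_id, weights=mesh.vertices[:, d], minlength=n_clusters
        ) / counts
    f = cluster_id[mesh.faces]
    nondegenerate = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    f = f[nondegenerate]
    if len(f):
        # drop duplicate faces irrespective of winding
        f_sorted = np.sort(f, axis=1)
        _, first = np.unique(f_sorted, axis=0, return_index=True)
        f = f[np.sort(first)]
    return TriMesh(reps, f.reshape(-1, 3))


def decimate_to_budget(mesh: TriMesh, max_faces: int) -> TriMesh:
    """Reduce the face count to at most ``max_faces`` (polygon budget).

    Identity when already within budget. Otherwise vertices are merged by
    grid clustering at the finest pitch (found by bisection) that meets the
    budget; the one-sided Hausdorff drift of the new vertices from the
    original surface is recorded in ``metadata['decimation_drift_mm']``.
    """
    if max_faces < 4:
        raise ValueError("max_faces must be at least 4")
    if mesh.n_faces <= max_faces:
        return mesh
    edges = mesh.vertices[mesh.faces[:, 0]] - mesh.vertices[mesh.faces[:, 1]]
    pitch_lo = float(np.linalg.norm(edges, axis=1).mean())  # too fine
    pitch_hi = pitch_lo
    result = None
    for _ in range(60):
        cand = _cluster_decimate(mesh, pitch_hi)
        if cand.n_faces <= max_faces:
            result = (pitch_hi, cand)
            break
        pitch_hi *= 1.5
    if result is None:
        raise RuntimeError("decimation failed to reach the face budget")
    # bisect toward the finest pitch that still meets the budget
    lo, (hi, best) = pitch_lo, result
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        cand = _cluster_decimate(mesh, mid)
        if cand.n_faces <= max_faces:
            hi, best = mid, cand
        else:
            lo = mid
    if best.is_empty:
        drift = float("nan")
    else:
        q = ClosestPointQuery(mesh.vertices, mesh.faces)
        _, _, d = q.query(best.vertices)
        drift = float(np.max(d))
    best.metadata["decimation_drift_mm"] = drift
    return best


# ---------------------------------------------------------------------------
# region selection
# ---------------------------------------------------------------------------


def select_region(mesh: TriMesh, descriptor) -> RegionMask:
    """Faces whose centroids fall inside an analytic descriptor
    (:class:`~cranioreg.geometry.Ball` or capped cylinder)."""
    inside = descriptor.contains(mesh.face_centroids())
    ids = np.nonzero(inside)[0]
    if len(ids) == 0:
        raise RegionMissError(
            f"descriptor {getattr(descriptor, 'label', '')!r} selected no faces"
        )
    mask = RegionMask(ids, label=getattr(descriptor, "label", ""))
    mask.achieved_area_mm2 = float(mesh.face_areas()[ids].sum())
    return mask


def circular_patch(
    mesh: TriMesh,
    center,
    area_mm2: float,
    label: str = "patch",
    max_center_dist_mm: float = 2.0,
) -> RegionMask:
    """Geodesic patch grown from the face nearest ``center`` until the
    cumulative face area reaches ``area_mm2`` (measurement patches, e.g. the
    5 mm² fiducial circles). Growth order is geodesic distance approximated
    by shortest paths through face-adjacency centroid hops."""
    center = np.asarray(center, float).reshape(3)
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    q = ClosestPointQuery(mesh.vertices, mesh.faces)
    _, seed_face, dist = q.query(center)
    if dist > max_center_dist_mm:
        raise RegionMissError(
            f"patch center is {dist:.2f} mm from the surface "
            f"(limit {max_center_dist_mm} mm)"
        )
    tm = mesh.to_trimesh()
    adj = tm.face_adjacency
    centroids = mesh.face_centroids()
    areas = mesh.face_areas()
    # adjacency lists
    nbr = [[] for _ in range(mesh.n_faces)]
    for a, b in adj:
        w = float(np.linalg.norm(centroids[a] - centroids[b]))
        nbr[a].append((b, w))
        nbr[b].append((a, w))

    visited = set()
    picked = []
    total = 0.0
    heap = [(0.0, int(seed_face))]
    while heap and total < area_mm2:
        d, fid = heappop(heap)
        if fid in visited:
            continue
        visited.add(fid)
        picked.append(fid)
        total += float(areas[fid])
        for nb, w in nbr[fid]:
            if nb not in visited:
                heappush(heap, (d + w, nb))
    if total < area_mm2:
        raise RegionMissError(
            f"surface exhausted at {total:.2f} mm² before reaching {area_mm2} mm²"
        )
    mask = RegionMask(np.array(picked), label=label)
    mask.achieved_area_mm2 = total
    return mask


# ---------------------------------------------------------------------------
# STL I/O (mm convention; STL itself is unitless)
# ---------------------------------------------------------------------------


def write_stl(mesh: TriMesh, path, mode: str = "binary") -> None:
    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    tm = mesh.to_trimesh()
    file_type = "stl" if mode == "binary" else "stl_ascii"
    data = tm.export(file_type=file_type)
    path = str(path)
    if isinstance(data, str):
        with open(path, "w") as fh:
            fh.write(data)
    else:
        with open(path, "wb") as fh:
            fh.write(data)


def _read_stl_binary(raw: bytes) -> TriMesh:
    if len(raw) < 84:
        raise StlParseError("binary STL shorter than 84-byte preamble", len(raw))
    (n,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n
    if len(raw) < expected:
        raise StlParseError(
            f"binary STL declares {n} triangles but is truncated", len(raw)
        )
    rec = np.frombuffer(raw[84:expected], dtype=np.uint8).reshape(n, 50)
    tri = (
        rec[:, 12:48]
        .copy()
        .view("<f4")
        .reshape(n, 3, 3)
        .astype(float)
    )
    verts = tri.reshape(-1, 3)
    uniq, inv = np.unique(verts, axis=0, return_inverse=True)
    return TriMesh(uniq, inv.reshape(-1, 3))


def _read_stl_ascii(text: str) -> TriMesh:
    tokens = text.split()
    tri = []
    i = 0
    try:
        while i < len(tokens):
            if tokens[i] == "vertex":
                tri.append(
                    [float(tokens[i + 1]), float(tokens[i + 2]), float(tokens[i + 3])]
                )
                i += 4
            else:
                i += 1
    except (IndexError, ValueError) as exc:
        raise StlParseError(f"malformed ASCII STL near token {i}") from exc
    if not tri or len(tri) % 3:
        raise StlParseError("ASCII STL does not contain whole triangles")
    verts = np.array(tri, float)
    uniq, inv = np.unique(verts, axis=0, return_inverse=True)
    return TriMesh(uniq, inv.reshape(-1, 3))


def read_stl(path) -> TriMesh:
    with open(str(path), "rb") as fh:
        raw = fh.read()
    # ASCII files start with 'solid' AND contain 'facet'; some binary files
    # also start with 'solid', so check decodability too.
    head = raw[:512]
    if head[:5] == b"solid":
        try:
            text = raw.decode("ascii")
            if "facet" in text or raw.strip() == b"solid":
                return _read_stl_ascii(text)
        except UnicodeDecodeError:
            pass
    return _read_stl_binary(raw)


# ---------------------------------------------------------------------------
# volume I/O: a minimal self-describing grid container (.npz) and an
# optional DICOM-series convenience reader.
# ---------------------------------------------------------------------------


def save_volume(volume: Volume, path) -> None:
    np.savez_compressed(
        str(path),
        intensities=volume.intensities,
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )


def load_volume(path) -> Volume:
    with np.load(str(path)) as z:
        return Volume(z["intensities"], z["spacing_mm"], z["origin_mm"])


def read_dicom_series(directory) -> Volume:
    """Stack a single-series DICOM directory into a :class:`Volume` (reader
    convenience only; writing DICOM is out of scope)."""
    import pydicom  # optional dependency, imported lazily

    from pathlib import Path

    files = sorted(Path(directory).glob("*"))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    arr = np.stack([s.pixel_array.astype(float) for s in slices], axis=-1)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    px = [float(v) for v in slices[0].PixelSpacing]
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(
            slices[0].ImagePositionPatient[2]
        )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    origin = [float(v) for v in slices[0].ImagePositionPatient]
    return Volume(arr, (px[0], px[1], abs(dz)), origin)
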