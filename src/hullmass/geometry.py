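"""Mesh input/output and exact convex-hull volume/centroid computation.

Skeletal body segments arrive as triangle meshes (OBJ/PLY/STL, one file per
segment).  Each segment is wrapped in its minimum convex hull (MCH) and the
hull's volume and volume-weighted centroid are computed exactly by
signed-tetrahedron summation over the hull's outward-oriented faces — the
divergence theorem applied to a polytope, so there is no voxelisation or
sampling error.  All internal lengths are metres.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull as _SciPyHull
from scipy.spatial import QhullError

__all__ = [
    "TriMesh",
    "ConvexHullResult",
    "DegenerateGeometryError",
    "MeshFormatError",
    "OrientationError",
    "read_mesh",
    "convex_hull",
    "hull_volume",
    "hull_centroid",
    "contains",
    "write_segment_table",
    "CONTAINMENT_TOL",
]

#: Default containment tolerance, metres.
CONTAINMENT_TOL = 1e-9

_UNIT_TO_M = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}

_MESH_SUFFIXES = {".obj", ".ply", ".stl"}


class DegenerateGeometryError(ValueError):
    """Input points do not span three dimensions (or a hull has zero volume)."""


class MeshFormatError(ValueError):
    """A mesh file could not be read as OBJ, PLY, or STL."""


class OrientationError(ValueError):
    """Hull faces are not consistently outward-oriented."""


@dataclass(frozen=True)
class TriMesh:
    """Raw vertex/face geometry of one skeletal body segment.

    Coordinates are stored in metres regardless of the unit of the source
    file; ``units`` records the declared unit of that source.
    """

    vertices: np.ndarray  # (n, 3) float, metres
    faces: np.ndarray  # (m, 3) int indices into vertices
    units: str = "m"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f.reshape(-1, 3) if f.size else f)


@dataclass(frozen=True)
class ConvexHullResult:
    """A minimum convex hull with exact polytope volume and centroid.

    ``faces`` index into ``vertices`` and are wound so every triangle's
    normal points out of the hull (total signed volume positive).
    """

    vertices: np.ndarray  # (k, 3) hull vertices, metres
    faces: np.ndarray  # (m, 3) outward-oriented triangles
    volume: float  # m^3
    centroid: np.ndarray = field(default=None)  # (3,) metres
    equations: np.ndarray = field(default=None, repr=False)  # (m, 4) halfspaces


def _to_meters(vertices: np.ndarray, units: str) -> np.ndarray:
    try:
        scale = _UNIT_TO_M[units]
    except KeyError:
        raise ValueError(f"unknown length unit {units!r}; expected one of {sorted(_UNIT_TO_M)}")
    return vertices if scale == 1.0 else vertices * scale


def read_mesh(path: str | Path, units: str = "m") -> TriMesh:
    """Read an OBJ, PLY, or STL triangle mesh and convert coordinates to metres.

    Parameters
    ----------
    path
        Mesh file; the format is taken from the suffix.
    units
        Length unit of the file's coordinates (``"m"``, ``"mm"`` or ``"cm"``);
        millimetres are multiplied by exactly 1e-3.

    Raises
    ------
    MeshFormatError
        If the file cannot be parsed as a supported mesh format.
    DegenerateGeometryError
        If the mesh has fewer than 4 vertices (cannot bound a volume).
    """
    import trimesh as _trimesh

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format {path.suffix!r} (expected OBJ/PLY/STL)")
    try:
        loaded = _trimesh.load(str(path), force="mesh", process=False)
        vertices = np.asarray(loaded.vertices, dtype=float)
        faces = np.asarray(loaded.faces, dtype=int)
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshFormatError(f"could not read {path}: {exc}") from exc
    if len(vertices) < 4:
        raise DegenerateGeometryError(
            f"{path.name}: {len(vertices)} vertices; at least 4 are required to bound a volume"
        )
    return TriMesh(vertices=_to_meters(vertices, units), faces=faces, units=units)


def _affine_rank(points: np.ndarray) -> int:
    centered = points - points.mean(axis=0)
    return int(np.linalg.matrix_rank(centered, tol=1e-12 * max(1.0, np.abs(points).max())))


def convex_hull(points: np.ndarray | TriMesh) -> ConvexHullResult:
    """Minimum convex hull of a 3D point set.

    Hull vertices are a subset of the input points.  Faces are re-wound so
    that each triangle's outward normal agrees with the hull's halfspace
    equations, making the total signed volume positive irrespective of the
    winding the hull routine emits.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 4 points or coplanar/collinear input; the message
        names the deficient affine rank.
    """
    if isinstance(points, TriMesh):
        points = points.vertices
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got {pts.shape}")
    if len(pts) < 4:
        raise DegenerateGeometryError(f"need at least 4 points, got {len(pts)}")
    rank = _affine_rank(pts)
    if rank < 3:
        kind = {0: "coincident", 1: "collinear", 2: "coplanar"}[rank]
        raise DegenerateGeometryError(f"points are {kind} (affine rank {rank} < 3)")
    try:
        qh = _SciPyHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"hull construction failed: {exc}") from exc

    hull_vertex_idx = qh.vertices  # indices into pts
    remap = np.full(len(pts), -1, dtype=int)
    remap[hull_vertex_idx] = np.arange(len(hull_vertex_idx))
    verts = pts[hull_vertex_idx]
    faces = remap[qh.simplices]

    # Re-wind each triangle so its geometric normal matches the outward
    # halfspace normal reported by the hull routine.
    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", normals, qh.equations[:, :3]) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]

    volume, centroid = _volume_centroid(verts, faces)
    if volume <= 0:
        raise DegenerateGeometryError("hull has non-positive volume")
    return ConvexHullResult(
        vertices=verts,
        faces=faces,
        volume=volume,
        centroid=centroid,
        equations=qh.equations.copy(),
    )


def _volume_centroid(vertices: np.ndarray, faces: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed-tetrahedron volume and volume-weighted centroid of a closed
    triangulated surface, via the divergence theorem with the origin as apex.

    Shifting all vertices by the point-set mean first keeps the signed terms
    well conditioned; the result is origin-independent for a closed surface.
    """
    shift = vertices.mean(axis=0)
    v = vertices - shift
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    volume = float(signed.sum())
    # Tetra centroid is the mean of its 4 vertices (apex at the local origin).
    weighted = (signed[:, None] * (a + b + c) / 4.0).sum(axis=0)
    centroid = weighted / volume + shift if volume != 0 else shift
    return volume, centroid


def hull_volume(hull: ConvexHullResult) -> float:
    """Exact polytope volume (m^3) of a hull by signed-tetrahedron summation.

    Raises :class:`OrientationError` if the face windings are inconsistent
    (total signed volume non-positive).
    """
    volume, _ = _volume_centroid(hull.vertices, hull.faces)
    if volume <= 0:
        raise OrientationError(
            f"total signed volume {volume:g} <= 0; faces are not consistently outward-oriented"
        )
    return volume


def hull_centroid(hull: ConvexHullResult) -> np.ndarray:
    """Volume-weighted centroid (metres) via tetrahedral decomposition."""
    volume, centroid = _volume_centroid(hull.vertices, hull.faces)
    if volume <= 0:
        raise DegenerateGeometryError("hull volume is non-positive; centroid undefined")
    return centroid


def contains(hull: ConvexHullResult, point, tol: float = CONTAINMENT_TOL) -> bool:
    """True iff ``point`` lies inside or within ``tol`` of the hull boundary.

    Tests the point against every outward face halfspace; boundary points
    count as contained (closed-hull convention).
    """
    p = np.asarray(point, dtype=float)
    if hull.equations is not None:
        return bool(np.all(hull.equations[:, :3] @ p + hull.equations[:, 3] <= tol))
    # Fall back to face-plane tests for hulls built without equations.
    tri = hull.vertices[hull.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    offsets = np.einsum("ij,ij->i", normals, tri[:, 0])
    return bool(np.all(normals @ p - offsets <= tol))


def write_segment_table(rows: list[dict], path: str | Path) -> None:
    """Write per-segment hull results as CSV.

    Each row needs keys ``specimen``, ``segment``, ``volume_m3``,
    ``cx``, ``cy``, ``cz``.
    """
    fieldnames = ["specimen", "segment", "volume_m3", "cx", "cy", "cz"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in fieldnames})
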