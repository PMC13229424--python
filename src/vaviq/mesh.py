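"""Triangulated vessel-surface meshes and centerlines (units: mm).

The geometry container is deliberately minimal: node coordinates, a
triangle index array and optional outward unit normals.  Patient meshes
come out of image segmentation upstream; the synthetic module builds
tubes with the same container so every downstream stage is agnostic to
the origin of the surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "Centerline",
    "read_surface_mesh",
    "write_surface_mesh",
]


class MeshValidationError(ValueError):
    """Raised when a mesh or centerline violates its structural invariants."""


@dataclass
class SurfaceMesh:
    """A triangulated surface.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array, mm
    triangles : (n_tri, 3) int array of node indices
    node_normals : (n_nodes, 3) float array of outward unit normals, or None
    """

    node_coords: np.ndarray
    triangles: np.ndarray
    node_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise MeshValidationError("node_coords must be (n_nodes, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be (n_tri, 3)")
        n = self.n_nodes
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            bad = np.unique(
                self.triangles[(self.triangles < 0) | (self.triangles >= n)]
            )
            raise MeshValidationError(
                f"triangle indices out of range [0, {n}): {bad[:10].tolist()}"
            )
        areas = self.triangle_areas()
        degenerate = np.flatnonzero(areas <= 0)
        if degenerate.size:
            raise MeshValidationError(
                f"{degenerate.size} degenerate (zero-area) triangle(s): "
                f"indices {degenerate[:10].tolist()}"
            )
        if self.node_normals is not None:
            self.node_normals = np.asarray(self.node_normals, dtype=float)
            if self.node_normals.shape != self.node_coords.shape:
                raise MeshValidationError("node_normals shape mismatch")
            norms = np.linalg.norm(self.node_normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise MeshValidationError("node_normals must be unit length")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.node_coords[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def node_areas(self) -> np.ndarray:
        """One third of incident-triangle area per node (barycentric lumping)."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.triangles.ravel(), np.repeat(areas / 3.0, 3))
        return out


@dataclass
class Centerline:
    """Ordered vessel centerline with cumulative arclength (mm).

    By convention arclength 0 is the anastomosis end, so the
    juxta-anastomotic analysis region is ``arclength <= extent``.
    """

    points: np.ndarray
    arclength: np.ndarray | None = None
    tangents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshValidationError("centerline points must be (n, 3)")
        if self.points.shape[0] < 2:
            raise MeshValidationError("centerline needs >= 2 points")
        if self.arclength is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arclength = np.asarray(self.arclength, dtype=float)
        if self.arclength[0] != 0.0 or np.any(np.diff(self.arclength) <= 0):
            raise MeshValidationError(
                "arclength must start at 0 and be strictly increasing"
            )
        if self.tangents is None:
            t = np.gradient(self.points, self.arclength, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            self.tangents = t
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)
            if not np.allclose(np.linalg.norm(self.tangents, axis=1), 1.0, atol=1e-6):
                raise MeshValidationError("tangents must be unit length")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


def read_surface_mesh(path: str | Path) -> SurfaceMesh:
    """Read a triangulated surface from an ASCII OBJ file (mm).

    Node order is preserved exactly, because time-series fields are
    stored per node in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() != ".obj":
        raise ValueError(f"unsupported mesh format {path.suffix!r}; expected .obj")
    tm = trimesh.load(str(path), file_type="obj", process=False, maintain_order=True)
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshValidationError(f"{path} does not contain a single triangulated surface")
    normals = None
    # vn records are authoritative when present and per-vertex
    vn = tm.metadata.get("vertex_normals") if tm.metadata else None
    if vn is None and tm.vertex_normals is not None and len(tm.vertex_normals) == len(tm.vertices):
        # trimesh recomputes these from faces; only trust explicit files
        normals = None
    return SurfaceMesh(
        node_coords=np.asarray(tm.vertices, dtype=float),
        triangles=np.asarray(tm.faces, dtype=int),
        node_normals=normals,
    )


def write_surface_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a SurfaceMesh to ASCII OBJ, preserving node order."""
    path = Path(path)
    buf = io.StringIO()
    for v in mesh.node_coords:
        buf.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    for t in mesh.triangles:
        buf.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    path.write_text(buf.getvalue())
    return path
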