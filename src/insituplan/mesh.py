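"""Triangulated substrate meshes and vertical surface probing.

The printing substrate (a scanned skull phantom, or the synthetic spherical-cap
stand-in from :mod:`insituplan.phantom`) is a triangle mesh in millimetres,
z-up.  Toolpath planning needs exactly one geometric query against it: given a
plan-frame ``(x, y)``, where is the outermost upward-facing surface and how
steep is it?  That vertical ray cast is implemented here with a uniform 2D grid
index over face bounding boxes, which is orders of magnitude faster than a
generic ray-mesh intersector for the many thousands of purely vertical probes a
slicing run issues.

STL input/output is delegated to :mod:`trimesh`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import trimesh as _trimesh
from shapely.geometry import Polygon

from .errors import MeshIOError, OutOfFootprintError, ValidationError

# Vertices closer than this (mm) are merged on load; far below any feature of
# interest (0.6 mm layers, 0.8 mm needle).
MERGE_TOLERANCE = 1e-6
# Faces with area below this (mm^2) are considered degenerate and dropped.
AREA_THRESHOLD = 1e-9


# --------------------------------------------------------------------------- #
# Core containers
# --------------------------------------------------------------------------- #

@dataclass
class TriMesh:
    """A validated triangle surface mesh (mm, z-up, 0-based face indices)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str | None = None

    _probe: "_ProbeIndex | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if len(self.faces) < 1:
            raise ValidationError("mesh must contain at least one face")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("mesh vertices contain non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError("face indices out of range")
        if np.any(_face_areas(self.vertices, self.faces) <= AREA_THRESHOLD):
            raise ValidationError("mesh contains zero-area faces; clean it first")

    # -- derived quantities ------------------------------------------------- #

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit face normals (orientation as stored, not re-oriented)."""
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals, each oriented to have z >= 0."""
        tri = self.triangles
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
        fn = fn * np.sign(fn[:, 2:3] + (fn[:, 2:3] == 0.0))
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return vn / norms

    def xy_bounds(self) -> np.ndarray:
        """[[xmin, ymin], [xmax, ymax]] of the projected footprint."""
        return np.array([self.vertices[:, :2].min(axis=0),
                         self.vertices[:, :2].max(axis=0)])

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices.copy(),
                                faces=self.faces.copy(), process=False)

    def save(self, path) -> None:
        """Write the mesh as STL (binary for .stl, ASCII honoured by trimesh)."""
        self.to_trimesh().export(str(path))

    # -- probing ------------------------------------------------------------ #

    def _probe_index(self) -> "_ProbeIndex":
        if self._probe is None:
            self._probe = _ProbeIndex(self)
        return self._probe


@dataclass(frozen=True)
class SurfacePoint:
    """The outermost surface hit of a vertical probe line."""

    position: np.ndarray        # (3,) mm
    normal: np.ndarray          # unit, z-component > 0
    slope_deg: float            # angle between normal and +z, degrees

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "normal", np.asarray(self.normal, float))
        n = float(np.linalg.norm(self.normal))
        if abs(n - 1.0) > 1e-9:
            raise ValidationError(f"normal must be unit length, got |n|={n}")
        if not 0.0 <= self.slope_deg <= 180.0:
            raise ValidationError("slope_deg outside [0, 180]")


class Footprint2D:
    """A simple, counter-clockwise closed polygon in the xy plane (mm).

    Used both as the defect outline extracted from the pre-operative model and
    as the clipping region for infill generation.
    """

    def __init__(self, boundary: Sequence):
        b = np.asarray(boundary, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or len(b) < 3:
            raise ValidationError("boundary must be an (n>=3, 2) array")
        if not np.all(np.isfinite(b)):
            raise ValidationError("boundary contains non-finite coordinates")
        # drop an explicit closing vertex
        if np.allclose(b[0], b[-1]):
            b = b[:-1]
        poly = Polygon(b)
        if not poly.is_valid or poly.area <= 1e-9:
            raise ValidationError("footprint polygon must be simple with area > 0")
        if not poly.exterior.is_ccw:
            b = b[::-1].copy()
            poly = Polygon(b)
        self.boundary = b
        self.polygon = poly

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def contains(self, x: float, y: float) -> bool:
        return bool(shapely.contains_xy(self.polygon, x, y))

    def contains_many(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        return shapely.contains_xy(self.polygon, xy[:, 0], xy[:, 1])

    @classmethod
    def circle(cls, center, radius: float, n: int = 256) -> "Footprint2D":
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        cx, cy = center
        return cls(np.column_stack([cx + radius * np.cos(t),
                                    cy + radius * np.sin(t)]))

    @classmethod
    def from_json(cls, path) -> "Footprint2D":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([[float(x), float(y)] for x, y in self.boundary], fh)

    def __repr__(self):
        return f"Footprint2D({len(self.boundary)} vertices, area={self.area:.1f} mm^2)"


# --------------------------------------------------------------------------- #
# STL ingestion
# --------------------------------------------------------------------------- #

def load_mesh(path, name: str | None = None) -> TriMesh:
    """Load an STL file, merge near-duplicate vertices and drop degenerate faces."""
    path = Path(path)
    try:
        tm = _trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - normalise I/O failures
        raise MeshIOError(f"cannot read mesh file {path}: {exc}") from exc
    if isinstance(tm, _trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValidationError(f"{path} contains no mesh geometry")
        tm = _trimesh.util.concatenate(geoms)
    return clean_mesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64),
                      name=name or path.stem)


def clean_mesh(vertices: np.ndarray, faces: np.ndarray,
               name: str | None = None) -> TriMesh:
    """Merge vertices within ``MERGE_TOLERANCE`` and drop zero-area faces."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, np.int64)
    # quantise-and-unique merge: adequate for tolerance far below feature size
    key = np.round(vertices / MERGE_TOLERANCE).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    faces = inverse[faces]
    # drop faces with repeated vertices or negligible area
    distinct = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
                & (faces[:, 0] != faces[:, 2]))
    faces = faces[distinct]
    if len(faces):
        faces = faces[_face_areas(merged, faces) > AREA_THRESHOLD]
    if len(faces) == 0:
        raise ValidationError("mesh is empty after cleaning")
    used = np.unique(faces)
    remap = np.full(len(merged), -1, np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(merged[used], remap[faces], name=name)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)


# --------------------------------------------------------------------------- #
# Vertical probing
# --------------------------------------------------------------------------- #

class _ProbeIndex:
    """Uniform 2D grid over face xy bounding boxes for vertical ray casts."""

    def __init__(self, mesh: TriMesh, target_faces_per_cell: float = 8.0):
        tri = mesh.triangles
        self.a2 = tri[:, 0, :2]
        e1 = tri[:, 1, :2] - self.a2
        e2 = tri[:, 2, :2] - self.a2
        denom = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        # faces (near-)vertical in projection can never be probe hits
        ok = np.abs(denom) > 1e-12
        self.face_ids = np.nonzero(ok)[0]
        self.a2 = self.a2[ok]
        self.e1, self.e2 = e1[ok], e2[ok]
        self.inv_denom = 1.0 / denom[ok]
        self.z = tri[ok][:, :, 2]
        n = np.cross(tri[ok][:, 1] - tri[ok][:, 0], tri[ok][:, 2] - tri[ok][:, 0])
        n = n * np.sign(n[:, 2:3])  # orient upward
        self.normals = n / np.linalg.norm(n, axis=1, keepdims=True)
        self.mesh = mesh

        lo = tri[ok][:, :, :2].min(axis=1)
        hi = tri[ok][:, :, :2].max(axis=1)
        self.origin = lo.min(axis=0)
        extent = hi.max(axis=0) - self.origin
        m = len(self.face_ids)
        # pick a cell size so the average cell holds few faces
        area = max(extent[0] * extent[1], 1e-12)
        self.cell = max(float(np.sqrt(area * target_faces_per_cell / max(m, 1))), 1e-6)
        self.nx = max(int(np.ceil(extent[0] / self.cell)), 1)
        self.ny = max(int(np.ceil(extent[1] / self.cell)), 1)

        ij_lo = np.clip(((lo - self.origin) / self.cell).astype(np.int64),
                        0, [self.nx - 1, self.ny - 1])
        ij_hi = np.clip(((hi - self.origin) / self.cell).astype(np.int64),
                        0, [self.nx - 1, self.ny - 1])
        counts = (ij_hi[:, 0] - ij_lo[:, 0] + 1) * (ij_hi[:, 1] - ij_lo[:, 1] + 1)
        face_rep = np.repeat(np.arange(m), counts)
        cells = np.empty(counts.sum(), np.int64)
        pos = 0
        # most faces span a single cell; expand multi-cell spans explicitly
        span = counts.max() if m else 1
        if span == 1:
            cells = ij_lo[:, 0] * self.ny + ij_lo[:, 1]
        else:
            for f in range(m):
                for i in range(ij_lo[f, 0], ij_hi[f, 0] + 1):
                    base = i * self.ny
                    nj = ij_hi[f, 1] - ij_lo[f, 1] + 1
                    cells[pos:pos + nj] = base + np.arange(ij_lo[f, 1],
                                                           ij_hi[f, 1] + 1)
                    pos += nj
        order = np.argsort(cells, kind="stable")
        self.sorted_faces = face_rep[order]
        sorted_cells = cells[order]
        self.cell_start = np.searchsorted(sorted_cells, np.arange(self.nx * self.ny))
        self.cell_end = np.searchsorted(sorted_cells, np.arange(self.nx * self.ny),
                                        side="right")

    def candidates(self, x: float, y: float) -> np.ndarray:
        i = int((x - self.origin[0]) / self.cell)
        j = int((y - self.origin[1]) / self.cell)
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            return np.empty(0, np.int64)
        c = i * self.ny + j
        return self.sorted_faces[self.cell_start[c]:self.cell_end[c]]

    def cast(self, x: float, y: float, interpolate_normals: bool,
             vertex_normals: np.ndarray | None):
        """Return (z, normal) of the topmost upward-facing hit, or None."""
        cand = self.candidates(x, y)
        if len(cand) == 0:
            return None
        d = np.array([x, y]) - self.a2[cand]
        u = (d[:, 0] * self.e2[cand][:, 1] - d[:, 1] * self.e2[cand][:, 0]) \
            * self.inv_denom[cand]
        v = (self.e1[cand][:, 0] * d[:, 1] - self.e1[cand][:, 1] * d[:, 0]) \
            * self.inv_denom[cand]
        w = 1.0 - u - v
        eps = -1e-9
        hit = (u >= eps) & (v >= eps) & (w >= eps)
        if not hit.any():
            return None
        idx = cand[hit]
        bary = np.column_stack([w[hit], u[hit], v[hit]])
        zs = (bary * self.z[idx]).sum(axis=1)
        best = int(np.argmax(zs))
        fi = idx[best]
        if interpolate_normals:
            face = self.mesh.faces[self.face_ids[fi]]
            n = bary[best] @ vertex_normals[face]
            nrm = np.linalg.norm(n)
            n = n / nrm if nrm > 0 else self.normals[fi]
            if n[2] < 0:
                n = -n
        else:
            n = self.normals[fi]
        return float(zs[best]), n


def surface_probe(mesh: TriMesh, x: float, y: float,
                  interpolate_normals: bool = False) -> SurfacePoint:
    """Cast a vertical line through ``(x, y)`` and return the outermost surface.

    Among upward-facing intersections the one with the largest z is returned
    (the exposed outer surface).  Raises :class:`OutOfFootprintError` on a miss.
    """
    pts, normals, slopes = surface_probe_batch(
        mesh, np.array([[x, y]]), interpolate_normals=interpolate_normals)
    return SurfacePoint(pts[0], normals[0], float(slopes[0]))


def surface_probe_batch(mesh: TriMesh, xy: np.ndarray,
                        interpolate_normals: bool = False):
    """Vectorised :func:`surface_probe` over an (n, 2) array of probe points.

    Returns ``(positions (n,3), normals (n,3), slope_deg (n,))``.
    """
    xy = np.atleast_2d(np.asarray(xy, float))
    index = mesh._probe_index()
    vn = mesh.vertex_normals() if interpolate_normals else None
    positions = np.empty((len(xy), 3))
    normals = np.empty((len(xy), 3))
    misses = []
    for k, (x, y) in enumerate(xy):
        hit = index.cast(x, y, interpolate_normals, vn)
        if hit is None:
            misses.append((x, y))
            continue
        z, n = hit
        positions[k] = (x, y, z)
        normals[k] = n
    if misses:
        raise OutOfFootprintError(misses)
    slopes = np.degrees(np.arccos(np.clip(normals[:, 2], -1.0, 1.0)))
    return positions, normals, slopes


# --------------------------------------------------------------------------- #
# Patch extraction
# --------------------------------------------------------------------------- #

def extract_patch(mesh: TriMesh, footprint: Footprint2D) -> TriMesh:
    """Sub-mesh of faces whose centroid projects inside the footprint.

    This is the defect-extraction step: the region of the substrate to be
    rebuilt is cut out of the full scan by its planned 2D outline.
    """
    c = mesh.face_centroids()
    keep = footprint.contains_many(c[:, :2])
    if not keep.any():
        raise ValidationError("footprint selects no faces of the mesh")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used], remap[faces],
                   name=(mesh.name or "mesh") + "_patch")
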