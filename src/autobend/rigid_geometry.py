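"""Rigid transforms, sphere fitting, and mesh intersection measurement.

All geometry is in millimetres and all angles in degrees.  The joint
coordinate frame follows the motion-segment convention: ``x`` is the
craniocaudal centrum long axis (axial rotation), ``y`` is dorsoventral
(lateral bending), ``z`` is mediolateral (sagittal bending).

The boolean-intersection measurement has two backends:

* an exact backend for watertight bodies whose connected components are
  convex — the intersection of each convex pair is computed as a halfspace
  intersection (LP Chebyshev centre for a strictly interior point, then
  scipy ``HalfspaceIntersection`` / ``ConvexHull``);
* a voxel fallback for anything else (occupancy grid and marching cubes),
  which flags its result as approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

__all__ = [
    "JointFrame", "SphereFit", "fit_sphere", "rotate_about_frame",
    "translate_along_frame", "surface_area", "boolean_intersection_area",
    "IntersectionMeasure", "RigidShape",
]

_ORTHO_TOL = 1e-6


# ---------------------------------------------------------------------------
# Joint frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointFrame:
    """Centre of rotation plus right-handed orthonormal axes.

    ``x_axis`` points caudally (anterior -> posterior vertebra), ``y_axis``
    dorsally, ``z_axis`` completes the right-handed triad.
    """

    cor: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("cor", "x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite {name}")
        for name in ("x_axis", "y_axis", "z_axis"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} is not unit length")
        x, y, z = self.x_axis, self.y_axis, self.z_axis
        if (abs(x @ y) > _ORTHO_TOL or abs(y @ z) > _ORTHO_TOL
                or abs(x @ z) > _ORTHO_TOL):
            raise ValueError("frame axes are not mutually orthogonal")
        if np.cross(x, y) @ z < 1.0 - 1e-6:
            raise ValueError("frame is not right-handed")

    @classmethod
    def standard(cls, cor=(0.0, 0.0, 0.0)) -> "JointFrame":
        return cls(np.asarray(cor, float), np.array([1.0, 0, 0]),
                   np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.x_axis, "y": self.y_axis, "z": self.z_axis}[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}") from None

    def rotation_matrix(self, axis: str, angle_deg: float) -> np.ndarray:
        """Homogeneous 4x4 rotation by ``angle_deg`` about ``axis`` through the COR."""
        if not np.isfinite(angle_deg):
            raise ValueError("non-finite angle")
        return trimesh.transformations.rotation_matrix(
            np.radians(angle_deg), self.axis(axis), self.cor)

    def to_dict(self) -> dict:
        return {"cor": self.cor.tolist(), "x_axis": self.x_axis.tolist(),
                "y_axis": self.y_axis.tolist(), "z_axis": self.z_axis.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "JointFrame":
        return cls(np.asarray(d["cor"], float), np.asarray(d["x_axis"], float),
                   np.asarray(d["y_axis"], float), np.asarray(d["z_axis"], float))


# ---------------------------------------------------------------------------
# Sphere fitting (COR placement from zygapophyseal facet points)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


def fit_sphere(points: Sequence) -> SphereFit:
    """Fit a sphere to >=4 points.

    Exactly four points give the unique interpolating sphere (the classic
    four-point construction used for centre-of-rotation placement); more
    points give the algebraic least-squares sphere.  Degenerate (coplanar or
    coincident) configurations raise rather than guess.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point coordinates")
    n = len(pts)
    if n < 4:
        raise ValueError("at least 4 points are required to fit a sphere")

    # |p|^2 = 2 c.p + (r^2 - |c|^2): linear in (c, k)
    A = np.column_stack([2.0 * pts, np.ones(n)])
    b = np.einsum("ij,ij->i", pts, pts)
    # rank 4 requires points spanning 3D (non-coplanar)
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 4:
        raise ValueError("degenerate point configuration (coplanar or coincident)")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate point configuration")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius,
                     rms_residual=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

def _apply_transform(obj, matrix: np.ndarray):
    """Return a transformed copy of an (n,3) array or a Trimesh."""
    if isinstance(obj, trimesh.Trimesh):
        out = obj.copy()
        out.apply_transform(matrix)
        return out
    pts = np.atleast_2d(np.asarray(obj, dtype=float))
    out = pts @ matrix[:3, :3].T + matrix[:3, 3]
    return out if np.asarray(obj).ndim == 2 else out[0]


def rotate_about_frame(obj, frame: JointFrame, axis: str, angle_deg: float):
    """Rotate points or a mesh about a frame axis through the COR.

    The rotation is always composed fresh from the input pose — callers
    rotate from neutral by the full angle at every probe, never by
    accumulating increments, which avoids floating-point drift.
    """
    return _apply_transform(obj, frame.rotation_matrix(axis, angle_deg))


def translate_along_frame(obj, frame: JointFrame, direction: np.ndarray,
                          distance: float):
    """Translate points or a mesh by ``distance`` along a unit ``direction``."""
    if not np.isfinite(distance):
        raise ValueError("non-finite distance")
    d = np.asarray(direction, dtype=float).reshape(3)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    m = np.eye(4)
    m[:3, 3] = d * distance
    return _apply_transform(obj, m)


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area (mm^2) as the sum of triangle areas."""
    if len(mesh.faces) == 0:
        raise ValueError("mesh has no triangles")
    return float(mesh.area)


# ---------------------------------------------------------------------------
# Boolean intersection measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntersectionMeasure:
    """Result of an intersection measurement.

    ``area`` is the surface area of the intersection solid (the quantity the
    bony-contact threshold is applied to); ``volume`` is recorded for
    diagnostics.  ``flagged`` marks voxel-fallback (approximate) results.
    """
    area: float
    volume: float
    method: str            # "convex-exact" | "voxel"
    flagged: bool = False

    def measure(self, mode: str = "surface_area") -> float:
        if mode == "surface_area":
            return self.area
        if mode == "volume":
            return self.volume
        raise ValueError(f"unknown intersection measure mode {mode!r}")


class _ConvexPiece:
    """One convex connected component: hull planes + cached geometry."""

    __slots__ = ("points", "planes", "bounds_lo", "bounds_hi")

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, float)
        hull = ConvexHull(self.points)
        eqs = hull.equations  # rows (n, c): n.x + c <= 0 inside, |n| = 1
        self.planes = np.unique(np.round(eqs, 9), axis=0)
        self.bounds_lo = self.points.min(axis=0)
        self.bounds_hi = self.points.max(axis=0)

    def transformed(self, matrix: np.ndarray) -> "_ConvexPiece":
        out = object.__new__(_ConvexPiece)
        out.points = self.points @ matrix[:3, :3].T + matrix[:3, 3]
        # planes transform as n' = R n, c' = c - n'. t
        n = self.planes[:, :3] @ matrix[:3, :3].T
        c = self.planes[:, 3] - n @ matrix[:3, 3]
        out.planes = np.column_stack([n, c])
        out.bounds_lo = out.points.min(axis=0)
        out.bounds_hi = out.points.max(axis=0)
        return out


class RigidShape:
    """A watertight body pre-split into connected components.

    When every component is convex the exact intersection backend applies;
    otherwise the voxel fallback is used.  Instances are immutable; posed
    copies are produced with :meth:`transformed`.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        parts = mesh.split(only_watertight=False)
        if len(parts) == 0:
            parts = [mesh]
        self.all_convex = all(p.is_convex for p in parts)
        self.pieces = ([_ConvexPiece(p.vertices) for p in parts]
                       if self.all_convex else [])

    def transformed(self, matrix: np.ndarray) -> "RigidShape":
        out = object.__new__(RigidShape)
        out.mesh = None  # built lazily only if the voxel path needs it
        out._source = self
        out._matrix = matrix
        out.all_convex = self.all_convex
        out.pieces = [p.transformed(matrix) for p in self.pieces]
        return out

    def _materialize(self) -> trimesh.Trimesh:
        if self.mesh is None:
            self.mesh = _apply_transform(self._source.mesh, self._matrix)
        return self.mesh


def _chebyshev_center(planes: np.ndarray):
    """Largest inscribed ball of the polytope {x : n.x + c <= 0}."""
    A = np.column_stack([planes[:, :3], np.ones(len(planes))])
    res = linprog(c=[0.0, 0.0, 0.0, -1.0], A_ub=A, b_ub=-planes[:, 3],
                  bounds=[(None, None)] * 3 + [(0, None)], method="highs")
    if not res.success or res.x[3] <= 1e-9:
        return None
    return res.x[:3], res.x[3]


def _convex_pair_intersection(a: _ConvexPiece, b: _ConvexPiece):
    """(area, volume) of the intersection of two convex pieces; (0, 0) when
    disjoint or touching without volumetric overlap."""
    if np.any(a.bounds_lo > b.bounds_hi) or np.any(b.bounds_lo > a.bounds_hi):
        return 0.0, 0.0
    planes = np.vstack([a.planes, b.planes])
    cheb = _chebyshev_center(planes)
    if cheb is None:
        return 0.0, 0.0
    interior, _ = cheb
    try:
        hs = HalfspaceIntersection(planes, interior)
        hull = ConvexHull(hs.intersections)
    except QhullError:
        return 0.0, 0.0
    return float(hull.area), float(hull.volume)


def _contains(mesh: trimesh.Trimesh, points: np.ndarray,
              chunk: int = 8192) -> np.ndarray:
    """Point-in-mesh by ray-crossing parity (vectorized Moller-Trumbore).

    Assumes a closed surface; the ray direction is deliberately oblique to
    the coordinate axes so axis-aligned faces are never grazed.
    """
    d = np.array([0.577215, 0.618034, 0.532988])
    d /= np.linalg.norm(d)
    tri = mesh.triangles  # (F, 3, 3)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    h = np.cross(d, e2)
    det = np.einsum("fj,fj->f", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    out = np.zeros(len(points), dtype=bool)
    for i in range(0, len(points), chunk):
        p = points[i:i + chunk]
        s = p[:, None, :] - v0[None, :, :]            # (P, F, 3)
        u = np.einsum("pfj,fj->pf", s, h) * inv
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pfj,j->pf", q, d) * inv
        t = np.einsum("pfj,fj->pf", q, e2) * inv
        hit = (ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0))
        out[i:i + chunk] = (hit.sum(axis=1) % 2) == 1
    return out


def _voxel_intersection(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
                        pitch: float, max_cells: int = 2_000_000):
    from skimage import measure as skmeasure

    lo = np.maximum(mesh_a.bounds[0], mesh_b.bounds[0]) - 2 * pitch
    hi = np.minimum(mesh_a.bounds[1], mesh_b.bounds[1]) + 2 * pitch
    if np.any(hi <= lo):
        return 0.0, 0.0
    # coarsen the pitch if the grid would be unreasonably large
    while np.prod(np.maximum((hi - lo) / pitch, 1).astype(int)) > max_cells:
        pitch *= 1.5
    axes = [np.arange(lo[i] + pitch / 2, hi[i], pitch) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    pts = grid.reshape(-1, 3)
    inside = _contains(mesh_a, pts)
    inside[inside] &= _contains(mesh_b, pts[inside])
    if not inside.any():
        return 0.0, 0.0
    volume = float(inside.sum()) * pitch ** 3
    field = np.pad(inside.reshape(shape).astype(np.float32), 1)
    verts, faces, _, _ = skmeasure.marching_cubes(field, 0.5,
                                                  spacing=(pitch,) * 3)
    area = float(skmeasure.mesh_surface_area(verts, faces))
    return area, volume


def _default_pitch(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> float:
    # sqrt(mean surface area)/200: resolves overlap fractions of 0.25%
    mean_area = 0.5 * (mesh_a.area + mesh_b.area)
    return float(np.sqrt(mean_area) / 200.0)


def intersect_shapes(shape_a: RigidShape, shape_b: RigidShape,
                     pitch: float | None = None) -> IntersectionMeasure:
    """Intersection measure between two rigid shapes (posed copies allowed)."""
    if shape_a.all_convex and shape_b.all_convex:
        area = 0.0
        volume = 0.0
        for pa in shape_a.pieces:
            for pb in shape_b.pieces:
                a, v = _convex_pair_intersection(pa, pb)
                area += a
                volume += v
        return IntersectionMeasure(area, volume, "convex-exact", False)
    mesh_a = shape_a._materialize() if shape_a.mesh is None else shape_a.mesh
    mesh_b = shape_b._materialize() if shape_b.mesh is None else shape_b.mesh
    if pitch is None:
        pitch = _default_pitch(mesh_a, mesh_b)
    area, volume = _voxel_intersection(mesh_a, mesh_b, pitch)
    return IntersectionMeasure(area, volume, "voxel", True)


def boolean_intersection_area(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
                              pitch: float | None = None,
                              full_result: bool = False):
    """Surface area (mm^2) of the boolean intersection solid of two meshes.

    Returns 0 for disjoint bodies or for contact without volumetric overlap.
    Bodies whose connected components are all convex are measured exactly;
    anything else goes through the flagged voxel fallback.  With
    ``full_result=True`` the full :class:`IntersectionMeasure` is returned.
    """
    res = intersect_shapes(RigidShape(mesh_a), RigidShape(mesh_b), pitch=pitch)
    return res if full_result else res.area
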