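"""Convex-geometry primitives shared by the whole pipeline.

All geometry lives in physical coordinates (the same length unit as the voxel
spacing); points are ``(N, 3)`` float arrays in ``(x, y, z)`` order.  A nuclear
boundary is always a convex polytope — the convex hull of segmented envelope
voxels or of a sampled synthetic surface — represented by its vertices,
outward-oriented triangular facets and facet half-space equations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DataError

try:  # optional acceleration for the half-space containment test
    from numba import njit as _njit

    @_njit(cache=False, fastmath=True)
    def _inside_halfspaces(points, normals, offsets, tol):  # pragma: no cover
        n = points.shape[0]
        F = normals.shape[0]
        out = np.ones(n, dtype=np.bool_)
        for i in range(n):
            x, y, z = points[i, 0], points[i, 1], points[i, 2]
            for f in range(F):
                if normals[f, 0] * x + normals[f, 1] * y + normals[f, 2] * z + offsets[f] > tol:
                    out[i] = False
                    break
        return out

except ImportError:  # pragma: no cover
    _inside_halfspaces = None

__all__ = [
    "ConvexBoundary",
    "PointPattern",
    "convex_boundary_from_points",
    "ray_exit_distance",
    "fractional_radius",
    "sample_uniform",
    "clip_to_surface",
]


@dataclass(frozen=True)
class ConvexBoundary:
    """Convex hull of one nucleus in physical coordinates.

    Attributes
    ----------
    vertices : (V, 3) array
        Hull vertices; every row is an extreme point.
    facets : (F, 3) int array
        Triangle vertex indices, ordered so the right-hand normal points
        outward.
    equations : (F, 4) array
        Facet half-spaces ``n·x + d <= 0`` for interior points, ``|n| = 1``.
    centroid : (3,) array
        Volume centroid (centre of mass of the solid hull).
    volume : float
        Enclosed volume.
    """

    vertices: np.ndarray
    facets: np.ndarray
    equations: np.ndarray
    centroid: np.ndarray
    volume: float

    def __post_init__(self):
        if self.volume <= 0:
            raise DataError("degenerate boundary: non-positive volume")
        if not bool(self.contains(self.centroid[None, :], tol=1e-9)[0]):
            raise DataError("boundary centroid is not interior")

    # -- queries ----------------------------------------------------------

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Max over facets of ``n·x + d``: negative inside, positive outside.

        This equals the Euclidean distance to the surface for points whose
        nearest surface point lies on a facet interior, and is a lower bound
        otherwise.
        """
        points = np.atleast_2d(points)
        return points @ self.equations[:, :3].T + self.equations[:, 3]

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside (or within ``tol`` of) the hull.

        A point is inside iff no facet half-space ``n·x + d`` exceeds
        ``tol``; large queries run through a compiled early-exit kernel.
        """
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=float)
        if _inside_halfspaces is not None and points.shape[0] * self.equations.shape[0] > 20_000:
            return _inside_halfspaces(
                points,
                np.ascontiguousarray(self.equations[:, :3]),
                np.ascontiguousarray(self.equations[:, 3]),
                float(tol),
            )
        return self.signed_distance(points).max(axis=1) <= tol

    @property
    def diameter(self) -> float:
        return float(np.linalg.norm(np.ptp(self.vertices, axis=0)))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ConvexBoundary":
        """Apply the map ``x -> R @ x + t``.

        For a proper rigid rotation the facets, volume and half-space
        equations transform analytically (no re-hulling); a general linear
        map falls back to rebuilding the hull.
        """
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float).reshape(3)
        is_rigid = (
            np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-12)
            and np.linalg.det(rotation) > 0
        )
        if not is_rigid:
            return convex_boundary_from_points(self.vertices @ rotation.T + translation)
        vertices = self.vertices @ rotation.T + translation
        normals = self.equations[:, :3] @ rotation.T
        offsets = self.equations[:, 3] - normals @ translation
        return ConvexBoundary(
            vertices=vertices,
            facets=self.facets.copy(),
            equations=np.column_stack([normals, offsets]),
            centroid=rotation @ self.centroid + translation,
            volume=self.volume,
        )


@dataclass
class PointPattern:
    """A set of compartment centres belonging to one replicate nucleus."""

    points: np.ndarray  # (N, 3) physical coordinates
    replicate_id: str = ""
    source_sizes: Optional[np.ndarray] = None  # voxel count per centre
    clipped: Optional[np.ndarray] = None  # bool per centre, True if moved onto hull

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]


def convex_boundary_from_points(points: np.ndarray) -> ConvexBoundary:
    """Build a :class:`ConvexBoundary` from an arbitrary 3D point cloud.

    Raises :class:`DataError` when the cloud is degenerate (fewer than four
    points, or coplanar).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] < 4:
        raise DataError(
            f"need at least 4 points to build a 3D hull, got {points.shape[0]}"
        )
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DataError(f"degenerate point set for convex hull: {exc}") from exc

    vertices = points[hull.vertices]
    # Remap simplices from original-cloud indices to hull-vertex indices.
    remap = np.full(points.shape[0], -1, dtype=int)
    remap[hull.vertices] = np.arange(hull.vertices.size)
    facets = remap[hull.simplices]
    equations = hull.equations.copy()

    # Orient each triangle so its right-hand normal agrees with the outward
    # facet normal from qhull.
    tri = vertices[facets]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", cross, equations[:, :3]) < 0
    facets[flip] = facets[flip][:, [0, 2, 1]]

    # Volume centroid by fan decomposition into tetrahedra from an interior
    # reference point (the vertex mean is interior for a convex body).
    ref = vertices.mean(axis=0)
    tri = vertices[facets]
    a, b, c = tri[:, 0] - ref, tri[:, 1] - ref, tri[:, 2] - ref
    tet_vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    tet_cen = ref + (a + b + c) / 4.0
    volume = float(tet_vol.sum())
    centroid = (tet_cen * tet_vol[:, None]).sum(axis=0) / volume

    return ConvexBoundary(
        vertices=vertices,
        facets=facets,
        equations=equations,
        centroid=centroid,
        volume=volume,
    )


def ray_exit_distance(
    boundary: ConvexBoundary, origin: np.ndarray, directions: np.ndarray
) -> np.ndarray:
    """Distance from an interior origin to the hull surface along each ray.

    ``directions`` is ``(N, 3)`` of unit (or at least non-zero) vectors; the
    returned ``(N,)`` distances satisfy ``origin + t*dir`` on the surface.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if not bool(boundary.contains(origin[None, :], tol=1e-9)[0]):
        raise DataError("ray origin is not inside the boundary")
    normals = boundary.equations[:, :3]
    offsets = boundary.equations[:, 3]
    denom = directions @ normals.T  # (N, F)
    numer = -(origin @ normals.T + offsets)  # (F,) >= 0 for interior origin
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 1e-12, numer[None, :] / denom, np.inf)
    t_exit = t.min(axis=1)
    if not np.all(np.isfinite(t_exit)):
        raise DataError("ray never exits the hull (zero direction?)")
    return t_exit


def fractional_radius(boundary: ConvexBoundary, points: np.ndarray) -> np.ndarray:
    """Shape-normalized radial coordinate: 0 at the centroid, 1 on the surface.

    For each point, the distance to the volume centroid divided by the
    centroid-to-surface distance along the same ray.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    delta = points - boundary.centroid
    r = np.linalg.norm(delta, axis=1)
    frac = np.zeros(points.shape[0])
    nz = r > 1e-12 * max(boundary.diameter, 1.0)
    if np.any(nz):
        dirs = delta[nz] / r[nz, None]
        frac[nz] = r[nz] / ray_exit_distance(boundary, boundary.centroid, dirs)
    return frac


def sample_uniform(
    boundary: ConvexBoundary, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points uniformly inside the hull by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 3))
    lo, hi = boundary.bounding_box()
    accept_rate = max(boundary.volume / float(np.prod(hi - lo)), 1e-3)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        batch = max(int((n - filled) / accept_rate * 1.2) + 8, 16)
        cand = rng.uniform(lo, hi, size=(batch, 3))
        good = cand[boundary.contains(cand, tol=0.0)]
        take = min(n - filled, good.shape[0])
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def clip_to_surface(
    boundary: ConvexBoundary, points: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Move points outside the hull onto its surface.

    Returns ``(clipped_points, was_clipped)``.  Each outside point is first
    orthogonally projected onto the plane of its most violated facet — which
    is the exact nearest surface point whenever that projection lands on the
    facet — and otherwise falls back to the intersection of the
    centroid-to-point segment with the surface.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    abs_tol = tol * max(boundary.diameter, 1.0)
    outside = ~boundary.contains(points, tol=abs_tol)
    if not np.any(outside):
        return points, outside
    idx = np.flatnonzero(outside)
    sd = boundary.signed_distance(points[idx])
    worst = sd.max(axis=1)
    facet = sd.argmax(axis=1)
    normals = boundary.equations[facet, :3]
    proj = points[idx] - worst[:, None] * normals
    ok = boundary.contains(proj, tol=1e-7 * max(boundary.diameter, 1.0))
    # Fallback: shrink toward the centroid until on the surface.
    bad = idx[~ok]
    if bad.size:
        delta = points[bad] - boundary.centroid
        r = np.linalg.norm(delta, axis=1)
        dirs = delta / r[:, None]
        t = ray_exit_distance(boundary, boundary.centroid, dirs)
        proj[~ok] = boundary.centroid + dirs * t[:, None]
    points[idx] = proj
    return points, outside
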