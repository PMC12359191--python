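"""Convex-polytope primitives.

Lobule components and clipped vessel segments are represented as unions of
convex polytopes: exact volumes come from ``scipy.spatial.ConvexHull``,
point-membership from the hull's facet half-space equations, and cropping is
closed under half-space clipping.  Curved shapes (cylinders, annular shells)
are polygonal approximations whose tessellation count is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError


@dataclass
class ConvexPoly:
    """A convex polytope defined by its vertex set (hull taken on demand)."""

    vertices: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self._hull: ConvexHull | None = None

    @property
    def hull(self) -> ConvexHull:
        if self._hull is None:
            self._hull = ConvexHull(self.vertices)
        return self._hull

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    @property
    def faces(self) -> np.ndarray:
        """Outward-oriented triangles (indices into hull points)."""
        h = self.hull
        faces = h.simplices.copy()
        # Qhull does not guarantee orientation; flip triangles whose normal
        # points toward the interior.
        pts = h.points
        centroid = pts[np.unique(faces)].mean(axis=0)
        tri = pts[faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        inward = np.einsum("ij,ij->i", n, tri.mean(axis=1) - centroid) < 0
        faces[inward] = faces[inward][:, ::-1]
        return faces

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points satisfy every facet half-space."""
        pts = np.atleast_2d(np.asarray(points, float))
        eqs = self.hull.equations  # A x + b <= 0 inside
        val = pts @ eqs[:, :3].T + eqs[:, 3]
        return (val <= tol).all(axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def translated(self, offset) -> "ConvexPoly":
        return ConvexPoly(self.vertices + np.asarray(offset, float))

    def clip_halfspace(self, normal, d: float, tol: float = 1e-12) -> "ConvexPoly | None":
        """Intersect with the half-space ``normal . x <= d``.

        Returns None when the intersection is empty or degenerate (volume 0).
        """
        n = np.asarray(normal, float)
        verts = self.hull.points
        side = verts @ n - d
        keep = side <= tol
        if keep.all():
            return self
        if not keep.any():
            return None
        new_pts = [verts[keep]]
        # intersect every hull edge that crosses the plane
        edges = set()
        for simplex in self.hull.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                edges.add((min(a, b), max(a, b)))
        for a, b in edges:
            sa, sb = side[a], side[b]
            if (sa > tol) != (sb > tol) and abs(sa - sb) > 0:
                t = sa / (sa - sb)
                new_pts.append((verts[a] + t * (verts[b] - verts[a]))[None, :])
        pts = np.vstack(new_pts)
        try:
            hull = ConvexHull(pts)
        except QhullError:
            return None
        if hull.volume <= 0:
            return None
        out = ConvexPoly(pts)
        out._hull = hull
        return out

    def clip_box(self, lo, hi) -> "ConvexPoly | None":
        """Intersect with an axis-aligned box."""
        poly: ConvexPoly | None = self
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        for axis in range(3):
            if poly is None:
                return None
            e = np.zeros(3)
            e[axis] = 1.0
            poly = poly.clip_halfspace(e, hi[axis])
            if poly is None:
                return None
            poly = poly.clip_halfspace(-e, -lo[axis])
        return poly


# ---------------------------------------------------------------------------
# primitive constructors
# ---------------------------------------------------------------------------

def box(lo, hi) -> ConvexPoly:
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    return ConvexPoly(corners)


def cylinder(start, end, radius: float, n_sides: int = 24, phase: float = 0.0) -> ConvexPoly:
    """Polygonal right cylinder from ``start`` to ``end``.

    The polygon is inscribed at a radius chosen so the polygonal cross-section
    area equals the true circle area (volume-faithful tessellation).
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    axis = end - start
    length = np.linalg.norm(axis)
    if length <= 0:
        raise ValueError("zero-length cylinder")
    axis = axis / length
    # area-preserving vertex radius: n/2 * R^2 * sin(2 pi / n) = pi r^2
    n = n_sides
    r_eff = radius * np.sqrt(2 * np.pi / (n * np.sin(2 * np.pi / n)))
    u = _any_perpendicular(axis)
    v = np.cross(axis, u)
    ang = phase + 2 * np.pi * np.arange(n) / n
    ring = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    verts = np.vstack([start + r_eff * ring, end + r_eff * ring])
    return ConvexPoly(verts)


def regular_hex_prism(side: float, height: float, center=(0.0, 0.0, 0.0)) -> ConvexPoly:
    """Flat-top hexagonal prism: vertices at azimuths 0, 60, ..., 300 deg."""
    c = np.asarray(center, float)
    ang = np.deg2rad(np.arange(6) * 60.0)
    ring = np.stack([side * np.cos(ang), side * np.sin(ang), np.zeros(6)], axis=1)
    lo = ring + [0, 0, -height / 2]
    hi = ring + [0, 0, height / 2]
    return ConvexPoly(np.vstack([lo, hi]) + c)


def icosahedron(center, circumradius: float, rng: np.random.Generator | None = None) -> ConvexPoly:
    """Regular icosahedron, optionally randomly oriented."""
    phi = (1 + np.sqrt(5)) / 2
    base = np.array(
        [[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
         [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
         [phi, 0, 1], [phi, 0, -1], [-phi, 0, 1], [-phi, 0, -1]],
        float,
    )
    base /= np.linalg.norm(base[0])
    if rng is not None:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        base = base @ _quat_matrix(q).T
    return ConvexPoly(np.asarray(center, float) + circumradius * base)


def annular_shell_wedges(
    start, end, r_inner: float, r_outer: float, n_sides: int = 24, phase: float = 0.0
) -> list[ConvexPoly]:
    """Annular tube (hollow shell) around a segment, as convex wedge prisms.

    Each wedge is the convex quad-prism between consecutive azimuths of the
    inner and outer polygons; the union tiles the shell exactly (polygonal
    approximation, area-preserving radii).
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    axis = end - start
    length = np.linalg.norm(axis)
    if length <= 0:
        raise ValueError("zero-length shell")
    axis = axis / length
    n = n_sides
    scale = np.sqrt(2 * np.pi / (n * np.sin(2 * np.pi / n)))
    ri, ro = r_inner * scale, r_outer * scale
    u = _any_perpendicular(axis)
    v = np.cross(axis, u)
    ang = phase + 2 * np.pi * np.arange(n + 1) / n
    dirs = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    wedges = []
    for k in range(n):
        quad = np.array([ri * dirs[k], ro * dirs[k], ro * dirs[k + 1], ri * dirs[k + 1]])
        wedges.append(ConvexPoly(np.vstack([start + quad, end + quad])))
    return wedges


def _any_perpendicular(axis: np.ndarray) -> np.ndarray:
    a = np.asarray(axis, float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    return u / np.linalg.norm(u)


def _quat_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
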