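"""Bounded 2D/3D growth regions built from point sets via alpha shapes.

A growth volume is the region a repair is allowed to fill. It is defined by
a set of points and a tightness parameter ``alpha`` in [0, 1]: ``alpha = 0``
keeps the full Delaunay complex (the convex hull of the points) and
``alpha = 1`` the tightest boundary that still touches every defining point.
Intermediate values interpolate on the circumradius scale of the Delaunay
simplices, so the enclosed measure is non-increasing in ``alpha``.

Planar point sets (within numerical rank tolerance) are handled natively in
2D: the volume is then an area in the plane of the points, containment
requires the query to lie in that plane, and sampling stays in-plane.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Delaunay, cKDTree


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay simplex (robust lstsq solve)."""
    radii = np.empty(len(simplices))
    for k, simp in enumerate(simplices):
        verts = points[simp]
        a = 2.0 * (verts[1:] - verts[0])
        b = (verts[1:] ** 2).sum(axis=1) - (verts[0] ** 2).sum()
        centre, *_ = np.linalg.lstsq(a, b, rcond=None)
        radii[k] = float(np.linalg.norm(verts[0] - centre))
    return radii


def _simplex_measures(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    d = points.shape[1]
    mats = points[simplices[:, 1:]] - points[simplices[:, :1]]
    return np.abs(np.linalg.det(mats)) / math.factorial(d)


class GrowthVolume:
    """Watertight 2D/3D region with containment, geometry and sampling.

    Parameters
    ----------
    points : (n, 2) or (n, 3) array
        Defining point set. 3-column coplanar sets are detected and handled
        as planar (2D) volumes embedded in 3D.
    alpha : float in [0, 1]
        Boundary tightness; 0 is the convex hull, 1 the tightest boundary.
    plane_tol : float
        Out-of-plane tolerance for containment tests of planar volumes (µm).
    """

    def __init__(self, points, alpha: float = 0.0, plane_tol: float = 1e-6):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ValueError("points must be (n, 2) or (n, 3)")
        if pts.shape[1] == 2:
            pts = np.column_stack([pts, np.zeros(len(pts))])
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        self.points = pts
        self.alpha = float(alpha)
        self.plane_tol = float(plane_tol)

        centred = pts - pts.mean(axis=0)
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        scale = s[0] if s[0] > 0 else 1.0
        rank = int((s > 1e-9 * scale).sum())
        if rank < 2:
            raise ValueError("degenerate point set: points are collinear or identical")
        self.ndim = 2 if rank == 2 else 3
        self._origin = pts.mean(axis=0)
        self._basis = vt[: self.ndim]          # rows: orthonormal plane/space basis
        self._local = centred @ self._basis.T  # (n, ndim)

        try:
            self._tri = Delaunay(self._local)
        except Exception as exc:  # pragma: no cover - qhull failure modes
            raise ValueError(f"degenerate point set: {exc}") from exc
        simp = self._tri.simplices
        radii = _circumradii(self._local, simp)
        r_max = radii.max()
        # tightest threshold that still leaves every vertex in some simplex
        min_incident = np.full(len(self._local), np.inf)
        for k, s_ in enumerate(simp):
            np.minimum.at(min_incident, s_, radii[k])
        r_crit = float(min_incident.max())
        thr = (1.0 - self.alpha) * r_max + self.alpha * r_crit
        self._kept = radii <= thr * (1 + 1e-9) + 1e-12
        self._radii = radii
        self._measures = _simplex_measures(self._local, simp)
        kept_vertices = np.unique(simp[self._kept])
        self._kept_vertex_tree = cKDTree(self.points[kept_vertices])

    # -- geometry -------------------------------------------------------
    def to_local(self, q) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        if q.shape[1] == 2:
            q = np.column_stack([q, np.zeros(len(q))])
        return (q - self._origin) @ self._basis.T

    def _out_of_plane(self, q) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        if q.shape[1] == 2:
            q = np.column_stack([q, np.zeros(len(q))])
        loc = (q - self._origin) @ self._basis.T
        recon = self._origin + loc @ self._basis
        return np.linalg.norm(q - recon, axis=1)

    @property
    def measure(self) -> float:
        """Enclosed area (planar volume) or volume, µm² / µm³."""
        return float(self._measures[self._kept].sum())

    def contains(self, q) -> np.ndarray:
        """Boolean containment for query point(s); boundary counts as inside."""
        q = np.atleast_2d(np.asarray(q, dtype=float))
        single = q.shape[0] == 1 and np.asarray(q).ndim <= 2
        loc = self.to_local(q)
        inside = np.zeros(len(loc), dtype=bool)
        simp = self._tri.find_simplex(loc, tol=1e-9)
        ok = simp >= 0
        inside[ok] = self._kept[simp[ok]]
        # points exactly at a kept vertex can land in a dropped simplex
        misses = np.flatnonzero(~inside)
        if len(misses):
            q3 = q if q.shape[1] == 3 else np.column_stack([q, np.zeros(len(q))])
            d, _ = self._kept_vertex_tree.query(q3[misses])
            inside[misses[d <= 1e-9]] = True
        if self.ndim == 2:
            inside &= self._out_of_plane(q) <= self.plane_tol
        return inside if not single else inside

    def distance(self, q) -> np.ndarray:
        """0 inside; otherwise the distance to the nearest kept vertex.

        This is an upper bound on the true distance to the boundary, used
        only in proximity heuristics (cut-terminal selection, attachment
        masks) where simplex-scale slack is acceptable.
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        if q.shape[1] == 2:
            q = np.column_stack([q, np.zeros(len(q))])
        d, _ = self._kept_vertex_tree.query(q)
        d[self.contains(q)] = 0.0
        return d

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the defining points (``V_mean``)."""
        return self.points.mean(axis=0)

    def far_point(self, root) -> np.ndarray:
        """Defining point farthest from *root* (``V_far``)."""
        root = np.asarray(root, dtype=float)
        return self.points[np.argmax(np.linalg.norm(self.points - root, axis=1))]

    def q_point(self, root) -> np.ndarray:
        """Midpoint of the volume centroid and the far point."""
        return 0.5 * (self.centroid + self.far_point(root))

    def chord_length(self, root) -> float:
        """Length of the line through *root* and Q that lies inside the volume.

        The line is clipped against every kept simplex; the result is the
        total measure of the union of the clipped parameter intervals.
        For planar volumes the root is first projected into the plane.
        """
        root = np.asarray(root, dtype=float)
        if root.shape == (2,):
            root = np.append(root, 0.0)
        q = self.q_point(root)
        r_loc = self.to_local(root)[0]
        q_loc = self.to_local(q)[0]
        direction = q_loc - r_loc
        norm = float(np.linalg.norm(direction))
        if norm < 1e-12:
            raise ValueError("root coincides with Q; cannot orient the chord line")
        direction /= norm
        intervals = []
        for k in np.flatnonzero(self._kept):
            simp = self._tri.simplices[k]
            lo, hi = -np.inf, np.inf
            verts = self._local[simp]
            for f in range(len(simp)):
                face = np.delete(np.arange(len(simp)), f)
                # inward-oriented halfspace through the face opposite vertex f
                if self.ndim == 2:
                    a, b = verts[face]
                    normal = np.array([-(b - a)[1], (b - a)[0]])
                else:
                    a, b, c = verts[face]
                    normal = np.cross(b - a, c - a)
                if np.dot(normal, verts[f] - verts[face[0]]) < 0:
                    normal = -normal
                denom = float(np.dot(normal, direction))
                num = float(np.dot(normal, verts[face[0]] - r_loc))
                if abs(denom) < 1e-14:
                    if num < -1e-12:
                        lo, hi = np.inf, -np.inf
                        break
                    continue
                t = num / denom
                if denom > 0:
                    lo = max(lo, t)
                else:
                    hi = min(hi, t)
            if lo < hi:
                intervals.append((lo, hi))
        if not intervals:
            return 0.0
        intervals.sort()
        total, cur_lo, cur_hi = 0.0, *intervals[0]
        for lo, hi in intervals[1:]:
            if lo > cur_hi + 1e-9:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        total += cur_hi - cur_lo
        return float(total)

    # -- sampling -------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator, density=None,
               exclusion=None, r_d: float = 0.0, max_batches: int = 400) -> np.ndarray:
        """Draw *n* points inside the volume by Monte Carlo.

        Proposals are exact uniform draws (simplex picked with probability
        proportional to its measure, barycentric Dirichlet inside), then
        thinned by rejection against the optional *density* weight and by
        the exclusion margin: every accepted point is at least *r_d* away
        from every point of *exclusion*.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        kept_idx = np.flatnonzero(self._kept)
        probs = self._measures[kept_idx]
        probs = probs / probs.sum()
        excl_tree = None
        if exclusion is not None and r_d > 0:
            excl = np.asarray(exclusion, dtype=float)
            if excl.shape[1] == 2:
                excl = np.column_stack([excl, np.zeros(len(excl))])
            excl_tree = cKDTree(excl)
        kept_idx_arr = kept_idx
        dens_ref = None
        if density is not None:
            # pilot uniform draw to estimate the density maximum in V
            pilot_choice = kept_idx_arr[rng.choice(len(kept_idx_arr), size=512,
                                                   p=probs)]
            pilot_bary = rng.dirichlet(np.ones(self.ndim + 1), size=512)
            pilot_verts = self._local[self._tri.simplices[pilot_choice]]
            pilot = self._origin + np.einsum("bi,bij->bj", pilot_bary,
                                             pilot_verts) @ self._basis
            ref_pts = np.vstack([self.points, pilot])
            dens_ref = float(np.max(density(ref_pts))) * 1.3
            if dens_ref <= 0:
                raise RuntimeError("density weight is zero everywhere in the volume")

        out: list[np.ndarray] = []
        batch = max(4 * n, 64)
        for _ in range(max_batches):
            choice = kept_idx[rng.choice(len(kept_idx), size=batch, p=probs)]
            bary = rng.dirichlet(np.ones(self.ndim + 1), size=batch)
            verts = self._local[self._tri.simplices[choice]]
            loc = np.einsum("bi,bij->bj", bary, verts)
            pts = self._origin + loc @ self._basis
            if excl_tree is not None:
                d, _ = excl_tree.query(pts)
                pts = pts[d >= r_d]
            if density is not None and len(pts):
                w = np.asarray(density(pts), dtype=float) / dens_ref
                pts = pts[rng.random(len(pts)) < w]
            if len(pts):
                out.append(pts)
            if sum(len(p) for p in out) >= n:
                return np.vstack(out)[:n]
        raise RuntimeError(
            "target-point sampling failed: the volume is fully excluded or the "
            "density weight rejects everything within the attempt budget")
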