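"""Morphological statistics and curve metrics used for validation.

Branch statistics follow the usual topological decomposition: a segment runs
from one branch point to the next branch point or termination, so an
unbranched cable is a single segment and a symmetric Y has three. Sholl
analysis counts crossings of dendrite with concentric spheres centred on the
root; the crossing count of an edge with a sphere is computed exactly from
the quadratic intersection, so an edge that dips through a shell twice
contributes two crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MorphTree, label_of
from .volume import GrowthVolume


@dataclass
class MorphoStats:
    """Summary morphometrics of one morphology."""

    n_branch_points: int
    total_length: float
    n_segments: int
    mean_segment_length: float
    segment_length_by_label: dict
    segment_diameter_by_label: dict
    sholl_radii: np.ndarray
    sholl_counts: np.ndarray

    def to_dict(self) -> dict:
        d = {
            "n_branch_points": self.n_branch_points,
            "total_length": self.total_length,
            "n_segments": self.n_segments,
            "mean_segment_length": self.mean_segment_length,
        }
        for k, v in self.segment_length_by_label.items():
            d[f"segment_length_{k}"] = v
        for k, v in self.segment_diameter_by_label.items():
            d[f"segment_diameter_{k}"] = v
        return d


def branch_stats(tree: MorphTree, sholl_step: float = 10.0) -> MorphoStats:
    """Branch-point count, cable length, per-segment and Sholl statistics.

    Per-label statistics (e.g. basal vs apical) attribute each segment to
    the structure label of its distal endpoint; segment diameter is the mean
    diameter (2r) over the segment's nodes excluding the proximal endpoint,
    which belongs to the parent segment.
    """
    segs = tree.segments()
    el = tree.edge_lengths()
    seg_lengths = np.array([el[s[1:]].sum() for s in segs]) if segs else np.array([])
    seg_labels = [label_of(tree.code[s[-1]]) for s in segs]
    seg_diams = [float(np.mean(2 * tree.radius[s[1:]])) for s in segs]

    by_label_len: dict[str, float] = {}
    by_label_diam: dict[str, float] = {}
    for lab in sorted(set(seg_labels)):
        sel = [i for i, l in enumerate(seg_labels) if l == lab]
        by_label_len[lab] = float(np.mean(seg_lengths[sel]))
        by_label_diam[lab] = float(np.mean([seg_diams[i] for i in sel]))

    radii, counts = sholl(tree, sholl_step)
    total = float(seg_lengths.sum())
    return MorphoStats(
        n_branch_points=int(tree.branch_point_mask().sum()),
        total_length=total,
        n_segments=len(segs),
        mean_segment_length=float(seg_lengths.mean()) if len(segs) else 0.0,
        segment_length_by_label=by_label_len,
        segment_diameter_by_label=by_label_diam,
        sholl_radii=radii,
        sholl_counts=counts,
    )


def sholl(tree: MorphTree, step: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Sholl profile: crossings of spheres of radii step, 2·step, … at the root."""
    if step <= 0:
        raise ValueError("step must be positive")
    centre = tree.xyz[0]
    dist = np.linalg.norm(tree.xyz - centre, axis=1)
    rmax = dist.max()
    if rmax <= 0:
        return np.array([]), np.array([], dtype=int)
    radii = np.arange(step, rmax + step * (1 - 1e-9), step)
    radii = radii[radii <= rmax + 1e-9]
    counts = np.zeros(len(radii), dtype=int)
    p0 = tree.xyz[tree.parent[1:]] - centre
    seg = tree.xyz[1:] - tree.xyz[tree.parent[1:]]
    a = (seg ** 2).sum(axis=1)
    b = 2 * (p0 * seg).sum(axis=1)
    c0 = (p0 ** 2).sum(axis=1)
    for k, r in enumerate(radii):
        c = c0 - r * r
        disc = b * b - 4 * a * c
        ok = (disc >= 0) & (a > 0)
        sq = np.sqrt(np.clip(disc, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / (2 * a)
            t2 = (-b + sq) / (2 * a)
        eps = 1e-12
        n_cross = (ok & (t1 > eps) & (t1 <= 1 + eps)).astype(int) \
            + (ok & (t2 > eps) & (t2 <= 1 + eps) & (t2 - t1 > eps)).astype(int)
        counts[k] = int(n_cross.sum())
    return radii, counts


def root_angle_distribution(tree: MorphTree) -> np.ndarray:
    """Angle between each edge direction and the away-from-root direction.

    For every non-root node the local growth direction (parent → node) is
    compared with the radial direction (root → node); perfectly radial
    growth gives 0, growth perpendicular to the radial direction π/2.
    Nodes coincident with their parent or with the root are skipped.
    """
    u = tree.xyz[1:] - tree.xyz[tree.parent[1:]]
    v = tree.xyz[1:] - tree.xyz[0]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 1e-12) & (nv > 1e-12)
    cosang = (u[ok] * v[ok]).sum(axis=1) / (nu[ok] * nv[ok])
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def rmse_percent(values, reference: float) -> float:
    """Root mean square error as a percentage of the reference value."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    v = np.asarray(values, dtype=float)
    return float(100.0 * np.sqrt(np.mean((v - reference) ** 2)) / abs(reference))


def discrete_frechet(p, q) -> float:
    """Discrete Fréchet distance between two point sequences (DP recursion)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if len(p) == 0 or len(q) == 0:
        raise ValueError("sequences must be non-empty")
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[n - 1, m - 1])


def boundary_volume(points, alpha: float = 0.0, **kwargs) -> GrowthVolume:
    """Alpha-shape boundary of a 2D/3D point set as a :class:`GrowthVolume`.

    ``alpha = 0`` is the convex hull; ``alpha = 1`` the tightest boundary
    still touching every point. Raises ``ValueError`` on degenerate sets.
    """
    return GrowthVolume(points, alpha=alpha, **kwargs)


def sholl_l1_distance(tree_a: MorphTree, tree_b: MorphTree, step: float = 10.0) -> float:
    """L1 distance between two Sholl profiles on a common radius grid."""
    ra, ca = sholl(tree_a, step)
    rb, cb = sholl(tree_b, step)
    n = max(len(ra), len(rb))
    pa = np.zeros(n)
    pb = np.zeros(n)
    pa[:len(ca)] = ca
    pb[:len(cb)] = cb
    return float(np.abs(pa - pb).sum())
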