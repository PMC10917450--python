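"""The repair orchestrator: estimate growth parameters from the input
neuron, distribute target points in a growth volume, grow, and post-process.

Pipeline (``fix_tree``): resample to 1 µm → estimate the balancing factor,
taper parameters, target-point count and growth threshold where unset →
optional straight main-branch growth → Monte Carlo target distribution →
mode-constrained greedy growth (optionally iterated to match a desired
branch-point count) → spatial jitter → quadratic diameter taper → optional
pruning to a target cable length.

The balancing factor of an input morphology is recovered from its root-angle
distribution: radial, path-optimised trees (bf → 1) have root angles near 0,
while cable-optimised trees (bf → 0) have broad root-angle distributions.
The mean root angle is inverted through a monotone calibration curve
precomputed by growing reference trees across a bf grid with fixed seeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.spatial import ConvexHull
from scipy.stats import gaussian_kde

from .core import MorphTree, append_nodes, resample_tree
from .growth import GrowthParams, GrowthResult, grow_mst
from .morphometry import MorphoStats, branch_stats, root_angle_distribution
from .volume import GrowthVolume

logger = logging.getLogger(__name__)

RESAMPLE_SPACING = 1.0  # µm; growth assumes dense uniform attachment candidates


@dataclass
class TaperParams:
    """Quadratic taper ``d(p) = scale * (1 - p/P)^2 + offset`` with floor d_min."""

    scale: float
    offset: float
    d_min: float


@dataclass
class RepairResult:
    """Repaired tree plus everything needed to audit the repair."""

    tree: MorphTree
    new_node_ids: np.ndarray
    fitted_params: GrowthParams
    stats_before: MorphoStats
    stats_after: MorphoStats
    unconnected_targets: int
    regeneration_percent: float | None = None


# ---------------------------------------------------------------------------
# Balancing-factor estimation (root-angle calibration inversion)
# ---------------------------------------------------------------------------

_BF_GRID = np.round(np.arange(0.0, 1.01, 0.1), 2)


@lru_cache(maxsize=1)
def _bf_calibration() -> tuple[np.ndarray, np.ndarray]:
    """Mean root angle of reference trees grown across the bf grid.

    Reference trees: 150 uniform targets in a 100 µm sphere grown from a
    central root, three fixed seeds per bf, resampled to 1 µm — the same
    conditions under which estimates are later inverted. The curve is made
    monotone non-increasing in bf before use.
    """
    root = MorphTree(np.zeros((1, 3)), [1.0], [-1], [1], [False])
    angles = np.empty(len(_BF_GRID))
    for i, bf in enumerate(_BF_GRID):
        vals = []
        for seed in (101, 202, 303):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(400, 3))
            pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
            pts *= 100.0 * rng.random(400)[:, None] ** (1 / 3)
            res = grow_mst(root, pts[:150], bf=float(bf))
            tree = resample_tree(res.tree, RESAMPLE_SPACING)
            vals.append(float(np.mean(root_angle_distribution(tree))))
        angles[i] = np.mean(vals)
    # enforce monotone non-increasing mean angle in bf
    angles = np.minimum.accumulate(angles)
    return _BF_GRID.copy(), angles


def estimate_bf(tree: MorphTree) -> float:
    """Estimate the balancing factor of a morphology from its root angles.

    Falls back to 0.5 with a warning for trees with fewer than 20 nodes
    after 1 µm resampling (too little material to estimate from).
    """
    tree = resample_tree(tree, RESAMPLE_SPACING)
    if tree.n_nodes < 20:
        warnings.warn("fewer than 20 nodes after resampling; falling back to bf = 0.5")
        return 0.5
    mean_angle = float(np.mean(root_angle_distribution(tree)))
    grid, angles = _bf_calibration()
    # angles decreasing in bf: invert by interpolation on the reversed axis
    bf = float(np.interp(mean_angle, angles[::-1], grid[::-1]))
    return float(np.clip(bf, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Geometry-derived parameters
# ---------------------------------------------------------------------------

def growth_threshold(volume: GrowthVolume, root) -> float:
    """Growth threshold: chord of the line through the root and Q inside V.

    Q is the midpoint of the volume centroid ``V_mean`` and the defining
    point farthest from the root ``V_far``.
    """
    g = volume.chord_length(root)
    if g <= 0:
        raise ValueError(
            "the line through the root and Q misses the growth volume; "
            "set the growth threshold g_thr manually")
    return g


def _spanning_measure(tree: MorphTree, volume: GrowthVolume) -> float:
    """Hull measure of the tree's spanning field, in the volume's dimension."""
    pts = tree.xyz
    if volume.ndim == 2:
        loc = volume.to_local(pts)
        try:
            return float(ConvexHull(loc).volume)
        except Exception:
            return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except Exception:
        # degenerate in 3D (e.g. planar tree): fall back to its plane
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        try:
            return float(ConvexHull(centred @ vt[:2].T).volume)
        except Exception:
            return 0.0


def estimate_target_count(tree: MorphTree, volume: GrowthVolume, k: float = 2.0) -> int:
    """Number of target points from the input's topological-point density.

    ``Npts = round(k * rho * |V|)`` with rho the density of branch plus
    termination points over the input's spanning-field hull and *k* target
    points per expected topological point; floored at 1.
    """
    n_topo = int(tree.branch_point_mask().sum() + tree.terminal_mask().sum())
    span = _spanning_measure(tree, volume)
    if span <= 0 or n_topo == 0:
        return 1
    rho = n_topo / span
    return max(1, int(round(k * rho * volume.measure)))


def topological_density(tree: MorphTree, volume: GrowthVolume):
    """Kernel-density weight built from the input's branch + termination points.

    Evaluated in the volume's local coordinates so planar morphologies do
    not produce a singular covariance. Returns None — meaning uniform
    sampling — when too few points exist for a stable estimate, or when the
    input has no topological points inside the growth volume: a lesioned
    region is empty of surviving branch points, and extrapolating the
    kernel density into it would only pile targets up against the rim.
    """
    mask = tree.branch_point_mask() | tree.terminal_mask()
    pts = tree.xyz[mask]
    if len(pts) < volume.ndim + 3:
        return None
    if int(volume.contains(pts).sum()) < volume.ndim + 3:
        return None
    loc = volume.to_local(pts).T
    try:
        kde = gaussian_kde(loc)
    except Exception:
        return None

    def density(q):
        return kde(volume.to_local(q).T)

    return density


def distribute_targets(volume: GrowthVolume, npts: int, density=None,
                       exclusion=None, r_d: float = 0.0,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Monte Carlo distribution of exactly *npts* target points inside V.

    Points are at least *r_d* away from every exclusion point and thinned
    against the optional density weight; reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return volume.sample(npts, rng, density=density, exclusion=exclusion, r_d=r_d)


# ---------------------------------------------------------------------------
# Cut terminals and main-branch growth
# ---------------------------------------------------------------------------

def find_cut_terminals(tree: MorphTree, volume: GrowthVolume,
                       reach_fraction: float = 0.1) -> np.ndarray:
    """Flagged cut nodes close enough to the growth volume to grow from.

    "Close enough" is within ``reach_fraction`` (default 10%) of the tree's
    bounding-box diagonal — the reach scales with the size of the input
    tree. If the morphology carries no cut flags, terminals within that
    distance whose radius exceeds the median terminal radius are returned
    as a heuristic guess, with a warning.
    """
    diag = float(np.linalg.norm(tree.xyz.max(axis=0) - tree.xyz.min(axis=0)))
    reach = reach_fraction * diag
    flagged = np.flatnonzero(tree.cut)
    if len(flagged):
        near = flagged[volume.distance(tree.xyz[flagged]) <= reach]
        return near + 1
    warnings.warn("no cut flags on the morphology; guessing incomplete terminals "
                  "from thick terminals near the volume")
    term = np.flatnonzero(tree.terminal_mask())
    if len(term) == 0:
        return np.array([], dtype=int)
    med = np.median(tree.radius[term])
    cand = term[(tree.radius[term] > med)
                & (volume.distance(tree.xyz[term]) <= reach)]
    return cand + 1


def grow_main_branch(tree: MorphTree, volume: GrowthVolume, cut_ids,
                     fraction: float = 0.95,
                     step: float = RESAMPLE_SPACING) -> tuple[MorphTree, np.ndarray]:
    """Grow a straight main (apical) branch from the thickest cut terminal.

    The branch follows the direction of the line through the root and Q —
    the same line that defines the growth threshold — in 1 µm steps, until
    ~95% of the chord length is covered or the boundary is left. New nodes
    are labelled apical. Returns the extended tree and the new 1-based ids.
    """
    cut_ids = np.asarray(list(cut_ids), dtype=int)
    if len(cut_ids) == 0:
        raise ValueError("cut_ids must be non-empty")
    rows = cut_ids - 1
    start_row = rows[np.argmax(tree.radius[rows])]
    root = tree.xyz[0]
    q = volume.q_point(root)
    direction = q - root
    nrm = float(np.linalg.norm(direction))
    if nrm < 1e-12:
        raise ValueError("root coincides with Q; main-branch direction undefined")
    direction /= nrm
    chord = volume.chord_length(root)
    n_steps = int(np.floor(fraction * chord / step))
    xyz, parents = [], []
    prev_row = start_row
    p = tree.xyz[start_row].copy()
    entered = False
    for _ in range(n_steps):
        nxt = p + step * direction
        inside = bool(volume.contains(nxt[None, :])[0])
        if entered and not inside:
            break  # left the volume through the far boundary
        entered = entered or inside
        xyz.append(nxt)
        parents.append(prev_row)
        prev_row = tree.n_nodes + len(xyz) - 1
        p = nxt
    if not entered:
        return tree, np.array([], dtype=int)
    if not xyz:
        return tree, np.array([], dtype=int)
    r0 = tree.radius[start_row]
    out = append_nodes(tree, np.asarray(xyz), np.full(len(xyz), r0),
                       parents, np.full(len(xyz), 4, dtype=int))
    return out, np.arange(tree.n_nodes + 1, out.n_nodes + 1)


# ---------------------------------------------------------------------------
# Post-processing: jitter, taper, pruning
# ---------------------------------------------------------------------------

def _new_runs(tree: MorphTree, new_rows: np.ndarray) -> list[tuple[np.ndarray, bool]]:
    """Maximal runs of consecutive new nodes inside segments.

    Returns (row array ordered proximal→distal, end_pinned) per run; run
    interiors contain no branch points by construction.
    """
    new_mask = np.zeros(tree.n_nodes, dtype=bool)
    new_mask[new_rows] = True
    bp = tree.branch_point_mask()
    runs = []
    for seg in tree.segments():
        inner = seg[(new_mask[seg])]
        if len(inner) == 0:
            continue
        # split into consecutive stretches along the segment
        pos = {row: i for i, row in enumerate(seg)}
        idx = np.array([pos[r] for r in inner])
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for chunk in np.split(inner, breaks + 1):
            end_row = chunk[-1]
            end_pinned = bp[end_row] or (end_row != seg[-1])
            # a run ending at the segment's distal endpoint is pinned unless
            # that endpoint is a termination
            if end_row == seg[-1]:
                end_pinned = bp[end_row]
            runs.append((chunk, bool(end_pinned)))
    return runs


def default_jitter_amplitude(tree: MorphTree) -> float:
    """Jitter s.d. from the input's tortuosity: 0.3 × mean per-edge excess
    of segment path length over segment chord length."""
    segs = tree.segments()
    el = tree.edge_lengths()
    resid = []
    for seg in segs:
        lp = float(el[seg[1:]].sum())
        lc = float(np.linalg.norm(tree.xyz[seg[-1]] - tree.xyz[seg[0]]))
        n_edges = max(len(seg) - 1, 1)
        resid.append((lp - lc) / n_edges)
    return 0.3 * float(np.mean(resid)) if resid else 0.0


def jitter_new_nodes(tree: MorphTree, new_ids, amplitude: float,
                     window: int = 5,
                     seed: int | np.random.Generator = 0) -> MorphTree:
    """Impose low-pass filtered spatial noise on the grown dendrite.

    Per-branch independent 3D Gaussian noise (s.d. = amplitude) is smoothed
    with a centred moving average of *window* nodes and added to the new
    coordinates. Branch points and attachment junctions are pinned (zero
    displacement); topology is unchanged.
    """
    if amplitude <= 0:
        return tree.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_rows = np.asarray(list(new_ids), dtype=int) - 1
    out = tree.copy()
    bp = tree.branch_point_mask()
    for chunk, end_pinned in _new_runs(tree, new_rows):
        n = len(chunk)
        noise = rng.normal(0.0, amplitude, size=(n, 3))
        if window > 1 and n > 1:
            kern = np.ones(min(window, n)) / min(window, n)
            noise = np.column_stack([np.convolve(noise[:, k], kern, mode="same")
                                     for k in range(3)])
        # pin the proximal junction; pin the distal end unless it is a tip
        noise -= noise[0]
        if end_pinned and n > 1:
            ramp = np.linspace(0.0, 1.0, n)[:, None]
            noise -= ramp * noise[-1]
        movable = ~bp[chunk]
        out.xyz[chunk[movable]] += noise[movable]
    return out


def fit_taper(tree: MorphTree) -> TaperParams:
    """Least-squares quadratic taper fit over the input's dendritic nodes.

    Fits ``d(p) = scale * (1 - p/P)^2 + offset`` with p the path length to
    the root and P the maximum path length within the node's structure
    label. ``d_min`` is the 5th percentile of terminal diameters.
    """
    dend = ~np.isin(tree.code, (1, 2))
    if dend.sum() < 2:
        dend = np.ones(tree.n_nodes, dtype=bool)
        dend[0] = False
    pl = tree.path_lengths()
    x = np.zeros(tree.n_nodes)
    for code in np.unique(tree.code[dend]):
        sel = dend & (tree.code == code)
        pmax = pl[sel].max()
        x[sel] = (1.0 - pl[sel] / pmax) ** 2 if pmax > 0 else 0.0
    d = 2.0 * tree.radius[dend]
    a = np.column_stack([x[dend], np.ones(dend.sum())])
    (scale, offset), *_ = np.linalg.lstsq(a, d, rcond=None)
    term = tree.terminal_mask() & dend
    d_min = float(np.percentile(2.0 * tree.radius[term], 5)) if term.any() \
        else float(d.min())
    return TaperParams(float(scale), float(offset), max(d_min, 1e-6))


def apply_taper(tree: MorphTree, new_ids, taper: TaperParams) -> MorphTree:
    """Set new-node diameters by the fitted quadratic, floored at d_min.

    Diameters are additionally forced non-increasing from the attachment
    point toward the tips along new material.
    """
    new_rows = np.asarray(list(new_ids), dtype=int) - 1
    if len(new_rows) == 0:
        return tree.copy()
    out = tree.copy()
    pl = tree.path_lengths()
    new_mask = np.zeros(tree.n_nodes, dtype=bool)
    new_mask[new_rows] = True
    pmax_by_code = {int(c): float(pl[tree.code == c].max())
                    for c in np.unique(tree.code)}
    diam = 2.0 * out.radius
    for row in sorted(new_rows):
        pmax = max(pmax_by_code[int(tree.code[row])], 1e-12)
        val = taper.scale * (1.0 - pl[row] / pmax) ** 2 + taper.offset
        pr = tree.parent[row]
        if pr >= 0 and new_mask[pr]:
            val = min(val, diam[pr])
        diam[row] = max(val, taper.d_min)
    out.radius = diam / 2.0
    return out


def prune_to_length(tree: MorphTree, new_ids, target_total: float) -> tuple[MorphTree, np.ndarray]:
    """Trim excess new material: repeatedly remove the shortest terminal
    segment composed entirely of new nodes until the total cable length is
    at most *target_total*. Input nodes are never removed. Returns the
    pruned tree and the surviving new ids."""
    new_rows = set(int(i) - 1 for i in new_ids)
    cur = tree
    while cur.total_length() > target_total:
        el = cur.edge_lengths()
        term = cur.terminal_mask()
        candidates = []
        for seg in cur.segments():
            if term[seg[-1]] and all(r in new_rows for r in seg[1:]):
                candidates.append((float(el[seg[1:]].sum()), seg))
        if not candidates:
            warnings.warn("prune target below the non-removable cable length; "
                          "input material left intact")
            break
        candidates.sort(key=lambda c: (c[0], c[1][-1]))
        _, seg = candidates[0]
        drop = set(int(r) for r in seg[1:])
        keep = np.array([r for r in range(cur.n_nodes) if r not in drop], dtype=int)
        remap = {old: new for new, old in enumerate(keep)}
        parent = np.array([-1 if cur.parent[r] == -1 else remap[cur.parent[r]]
                           for r in keep], dtype=int)
        cur = MorphTree(cur.xyz[keep], cur.radius[keep], parent,
                        cur.code[keep], cur.cut[keep], cur.provenance)
        new_rows = {remap[r] for r in new_rows if r not in drop}
    return cur, np.array(sorted(r + 1 for r in new_rows), dtype=int)


# ---------------------------------------------------------------------------
# The orchestrator
# ---------------------------------------------------------------------------

def _grow_once(base: MorphTree, targets: np.ndarray, bf: float, g_thr: float,
               attach_ids) -> GrowthResult:
    return grow_mst(base, targets, bf=bf, g_thr=g_thr, attach_mask=attach_ids)


def fix_tree(tree: MorphTree, volume: GrowthVolume,
             params: GrowthParams | None = None,
             reference: MorphTree | None = None,
             density: str | None = "auto") -> RepairResult:
    """Repair an incomplete morphology by growing into *volume*.

    Parameters left unset in *params* are estimated from the input: the
    balancing factor from the root-angle distribution, the taper from the
    input diameters, the growth threshold from the root–Q chord of the
    volume and the target-point count from the input's topological-point
    density. With a *reference* (or ``params.target_nbr``), the growth is
    iterated with a bisection on the number of target points (nested target
    sets, at most 12 iterations) to match the desired branch-point count.

    In conserved mode new material can only attach at flagged cut terminals
    (and its own descendants); in biological mode at any node within the
    growth threshold of the volume. Deterministic given ``params.seed``.
    """
    params = params or GrowthParams()
    base = resample_tree(tree, RESAMPLE_SPACING)
    n_input = base.n_nodes
    stats_before = branch_stats(base)
    rng = np.random.default_rng(params.seed)

    bf = params.bf if params.bf is not None else estimate_bf(base)
    taper = TaperParams(*params.taper) if params.taper is not None else fit_taper(base)
    g_thr = params.g_thr if params.g_thr is not None \
        else growth_threshold(volume, base.xyz[0])

    cut_ids = find_cut_terminals(base, volume) if (
        params.mode == "conserved" or params.main_growth or base.cut.any()) else np.array([], dtype=int)

    grown = base
    main_ids = np.array([], dtype=int)
    if params.main_growth and len(cut_ids):
        grown, main_ids = grow_main_branch(base, volume, cut_ids)

    if params.mode == "conserved":
        if len(cut_ids) == 0:
            warnings.warn("conserved mode but no cut terminals near the volume; "
                          "returning the input unchanged")
            return RepairResult(base, np.array([], dtype=int),
                                replace(params, bf=bf, g_thr=g_thr,
                                        taper=(taper.scale, taper.offset, taper.d_min)),
                                stats_before, stats_before, 0)
        attach_ids = np.concatenate([cut_ids, main_ids]).astype(int)
    else:
        near = np.flatnonzero(volume.distance(grown.xyz) <= g_thr) + 1
        attach_ids = np.unique(np.concatenate([near, main_ids.astype(int)])) \
            if len(main_ids) else near
        if len(attach_ids) == 0:
            warnings.warn("no attachable nodes within the growth threshold of the "
                          "volume; returning the input unchanged")
            return RepairResult(base, np.array([], dtype=int),
                                replace(params, bf=bf, g_thr=g_thr),
                                stats_before, stats_before, 0)

    target_nbr = params.target_nbr
    if target_nbr is None and reference is not None:
        target_nbr = int(branch_stats(reference).n_branch_points)

    dens = topological_density(base, volume) if density == "auto" else density
    npts0 = params.npts if params.npts is not None \
        else estimate_target_count(base, volume)
    if target_nbr is not None:
        delta = max(target_nbr - stats_before.n_branch_points, 1)
        npts0 = max(npts0, 3 * delta)

    exclusion = base.xyz if params.r_d > 0 else None
    if target_nbr is None:
        targets = distribute_targets(volume, npts0, density=dens,
                                     exclusion=exclusion, r_d=params.r_d,
                                     seed=rng) if npts0 > 0 else np.empty((0, 3))
        result = _grow_once(grown, targets, bf, g_thr, attach_ids)
        best_n = npts0
    else:
        hi = max(4 * npts0, 8)
        pool = distribute_targets(volume, hi, density=dens,
                                  exclusion=exclusion, r_d=params.r_d, seed=rng)
        best = None
        lo_n, hi_n = 1, hi
        for _ in range(12):
            mid = (lo_n + hi_n) // 2
            res = _grow_once(grown, pool[:mid], bf, g_thr, attach_ids)
            nbr = int(res.tree.branch_point_mask().sum())
            err = abs(nbr - target_nbr)
            if best is None or err < best[0] or (err == best[0] and mid < best[2]):
                best = (err, res, mid)
            if nbr < target_nbr:
                lo_n = mid + 1
            elif nbr > target_nbr:
                hi_n = mid - 1
            else:
                break
            if lo_n > hi_n:
                break
        result = best[1]
        best_n = best[2]

    out = result.tree
    new_ids = np.concatenate([main_ids, result.new_ids]).astype(int)

    amplitude = params.jitter_amplitude if params.jitter_amplitude is not None \
        else default_jitter_amplitude(base)
    out = jitter_new_nodes(out, new_ids, amplitude, params.jitter_window,
                           seed=np.random.default_rng(params.seed + 1))
    out = apply_taper(out, new_ids, taper)
    if params.prune_length is not None:
        out, new_ids = prune_to_length(out, new_ids, params.prune_length)

    stats_after = branch_stats(out)
    fitted = replace(params, bf=bf, g_thr=g_thr, npts=best_n,
                     jitter_amplitude=amplitude,
                     taper=(taper.scale, taper.offset, taper.d_min),
                     target_nbr=target_nbr)
    logger.info("repair: bf=%.3f g_thr=%.1f npts=%d mode=%s new_nodes=%d "
                "unconnected=%d", bf, g_thr, best_n, params.mode, len(new_ids),
                len(result.unconnected))
    assert out.n_nodes >= n_input
    return RepairResult(out, new_ids, fitted, stats_before, stats_after,
                        len(result.unconnected))
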