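"""Greedy optimal-wiring growth: connect target points to an existing tree.

Each unconnected target point is appended as a child of the tree node that
minimises

    total cost = wiring cost + bf * path length cost
               = d + bf * (PL(node) + d)

where ``d`` is the Euclidean distance from the target to the candidate node
and ``PL(node)`` the cable path length from that node to the root, i.e. the
path length the new point would have. With ``bf = 0`` the rule reduces to
nearest-point accretion (exactly Prim's algorithm, so the result is the
classical Euclidean minimum spanning tree); with ``bf = 1`` it favours
direct, radial paths to the soma at the price of extra cable.

Connections longer than the growth threshold ``G_thr`` are forbidden.
Ties are broken lexicographically on (cost, node id, target index), making
the growth deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import MorphTree, append_nodes


@dataclass
class GrowthParams:
    """Free parameters of the repair.

    Attributes
    ----------
    bf : balancing factor in [0, 1]; None means estimate from the input.
    g_thr : growth threshold, µm; maximum span of one connection
        (None = derive from the growth volume; ``inf`` = unbounded).
    npts : number of target points (None = estimate from branch density).
    r_d : exclusion margin around the existing neuron for target points, µm.
    mode : 'biological' (attach anywhere near the volume) or 'conserved'
        (attach only at flagged cut terminals).
    main_growth : grow a straight main (apical) branch first.
    target_nbr : desired branch-point count of the output (None = no matching).
    prune_length : total cable length to prune the repair back to, µm.
    jitter_amplitude : spatial jitter s.d., µm (None = from input tortuosity).
    jitter_window : moving-average window of the jitter low-pass, in nodes.
    taper : (scale, offset, d_min) quadratic taper (None = fit from input).
    seed : integer seed for all stochastic steps.
    """

    bf: float | None = None
    g_thr: float | None = None
    npts: int | None = None
    r_d: float = 0.0
    mode: str = "biological"
    main_growth: bool = False
    target_nbr: int | None = None
    prune_length: float | None = None
    jitter_amplitude: float | None = None
    jitter_window: int = 5
    taper: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.bf is not None and not 0.0 <= self.bf <= 1.0:
            raise ValueError("bf must be in [0, 1]")
        if self.npts is not None and self.npts < 0:
            raise ValueError("npts must be >= 0")
        if self.mode not in ("biological", "conserved"):
            raise ValueError("mode must be 'biological' or 'conserved'")
        if self.r_d < 0:
            raise ValueError("r_d must be >= 0")


@dataclass
class GrowthResult:
    """Outcome of one greedy growth pass."""

    tree: MorphTree
    new_ids: np.ndarray            # 1-based ids of appended nodes, in growth order
    order: list                    # target indices in connection order
    unconnected: list              # target indices that were never reachable

    def growth_order(self) -> list:
        """Connection order of the targets (a valid accretion sequence)."""
        return list(self.order)


def connection_cost(target, node: int, tree: MorphTree, bf: float) -> float:
    """Cost of wiring *target* to 1-based *node*: ``d + bf * (PL(node) + d)``."""
    idx = int(node) - 1
    if not 0 <= idx < tree.n_nodes:
        raise KeyError(f"unknown node id {node}")
    d = float(np.linalg.norm(np.asarray(target, dtype=float) - tree.xyz[idx]))
    pl = tree.path_lengths()[idx]
    return d + bf * (pl + d)


def grow_mst(seed_tree: MorphTree, targets, bf: float = 0.3,
             g_thr: float = np.inf, attach_mask=None,
             label_code: int | None = None) -> GrowthResult:
    """Greedily connect *targets* to *seed_tree* by minimal total cost.

    Parameters
    ----------
    seed_tree : existing morphology; never modified (nodes are appended only).
    targets : (m, 3) or (m, 2) array of target points.
    bf : balancing factor.
    g_thr : maximum Euclidean span of a single connection, µm.
    attach_mask : iterable of 1-based node ids initially allowed as
        attachment points (default: all seed nodes). Newly appended nodes
        are always attachable — they are descendants of the mask.
    label_code : structure code for new nodes (default: inherited from the
        attachment node).

    Unreachable targets (no attachable node within ``g_thr``) are reported
    in :attr:`GrowthResult.unconnected`.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape[1] not in (2, 3):
        raise ValueError("targets must be (m, 2) or (m, 3)")
    if targets.shape[1] == 2:
        targets = np.column_stack([targets, np.zeros(len(targets))])
    m = len(targets)
    n0 = seed_tree.n_nodes
    if attach_mask is None:
        attach_rows = np.arange(n0)
    else:
        attach_rows = np.asarray(sorted(int(i) - 1 for i in attach_mask), dtype=int)
        if len(attach_rows) == 0:
            raise ValueError("attach_mask must be non-empty")
        if attach_rows.min() < 0 or attach_rows.max() >= n0:
            raise KeyError("attach_mask contains unknown node ids")

    seed_pl = seed_tree.path_lengths()
    # growing node store: positions, path lengths, parent rows, codes, radii
    pos = np.empty((n0 + m, 3))
    pos[:n0] = seed_tree.xyz
    pl = np.empty(n0 + m)
    pl[:n0] = seed_pl
    new_parent = np.empty(m, dtype=int)
    new_code = np.empty(m, dtype=int)
    new_radius = np.empty(m)

    best_cost = np.full(m, np.inf)
    best_node = np.full(m, -1, dtype=int)
    alive = np.ones(m, dtype=bool)

    def update_against(node_row: int):
        d = np.linalg.norm(targets - pos[node_row], axis=1)
        cost = d + bf * (pl[node_row] + d)
        ok = alive & (d <= g_thr)
        better = ok & ((cost < best_cost)
                       | (np.isclose(cost, best_cost, rtol=0, atol=1e-12)
                          & (node_row < best_node)))
        best_cost[better] = cost[better]
        best_node[better] = node_row

    for row in attach_rows:
        update_against(row)

    order: list[int] = []
    for step in range(m):
        finite = np.isfinite(best_cost) & alive
        if not finite.any():
            break
        c = best_cost.copy()
        c[~finite] = np.inf
        cmin = c.min()
        cands = np.flatnonzero(np.isclose(c, cmin, rtol=0, atol=1e-12))
        t = min(cands, key=lambda i: (best_node[i], i))
        parent_row = best_node[t]
        new_row = n0 + len(order)
        pos[new_row] = targets[t]
        d_edge = float(np.linalg.norm(targets[t] - pos[parent_row]))
        pl[new_row] = pl[parent_row] + d_edge
        new_parent[len(order)] = parent_row
        if parent_row < n0:
            new_code[len(order)] = seed_tree.code[parent_row] if label_code is None \
                else label_code
            new_radius[len(order)] = seed_tree.radius[parent_row]
        else:
            new_code[len(order)] = new_code[parent_row - n0] if label_code is None \
                else label_code
            new_radius[len(order)] = new_radius[parent_row - n0]
        order.append(int(t))
        alive[t] = False
        best_cost[t] = np.inf
        update_against(new_row)

    k = len(order)
    tree = append_nodes(seed_tree, pos[n0:n0 + k], new_radius[:k],
                        new_parent[:k], new_code[:k])
    new_ids = np.arange(n0 + 1, n0 + k + 1)
    unconnected = [int(i) for i in np.flatnonzero(alive)]
    return GrowthResult(tree, new_ids, order, unconnected)
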