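"""Morphology data model, SWC I/O, resampling and elementary tree surgery.

A neuronal morphology is a rooted tree of 3D points with radii, stored in
parent-before-child order. On disk this is the community-standard 7-column
SWC format (``id type x y z radius parent``), with structure codes
1=soma, 2=axon, 3=basal dendrite, 4=apical dendrite and anything else
treated as a custom neurite type.

Known-incomplete ("cut") terminals have no standard SWC field; this module
persists them in a ``# cut: <ids>`` header comment, a dialect local to this
package. Files without the header simply have no flagged terminals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

CODE_LABELS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
LABEL_CODES = {v: k for k, v in CODE_LABELS.items()}


class SWCFormatError(ValueError):
    """Raised when an SWC stream violates the format invariants."""


def label_of(code: int) -> str:
    return CODE_LABELS.get(int(code), "custom")


@dataclass
class MorphTree:
    """Rooted labelled tree of 3D nodes with radii.

    Nodes are stored in parent-before-child order; node ids exposed through
    the public API are 1-based row numbers of the current tree (renumbered
    after any surgery). ``parent`` holds 0-based row indices, -1 for the root.
    """

    xyz: np.ndarray          # (n, 3) float, µm
    radius: np.ndarray       # (n,) float, µm, > 0
    parent: np.ndarray       # (n,) int, row index of parent, -1 for root
    code: np.ndarray         # (n,) int, SWC structure code
    cut: np.ndarray          # (n,) bool, flagged incomplete terminals
    provenance: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float).ravel()
        self.parent = np.asarray(self.parent, dtype=int).ravel()
        self.code = np.asarray(self.code, dtype=int).ravel()
        self.cut = np.asarray(self.cut, dtype=bool).ravel()
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.radius)
        if n == 0:
            raise ValueError("empty morphology")
        if not (len(self.xyz) == len(self.parent) == len(self.code) == len(self.cut) == n):
            raise ValueError("inconsistent array lengths")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError(f"exactly one root at index 0 required, got {roots.tolist()}")
        idx = np.arange(n)
        if np.any(self.parent[1:] >= idx[1:]) or np.any(self.parent[1:] < 0):
            raise ValueError("parents must precede children")
        if np.any(self.radius <= 0):
            raise ValueError("non-positive radius")

    # -- basic queries --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.radius)

    @property
    def root(self) -> int:
        """1-based id of the root node."""
        return 1

    @property
    def labels(self) -> list[str]:
        return [label_of(c) for c in self.code]

    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_nodes + 1)

    def n_children(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parent[1:], 1)
        return counts

    def children(self) -> list[np.ndarray]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return [np.asarray(c, dtype=int) for c in ch]

    def edge_lengths(self) -> np.ndarray:
        """Length of the edge from each node to its parent; 0 at the root."""
        el = np.zeros(self.n_nodes)
        el[1:] = np.linalg.norm(self.xyz[1:] - self.xyz[self.parent[1:]], axis=1)
        return el

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def path_lengths(self) -> np.ndarray:
        """Cable distance from every node to the root along the tree."""
        el = self.edge_lengths()
        pl = np.zeros(self.n_nodes)
        par = self.parent
        for i in range(1, self.n_nodes):
            pl[i] = pl[par[i]] + el[i]
        return pl

    def branch_point_mask(self) -> np.ndarray:
        return self.n_children() >= 2

    def terminal_mask(self) -> np.ndarray:
        return self.n_children() == 0

    def topological_mask(self) -> np.ndarray:
        """Root, branch points and terminations."""
        m = self.branch_point_mask() | self.terminal_mask()
        m[0] = True
        return m

    def segments(self) -> list[np.ndarray]:
        """Topological decomposition into segments.

        Each segment is the array of row indices from one topological point
        (root/branch point) down to the next topological point, both
        inclusive; interior rows are continuation nodes.
        """
        topo = self.topological_mask()
        segs = []
        for end in range(1, self.n_nodes):
            if not topo[end]:
                continue
            run = [end]
            j = self.parent[end]
            while not topo[j]:
                run.append(j)
                j = self.parent[j]
            run.append(j)
            segs.append(np.asarray(run[::-1], dtype=int))
        return segs

    def descendants(self, idx: int) -> np.ndarray:
        """Row indices of the subtree rooted at ``idx`` (inclusive)."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[idx] = True
        par = self.parent
        for i in range(idx + 1, self.n_nodes):
            if par[i] >= 0 and mask[par[i]]:
                mask[i] = True
        return np.flatnonzero(mask)

    def subtree_lengths(self) -> np.ndarray:
        """Total cable length of the subtree below each node (edge to parent excluded)."""
        el = self.edge_lengths()
        acc = np.zeros(self.n_nodes)
        par = self.parent
        for i in range(self.n_nodes - 1, 0, -1):
            acc[par[i]] += acc[i] + el[i]
        return acc

    def copy(self) -> "MorphTree":
        return MorphTree(self.xyz.copy(), self.radius.copy(), self.parent.copy(),
                         self.code.copy(), self.cut.copy(), self.provenance)


# ---------------------------------------------------------------------------
# SWC reading / writing
# ---------------------------------------------------------------------------

def read_swc(stream) -> MorphTree:
    """Parse a 7-column SWC text stream into a :class:`MorphTree`.

    Node order is normalised so that parents precede children (depth-first,
    preserving file order among siblings). Raises :class:`SWCFormatError`
    on dangling parent references, multiple roots or non-positive radii.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = []
    cut_file_ids: set[int] = set()
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("cut:"):
                cut_file_ids.update(int(t) for t in body[4:].replace(",", " ").split())
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SWCFormatError(f"expected 7 columns, got: {line!r}")
        rows.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[4]), float(parts[5]), int(parts[6])))
    if not rows:
        raise SWCFormatError("no nodes in SWC stream")

    file_ids = [r[0] for r in rows]
    if len(set(file_ids)) != len(file_ids):
        raise SWCFormatError("duplicate node ids")
    by_id = {r[0]: r for r in rows}
    roots = [r[0] for r in rows if r[6] == -1]
    if len(roots) == 0:
        raise SWCFormatError("no root node (parent -1)")
    if len(roots) > 1:
        raise SWCFormatError(f"multiple roots: ids {roots}")
    for r in rows:
        if r[6] != -1 and r[6] not in by_id:
            raise SWCFormatError(f"node {r[0]} references missing parent {r[6]}")
        if r[5] <= 0:
            raise SWCFormatError(f"node {r[0]} has non-positive radius {r[5]}")

    # keep file order when parents already precede children; otherwise
    # normalise by DFS from the root (file order among siblings)
    seen: set[int] = set()
    ordered = True
    for r in rows:
        if r[6] != -1 and r[6] not in seen:
            ordered = False
            break
        seen.add(r[0])
    if ordered:
        order = [r[0] for r in rows]
    else:
        kids: dict[int, list[int]] = {fid: [] for fid in file_ids}
        for r in rows:
            if r[6] != -1:
                kids[r[6]].append(r[0])
        order = []
        stack = [roots[0]]
        while stack:
            fid = stack.pop()
            order.append(fid)
            stack.extend(reversed(kids[fid]))
    if len(order) != len(rows):
        raise SWCFormatError("tree is not connected to the root")

    new_index = {fid: i for i, fid in enumerate(order)}
    n = len(order)
    xyz = np.empty((n, 3))
    radius = np.empty(n)
    parent = np.empty(n, dtype=int)
    code = np.empty(n, dtype=int)
    cut = np.zeros(n, dtype=bool)
    for fid in order:
        i = new_index[fid]
        r = by_id[fid]
        code[i] = r[1]
        xyz[i] = (r[2], r[3], r[4])
        radius[i] = r[5]
        parent[i] = -1 if r[6] == -1 else new_index[r[6]]
        cut[i] = fid in cut_file_ids
    return MorphTree(xyz, radius, parent, code, cut)


def write_swc(tree: MorphTree, stream=None) -> str | None:
    """Write a tree as 7-column SWC, ids renumbered 1..N.

    Cut flags are emitted as a ``# cut: <ids>`` header comment. If *stream*
    is None the SWC text is returned as a string.
    """
    tree.validate()
    lines = []
    cut_ids = np.flatnonzero(tree.cut) + 1
    if len(cut_ids):
        lines.append("# cut: " + " ".join(str(i) for i in cut_ids))
    for i in range(tree.n_nodes):
        p = -1 if tree.parent[i] == -1 else tree.parent[i] + 1
        x, y, z = tree.xyz[i]
        lines.append(f"{i + 1} {tree.code[i]} {x:.6f} {y:.6f} {z:.6f} "
                     f"{tree.radius[i]:.6f} {p}")
    text = "\n".join(lines) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None


# ---------------------------------------------------------------------------
# Resampling and surgery
# ---------------------------------------------------------------------------

def resample_tree(tree: MorphTree, spacing: float = 1.0) -> MorphTree:
    """Subdivide edges so consecutive-node distances are at most *spacing*.

    Branch points, terminations and every original node are preserved
    exactly (subdivide-only), so the piecewise-linear geometry and the total
    cable length are unchanged. Interpolated nodes inherit the child's
    structure code and linearly interpolated radii.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xyz_out = [tree.xyz[0]]
    rad_out = [tree.radius[0]]
    par_out = [-1]
    code_out = [tree.code[0]]
    cut_out = [bool(tree.cut[0])]
    old2new = np.empty(tree.n_nodes, dtype=int)
    old2new[0] = 0
    for i in range(1, tree.n_nodes):
        p = tree.parent[i]
        a, b = tree.xyz[p], tree.xyz[i]
        d = float(np.linalg.norm(b - a))
        k = max(1, int(np.ceil(d / spacing - 1e-12)))
        prev = old2new[p]
        for j in range(1, k + 1):
            t = j / k
            # original endpoints must survive bit-exactly
            xyz_out.append(b.copy() if j == k else a + t * (b - a))
            rad_out.append(tree.radius[i] if j == k
                           else tree.radius[p] + t * (tree.radius[i] - tree.radius[p]))
            par_out.append(prev)
            code_out.append(tree.code[i])
            cut_out.append(bool(tree.cut[i]) if j == k else False)
            prev = len(xyz_out) - 1
        old2new[i] = prev
    return MorphTree(np.asarray(xyz_out), np.asarray(rad_out), np.asarray(par_out),
                     np.asarray(code_out), np.asarray(cut_out), tree.provenance)


def _subset(tree: MorphTree, rows: np.ndarray, new_root_row: int) -> MorphTree:
    """Extract the rows as a tree re-rooted at ``new_root_row`` (order preserved)."""
    rows = np.sort(np.asarray(rows, dtype=int))
    remap = {old: new for new, old in enumerate(rows)}
    parent = np.empty(len(rows), dtype=int)
    for new, old in enumerate(rows):
        if old == new_root_row:
            parent[new] = -1
        else:
            parent[new] = remap[tree.parent[old]]
    return MorphTree(tree.xyz[rows], tree.radius[rows], parent,
                     tree.code[rows], tree.cut[rows], tree.provenance)


def delete_subtree(tree: MorphTree, node: int) -> tuple[MorphTree, MorphTree]:
    """Remove the subtree rooted at 1-based id *node*.

    Returns ``(remaining, severed)``; the remaining tree keeps the parent of
    *node*, the severed part is re-rooted at *node*. Node counts and cable
    length are conserved across the two parts up to the severed edge, which
    belongs to neither after the cut.
    """
    idx = int(node) - 1
    if idx == 0:
        raise ValueError("cannot delete the root subtree")
    if not 0 < idx < tree.n_nodes:
        raise KeyError(f"unknown node id {node}")
    sub = tree.descendants(idx)
    keep = np.setdiff1d(np.arange(tree.n_nodes), sub)
    return _subset(tree, keep, 0), _subset(tree, sub, idx)


def path_length(tree: MorphTree, node: int) -> float:
    """Cable distance (µm) from 1-based id *node* to the root."""
    idx = int(node) - 1
    if not 0 <= idx < tree.n_nodes:
        raise KeyError(f"unknown node id {node}")
    total = 0.0
    while tree.parent[idx] != -1:
        total += float(np.linalg.norm(tree.xyz[idx] - tree.xyz[tree.parent[idx]]))
        idx = tree.parent[idx]
    return total


def append_nodes(tree: MorphTree, xyz, radius, parent_rows, code, cut=None) -> MorphTree:
    """Append new nodes (parents may be existing rows or earlier new rows)."""
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    m = len(xyz)
    cut = np.zeros(m, dtype=bool) if cut is None else np.asarray(cut, dtype=bool)
    return MorphTree(
        np.vstack([tree.xyz, xyz]),
        np.concatenate([tree.radius, np.asarray(radius, dtype=float).ravel()]),
        np.concatenate([tree.parent, np.asarray(parent_rows, dtype=int).ravel()]),
        np.concatenate([tree.code, np.asarray(code, dtype=int).ravel()]),
        np.concatenate([tree.cut, cut]),
        tree.provenance,
    )
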