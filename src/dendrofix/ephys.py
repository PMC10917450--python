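"""Steady-state passive input resistance of a morphology.

Removing dendritic material removes membrane shunt paths, so a cut neuron
has a higher somatic input resistance and is thereby more excitable for
fixed channel densities; a successful repair should bring the input
resistance back toward the reference. This module operationalises that
size/excitability mechanism with a steady-state passive compartmental
model: each parent–child edge is a frustum with axial resistance
``Ra * l / (pi * r0 * r1)``, each node carries the membrane leak of half of
its adjacent frustum surfaces, and an isolated soma node is a sphere.
Capacitance plays no role at steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import factorized

from .core import MorphTree

UM_TO_CM = 1e-4


@dataclass
class PassiveSpec:
    """Passive membrane parameters.

    rm : membrane resistivity, Ω·cm² (default 28 kΩ·cm², a typical
        pyramidal-cell value).
    ra : axial resistivity, Ω·cm (default 150 Ω·cm).
    """

    rm: float = 28e3
    ra: float = 150.0

    def __post_init__(self):
        if self.rm <= 0 or self.ra <= 0:
            raise ValueError("rm and ra must be positive")


def _conductance_system(tree: MorphTree, spec: PassiveSpec):
    n = tree.n_nodes
    if np.any(tree.radius <= 0):
        raise ValueError("zero or negative radius makes the system singular")
    r = tree.radius * UM_TO_CM
    xyz = tree.xyz * UM_TO_CM
    par = tree.parent

    g_axial = np.zeros(n)          # conductance of edge (i, parent i)
    area = np.zeros(n)             # membrane area per node, cm²
    for i in range(1, n):
        p = par[i]
        l = float(np.linalg.norm(xyz[i] - xyz[p]))
        if l <= 0:
            # coincident nodes: tie them together with a large conductance
            g_axial[i] = 1e6
            continue
        slant = np.hypot(l, r[i] - r[p])
        a_edge = np.pi * (r[i] + r[p]) * slant
        area[i] += 0.5 * a_edge
        area[p] += 0.5 * a_edge
        g_axial[i] = np.pi * r[i] * r[p] / (spec.ra * l)

    soma_rows = np.flatnonzero(tree.code == 1)
    if len(soma_rows) == 1:
        area[soma_rows[0]] += 4.0 * np.pi * r[soma_rows[0]] ** 2

    g_m = area / spec.rm
    if n == 1:
        g_m[0] = area[0] / spec.rm
    rows, cols, vals = [], [], []
    diag = g_m.copy()
    for i in range(1, n):
        p = par[i]
        g = g_axial[i]
        diag[i] += g
        diag[p] += g
        rows += [i, p]
        cols += [p, i]
        vals += [-g, -g]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return csc_matrix((vals, (rows, cols)), shape=(n, n))


def input_resistance(tree: MorphTree, spec: PassiveSpec | None = None,
                     site: int = 1) -> float:
    """Steady-state input resistance V(site)/I at 1-based node *site*, in MΩ."""
    spec = spec or PassiveSpec()
    idx = int(site) - 1
    if not 0 <= idx < tree.n_nodes:
        raise KeyError(f"unknown node id {site}")
    g = _conductance_system(tree, spec)
    current = np.zeros(tree.n_nodes)
    current[idx] = 1.0
    v = factorized(g)(current)
    return float(v[idx]) / 1e6


def transfer_resistance(tree: MorphTree, spec: PassiveSpec | None = None,
                        site_i: int = 1, site_j: int = 1) -> float:
    """Transfer resistance V(j)/I(i), MΩ; symmetric in its two sites."""
    spec = spec or PassiveSpec()
    g = _conductance_system(tree, spec)
    current = np.zeros(tree.n_nodes)
    current[int(site_i) - 1] = 1.0
    v = factorized(g)(current)
    return float(v[int(site_j) - 1]) / 1e6


def restoration_check(reference: MorphTree, cut: MorphTree, repaired: MorphTree,
                      spec: PassiveSpec | None = None) -> dict:
    """Check that cutting raises R_in and repairing restores it.

    Returns the three input resistances (MΩ) plus two booleans: the cut
    tree's R_in exceeds the reference's, and the repaired tree's R_in is
    closer to the reference than the cut tree's. A degenerate comparison
    (cut identical to reference) is flagged.
    """
    spec = spec or PassiveSpec()
    r_ref = input_resistance(reference, spec)
    r_cut = input_resistance(cut, spec)
    r_rep = input_resistance(repaired, spec)
    degenerate = np.isclose(r_cut, r_ref, rtol=1e-12)
    return {
        "r_in_reference_mohm": r_ref,
        "r_in_cut_mohm": r_cut,
        "r_in_repaired_mohm": r_rep,
        "cut_exceeds_reference": bool(r_cut > r_ref),
        "repair_improves": bool(abs(r_rep - r_ref) < abs(r_cut - r_ref)),
        "degenerate": bool(degenerate),
    }
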