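"""Synthetic-morphology generators.

These generators build stand-in arbours with the same growth rule the
repair uses, so every experiment in the package runs without downloads:
a flat, dense, space-filling arbour resembling a Drosophila class IV
dendritic-arborisation neuron, and a pyramidal-like cell with a basal
sphere plus an apical cone with a straight main trunk. They are stand-ins
tuned to the qualitative regimes (flat dense versus sparse radial), not
statistical clones of any specimen. All generators are deterministic per
seed.
"""

from __future__ import annotations

import numpy as np

from .core import MorphTree, append_nodes, resample_tree
from .growth import grow_mst
from .repair import TaperParams, apply_taper

_DEFAULT_TAPER = TaperParams(scale=1.2, offset=0.5, d_min=0.3)


def _sample_shape(shape: str, n: int, rng: np.random.Generator,
                  radius: float) -> np.ndarray:
    if shape == "disc2D":
        r = radius * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        return np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
    if shape == "sphere":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v * radius * rng.random(n)[:, None] ** (1 / 3)
    if shape == "cone":
        # apex at origin, axis +y, height 2*radius, base radius = radius
        h = 2 * radius * rng.random(n) ** (1 / 3)
        rmax = (h / (2 * radius)) * radius
        rr = rmax * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        return np.column_stack([rr * np.cos(th), h, rr * np.sin(th)])
    if shape == "slab":
        return np.column_stack([
            radius * (2 * rng.random(n) - 1),
            radius * (2 * rng.random(n) - 1),
            0.1 * radius * (2 * rng.random(n) - 1),
        ])
    raise ValueError(f"unknown shape {shape!r}")


def make_synthetic_tree(volume_shape: str = "sphere", n: int = 150,
                        bf: float = 0.3, seed: int = 0,
                        radius: float = 100.0,
                        label_code: int = 3,
                        taper: TaperParams | None = None) -> MorphTree:
    """Grow a synthetic arbour: uniform targets in a shape, greedy growth
    from a central soma, 1 µm resampling and a default quadratic taper."""
    rng = np.random.default_rng(seed)
    pts = _sample_shape(volume_shape, n, rng, radius)
    root = MorphTree(np.zeros((1, 3)), [2.0], [-1], [1], [False])
    res = grow_mst(root, pts, bf=bf, label_code=label_code)
    tree = resample_tree(res.tree, 1.0)
    new_ids = np.arange(2, tree.n_nodes + 1)
    return apply_taper(tree, new_ids, taper or _DEFAULT_TAPER)


def make_classIV_like(seed: int = 0, n: int = 800, radius: float = 200.0,
                      bf: float = 0.2) -> MorphTree:
    """Flat, dense, space-filling arbour for the lesion experiments.

    Grown in a 200 µm disc with low bf and ~800 targets — the regime of a
    class IV dendritic-arborisation cell, which arborises in a thin 2D
    layer beneath the larval epidermis.
    """
    return make_synthetic_tree("disc2D", n=n, bf=bf, seed=seed, radius=radius)


def make_pyramidal_like(seed: int = 0) -> MorphTree:
    """Basal sphere plus apical cone with one straight main trunk.

    The basal arbour (label basal) grows with bf 0.7 in an 80 µm sphere;
    the apical trunk is a straight 300 µm cable along +y from the soma,
    and oblique/tuft dendrites (label apical) grow into a cone around it
    with bf 0.8.
    """
    rng = np.random.default_rng(seed)
    soma = MorphTree(np.zeros((1, 3)), [5.0], [-1], [1], [False])

    trunk_len = 300
    steps = np.arange(1, trunk_len + 1, dtype=float)
    trunk_xyz = np.column_stack([np.zeros(trunk_len), steps, np.zeros(trunk_len)])
    parents = np.arange(0, trunk_len)
    tree = append_nodes(soma, trunk_xyz, np.full(trunk_len, 2.5),
                        parents, np.full(trunk_len, 4, dtype=int))
    trunk_ids = np.arange(2, tree.n_nodes + 1)

    basal_pts = _sample_shape("sphere", 120, rng, 80.0)
    basal_pts[:, 1] = -np.abs(basal_pts[:, 1]) * 0.8  # keep basal below the soma
    res = grow_mst(tree, basal_pts, bf=0.7, attach_mask=[1], label_code=3)
    tree = res.tree

    apical_pts = _sample_shape("cone", 180, rng, 150.0)
    apical_pts[:, 1] += 20.0
    res = grow_mst(tree, apical_pts, bf=0.8,
                   attach_mask=trunk_ids, label_code=4)
    tree = resample_tree(res.tree, 1.0)
    new_ids = np.arange(2, tree.n_nodes + 1)
    return apply_taper(tree, new_ids, TaperParams(scale=2.0, offset=0.6, d_min=0.4))


def make_demo_2d() -> tuple[MorphTree, list[int]]:
    """Small hand-coded 2D arbour with designated cut terminals.

    Used for documentation and smoke tests; the returned ids are terminals
    flagged as known-incomplete ends.
    """
    #           1 (soma)
    #     2 ———— + ———— 6
    #    /|             |\
    #   3 4             7 8
    #     |               |
    #     5               9
    xyz = np.array([
        [0, 0, 0],     # 1 soma
        [-20, 10, 0],  # 2
        [-35, 25, 0],  # 3 terminal
        [-25, 30, 0],  # 4
        [-28, 50, 0],  # 5 terminal (cut)
        [20, 10, 0],   # 6
        [30, 28, 0],   # 7 terminal (cut)
        [38, 20, 0],   # 8
        [55, 32, 0],   # 9 terminal
    ], dtype=float)
    parent = np.array([-1, 0, 1, 1, 3, 0, 5, 5, 7])
    radius = np.array([4.0, 1.2, 0.6, 1.0, 0.7, 1.2, 0.8, 0.9, 0.6])
    code = np.array([1, 3, 3, 3, 3, 3, 3, 3, 3])
    cut = np.zeros(9, dtype=bool)
    cut[[4, 6]] = True
    tree = MorphTree(xyz, radius, parent, code, cut)
    return tree, [5, 7]
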