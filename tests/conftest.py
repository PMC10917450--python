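import numpy as np
import pytest

from dendrofix import MorphTree


def straight_cable(n: int, step: float = 1.0, radius: float = 1.0,
                   axis=(0.0, 0.0, 1.0), code: int = 3) -> MorphTree:
    """Unbranched cable of n nodes starting at the origin along *axis*."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    xyz = np.outer(np.arange(n, dtype=float) * step, axis)
    parent = np.r_[-1, np.arange(n - 1)]
    return MorphTree(xyz, np.full(n, radius), parent, np.full(n, code),
                     np.zeros(n, dtype=bool))


def y_tree(arm: float = 10.0) -> MorphTree:
    """Symmetric Y: one 10 µm stem and two 10 µm arms (3 segments)."""
    xyz = np.array([
        [0, 0, 0],
        [0, 0, arm],
        [arm * 0.6, 0, arm + arm * 0.8],
        [-arm * 0.6, 0, arm + arm * 0.8],
    ], dtype=float)
    parent = np.array([-1, 0, 1, 1])
    return MorphTree(xyz, np.full(4, 1.0), parent, np.array([1, 3, 3, 3]),
                     np.zeros(4, dtype=bool))


def random_tree(seed: int, n: int = 40, bf: float = 0.3) -> MorphTree:
    from dendrofix import grow_mst
    rng = np.random.default_rng(seed)
    root = MorphTree(np.zeros((1, 3)), [1.5], [-1], [1], [False])
    pts = rng.random((n, 3)) * 80
    return grow_mst(root, pts, bf=bf).tree


@pytest.fixture
def cable10():
    return straight_cable(2, step=10.0)


@pytest.fixture
def ytree():
    return y_tree()
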