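"""Parameter estimation, target distribution and the repair pipeline."""

import warnings

import numpy as np
import pytest

from dendrofix import (GrowthParams, GrowthVolume, MorphTree, apply_taper,
                       distribute_targets, estimate_bf, estimate_target_count,
                       find_cut_terminals, fit_taper, fix_tree,
                       grow_main_branch, growth_threshold, jitter_new_nodes,
                       make_synthetic_tree, prune_to_length, random_cut,
                       resample_tree, write_swc)
from dendrofix.core import append_nodes
from dendrofix.repair import TaperParams

from conftest import straight_cable


def sphere_cloud(r=50.0, n=300, centre=(0, 0, 0), seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(centre, dtype=float) + r * v


class TestEstimateBf:
    def test_radial_star_maps_to_high_bf(self):
        # 8 straight radial arms from the root: root angles all ~0
        xyz = [np.zeros(3)]
        parent = [-1]
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1], [1, 1, 0], [-1, 1, 0]], float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for d in dirs:
            for k in range(1, 31):
                xyz.append(k * d)
                parent.append(0 if k == 1 else len(xyz) - 2)
        n = len(xyz)
        star = MorphTree(np.asarray(xyz), np.ones(n), parent,
                         np.full(n, 3), np.zeros(n, bool))
        assert estimate_bf(star) >= 0.9

    def test_tiny_tree_falls_back(self):
        with pytest.warns(UserWarning, match="fewer than 20"):
            assert estimate_bf(straight_cable(3, step=1.0)) == 0.5

    @pytest.mark.parametrize("true_bf", [0.2, 0.8])
    def test_parameter_recovery(self, true_bf):
        ests = [estimate_bf(make_synthetic_tree("sphere", n=150, bf=true_bf,
                                                seed=s)) for s in range(8)]
        assert abs(np.mean(ests) - true_bf) <= 0.2


class TestGrowthThreshold:
    def test_sphere_centred_on_root_gives_diameter(self):
        r = 40.0
        vol = GrowthVolume(sphere_cloud(r=r, n=400), alpha=0.0)
        g = growth_threshold(vol, np.zeros(3))
        assert g == pytest.approx(2 * r, rel=0.05)

    def test_box_chord_closed_form(self):
        # box [0,1]x[0,1]x[0,4], root at the centre of the bottom face
        import itertools
        corners = np.array([(x, y, z) for x, y, z in
                            itertools.product([0, 1], [0, 1], [0, 4])], float)
        vol = GrowthVolume(corners, alpha=0.0)
        root = np.array([0.5, 0.5, 0.0])
        # V_mean=(0.5,0.5,2); V_far is a top corner; Q=midpoint; the line
        # exits through the top face: chord = |dir| * t_exit
        v_far = vol.far_point(root)
        q = 0.5 * (np.array([0.5, 0.5, 2.0]) + v_far)
        direction = q - root
        t_exit = 4.0 / direction[2]
        expected = np.linalg.norm(direction) * t_exit
        assert growth_threshold(vol, root) == pytest.approx(expected, rel=1e-6)

    def test_missed_volume_advises_manual_threshold(self):
        class _MissedVolume(GrowthVolume):
            def chord_length(self, root):
                return 0.0  # line through root and Q misses the region

        vol = _MissedVolume(sphere_cloud(r=5.0), alpha=0.0)
        with pytest.raises(ValueError, match="g_thr"):
            growth_threshold(vol, np.array([500.0, 0.0, 0.0]))


class TestTargetCount:
    def test_floor_of_one(self):
        t = make_synthetic_tree("sphere", n=30, seed=0)
        tiny = GrowthVolume(sphere_cloud(r=0.5, n=50, centre=(200, 0, 0)))
        assert estimate_target_count(t, tiny) == 1

    def test_linear_in_volume(self):
        t = make_synthetic_tree("sphere", n=100, seed=1)
        v1 = GrowthVolume(sphere_cloud(r=20, n=300, centre=(150, 0, 0)))
        v2 = GrowthVolume(sphere_cloud(r=20 * 2 ** (1 / 3), n=300,
                                       centre=(150, 0, 0)))
        n1 = estimate_target_count(t, v1)
        n2 = estimate_target_count(t, v2)
        assert abs(n2 - 2 * n1) <= max(2, 0.15 * n1)

    def test_matches_topological_density_arithmetic(self):
        t = make_synthetic_tree("sphere", n=120, seed=2)
        from scipy.spatial import ConvexHull
        hull = ConvexHull(t.xyz)
        vol = GrowthVolume(t.xyz[np.random.default_rng(0).choice(t.n_nodes, 400)])
        n_topo = int(t.branch_point_mask().sum() + t.terminal_mask().sum())
        expected = round(2 * n_topo / hull.volume * vol.measure)
        assert estimate_target_count(t, vol) == max(1, expected)


class TestDistributeTargets:
    def test_count_containment_and_margin(self):
        vol = GrowthVolume(sphere_cloud(r=30, n=200), alpha=0.0)
        excl = np.zeros((1, 3))
        pts = distribute_targets(vol, 100, exclusion=excl, r_d=10.0, seed=4)
        assert pts.shape == (100, 3)
        assert vol.contains(pts).all()
        assert np.all(np.linalg.norm(pts, axis=1) >= 10.0)

    def test_impossible_margin_errors(self):
        vol = GrowthVolume(sphere_cloud(r=5, n=100), alpha=0.0)
        with pytest.raises(RuntimeError):
            distribute_targets(vol, 5, exclusion=np.zeros((1, 3)), r_d=1e3,
                               seed=0)

    def test_two_cluster_density_is_respected(self):
        rng = np.random.default_rng(9)
        box = np.array([[x, y, z] for x in (0, 100.) for y in (0, 100.)
                        for z in (0, 100.)])
        vol = GrowthVolume(box, alpha=0.0)
        c1, c2 = np.array([25., 25, 25]), np.array([75., 75, 75])
        bw = 8.0

        def density(q):
            q = np.atleast_2d(q)
            return (np.exp(-((q - c1) ** 2).sum(1) / (2 * bw ** 2))
                    + np.exp(-((q - c2) ** 2).sum(1) / (2 * bw ** 2)))

        pts = vol.sample(500, rng, density=density)
        d = np.minimum(np.linalg.norm(pts - c1, axis=1),
                       np.linalg.norm(pts - c2, axis=1))
        assert (d <= 2 * bw).mean() >= 0.70


class TestCutTerminals:
    def test_flag_proximity_rule(self):
        t = straight_cable(200, step=1.0)  # 199 µm cable along z
        t = t.copy()
        t.cut[-1] = True    # tip at z=199, touching the volume
        t.cut[0] = False
        vol = GrowthVolume(sphere_cloud(r=10, n=100, centre=(0, 0, 210)))
        ids = find_cut_terminals(t, vol)
        assert list(ids) == [200]
        # a far-side flag is excluded
        t2 = t.copy()
        t2.cut[:] = False
        t2.cut[1] = True    # near the root, ~200 µm from the volume
        assert len(find_cut_terminals(t2, vol)) == 0

    def test_unflagged_heuristic_is_a_near_terminal_subset(self):
        t = make_synthetic_tree("sphere", n=80, seed=3)
        vol = GrowthVolume(sphere_cloud(r=20, n=100, centre=(60, 0, 0)))
        with pytest.warns(UserWarning, match="no cut flags"):
            ids = find_cut_terminals(t, vol)
        term_ids = set(np.flatnonzero(t.terminal_mask()) + 1)
        assert set(int(i) for i in ids) <= term_ids


class TestMainBranch:
    def _setup(self):
        t = straight_cable(40, step=1.0).copy()
        t.cut[-1] = True
        # slab volume ahead of the tip along +z
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-30, 30, 600),
                               rng.uniform(-30, 30, 600),
                               rng.uniform(40, 160, 600)])
        return t, GrowthVolume(pts, alpha=0.0)

    def test_length_is_95_percent_of_chord(self):
        t, vol = self._setup()
        g = vol.chord_length(t.xyz[0])
        out, new_ids = grow_main_branch(t, vol, [40])
        grown = out.edge_lengths()[new_ids - 1].sum()
        assert grown == pytest.approx(0.95 * g, abs=2.0)
        assert np.all(out.code[new_ids - 1] == 4)

    def test_thickest_terminal_chosen(self):
        t, vol = self._setup()
        t = t.copy()
        t.cut[20] = True
        t.radius[20] = 3.0      # thicker than the tip (1.0)
        out, new_ids = grow_main_branch(t, vol, [21, 40])
        assert out.parent[new_ids[0] - 1] == 20

    def test_empty_cut_ids(self):
        t, vol = self._setup()
        with pytest.raises(ValueError):
            grow_main_branch(t, vol, [])


class TestJitter:
    N_NEW = 120

    def _grown(self):
        t = straight_cable(5, step=1.0)
        m = self.N_NEW
        xyz = np.column_stack([np.zeros(m), np.zeros(m),
                               np.arange(5, 5 + m, dtype=float)])
        return append_nodes(t, xyz, np.ones(m),
                            np.r_[4, np.arange(5, 4 + m)], np.full(m, 3))

    def test_zero_amplitude_is_identity(self):
        t = self._grown()
        out = jitter_new_nodes(t, range(6, 6 + self.N_NEW), 0.0)
        assert np.array_equal(out.xyz, t.xyz)

    def test_junction_pinned_and_statistics(self):
        t = self._grown()
        new_ids = list(range(6, 6 + self.N_NEW))
        out = jitter_new_nodes(t, new_ids, amplitude=0.5, window=5, seed=1)
        disp = np.linalg.norm(out.xyz - t.xyz, axis=1)
        assert disp[5] == 0.0                      # first new node pinned
        assert disp[:5].max() == 0.0               # input untouched
        rms = np.sqrt((disp[6:] ** 2).mean())
        assert 0 < rms <= 0.5 * 1.5                # low-passed noise, sd-bounded
        assert np.array_equal(out.parent, t.parent)

    def test_smoothing_produces_autocorrelation(self):
        t = self._grown()
        out = jitter_new_nodes(t, range(6, 6 + self.N_NEW), amplitude=0.5,
                               window=7, seed=2)
        d = (out.xyz - t.xyz)[6:, 0]
        # neighbouring displacements of a low-passed signal correlate
        r = np.corrcoef(d[:-1], d[1:])[0, 1]
        assert r > 0.5


class TestTaper:
    def _quadratic_tree(self, scale=2.0, offset=0.6):
        t = straight_cable(101, step=1.0)
        pl = t.path_lengths()
        pmax = pl.max()
        t = t.copy()
        t.radius = (scale * (1 - pl / pmax) ** 2 + offset) / 2
        return t

    def test_exact_quadratic_recovered(self):
        t = self._quadratic_tree()
        taper = fit_taper(t)
        assert taper.scale == pytest.approx(2.0, abs=1e-6)
        assert taper.offset == pytest.approx(0.6, abs=1e-6)

    def test_constant_diameter(self):
        t = straight_cable(50, step=1.0, radius=0.7)
        taper = fit_taper(t)
        assert taper.scale == pytest.approx(0.0, abs=1e-9)
        assert taper.offset == pytest.approx(1.4, abs=1e-9)
        assert taper.d_min <= 1.4 + 1e-9

    def test_apply_floors_and_monotone(self):
        t = self._quadratic_tree()
        grown = append_nodes(t, t.xyz[-1] + np.outer(np.arange(1, 41), [0, 1e-3, 1.0]),
                             np.ones(40), np.r_[100, np.arange(101, 140)],
                             np.full(40, 3))
        taper = TaperParams(scale=2.0, offset=0.1, d_min=0.4)
        out = apply_taper(grown, range(102, 142), taper)
        d = 2 * out.radius[101:]
        assert np.all(d >= 0.4 - 1e-12)
        assert np.all(np.diff(d) <= 1e-12)


class TestPrune:
    def test_noop_when_under_target(self):
        t = straight_cable(20, step=1.0)
        out, ids = prune_to_length(t, [], 1e6)
        assert out.n_nodes == t.n_nodes

    def test_exact_excess_terminal_removed(self):
        t = straight_cable(20, step=1.0)
        # two new branches from the tip: 10 µm and 30 µm
        b1 = t.xyz[-1] + np.outer(np.arange(1, 11), [1.0, 0, 0])
        b2 = t.xyz[-1] + np.outer(np.arange(1, 31), [-1.0, 0, 0])
        g = append_nodes(t, np.vstack([b1, b2]), np.ones(40),
                         np.r_[19, np.arange(20, 29), 19, np.arange(30, 59)],
                         np.full(40, 3))
        new_ids = list(range(21, 61))
        target = g.total_length() - 10.0
        out, kept = prune_to_length(g, new_ids, target)
        assert out.total_length() == pytest.approx(target)
        assert len(kept) == 30  # the 10 µm branch went, the 30 µm one stayed

    def test_input_never_removed(self):
        t = straight_cable(20, step=1.0)
        with pytest.warns(UserWarning, match="prune target"):
            out, _ = prune_to_length(t, [], 1.0)
        assert out.n_nodes == t.n_nodes


class TestFixTree:
    def test_conserved_ancestry_and_immutability(self):
        ref = make_synthetic_tree("disc2D", n=300, bf=0.2, seed=1, radius=120)
        cut_tree, lesion = random_cut(ref, seed=2)
        res = fix_tree(cut_tree, lesion.severed_hull,
                       GrowthParams(bf=0.2, mode="conserved", seed=3),
                       reference=ref)
        tree = res.tree
        base = resample_tree(cut_tree, 1.0)
        n = base.n_nodes
        assert np.array_equal(tree.xyz[:n], base.xyz)
        assert np.array_equal(tree.radius[:n], base.radius)
        flagged = set(np.flatnonzero(tree.cut))
        for row in res.new_node_ids - 1:
            r = row
            seen = False
            while r != -1:
                if r in flagged:
                    seen = True
                    break
                r = tree.parent[r]
            assert seen, "new node does not trace through a cut terminal"

    def test_branch_point_matching(self):
        seed_tree = make_synthetic_tree("sphere", n=20, bf=0.3, seed=3,
                                        radius=60)
        vol = GrowthVolume(np.random.default_rng(0).normal(size=(150, 3)) * 45)
        res = fix_tree(seed_tree, vol, GrowthParams(bf=0.3, target_nbr=40,
                                                    seed=5))
        assert abs(res.stats_after.n_branch_points - 40) <= 2
        assert res.stats_after.n_branch_points >= res.stats_before.n_branch_points

    def test_deterministic_swc_output(self):
        ref = make_synthetic_tree("disc2D", n=200, bf=0.2, seed=4, radius=100)
        cut_tree, lesion = random_cut(ref, seed=5)
        p = GrowthParams(bf=0.2, seed=6)
        a = fix_tree(cut_tree, lesion.severed_hull, p)
        b = fix_tree(cut_tree, lesion.severed_hull, p)
        assert write_swc(a.tree) == write_swc(b.tree)

    def test_unreachable_volume_returns_input(self):
        t = make_synthetic_tree("sphere", n=40, bf=0.3, seed=7, radius=50)
        vol = GrowthVolume(sphere_cloud(r=5, n=80, centre=(500, 0, 0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fix_tree(t, vol, GrowthParams(bf=0.3, g_thr=3.0, seed=0))
        assert len(res.new_node_ids) == 0
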