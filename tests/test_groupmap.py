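import numpy as np
import pytest

from cortexproxy.core_io import InputError, VolumeGrid
from cortexproxy.groupmap import (
    Cluster,
    farthest_pair,
    find_clusters,
    group_ttest,
    subdivide,
    subdivision_features,
)

VS = (4.0, 4.0, 4.0)


def grid_of(data):
    return VolumeGrid(np.asarray(data), VS)


def random_connected_cluster(rng, n, span=40):
    """Grow a connected voxel set by a random 6-neighbor walk."""
    seen = {(span // 2, span // 2, span // 2)}
    frontier = list(seen)
    steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    while len(seen) < n:
        base = frontier[rng.integers(len(frontier))]
        nxt = tuple(np.clip(np.array(base) + steps[rng.integers(6)], 0, span - 1))
        if nxt not in seen:
            seen.add(nxt)
            frontier.append(nxt)
    return Cluster(np.array(sorted(seen)), VS)


class TestGroupTtest:
    def test_identical_nonzero_maps_flagged_zero_variance(self):
        maps = [grid_of(np.full((3, 3, 3), 2.0)) for _ in range(5)]
        gmap = group_ttest(maps)
        assert not gmap.defined_mask.any()
        assert not gmap.sig_mask.data.any()

    def test_sign_symmetric_maps_give_t_zero(self):
        w = np.random.default_rng(0).normal(size=(3, 3, 3))
        maps = [grid_of(w), grid_of(-w), grid_of(2 * w), grid_of(-2 * w)]
        gmap = group_ttest(maps)
        np.testing.assert_allclose(gmap.t[gmap.defined_mask], 0, atol=1e-12)
        np.testing.assert_allclose(gmap.p[gmap.defined_mask], 1, atol=1e-12)

    def test_t_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(1.0, 1.0, size=10)
        maps = [grid_of(np.full((2, 2, 2), d)) for d in draws]
        gmap = group_ttest(maps)
        expected = draws.mean() / (draws.std(ddof=1) / np.sqrt(10))
        np.testing.assert_allclose(gmap.t[gmap.defined_mask], expected, rtol=1e-12)

    def test_requires_two_maps(self):
        with pytest.raises(InputError):
            group_ttest([grid_of(np.zeros((2, 2, 2)))])

    def test_fdr_mask_subset_of_defined(self):
        rng = np.random.default_rng(2)
        maps = [grid_of(rng.normal(size=(4, 4, 4)) + 1.0) for _ in range(8)]
        gmap = group_ttest(maps)
        assert not np.any(gmap.sig_mask.data & ~gmap.defined_mask)


class TestFindClusters:
    def test_corner_touching_blocks_merge_under_26_connectivity(self):
        m = np.zeros((8, 8, 8), bool)
        m[0:3, 0:3, 0:3] = True
        m[3:6, 3:6, 3:6] = True  # touches only at the corner (3,3,3)-(2,2,2)
        clusters = find_clusters(grid_of(m))
        assert len(clusters) == 1
        assert clusters[0].size == 54

    def test_corner_touching_blocks_split_under_6_connectivity(self):
        m = np.zeros((8, 8, 8), bool)
        m[0:3, 0:3, 0:3] = True
        m[3:6, 3:6, 3:6] = True
        clusters = find_clusters(grid_of(m), connectivity=6)
        assert len(clusters) == 2

    def test_small_blobs_discarded(self):
        m = np.zeros((6, 6, 6), bool)
        m[0, 0, 0:4] = True  # 4 voxels < min_size 5
        assert find_clusters(grid_of(m), min_size=5) == []

    def test_matches_flood_fill_oracle_on_random_mask(self):
        rng = np.random.default_rng(3)
        m = rng.random((20, 20, 20)) < 0.1
        clusters = find_clusters(grid_of(m), min_size=1)

        # independent BFS flood fill with 26-neighborhood
        remaining = {tuple(v) for v in np.argwhere(m)}
        sizes = []
        while remaining:
            stack = [next(iter(remaining))]
            remaining.discard(stack[0])
            count = 1
            while stack:
                x, y, z = stack.pop()
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            nb = (x + dx, y + dy, z + dz)
                            if nb in remaining:
                                remaining.discard(nb)
                                stack.append(nb)
                                count += 1
            sizes.append(count)
        assert sorted(c.size for c in clusters) == sorted(sizes)

    def test_deterministic_ordering_by_size_then_coordinate(self):
        m = np.zeros((10, 10, 10), bool)
        m[7:9, 7:9, 7:9] = True   # 8 voxels, later coordinate
        m[0:2, 0:2, 0:2] = True   # 8 voxels, earlier coordinate
        m[4, 4, 0:6] = True       # 6 voxels
        clusters = find_clusters(grid_of(m), min_size=1)
        assert [c.size for c in clusters] == [8, 8, 6]
        assert tuple(clusters[0].voxels.min(axis=0)) == (0, 0, 0)


class TestFarthestPair:
    def test_rod_endpoints(self):
        voxels = np.array([[0, 0, z] for z in range(80)])
        p1, p2, v, mid = farthest_pair(Cluster(voxels, VS))
        assert np.linalg.norm(p2 - p1) == pytest.approx(79 * 4.0)
        np.testing.assert_allclose(mid, [0, 0, 79 * 4.0 / 2])

    def test_square_tie_broken_lexicographically(self):
        voxels = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]])
        p1, p2, v, mid = farthest_pair(Cluster(voxels, VS))
        # both diagonals tie; the pair starting at (0,0,0) wins
        np.testing.assert_allclose(p1, [0, 0, 0])
        np.testing.assert_allclose(p2, [4.0, 4.0, 0])

    def test_matches_quadratic_scan_oracle(self):
        rng = np.random.default_rng(4)
        voxels = np.unique(rng.integers(0, 15, size=(50, 3)), axis=0)
        cl = Cluster(voxels, (2.0, 3.0, 4.0))
        p1, p2, _, _ = farthest_pair(cl)
        best = -1.0
        for a in voxels:
            for b in voxels:
                d = np.linalg.norm((a - b) * np.array([2.0, 3.0, 4.0]))
                best = max(best, d)
        assert np.linalg.norm(p2 - p1) == pytest.approx(best)

    def test_singleton_rejected(self):
        with pytest.raises(InputError):
            farthest_pair(Cluster(np.array([[0, 0, 0]]), VS))


class TestSubdivide:
    def test_small_cluster_returned_unchanged(self):
        rng = np.random.default_rng(5)
        cl = random_connected_cluster(rng, 30)
        subs = subdivide([cl], max_voxels=40)
        assert len(subs.subdivisions) == 1
        assert {tuple(v) for v in subs.subdivisions[0].voxels} == {
            tuple(v) for v in cl.voxels
        }

    def test_rod_bisects_into_equal_halves(self):
        rod = Cluster(np.array([[0, 0, z] for z in range(80)]), VS)
        subs = subdivide([rod], max_voxels=40)
        sizes = sorted(s.voxels.shape[0] for s in subs.subdivisions)
        assert sizes == [40, 40]

    def test_partition_bound_and_determinism(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(41, 600))
            cl = random_connected_cluster(rng, n)
            subs1 = subdivide([cl], max_voxels=40)
            subs2 = subdivide([cl], max_voxels=40)
            all_vox = np.concatenate([s.voxels for s in subs1.subdivisions])
            # partition: disjoint union equals the cluster
            assert all_vox.shape[0] == n
            assert len({tuple(v) for v in all_vox}) == n
            assert {tuple(v) for v in all_vox} == {tuple(v) for v in cl.voxels}
            # size bound
            assert max(s.voxels.shape[0] for s in subs1.subdivisions) <= 40
            # determinism
            for s1, s2 in zip(subs1.subdivisions, subs2.subdivisions):
                np.testing.assert_array_equal(s1.voxels, s2.voxels)
                assert s1.history == s2.history

    def test_matches_independent_recursive_oracle(self):
        """Same plane construction and tie-breaks, implemented separately."""
        def oracle(voxels, vs):
            voxels = np.asarray(voxels)
            if voxels.shape[0] <= 40:
                return [voxels]
            order = np.lexsort(voxels.T[::-1])
            pts = voxels[order] * np.asarray(vs)
            d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
            ii, jj = np.nonzero(d2 == d2.max())
            keep = ii < jj
            i, j = int(ii[keep][0]), int(jj[keep][0])
            v = pts[j] - pts[i]
            b = float((pts[i] + pts[j]) / 2 @ v)
            proj = voxels * np.asarray(vs) @ v
            side1 = proj <= b
            if side1.all() or not side1.any():
                srt = np.argsort(proj, kind="stable")
                side1 = np.zeros(len(voxels), bool)
                side1[srt[: len(voxels) // 2]] = True
            return oracle(voxels[side1], vs) + oracle(voxels[~side1], vs)

        rng = np.random.default_rng(7)
        cl = random_connected_cluster(rng, 300)
        subs = subdivide([cl], max_voxels=40)
        expected = oracle(cl.voxels, VS)
        assert len(subs.subdivisions) == len(expected)
        for sub, exp in zip(subs.subdivisions, expected):
            np.testing.assert_array_equal(sub.voxels, exp)

    def test_degenerate_collinear_cluster_terminates(self):
        # 100 voxels on a line: plane through the midpoint works, but a
        # duplicate-projection pathological case must also terminate
        line = Cluster(np.array([[x, 0, 0] for x in range(100)]), VS)
        subs = subdivide([line], max_voxels=7)
        assert max(s.voxels.shape[0] for s in subs.subdivisions) <= 7
        assert sum(s.voxels.shape[0] for s in subs.subdivisions) == 100

    def test_volume_table_and_labels(self):
        rod = Cluster(np.array([[0, 0, z] for z in range(80)]), VS)
        subs = subdivide([rod], max_voxels=40)
        table = subs.to_table()
        assert list(table["n_voxels"]) == [40, 40]
        np.testing.assert_allclose(table["volume_mm3"], 40 * 64.0)
        labels = subs.to_label_volume((1, 1, 80))
        assert set(np.unique(labels.data)) == {1, 2}


class TestSubdivisionFeatures:
    def test_singleton_subdivisions_equal_voxel_features(self):
        from cortexproxy.core_io import BoldRun
        from cortexproxy.decoder import extract_features
        from cortexproxy.groupmap import Subdivision, SubdivisionSet

        rng = np.random.default_rng(8)
        data = rng.normal(size=(4, 4, 4, 12))
        run = BoldRun(data, VS, 2.0)
        coords = [(0, 1, 2), (2, 2, 2), (3, 0, 1)]
        subs = SubdivisionSet(
            [Subdivision(np.array([c]), 1, str(i)) for i, c in enumerate(coords)], VS
        )
        X = subdivision_features(run, subs)
        mask = np.zeros((4, 4, 4), bool)
        for c in coords:
            mask[c] = True
        Xvox = extract_features(run, VolumeGrid(mask, VS))
        np.testing.assert_allclose(np.sort(X.data, axis=1), np.sort(Xvox.data, axis=1))

    def test_size_weighted_halves_reconstruct_cluster_mean(self):
        from cortexproxy.core_io import BoldRun
        from cortexproxy.groupmap import Subdivision, SubdivisionSet

        rng = np.random.default_rng(9)
        data = rng.normal(size=(6, 6, 6, 10))
        run = BoldRun(data, VS, 2.0)
        rod = Cluster(np.array([[0, 0, z] for z in range(6)]), VS)
        subs = subdivide([rod], max_voxels=3)
        X = subdivision_features(run, subs)
        sizes = np.array([s.voxels.shape[0] for s in subs.subdivisions])
        combined = (X.data * sizes).sum(axis=1) / sizes.sum()
        np.testing.assert_allclose(combined, data[0, 0, :6].mean(axis=0), atol=1e-12)
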