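"""Nest calling: distances, clustering, cell-count estimation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestkin.nests import (
    NestConfig,
    apply_depth_guard,
    call_nests,
    estimate_cell_count,
    pairwise_distances,
    scale_total_nests,
    summarize_nests,
)
from nestkin.volumes import DetectedObject

SPHERE_20UM = 4 / 3 * np.pi * 10.0**3  # ~4189 um^3


def sphere_object(oid, x, y=0.0, z=0.0, volume=SPHERE_20UM, intensity=100.0):
    return DetectedObject(id=oid, centroid_um=(x, y, z), volume_um3=volume,
                          mean_intensity=intensity, voxel_count=1)


def brute_force_components(dist, cutoff):
    """Union-find over the <=cutoff adjacency graph (independent oracle)."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                parent[find(i)] = find(j)
    labels = [find(i) for i in range(n)]
    remap = {}
    return np.array([remap.setdefault(l, len(remap)) for l in labels])


def partitions_equal(a, b):
    pa = {}
    pb = {}
    for i, (x, y) in enumerate(zip(a, b)):
        pa.setdefault(x, set()).add(i)
        pb.setdefault(y, set()).add(i)
    return set(frozenset(s) for s in pa.values()) == set(frozenset(s) for s in pb.values())


class TestDistances:
    def test_border_mode_subtracts_equivalent_radii(self):
        objs = [sphere_object(0, 0.0), sphere_object(1, 25.0)]
        d = pairwise_distances(objs, mode="border")
        assert d[0, 1] == pytest.approx(5.0, abs=1e-9)

    def test_center_mode_is_euclidean(self):
        objs = [sphere_object(0, 0.0), sphere_object(1, 25.0)]
        assert pairwise_distances(objs, mode="center")[0, 1] == pytest.approx(25.0)

    def test_overlapping_objects_floor_at_zero(self):
        objs = [sphere_object(0, 0.0), sphere_object(1, 5.0)]
        d = pairwise_distances(objs, mode="border")
        assert d[0, 1] == 0.0

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        objs = [sphere_object(i, *rng.uniform(0, 100, 3)) for i in range(10)]
        d = pairwise_distances(objs)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)


class TestCellCountEstimate:
    @pytest.mark.parametrize("volume, expected", [
        (SPHERE_20UM, 1),
        (2 * SPHERE_20UM, 2),
        (100.0, 1),  # clamp to at least one cell
        (3.4 * SPHERE_20UM, 3),
    ])
    def test_rounding_against_reference_sphere(self, volume, expected):
        assert estimate_cell_count(volume, 20.0) == expected

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            estimate_cell_count(0.0, 20.0)


class TestCallNests:
    def test_single_linkage_chains_collinear_cells(self):
        # Consecutive gaps of 9 um chain into one nest even though the
        # end-to-end separation is 18 um.
        d = np.array([[0, 9, 18], [9, 0, 9], [18, 9, 0]], dtype=float)
        nests, singles = call_nests(d, NestConfig())
        assert len(nests) == 1 and nests[0].estimated_cell_count == 3
        assert singles == []

    def test_pairs_are_not_nests(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        nests, singles = call_nests(d, NestConfig())
        assert nests == [] and singles == [0, 1]

    def test_tie_at_cutoff_is_included(self):
        d = np.array([[0, 10, 20], [10, 0, 10], [20, 10, 0]], dtype=float)
        nests, _ = call_nests(d, NestConfig(cutoff_um=10.0))
        assert len(nests) == 1

    def test_merged_objects_count_their_estimated_cells(self):
        # One 2-cell object plus one single cell within the cutoff reach
        # the 3-cell minimum.
        d = np.array([[0.0, 8.0], [8.0, 0.0]])
        nests, _ = call_nests(d, NestConfig(), cell_counts=[2, 1])
        assert len(nests) == 1 and nests[0].estimated_cell_count == 3

    def test_asymmetric_and_negative_matrices_rejected(self):
        with pytest.raises(ValueError):
            call_nests(np.array([[0.0, 1.0], [2.0, 0.0]]), NestConfig())
        with pytest.raises(ValueError):
            call_nests(np.array([[0.0, -1.0], [-1.0, 0.0]]), NestConfig())

    def test_partition_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(2, 200)
            pts = rng.uniform(0, 120, (n, 3))
            diff = pts[:, None] - pts[None, :]
            d = np.sqrt((diff**2).sum(-1))
            nests, singles = call_nests(d, NestConfig(min_cells_per_nest=2))
            flat = np.full(n, -1)
            for k, nest in enumerate(nests):
                for m in nest.member_ids:
                    flat[m] = k
            for s in singles:
                flat[s] = 1000 + s
            oracle = brute_force_components(d, 10.0)
            # Compare partitions, folding oracle components of size 1.
            assert partitions_equal(flat, oracle)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=40), st.integers(0, 10_000))
    def test_membership_monotone_in_cutoff(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 60, (n, 3))
        diff = pts[:, None] - pts[None, :]
        d = np.sqrt((diff**2).sum(-1))
        comp_small = brute_force_components(d, 8.0)
        comp_big = brute_force_components(d, 14.0)
        # Growing the cutoff can only merge components, never split them.
        for c in np.unique(comp_small):
            members = np.where(comp_small == c)[0]
            assert len(np.unique(comp_big[members])) == 1


class TestSummaries:
    def _class_objects(self, n_nested, n_singleton):
        objs = [sphere_object(i, x=float(30 * i)) for i in range(n_nested + n_singleton)]
        return objs

    def test_worked_percent_example(self):
        # 8 nests of 4 cells + 6 singletons -> 100*32/38 ~ 84.2%.
        config = NestConfig()
        objs = self._class_objects(32, 6)
        nests = []
        from nestkin.nests import Nest
        for k in range(8):
            nests.append(Nest(id=k, member_ids=list(range(4 * k, 4 * k + 4)),
                              estimated_cell_count=4, mean_intensity=100.0))
        s = summarize_nests(nests, objs, config, "Bright")
        assert s.percent_of_cells_in_nests == pytest.approx(100 * 32 / 38)
        assert s.average_nest_size == 4
        assert s.total_nests == 8

    def test_all_singletons(self):
        s = summarize_nests([], self._class_objects(0, 5), NestConfig(), "Mid")
        assert s.percent_of_cells_in_nests == 0.0
        assert s.total_nests == 0

    def test_single_nest_containing_every_cell(self):
        from nestkin.nests import Nest
        objs = self._class_objects(3, 0)
        nest = Nest(id=0, member_ids=[0, 1, 2], estimated_cell_count=3,
                    mean_intensity=100.0)
        s = summarize_nests([nest], objs, NestConfig(), "Bright")
        assert s.percent_of_cells_in_nests == pytest.approx(100.0)

    def test_zero_cells_flagged_not_nan(self):
        s = summarize_nests([], [], NestConfig(), "Mid")
        assert s.undefined and s.percent_of_cells_in_nests is None


class TestScaling:
    def test_linear_scaling(self):
        assert scale_total_nests(50, 400, 800) == pytest.approx(100.0)

    def test_full_imaging_identity(self):
        assert scale_total_nests(37, 512, 512) == 37

    def test_inconsistent_inputs_warn_but_compute(self):
        with pytest.warns(UserWarning):
            est = scale_total_nests(10, 100, 50)
        assert est == pytest.approx(5.0)

    def test_zero_imaged_cells_rejected(self):
        with pytest.raises(ValueError):
            scale_total_nests(10, 0, 100)

    def test_depth_guard_drops_edge_objects(self):
        objs = [sphere_object(0, 0, z=10.0), sphere_object(1, 0, z=85.0)]
        kept = apply_depth_guard(objs, z_imaged_um=100.0, guard_um=20.0)
        assert [o.id for o in kept] == [0]
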