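import numpy as np
import pytest

from invasim import metrics, synthetic
from invasim.params import KIND_CAF, KIND_SCC


def brute_force_metrics(grid, kinds, interface):
    """Independent voxel-level recomputation of the basic invasion metrics
    and neighbour counts (plain Python loops, no shared helpers)."""
    nx, ny, nz = grid.shape
    voxels = {}
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                cid = int(grid[x, y, z])
                if cid > 0:
                    voxels.setdefault(cid, []).append((x, y, z))
    cents = {cid: tuple(np.mean(v, axis=0)) for cid, v in voxels.items()}

    def dist(c):
        if interface["type"] == "plane":
            return c[2] - interface["z"]
        ctr = interface["center"]
        return np.sqrt(sum((c[i] - ctr[i]) ** 2 for i in range(3))) - interface["radius"]

    inv = {cid: dist(c) for cid, c in cents.items()
           if kinds[cid] == KIND_SCC and dist(c) > 0}
    if inv:
        maxi = max(inv.values())
        score = len(inv) * np.mean(list(inv.values()))
    else:
        maxi = score = 0.0
    # SCC face-neighbour counts
    nbrs = {cid: set() for cid in voxels}
    for cid, vs in voxels.items():
        for (x, y, z) in vs:
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)):
                q = (x + d[0], y + d[1], z + d[2])
                if all(0 <= q[i] < grid.shape[i] for i in range(3)):
                    other = int(grid[q])
                    if other > 0 and other != cid:
                        nbrs[cid].add(other)
    scc_nbr_count = {cid: sum(1 for o in nbrs[cid] if kinds[o] == KIND_SCC)
                     for cid in voxels if kinds[cid] == KIND_SCC}
    return maxi, score, inv, scc_nbr_count


class TestInvasiveIdentification:
    def test_no_cell_beyond_interface(self):
        grid, kinds, interface, _, _ = synthetic.invasion_depth_fixture(depths=())
        ids, d = metrics.identify_invasive_cells(grid, kinds, interface)
        assert ids.size == 0 and d.size == 0

    def test_prescribed_depths_recovered(self):
        grid, kinds, interface, _, exp = synthetic.invasion_depth_fixture(
            depths=(10, 20, 30))
        ids, d = metrics.identify_invasive_cells(grid, kinds, interface)
        assert sorted(d) == exp["distances"]

    def test_centroid_exactly_on_interface_not_invasive(self):
        grid = np.zeros((12, 12, 12), dtype=np.int32)
        grid[4:7, 4:7, 5:8] = 1  # centroid z = 6.0
        kinds = np.array([0, KIND_SCC], dtype=np.int8)
        ids, _ = metrics.identify_invasive_cells(
            grid, kinds, {"type": "plane", "z": 6})
        assert ids.size == 0

    def test_missing_interface_raises(self):
        grid = np.zeros((4, 4, 4), dtype=np.int32)
        with pytest.raises(ValueError):
            metrics.identify_invasive_cells(grid, np.zeros(1, np.int8), None)


class TestBasicInvasionMetrics:
    def test_empty_set_gives_zeros(self):
        grid, kinds, interface, _, _ = synthetic.invasion_depth_fixture(depths=())
        assert metrics.invasion_metrics_basic(grid, kinds, interface) == (0.0, 0.0)

    def test_three_cell_fixture(self):
        grid, kinds, interface, _, exp = synthetic.invasion_depth_fixture(
            depths=(10, 20, 30))
        maxi, score = metrics.invasion_metrics_basic(grid, kinds, interface)
        assert maxi == pytest.approx(exp["max_invasion"])   # 30
        assert score == pytest.approx(exp["invasion_score"])  # 3 x 20

    def test_single_cell_collapse(self):
        grid, kinds, interface, _, _ = synthetic.invasion_depth_fixture(depths=(17,))
        maxi, score = metrics.invasion_metrics_basic(grid, kinds, interface)
        assert maxi == pytest.approx(17) and score == pytest.approx(17)

    def test_monotone_under_added_invasive_cell(self):
        a = synthetic.invasion_depth_fixture(depths=(10, 20))
        b = synthetic.invasion_depth_fixture(depths=(10, 20, 30))
        ma, sa = metrics.invasion_metrics_basic(a[0], a[1], a[2])
        mb, sb = metrics.invasion_metrics_basic(b[0], b[1], b[2])
        assert mb >= ma and sb > sa


class TestNeighboursAndTapering:
    def test_touching_invasive_pair_has_one_neighbour_each(self):
        grid, kinds, interface, exp = synthetic.touching_pair_fixture()
        nb, _ = metrics.neighbour_and_tapering(grid, kinds, interface)
        assert nb == pytest.approx(exp["mean_neighbours"])

    def test_chain_matches_bruteforce_and_flat_tapering(self):
        """A vertical chain of touching cells: neighbour counts equal the
        brute-force recount; constant-width strand tapering from the
        closed-form least-squares slope."""
        cells = [(KIND_SCC, (4, 4, 4 + 4 * i), 4) for i in range(5)]
        grid, kinds = synthetic.labelled_volume((16, 16, 32), cells)
        interface = {"type": "plane", "z": 2}
        nb, tap = metrics.neighbour_and_tapering(grid, kinds, interface)
        maxi, score, inv, counts = brute_force_metrics(grid, kinds, interface)
        assert nb == pytest.approx(np.mean([counts[c] for c in inv]))
        # closed-form OLS slope on (distance, neighbours)
        d = np.array([inv[c] for c in sorted(inv)])
        n = np.array([counts[c] for c in sorted(inv)], dtype=float)
        slope = np.sum((d - d.mean()) * (n - n.mean())) / np.sum((d - d.mean()) ** 2)
        assert tap == pytest.approx(slope)

    def test_no_bulk_mass_gives_zero_neighbours(self):
        grid = np.zeros((8, 8, 8), dtype=np.int32)
        kinds = np.array([0, KIND_SCC], dtype=np.int8)
        nb, tap = metrics.neighbour_and_tapering(
            grid, kinds, {"type": "plane", "z": 2})
        assert nb == 0.0 and np.isnan(tap)

    def test_single_distance_tapering_undefined(self):
        grid, kinds, interface, _ = synthetic.touching_pair_fixture()
        _, tap = metrics.neighbour_and_tapering(grid, kinds, interface)
        assert np.isnan(tap)  # both cells at the same depth


class TestFracturedObjects:
    def test_single_connected_mass(self):
        grid, kinds, _ = synthetic.fragmented_fixture(0)
        assert metrics.fractured_objects(grid, kinds) == 0

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_detached_scc_clusters_counted(self, n):
        grid, kinds, exp = synthetic.fragmented_fixture(n)
        assert metrics.fractured_objects(grid, kinds) == exp["fractured_objects"]

    def test_fibroblast_only_fragment_ignored(self):
        grid, kinds, _ = synthetic.fragmented_fixture(1, caf_only_fragments=2)
        assert metrics.fractured_objects(grid, kinds) == 1


class TestGrowthFit:
    def test_constant_count_zero_rate(self):
        assert metrics.growth_fit([0, 2880, 5760], [40, 40, 40]) == pytest.approx(0.0)

    def test_doubling_every_three_days(self):
        t = np.array([0, 1, 2, 3]) * 3 * 2880
        c = 50 * 2.0 ** np.arange(4)
        assert metrics.growth_fit(t, c) == pytest.approx(np.log(2) / 3)

    def test_noiseless_exponential_recovered_exactly(self):
        t = np.linspace(0, 4 * 2880, 9)
        rate = 0.37  # per day
        c = 30 * np.exp(rate * t / 2880)
        assert metrics.growth_fit(t, c) == pytest.approx(rate, abs=1e-8)

    def test_zero_counts_excluded(self):
        r = metrics.growth_fit([0, 2880, 5760, 8640], [0, 40, 80, 160])
        assert r == pytest.approx(np.log(2), rel=1e-6)


class TestTrackInvasionScore:
    def test_intact_matrix_scores_zero(self):
        density = np.ones((8, 8, 16))
        grid = np.zeros((8, 8, 16), dtype=np.int32)
        s = metrics.track_invasion_score(density, grid,
                                         {"type": "plane", "z": 4})
        assert s == 0.0

    def test_two_qualifying_voxels_sum_their_depths(self):
        grid, density, interface, exp = synthetic.track_density_fixture(
            qualifying=((5, 0.5), (7, 0.2)))
        s = metrics.track_invasion_score(density, grid, interface)
        assert s == pytest.approx(exp["track_invasion_score"])  # 12

    def test_threshold_is_inclusive(self):
        grid, density, interface, _ = synthetic.track_density_fixture(
            qualifying=((5, 0.75),))
        assert metrics.track_invasion_score(density, grid, interface) == pytest.approx(5)
        grid, density, interface, _ = synthetic.track_density_fixture(
            qualifying=((5, 0.7501),))
        assert metrics.track_invasion_score(density, grid, interface) == 0.0


class TestWidthAndCurvature:
    def test_flat_front_has_zero_curvature(self):
        grid = np.zeros((64, 64, 24), dtype=np.int32)
        grid[:, :, :8] = 1
        kinds = np.array([0, KIND_SCC], dtype=np.int8)
        _, curv = metrics.track_width_and_curvature(
            grid, kinds, {"type": "plane", "z": 8}, window=50)
        assert curv == pytest.approx(0.0, abs=1e-6)

    def test_circular_arc_profile_curvature(self):
        """The smoothed-profile circumcircle estimator recovers 1/r on an
        arc of radius far larger than the smoothing window."""
        r = 300.0
        x = np.arange(200) - 100
        profile = np.sqrt(r ** 2 - x ** 2)
        k = metrics.front_profile_curvature(profile, window=50)
        # moving-average smoothing slightly flattens a circular arc
        assert k == pytest.approx(1 / r, rel=0.15)

    def test_hemispherical_front_fixture(self):
        grid, kinds, interface, exp = synthetic.spherical_front_fixture()
        _, curv = metrics.track_width_and_curvature(grid, kinds, interface,
                                                    window=25)
        assert curv == pytest.approx(exp["curvature"], rel=0.25)

    def test_strand_width_matches_construction(self):
        grid = np.zeros((32, 32, 32), dtype=np.int32)
        grid[:, :, :6] = 1                      # base layer
        grid[10:17, 12:16, 6:28] = 2            # strand: 7 x 4 cross-section
        kinds = np.array([0, KIND_SCC, KIND_SCC], dtype=np.int8)
        w, _ = metrics.track_width_and_curvature(
            grid, kinds, {"type": "plane", "z": 5}, window=10)
        assert w == 7

    def test_uniform_advance_width_undefined(self):
        grid = np.zeros((24, 24, 24), dtype=np.int32)
        grid[:, :, :16] = 1  # whole mass advanced beyond the interface
        kinds = np.array([0, KIND_SCC], dtype=np.int8)
        w, _ = metrics.track_width_and_curvature(
            grid, kinds, {"type": "plane", "z": 8}, window=10)
        assert np.isnan(w)

    def test_non_invasive_width_undefined(self):
        grid = np.zeros((24, 24, 24), dtype=np.int32)
        grid[4:12, 4:12, :8] = 1
        kinds = np.array([0, KIND_SCC], dtype=np.int8)
        w, _ = metrics.track_width_and_curvature(
            grid, kinds, {"type": "plane", "z": 8}, window=10)
        assert np.isnan(w)


class TestHollowExclusion:
    def test_intact_spheroid_not_excluded(self):
        grid = np.zeros((24, 24, 24), dtype=np.int32)
        grid[8:16, 8:16, 8:16] = 1
        kinds = np.array([0, KIND_SCC], dtype=np.int8)
        assert not metrics.hollow_exclusion(grid, kinds)

    def test_broken_apart_mass_excluded(self):
        grid, kinds, exp = synthetic.hollow_fixture()
        assert metrics.hollow_exclusion(grid, kinds) is exp["excluded"]


class TestConsistency:
    def test_axis_permutation_invariance(self):
        """Swapping the two axes perpendicular to the cue leaves every
        planar metric unchanged."""
        grid, kinds, interface, _, _ = synthetic.invasion_depth_fixture(
            depths=(8, 14, 23))
        swapped = np.transpose(grid, (1, 0, 2)).copy()
        assert metrics.invasion_metrics_basic(grid, kinds, interface) == \
            metrics.invasion_metrics_basic(swapped, kinds, interface)
        np.testing.assert_equal(  # NaN-tolerant comparison
            metrics.neighbour_and_tapering(grid, kinds, interface),
            metrics.neighbour_and_tapering(swapped, kinds, interface))
        assert metrics.fractured_objects(grid, kinds) == \
            metrics.fractured_objects(swapped, kinds)

    def test_random_volume_matches_bruteforce(self):
        """Metric implementations agree with plain-Python voxel loops on a
        random labelled volume."""
        rng = np.random.default_rng(3)
        cells = []
        kinds_list = [KIND_SCC, KIND_SCC, KIND_CAF, KIND_SCC, KIND_SCC]
        for i, k in enumerate(kinds_list):
            corner = tuple(rng.integers(0, 20, 2)) + (int(rng.integers(0, 24)),)
            cells.append((k, corner, int(rng.integers(3, 6))))
        # later cubes may overwrite earlier ones: irregular shapes are fine,
        # both routes see the same grid
        grid, kinds = synthetic.labelled_volume((28, 28, 32), cells)
        interface = {"type": "plane", "z": 6}
        maxi, score = metrics.invasion_metrics_basic(grid, kinds, interface)
        b_maxi, b_score, _, _ = brute_force_metrics(grid, kinds, interface)
        assert maxi == pytest.approx(b_maxi)
        assert score == pytest.approx(b_score)
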