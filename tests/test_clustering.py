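"""DBSCAN, OPTICS, RD-plot segmentation and hull quantification."""

import numpy as np
import pytest

from miisr import (LocalizationTable, NOISE, cluster_hull_density, dbscan,
                   dbscan_parameter_sweep, extract_clusters_static_rd,
                   hier_segment_rd, optics_order)
from miisr.clustering import flag_subresolution_clusters


def two_blob_table(rng, n_per=100, centres=((0.0, 0.0), (1000.0, 1000.0)),
                   sd=30.0, n_noise=0, extent=2000.0):
    parts = [rng.normal(c, sd, (n_per, 2)) for c in centres]
    if n_noise:
        parts.append(rng.uniform(-200, extent, (n_noise, 2)))
    xy = np.vstack(parts)
    return LocalizationTable(x=xy[:, 0], y=xy[:, 1])


def brute_force_optics(coords, k):
    """Canonical OPTICS by literal priority scanning, O(n^3)-ish."""
    n = len(coords)
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    core = np.sort(d, axis=1)[:, k - 1]   # k-th closest counting self
    processed = [False] * n
    tentative = [np.inf] * n
    ordering, reach = [], []
    for _ in range(n):
        best, best_rd = None, np.inf
        for i in range(n):
            if not processed[i] and (best is None
                                     or tentative[i] < best_rd):
                best, best_rd = i, tentative[i]
        ordering.append(best)
        reach.append(tentative[best])
        processed[best] = True
        for j in range(n):
            if not processed[j]:
                rd = max(core[best], d[best, j])
                if rd < tentative[j]:
                    tentative[j] = rd
    return np.array(ordering), np.array(reach), core


class TestDbscan:
    def test_core_edge_noise_roles(self):
        # a tight 6-point clump (cores), one molecule on its fringe
        # (edge: inside a core's eps but with too few own neighbours),
        # and one isolated molecule (noise)
        clump = [(0, 0), (1, 0), (0, 1), (1, 1), (0.5, 0.5), (1, 0.5)]
        fringe = [(2.8, 0.5)]
        iso = [(50.0, 50.0)]
        pts = np.array(clump + fringe + iso, dtype=float)
        t = LocalizationTable(x=pts[:, 0], y=pts[:, 1])
        lab = dbscan(t, k=5, eps=2.0)
        assert all(lab.roles[i] == "core" for i in range(6))
        assert lab.roles[6] == "edge" and lab.labels[6] == lab.labels[0]
        assert lab.roles[7] == "noise" and lab.labels[7] == NOISE

    def test_matches_sklearn_on_two_blobs(self, rng):
        from sklearn.cluster import DBSCAN as SkDBSCAN
        t = two_blob_table(rng, n_noise=20)
        lab = dbscan(t, k=5, eps=60.0)
        sk = SkDBSCAN(eps=60.0, min_samples=5).fit(t.xy)
        # identical partitions (label names may differ)
        assert lab.n_clusters == sk.labels_.max() + 1 == 2
        np.testing.assert_array_equal(lab.labels == NOISE,
                                      sk.labels_ == -1)
        for lbl in range(lab.n_clusters):
            members = lab.members(lbl)
            assert len(set(sk.labels_[members])) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_on_random_fixtures(self, seed):
        from sklearn.cluster import DBSCAN as SkDBSCAN
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        xy = rng.uniform(0, 1000, (n, 2))
        t = LocalizationTable(x=xy[:, 0], y=xy[:, 1])
        k = int(rng.integers(3, 10))
        eps = float(rng.uniform(30, 120))
        lab = dbscan(t, k=k, eps=eps)
        sk = SkDBSCAN(eps=eps, min_samples=k).fit(xy)
        assert lab.n_clusters == sk.labels_.max() + 1
        np.testing.assert_array_equal(lab.labels == NOISE, sk.labels_ == -1)
        # same partition up to relabeling
        for lbl in range(lab.n_clusters):
            assert len(set(sk.labels_[lab.members(lbl)])) == 1
        # same core sets
        core = np.zeros(n, dtype=bool)
        core[sk.core_sample_indices_] = True
        np.testing.assert_array_equal(lab.roles == "core", core)

    def test_coincident_points_single_all_core_cluster(self):
        t = LocalizationTable(x=np.zeros(10), y=np.zeros(10))
        lab = dbscan(t, k=10, eps=1.0)
        assert lab.n_clusters == 1
        assert (lab.roles == "core").all()

    def test_parameter_sweep_single_cell_matches_direct(self, rng):
        t = two_blob_table(rng)
        grid = dbscan_parameter_sweep(t, [5], [60.0])
        direct = dbscan(t, k=5, eps=60.0)
        assert grid == [{"k": 5, "eps": 60.0,
                         "n_clusters": direct.n_clusters,
                         "noise_fraction": direct.noise_fraction}]

    def test_noise_fraction_nondecreasing_in_k(self, rng):
        t = two_blob_table(rng, n_noise=40)
        grid = dbscan_parameter_sweep(t, [3, 6, 12, 24], [60.0])
        fractions = [g["noise_fraction"] for g in grid]
        assert fractions == sorted(fractions)


class TestOptics:
    def test_matches_brute_force_oracle(self, rng):
        xy = rng.uniform(0, 500, (50, 2))
        t = LocalizationTable(x=xy[:, 0], y=xy[:, 1])
        prof = optics_order(t, min_cluster_size=5)
        o, r, core = brute_force_optics(xy, 5)
        np.testing.assert_array_equal(prof.ordering, o)
        np.testing.assert_allclose(prof.reachability, r)
        np.testing.assert_allclose(prof.core_distance, core)

    def test_reachability_vs_sklearn(self, rng):
        from sklearn.cluster import OPTICS as SkOPTICS
        xy = rng.uniform(0, 1000, (200, 2))
        t = LocalizationTable(x=xy[:, 0], y=xy[:, 1])
        prof = optics_order(t, min_cluster_size=5)
        sk = SkOPTICS(min_samples=5, max_eps=np.inf).fit(xy)
        np.testing.assert_array_equal(prof.ordering, sk.ordering_)
        np.testing.assert_allclose(
            prof.reachability[1:], sk.reachability_[sk.ordering_][1:])
        np.testing.assert_allclose(prof.core_distance, sk.core_distances_)

    def test_collinear_equally_spaced_rd_near_constant(self):
        t = LocalizationTable(x=np.arange(40) * 10.0, y=np.zeros(40))
        prof = optics_order(t, min_cluster_size=3)
        rd = prof.reachability[1:]
        # every reachability equals the grid spacing scale
        assert rd.max() - rd.min() <= 10.0

    def test_rd_is_min_over_preceding_expanders(self, rng):
        # with no eps cap, RD at position j equals the minimum over all
        # earlier-processed molecules o of max(core_dist(o), d(o, p))
        xy = rng.uniform(0, 500, (80, 2))
        t = LocalizationTable(x=xy[:, 0], y=xy[:, 1])
        prof = optics_order(t, min_cluster_size=4)
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        for j in range(1, prof.n):
            p = prof.ordering[j]
            before = prof.ordering[:j]
            expected = np.min(np.maximum(prof.core_distance[before],
                                         d[before, p]))
            assert prof.reachability[j] == pytest.approx(expected)

    def test_too_small_table_rejected(self, small_table):
        with pytest.raises(ValueError):
            optics_order(small_table, min_cluster_size=5)


class TestStaticRd:
    def test_threshold_below_global_minimum_gives_no_clusters(self, rng):
        t = two_blob_table(rng)
        prof = optics_order(t, min_cluster_size=5)
        finite = prof.reachability[np.isfinite(prof.reachability)]
        lab = extract_clusters_static_rd(prof, 0.5 * finite.min())
        assert lab.n_clusters == 0
        assert (lab.labels == NOISE).all()

    @pytest.mark.parametrize("threshold", [60.0, 90.0, 120.0])
    def test_two_blobs_recovered_over_threshold_band(self, rng, threshold):
        t = two_blob_table(rng, n_noise=15)
        prof = optics_order(t, min_cluster_size=10)
        lab = extract_clusters_static_rd(prof, threshold)
        assert lab.n_clusters == 2

    def test_reproduces_dbscan_on_homogeneous_blobs(self, rng):
        # OPTICS + static extraction at threshold eps vs DBSCAN(eps, k):
        # identical up to edge-point assignment
        t = two_blob_table(rng, n_per=150, sd=25.0, n_noise=25)
        eps, k = 60.0, 8
        db = dbscan(t, k=k, eps=eps)
        prof = optics_order(t, min_cluster_size=k)
        op = extract_clusters_static_rd(prof, eps)
        assert op.n_clusters == db.n_clusters
        core = db.roles == "core"
        # every DBSCAN core cluster maps to exactly one OPTICS cluster
        for lbl in range(db.n_clusters):
            members = [i for i in db.members(lbl) if core[i]]
            assert len(set(op.labels[members])) == 1


class TestHierSegment:
    @staticmethod
    def _nested_scene(rng, n_parents=4, subs_per_parent=3):
        # sub-blobs 40-80 nm across inside parent regions 200-500 nm
        # across, mimicking vesicles nested in larger bodies
        pts, truth_parent = [], []
        centres = rng.uniform(1000, 9000, (n_parents, 2))
        for p, c in enumerate(centres):
            for _ in range(subs_per_parent):
                sub_c = c + rng.uniform(-200, 200, 2)
                sub = rng.normal(sub_c, 15.0, (60, 2))
                pts.append(sub)
                truth_parent.append(np.full(60, p))
        xy = np.vstack(pts)
        noise = rng.uniform(0, 10000, (int(0.1 * len(xy)), 2))
        xy = np.vstack([xy, noise])
        return LocalizationTable(x=xy[:, 0], y=xy[:, 1]), n_parents, \
            n_parents * subs_per_parent

    def test_constant_rd_profile_single_root_no_splits(self):
        from miisr import ReachabilityProfile
        rd = np.full(100, 25.0)
        rd[0] = np.inf
        prof = ReachabilityProfile(ordering=np.arange(100),
                                   reachability=rd,
                                   core_distance=np.full(100, 25.0),
                                   min_cluster_size=5)
        tree = hier_segment_rd(prof, min_cluster_size=5)
        assert tree.root.is_leaf
        assert len(tree.leaves()) == 1

    def test_evenly_spaced_points_one_cluster(self):
        t = LocalizationTable(x=np.arange(100) * 10.0, y=np.zeros(100))
        prof = optics_order(t, min_cluster_size=3)
        tree = hier_segment_rd(prof, min_cluster_size=5)
        leaves = tree.leaves()
        assert len(leaves) == 1
        assert leaves[0].size >= 95

    def test_nested_scene_recovers_two_levels(self, rng):
        t, n_parents, n_subs = self._nested_scene(rng)
        prof = optics_order(t, min_cluster_size=10)
        tree = hier_segment_rd(prof, min_cluster_size=30,
                               split_significance=0.75)
        leaves = tree.leaves()
        depths = [lf.depth for lf in leaves]
        assert max(depths) >= 2
        # leaf count ~ number of sub-blobs (within ±10% plus rounding)
        good = [lf for lf in leaves if lf.size >= 30]
        assert abs(len(good) - n_subs) <= max(1, round(0.1 * n_subs))

    def test_heterogeneous_densities_all_recovered(self, rng):
        # two dense and two sparse blobs; a static RD cut that separates
        # the dense pair merges or loses the sparse pair, the
        # hierarchical segmentation finds all four
        dense = [rng.normal(c, 20.0, (200, 2))
                 for c in ((0, 0), (4000, 0))]
        sparse = [rng.normal(c, 150.0, (200, 2))
                  for c in ((0, 4000), (4000, 4000))]
        xy = np.vstack(dense + sparse)
        t = LocalizationTable(x=xy[:, 0], y=xy[:, 1])
        prof = optics_order(t, min_cluster_size=10)
        tree = hier_segment_rd(prof, min_cluster_size=50)
        big_leaves = [lf for lf in tree.leaves() if lf.size >= 50]
        assert len(big_leaves) == 4
        lab = tree.leaf_labeling()
        # every blob is one leaf: check purity of each quadrant
        # each blob maps to exactly one leaf (Gaussian tails may be
        # stripped as noise), and no leaf spans two blobs
        owners = []
        for i in range(4):
            segment_labels = lab.labels[i * 200:(i + 1) * 200]
            vals, counts = np.unique(segment_labels[segment_labels >= 0],
                                     return_counts=True)
            assert counts.max() >= 100
            owners.append(vals[np.argmax(counts)])
        assert len(set(owners)) == 4

    def test_molecule_in_at_most_one_leaf(self, rng):
        t, _, _ = self._nested_scene(rng)
        prof = optics_order(t, min_cluster_size=10)
        tree = hier_segment_rd(prof, min_cluster_size=30)
        seen = np.zeros(t.n, dtype=int)
        for leaf in tree.leaves():
            seen[tree.members(leaf)] += 1
        assert seen.max() <= 1

    def test_invalid_split_significance(self, rng):
        t = two_blob_table(rng)
        prof = optics_order(t, min_cluster_size=5)
        with pytest.raises(ValueError):
            hier_segment_rd(prof, min_cluster_size=5,
                            split_significance=1.5)


class TestHullDensity:
    def test_unit_square_with_interior_molecule(self):
        cluster = LocalizationTable(x=[0, 1, 1, 0], y=[0, 0, 1, 1])
        other = LocalizationTable(x=[0.5, 3.0], y=[0.5, 3.0])
        area, count, density = cluster_hull_density(cluster, other)
        assert area == pytest.approx(1.0)
        assert count == 1
        assert density == pytest.approx(1.0)

    def test_boundary_molecule_counted(self):
        cluster = LocalizationTable(x=[0, 2, 2, 0], y=[0, 0, 2, 2])
        other = LocalizationTable(x=[0.0], y=[1.0])   # on the hull edge
        _, count, _ = cluster_hull_density(cluster, other)
        assert count == 1

    def test_count_matches_point_in_polygon_oracle(self, rng):
        cluster = LocalizationTable(x=rng.uniform(0, 100, 30),
                                    y=rng.uniform(0, 100, 30))
        other = LocalizationTable(x=rng.uniform(-50, 150, 200),
                                  y=rng.uniform(-50, 150, 200))
        area, count, _ = cluster_hull_density(cluster, other)
        from scipy.spatial import ConvexHull
        from shapely.geometry import Point, Polygon
        hull = ConvexHull(cluster.xy)
        poly = Polygon(cluster.xy[hull.vertices])
        expected = sum(poly.buffer(1e-9).covers(Point(p))
                       for p in other.xy)
        assert count == expected

    def test_degenerate_hull_rejected(self):
        collinear = LocalizationTable(x=[0, 1, 2], y=[0, 1, 2])
        other = LocalizationTable(x=[0.5], y=[0.5])
        with pytest.raises(ValueError):
            cluster_hull_density(collinear, other)


class TestSubresolutionFlag:
    def test_precision_scale_cluster_flagged(self, rng):
        tight = rng.normal((0, 0), 8.0, (50, 2))       # repeat detections
        real = rng.normal((2000, 2000), 120.0, (50, 2))
        xy = np.vstack([tight, real])
        t = LocalizationTable(x=xy[:, 0], y=xy[:, 1])
        lab = dbscan(t, k=5, eps=100.0)
        assert lab.n_clusters == 2
        flags = flag_subresolution_clusters(lab, t, precision=20.0)
        flagged = {lab.labels[0]: True, lab.labels[50]: False}
        assert flags == flagged
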