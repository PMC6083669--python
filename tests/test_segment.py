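"""Octree connected components, artefact classification and the census."""

import numpy as np
import pytest

from treebench.cloud import PointCloud
from treebench.degrade import DegradeSpec, degrade
from treebench.segment import census, classify_clusters, connected_components


def _blob(rng, centre, n=120, sd=0.05):
    return centre + rng.normal(0, sd, (n, 3))


def _blob_cloud(centres, seed=0, n=120, sd=0.05):
    rng = np.random.default_rng(seed)
    pts = np.vstack([_blob(rng, np.asarray(c, float), n, sd) for c in centres])
    return PointCloud(pts)


def _union_find_oracle(cloud, level):
    """Brute-force reference segmentation: voxelize identically, then union
    all point pairs whose voxels are 26-adjacent (Chebyshev distance <= 1)."""
    pts = cloud.points
    lo = pts.min(axis=0)
    extent = float(np.max(pts.max(axis=0) - lo))
    edge = extent / 2**level
    idx = np.minimum(np.floor((pts - lo) / edge).astype(np.int64), 2**level - 1)
    parent = list(range(len(pts)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(len(pts)):
        diff = np.abs(idx - idx[i]).max(axis=1)
        for j in np.flatnonzero(diff <= 1):
            union(i, int(j))
    roots = {}
    labels = np.empty(len(pts), np.int64)
    for i in range(len(pts)):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


class TestConnectedComponents:
    def test_single_blob_is_one_cluster(self):
        cloud = _blob_cloud([(0, 0, 0)], n=300)
        res = connected_components(cloud, octree_level=2, min_cluster_points=1)
        assert len(res.clusters) == 1

    def test_two_distant_blobs_are_two_clusters(self):
        res = connected_components(
            _blob_cloud([(0, 0, 0), (5, 0, 0)], n=300), octree_level=5,
            min_cluster_points=1,
        )
        assert len(res.clusters) == 2

    @pytest.mark.parametrize("k", [1, 3, 5, 8, 10])
    def test_matches_union_find_oracle(self, k):
        rng = np.random.default_rng(k)
        centres = rng.uniform(-8, 8, (k, 3)) * np.array([1, 1, 0.3])
        # enforce separation so the draw is unambiguous
        centres = centres[np.argsort(centres[:, 0])]
        centres[:, 0] = np.linspace(-4 * k, 4 * k, k)
        cloud = _blob_cloud(centres, seed=k, n=180)
        level = 6
        res = connected_components(cloud, octree_level=level, min_cluster_points=1)
        oracle = _union_find_oracle(cloud, level)
        assert len(res.clusters) == len(np.unique(oracle))
        # exact partition equivalence
        ours = res.point_labels
        for lab in np.unique(oracle):
            members = np.flatnonzero(oracle == lab)
            assert len(set(ours[members])) == 1

    def test_component_count_non_increasing_with_coarser_grid(self):
        rng = np.random.default_rng(5)
        cloud = PointCloud(rng.uniform(-10, 10, (2500, 3)))
        counts = [
            len(connected_components(cloud, octree_level=lv, min_cluster_points=1).clusters)
            for lv in (10, 9, 8, 7, 6)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_point_order_permutation_invariance(self):
        cloud = _blob_cloud([(0, 0, 0), (4, 0, 0), (0, 5, 0)], n=200, seed=2)
        perm = np.random.default_rng(0).permutation(len(cloud))
        shuffled = cloud.subset(perm)
        a = connected_components(cloud, 6, 1)
        b = connected_components(shuffled, 6, 1)
        # same cluster sizes, and the same point sets cluster together
        assert sorted(c.point_count for c in a.clusters) == sorted(
            c.point_count for c in b.clusters
        )
        la, lb = a.point_labels, b.point_labels[np.argsort(perm)]
        for lab in np.unique(la):
            assert len(set(lb[la == lab])) == 1

    def test_min_cluster_points_moves_small_clusters_to_residue(self):
        cloud = PointCloud(np.vstack([
            _blob(np.random.default_rng(0), np.zeros(3), 300, 0.05),
            np.array([[9.0, 9.0, 9.0]]),
        ]))
        res = connected_components(cloud, 5, min_cluster_points=10)
        assert len(res.clusters) == 1
        assert len(res.residue) == 1
        assert res.residue[0].point_count == 1

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            connected_components(_blob_cloud([(0, 0, 0)]), octree_level=13)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            connected_components(PointCloud(np.empty((0, 3))))


class TestClassification:
    def test_largest_cluster_is_main_others_floating(self):
        cloud = _blob_cloud([(0, 0, 0)], n=500, seed=1)
        far = _blob_cloud([(20, 0, 0)], n=100, seed=2)
        combined = PointCloud(np.vstack([cloud.points, far.points]))
        res = connected_components(combined, 6, 5)
        rep = classify_clusters(res, combined)
        assert rep.main.point_count == 500
        assert rep.count("floating") == 1

    def test_nearby_cluster_is_attached(self):
        a = _blob_cloud([(0, 0, 0)], n=400, sd=0.3, seed=1)
        b = _blob_cloud([(0, 0, 30.0)], n=100, sd=0.3, seed=2)
        combined = PointCloud(np.vstack([a.points, b.points]))
        res = connected_components(combined, 5, 5)
        from scipy.spatial.distance import cdist
        gap = cdist(a.points, b.points).min()
        rep = classify_clusters(res, combined, gap_threshold=gap + 0.1)
        assert rep.count("attached") == 1
        other = next(c for c in rep.clusters if c.classification == "attached")
        assert other.min_gap_to_main == pytest.approx(gap, abs=1e-9)

    def test_tie_for_largest_warns_and_takes_lowest_id(self):
        a = _blob_cloud([(0, 0, 0)], n=200, seed=1)
        b = _blob_cloud([(50, 0, 0)], n=200, seed=2)
        combined = PointCloud(np.vstack([a.points, b.points]))
        res = connected_components(combined, 6, 5)
        with pytest.warns(UserWarning, match="tie"):
            rep = classify_clusters(res, combined)
        assert rep.main.id == 0


class TestCensus:
    def test_pristine_reference_is_one_main_component(self, default_scene):
        rep = census(default_scene.reference, default_scene.reference)
        assert rep["counts"]["main"] == 1
        assert rep["counts"]["floating"] == 0
        assert rep["counts"]["attached"] == 0
        assert rep["omission_fraction"] == 0.0

    @pytest.mark.parametrize("k", [2, 7])
    def test_floating_count_matches_manifest(self, default_scene, k):
        model, manifest = degrade(default_scene, DegradeSpec(floating_cluster_count=k, seed=k))
        rep = census(model, default_scene.reference)
        assert rep["counts"]["floating"] == manifest["floating_cluster_count"] == k

    def test_omission_recovery_against_manifest(self, default_scene):
        spec = DegradeSpec(omission_hole_count=5, omission_hole_radius=2.5, seed=4)
        model, manifest = degrade(default_scene, spec)
        rep = census(model, default_scene.reference, omission_gap=0.15)
        achieved = manifest["omission"]["achieved_fraction"]
        assert achieved > 0.1
        assert rep["omission_fraction_vegetation"] == pytest.approx(achieved, abs=0.05)

    def test_ground_membership_reported_not_artefact(self, default_scene):
        rep = census(default_scene.reference, default_scene.reference)
        membership = rep["component_membership_by_label"][0]
        assert max(membership, key=membership.get) == 0
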