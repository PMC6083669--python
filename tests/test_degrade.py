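"""Artefact injection operators: ground truth, determinism, identity."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from treebench.align import SimilarityTransform, estimate_similarity
from treebench.degrade import (
    DegradeSpec,
    PlacementError,
    add_floating_clusters,
    add_ghost,
    apply_omission,
    degrade,
    thin,
)
from treebench.segment import census


def _clouds_equal(a, b):
    return (
        np.array_equal(a.points, b.points)
        and np.array_equal(a.labels, b.labels)
        and np.array_equal(a.colors, b.colors)
    )


class TestIdentity:
    def test_all_default_spec_is_identity(self, small_scene):
        out, manifest = degrade(small_scene, DegradeSpec())
        assert _clouds_equal(out, small_scene.reference)
        assert manifest["artefact_count"] == 0

    def test_noise_free_operators_are_identity(self, small_scene):
        spec = DegradeSpec(jitter_sd=0.0, thinning_keep=1.0)
        ref = small_scene.reference
        out, _ = degrade(small_scene, spec)
        assert _clouds_equal(out, ref)


class TestOmission:
    def test_hole_leaves_no_points_inside_sphere(self, small_scene):
        spec = DegradeSpec(omission_hole_count=3, omission_hole_radius=1.2, seed=5)
        manifest = {}
        out = apply_omission(small_scene.reference, spec, manifest=manifest)
        for hole in manifest["omission"]["holes"]:
            d = np.linalg.norm(out.points - np.asarray(hole["centre"]), axis=1)
            assert np.all(d > hole["radius"] - 1e-12)

    @pytest.mark.parametrize("fraction", [0.2, 0.5])
    def test_removed_tree_fraction_meets_request(self, small_scene, fraction):
        spec = DegradeSpec(omission_fraction=fraction, seed=3)
        ref = small_scene.reference
        out = apply_omission(ref, spec)
        tree_before = int(np.isin(ref.labels, [1, 2, 3]).sum())
        tree_after = int(np.isin(out.labels, [1, 2, 3]).sum())
        removed = (tree_before - tree_after) / tree_before
        assert removed >= fraction - 1e-12
        assert removed < fraction + 0.001  # fraction rule removes no excess
        # non-tree points untouched by the fraction rule
        assert int((out.labels == 0).sum()) == int((ref.labels == 0).sum())

    def test_full_omission_removes_all_vegetation(self, small_scene):
        out = apply_omission(small_scene.reference, DegradeSpec(omission_fraction=1.0, seed=1))
        assert not np.isin(out.labels, [1, 2, 3]).any()


class TestFloatingClusters:
    def test_zero_count_is_identity(self, small_scene):
        out = add_floating_clusters(small_scene.reference, DegradeSpec(seed=1))
        assert _clouds_equal(out, small_scene.reference)

    def test_cluster_count_and_fresh_labels(self, default_scene):
        # 150 clusters mirrors the worst observed floating-artefact census
        spec = DegradeSpec(floating_cluster_count=150, seed=8)
        manifest = {}
        out = add_floating_clusters(default_scene.reference, spec, manifest=manifest)
        new = np.unique(out.labels[out.labels >= 100])
        assert len(new) == 150
        assert len(manifest["artefacts"]) == 150
        assert len(out) == len(default_scene.reference) + 150 * spec.floating_cluster_points

    def test_pairwise_centre_separation_by_all_pairs_scan(self, small_scene):
        spec = DegradeSpec(floating_cluster_count=20, seed=4)
        manifest = {}
        add_floating_clusters(small_scene.reference, spec, manifest=manifest)
        centres = np.array([a["centre"] for a in manifest["artefacts"]])
        d = cdist(centres, centres)
        min_sep = 2 * 6 * spec.floating_cluster_sd
        assert d[~np.eye(len(d), dtype=bool)].min() >= min_sep - 1e-9

    def test_region_inside_scene_is_rejected(self, small_scene):
        lo, hi = small_scene.reference.bbox()
        bad = np.array([lo, lo + 1.0])
        spec = DegradeSpec(floating_cluster_count=2, floating_region=bad, seed=0)
        with pytest.raises(PlacementError):
            add_floating_clusters(small_scene.reference, spec)


class TestAttachedRing:
    def test_disabled_is_identity(self, small_scene):
        out, _ = degrade(small_scene, DegradeSpec(attached_ring=False))
        assert _clouds_equal(out, small_scene.reference)

    def test_ring_points_lie_in_radial_band(self, default_scene):
        spec = DegradeSpec(attached_ring=True, seed=3)
        manifest = {}
        out, manifest = degrade(default_scene, spec)
        rec = next(a for a in manifest["artefacts"] if a["kind"] == "attached_ring")
        ring = out.points[out.labels == rec["label"]]
        radial = np.linalg.norm(ring[:, :2] - np.asarray(rec["centre_xy"]), axis=1)
        assert np.all(radial >= rec["major_radius"] - spec.ring_thickness - 1e-9)
        assert np.all(radial <= rec["major_radius"] + spec.ring_thickness + 1e-9)

    def test_touching_ring_merges_into_main_component(self, default_scene):
        out, manifest = degrade(default_scene, DegradeSpec(attached_ring=True, seed=3))
        rep = census(out, default_scene.reference)
        # the interpenetrating ring becomes part of the main structure:
        # no separate floating cluster appears
        assert rep["counts"]["floating"] == 0
        label = manifest["artefacts"][0]["label"]
        membership = rep["component_membership_by_label"][label]
        assert max(membership, key=membership.get) == 0  # main cluster id

    def test_requires_foliage(self, small_scene):
        ref = small_scene.reference
        bare = ref.subset(ref.labels != 3)
        with pytest.raises(ValueError, match="foliage"):
            degrade(bare, DegradeSpec(attached_ring=True))


class TestGhost:
    def test_zero_offset_duplicates_in_place(self, small_scene):
        spec = DegradeSpec(ghost_component=1, ghost_offset=(0.0, 0.0, 0.0))
        out = add_ghost(small_scene.reference, spec)
        ref = small_scene.reference
        assert len(out) == len(ref) + int((ref.labels == 1).sum())

    def test_ghost_point_count_equals_component(self, small_scene):
        ref = small_scene.reference
        manifest = {}
        out = add_ghost(ref, DegradeSpec(ghost_component=1, ghost_offset=(5, 0, 0)),
                        manifest=manifest)
        ghost_label = manifest["artefacts"][0]["label"]
        assert int((out.labels == ghost_label).sum()) == int((ref.labels == 1).sum())

    def test_ghost_coincides_with_shifted_original(self, small_scene):
        ref = small_scene.reference
        offset = np.array([5.0, 0.0, 0.0])
        manifest = {}
        out = add_ghost(ref, DegradeSpec(ghost_component=1, ghost_offset=offset),
                        manifest=manifest)
        ghost = out.points[out.labels == manifest["artefacts"][0]["label"]]
        shifted = ref.points[ref.labels == 1] + offset
        d, _ = cKDTree(shifted).query(ghost)
        assert np.all(d == 0.0)

    def test_missing_component_rejected(self, small_scene):
        with pytest.raises(ValueError):
            add_ghost(small_scene.reference, DegradeSpec(ghost_component=7))


class TestNoiseOperators:
    def test_thinning_keeps_binomial_fraction(self, default_scene):
        spec = DegradeSpec(thinning_keep=0.5, seed=6)
        ref = default_scene.reference
        out = thin(ref, spec)
        n = len(ref)
        se = np.sqrt(0.25 / n)
        assert abs(len(out) / n - 0.5) < 3 * se

    def test_pose_perturbation_recovered_by_alignment(self, small_scene):
        rng = np.random.default_rng(12)
        angle = np.radians(10.0)
        R = np.array(
            [[np.cos(angle), -np.sin(angle), 0],
             [np.sin(angle), np.cos(angle), 0],
             [0, 0, 1]]
        )
        T = SimilarityTransform(1.2, R, rng.uniform(-3, 3, 3))
        spec = DegradeSpec(pose_perturbation=T)
        out, _ = degrade(small_scene, spec)
        # estimate the inverse from the (perturbed) target centroids
        src = np.array([out.points[out.labels == lab].mean(axis=0)
                        for lab in range(10, 18)])
        back = estimate_similarity(src, small_scene.target_centroids)
        recovered = back.compose(T)
        assert recovered.scale == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(recovered.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(recovered.translation, 0.0, atol=1e-7)


class TestComposite:
    def test_manifest_counts_injected_artefacts(self, small_scene):
        spec = DegradeSpec(floating_cluster_count=4, attached_ring=True,
                           ghost_component=1, seed=2)
        _, manifest = degrade(small_scene, spec)
        assert manifest["artefact_count"] == 4 + 1 + 1
        assert manifest["floating_cluster_count"] == 4

    def test_deterministic_under_seed(self, small_scene):
        spec = DegradeSpec(omission_fraction=0.2, floating_cluster_count=5,
                           jitter_sd=0.01, thinning_keep=0.8, seed=13)
        a, ma = degrade(small_scene, spec)
        b, mb = degrade(small_scene, spec)
        assert _clouds_equal(a, b)
        assert ma == mb

    def test_ground_truth_recoverable_from_labels(self, small_scene):
        spec = DegradeSpec(floating_cluster_count=3, ghost_component=1, seed=7)
        out, manifest = degrade(small_scene, spec)
        injected = {a["label"] for a in manifest["artefacts"]}
        present = set(np.unique(out.labels[out.labels >= 100]).tolist())
        assert injected == present
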