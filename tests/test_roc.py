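"""Voxel confusion tables, ROC sweep and AUC."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from treebench.cloud import PointCloud
from treebench.roc import (
    ConfusionCounts,
    auc_from_points,
    confusion_at,
    default_bounds,
    ground_truth_radius,
    roc_curve,
    voxelize,
)


def _cloud(arr):
    return PointCloud(np.asarray(arr, dtype=float))


def _oracle_confusion(model, reference, r, voxel_size, bounds):
    """Exhaustive per-voxel scan: distances by dense pairwise computation."""
    bounds = np.asarray(bounds, float)
    dims = np.maximum(np.ceil((bounds[1] - bounds[0]) / voxel_size - 1e-9).astype(int), 1)
    ax = [bounds[0][a] + (np.arange(dims[a]) + 0.5) * voxel_size for a in range(3)]
    I, J, K = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    centres = np.column_stack([ax[0][I.ravel()], ax[1][J.ravel()], ax[2][K.ravel()]])
    d_ref = cdist(centres, reference.points).min(axis=1)
    r_pos = ground_truth_radius(voxel_size)
    positive = d_ref <= r_pos
    if len(model) and r > 0:
        predicted = cdist(centres, model.points).min(axis=1) <= r
    else:
        predicted = np.zeros(len(centres), bool)
    tp = int((positive & predicted).sum())
    fp = int((~positive & predicted).sum())
    return tp, fp, int(positive.sum()) - tp, int((~positive).sum()) - fp


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(17)
    reference = _cloud(rng.uniform(-1, 1, (400, 3)))
    model = _cloud(np.vstack([
        reference.points[:300] + rng.normal(0, 0.02, (300, 3)),
        rng.uniform(1.2, 2.0, (50, 3)),  # commission artefacts outside
    ]))
    return model, reference


class TestVoxelize:
    def test_empty_cloud(self):
        out = voxelize(_cloud(np.empty((0, 3))), 0.1, np.array([[0.0, 0, 0], [1, 1, 1]]))
        assert out.shape == (0, 3)

    def test_single_point_single_voxel(self):
        out = voxelize(_cloud([[0.55, 0.15, 0.95]]), 0.1,
                       np.array([[0.0, 0, 0], [1, 1, 1]]))
        assert np.array_equal(out, [[5, 1, 9]])

    def test_occupancy_matches_floor_division_scan(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, (500, 3))
        bounds = np.array([[0.0, 0, 0], [1, 1, 1]])
        out = voxelize(_cloud(pts), 0.13, bounds)
        dims = np.ceil((bounds[1] - bounds[0]) / 0.13 - 1e-9).astype(int)
        direct = np.unique(
            np.minimum(np.floor(pts / 0.13).astype(int), dims - 1), axis=0
        )
        assert np.array_equal(out, direct[np.lexsort(direct.T[::-1])])

    def test_outside_points_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = voxelize(_cloud([[5.0, 5, 5], [0.5, 0.5, 0.5]]), 0.5,
                           np.array([[0.0, 0, 0], [1, 1, 1]]))
        assert len(out) == 1


class TestConfusion:
    def test_zero_radius_has_no_predictions(self, pair):
        model, reference = pair
        c = confusion_at(model, reference, 0.0, voxel_size=0.2)
        assert c.tp == 0 and c.fp == 0
        assert c.fn + c.tn > 0

    def test_radius_beyond_scene_size_saturates(self, pair):
        model, reference = pair
        bounds = default_bounds(reference)
        diag = float(np.linalg.norm(bounds[1] - bounds[0]))
        c = confusion_at(model, reference, diag * 1.1, voxel_size=0.2)
        assert c.fn == 0 and c.tn == 0
        assert c.tpr == 1.0 and c.fpr == 1.0

    @pytest.mark.parametrize("seed,r", [(0, 0.05), (1, 0.15), (2, 0.4), (3, 1.0)])
    def test_matches_exhaustive_per_voxel_scan(self, seed, r):
        rng = np.random.default_rng(seed)
        reference = _cloud(rng.uniform(-1, 1, (300, 3)))
        model = _cloud(rng.uniform(-1, 1, (250, 3)))
        bounds = np.array([[-1.3, -1.3, -1.3], [1.3, 1.3, 1.3]])
        voxel = 2.6 / 32  # 32^3 grid
        c = confusion_at(model, reference, r, voxel, bounds)
        tp, fp, fn, tn = _oracle_confusion(model, reference, r, voxel, bounds)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_identity_model_at_ground_truth_radius(self):
        rng = np.random.default_rng(9)
        reference = _cloud(rng.uniform(-1, 1, (500, 3)))
        bounds = np.array([[-1.3, -1.3, -1.3], [1.3, 1.3, 1.3]])
        voxel = 2.6 / 32
        r_pos = ground_truth_radius(voxel)
        c = confusion_at(reference, reference, r_pos, voxel, bounds)
        assert c.fn == 0 and c.fp == 0  # predicted set == positive set exactly

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ConfusionCounts(r=-1.0, tp=0, fp=0, fn=0, tn=0)
        with pytest.raises(ValueError):
            ConfusionCounts(r=0.0, tp=-1, fp=0, fn=0, tn=0)


class TestRocCurve:
    def test_anchors_and_monotonicity(self, pair):
        model, reference = pair
        curve = roc_curve(model, reference, voxel_size=0.15)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_conservation_across_sweep(self, pair):
        model, reference = pair
        curve = roc_curve(model, reference, voxel_size=0.15)
        pos = {c.positives for c in curve.counts}
        neg = {c.negatives for c in curve.counts}
        assert len(pos) == 1 and len(neg) == 1

    def test_identity_model_reaches_perfect_corner(self, pair):
        _, reference = pair
        curve = roc_curve(reference, reference, voxel_size=0.15)
        at_perfect = [c for c in curve.counts if c.tpr == 1.0]
        assert min(c.fpr for c in at_perfect) == 0.0
        assert curve.auc >= 0.99

    def test_empty_model_curve_is_flat_until_anchor(self, pair):
        _, reference = pair
        empty = _cloud(np.empty((0, 3)))
        curve = roc_curve(empty, reference, voxel_size=0.15)
        assert np.all(curve.tpr[:-1] == 0.0)
        assert np.all(curve.fpr[:-1] == 0.0)
        assert curve.tpr[-1] == 1.0 and curve.fpr[-1] == 1.0

    def test_invariant_under_shared_translation_and_permutation(self, pair):
        model, reference = pair
        curve = roc_curve(model, reference, voxel_size=0.2)
        shift = np.array([100.0, -50.0, 20.0])
        m2 = _cloud(model.points[::-1] + shift)
        r2 = _cloud(reference.points[np.random.default_rng(0).permutation(len(reference))] + shift)
        curve2 = roc_curve(m2, r2, voxel_size=0.2)
        assert [(c.tp, c.fp, c.fn, c.tn) for c in curve.counts] == [
            (c.tp, c.fp, c.fn, c.tn) for c in curve2.counts
        ]

    def test_determinism_across_runs(self, pair):
        model, reference = pair
        a = roc_curve(model, reference, voxel_size=0.2)
        b = roc_curve(model, reference, voxel_size=0.2)
        assert np.array_equal(a.fpr, b.fpr)
        assert np.array_equal(a.tpr, b.tpr)
        assert a.auc == b.auc

    def test_bad_radii_rejected(self, pair):
        model, reference = pair
        with pytest.raises(ValueError):
            roc_curve(model, reference, radii=[0.2, 0.1], voxel_size=0.2)


class TestAuc:
    def test_diagonal_is_half(self):
        assert auc_from_points([0, 1], [0, 1]) == pytest.approx(0.5, abs=1e-15)

    def test_perfect_step_is_one(self):
        assert auc_from_points([0, 0, 1], [0, 1, 1]) == pytest.approx(1.0, abs=1e-15)

    def test_hand_computed_trapezoid(self):
        # segments: .2*(0+.6)/2 + .3*(.6+.9)/2 + .5*(.9+1)/2 = 0.76
        value = auc_from_points([0, 0.2, 0.5, 1.0], [0, 0.6, 0.9, 1.0])
        assert value == pytest.approx(0.76, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn_on_random_curves(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        f = np.sort(np.concatenate([[0.0, 1.0], rng.uniform(0, 1, 20)]))
        t = np.sort(np.concatenate([[0.0, 1.0], rng.uniform(0, 1, 20)]))
        assert auc_from_points(f, t) == pytest.approx(
            float(sklearn_metrics.auc(f, t)), abs=1e-12
        )

    def test_tied_fpr_keeps_max_tpr(self):
        # max-TPR polyline (0,0)-(0.5,0.8)-(1,1): 0.5*0.4 + 0.5*0.9 = 0.65
        assert auc_from_points([0, 0.5, 0.5, 1], [0, 0.2, 0.8, 1]) == pytest.approx(
            0.65, abs=1e-12
        )
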