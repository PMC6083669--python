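"""Procedural generation of the labelled reference scene.

The reference scene emulates, at the point-cloud level, the kind of virtual
benchmark used to ground-truth photogrammetric reconstructions of
vegetation: a single-trunk deciduous tree (default height 16 scene units)
with a recursive branching skeleton and foliage blobs at the branch tips,
a grass-textured ground plane wide enough to contain a 20-unit-radius
flight circle, and eight brightly coloured cube targets placed around the
tree for registration.

Everything is sampled directly as points with per-point component labels
(ground / trunk / branch / foliage / target index), so downstream
evaluators have exact ground truth without any rendering or image-based
reconstruction step.  A single integer seed fixes the entire scene.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .cloud import (
    LABEL_BRANCH,
    LABEL_FOLIAGE,
    LABEL_GROUND,
    LABEL_TRUNK,
    TARGET_LABELS,
    PointCloud,
)

__all__ = [
    "SceneParams",
    "SceneModel",
    "PointBudgetError",
    "generate_tree",
    "generate_ground",
    "place_targets",
    "assemble_scene",
    "count_skeleton_segments",
]


class PointBudgetError(ValueError):
    """The requested scene would exceed the configured point budget."""


@dataclasses.dataclass
class SceneParams:
    """Parameters of the synthetic reference scene.

    All lengths are in scene units (the reference's own unit; nothing
    downstream assumes metres). ``seed`` fixes the whole scene: the same
    parameters and seed always produce byte-identical output files.
    """

    tree_height: float = 16.0
    trunk_radius: float = 0.3
    branching_depth: int = 4
    branch_angle_deg: float = 35.0
    branches_per_node: int = 3
    foliage_points_per_tip: int = 400
    ground_extent: float = 40.0
    grass_noise_sd: float = 0.03
    target_edge: float = 0.5
    points_per_unit_area: float = 60.0
    seed: int = 0
    # safety cap; desk-scale default scenes stay near 2e5 points
    point_budget: int = 2_000_000
    branch_length_ratio: float = 0.6
    branch_radius_ratio: float = 0.62

    def validate(self) -> None:
        if self.tree_height <= 0:
            raise ValueError("tree_height must be positive")
        if self.branching_depth < 0:
            raise ValueError("branching_depth must be >= 0")
        if self.branches_per_node < 1:
            raise ValueError("branches_per_node must be >= 1")
        if self.points_per_unit_area <= 0 or self.foliage_points_per_tip <= 0:
            raise ValueError("densities must be positive")
        if self.ground_extent <= 0 or self.target_edge <= 0 or self.trunk_radius <= 0:
            raise ValueError("extents must be positive")
        if not 0.0 < self.branch_length_ratio < 1.0:
            raise ValueError("branch_length_ratio must be in (0, 1)")


@dataclasses.dataclass
class SceneModel:
    """A labelled reference cloud plus its registration targets.

    ``scene_width`` is the normaliser used by every relative distance
    threshold downstream: the larger of the x- and y-extents of the
    assembled reference bounding box.
    """

    reference: PointCloud
    target_centroids: np.ndarray  # (8, 3)
    scene_width: float

    def __post_init__(self) -> None:
        self.target_centroids = np.asarray(self.target_centroids, dtype=np.float64).reshape(8, 3)
        if not self.scene_width > 0:
            raise ValueError("scene_width must be positive")
        if self.reference.labels is None:
            raise ValueError("reference cloud must be labelled")
        present = set(np.unique(self.reference.labels).tolist())
        missing = [t for t in TARGET_LABELS if t not in present]
        if missing:
            raise ValueError(f"reference lacks target labels {missing}")


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def count_skeleton_segments(branches_per_node: int, branching_depth: int) -> int:
    """Number of skeleton segments: sum of b**i for i in 0..depth."""
    return sum(branches_per_node**i for i in range(branching_depth + 1))


def _skeleton(params: SceneParams, rng: np.random.Generator):
    """Recursive branching skeleton with unit trunk length.

    Returns a list of (start, end, radius, depth) with the trunk first.
    Each node spawns exactly ``branches_per_node`` children tilted by
    ``branch_angle_deg`` from the parent direction, azimuths evenly spaced
    with seeded jitter, lengths shrinking by ``branch_length_ratio``.
    """
    segments = []

    def grow(start, direction, length, radius, depth):
        end = start + direction * length
        segments.append((start, end, radius, depth))
        if depth >= params.branching_depth:
            return
        # orthonormal frame around the parent direction
        ref = np.array([0.0, 0.0, 1.0])
        if abs(direction @ ref) > 0.95:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(direction, ref)
        u /= np.linalg.norm(u)
        v = np.cross(direction, u)
        tilt = np.radians(params.branch_angle_deg)
        base_az = rng.uniform(0.0, 2.0 * np.pi)
        for k in range(params.branches_per_node):
            az = base_az + 2.0 * np.pi * k / params.branches_per_node
            az += rng.normal(0.0, 0.25)
            child_dir = (
                np.cos(tilt) * direction
                + np.sin(tilt) * (np.cos(az) * u + np.sin(az) * v)
            )
            child_dir /= np.linalg.norm(child_dir)
            grow(end, child_dir, length * params.branch_length_ratio,
                 radius * params.branch_radius_ratio, depth + 1)

    grow(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0, params.trunk_radius, 0)
    return segments


def _sample_cylinder(start, end, radius, n, rng):
    """n points on the lateral surface of the cylinder from start to end."""
    axis = end - start
    length = np.linalg.norm(axis)
    axis = axis / length
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    h = rng.uniform(0.0, length, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return (
        start
        + np.outer(h, axis)
        + radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    )


def generate_tree(params: SceneParams, rng: Optional[np.random.Generator] = None) -> PointCloud:
    """Sample the tree: cylinder surfaces for trunk/branches, foliage at tips.

    The skeleton is grown with a unit-length trunk and then rescaled
    uniformly so the highest branch tip sits exactly at ``tree_height``;
    sampled surface points can exceed it only by the (small) local radius,
    keeping the maximum z within 5% of ``tree_height``.

    With ``branching_depth == 0`` the result is a trunk-only cloud
    (labels all 1, no foliage).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    segments = _skeleton(params, rng)

    tip_height = max(seg[1][2] for seg in segments)
    scale = params.tree_height / tip_height
    segments = [(s * scale, e * scale, r, d) for s, e, r, d in segments]

    # budget estimate before sampling
    density = params.points_per_unit_area
    est = 0
    counts = []
    for s, e, r, d in segments:
        length = float(np.linalg.norm(e - s))
        area = 2.0 * np.pi * r * length
        n = max(int(np.ceil(area * density)), int(np.ceil(length / 0.05)), 8)
        counts.append(n)
        est += n
    n_tips = sum(1 for *_, d in segments if d == params.branching_depth)
    if params.branching_depth > 0:
        est += n_tips * params.foliage_points_per_tip
    if est > params.point_budget:
        raise PointBudgetError(
            f"tree would need ~{est} points, exceeding the budget of {params.point_budget}"
        )

    parts, labels = [], []
    for (s, e, r, d), n in zip(segments, counts):
        parts.append(_sample_cylinder(s, e, r, n, rng))
        labels.append(np.full(n, LABEL_TRUNK if d == 0 else LABEL_BRANCH, np.int64))
    if params.branching_depth > 0:
        semi = np.array([0.7, 0.7, 0.5]) * (params.tree_height / 16.0)
        for s, e, r, d in segments:
            if d != params.branching_depth:
                continue
            m = params.foliage_points_per_tip
            # uniform in the unit ball, then stretched to the ellipsoid
            x = rng.normal(size=(m, 3))
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            x *= rng.uniform(0.0, 1.0, (m, 1)) ** (1.0 / 3.0)
            parts.append(e + x * semi)
            labels.append(np.full(m, LABEL_FOLIAGE, np.int64))

    points = np.vstack(parts)
    lab = np.concatenate(labels)
    colors = np.empty((len(points), 3), dtype=np.uint8)
    wood = lab != LABEL_FOLIAGE
    colors[wood] = (101, 67, 33)
    colors[~wood] = (34, 139, 34)
    # small seeded colour texture
    jitter = rng.integers(-20, 21, size=(len(points), 3))
    colors = np.clip(colors.astype(np.int64) + jitter, 0, 255).astype(np.uint8)
    return PointCloud(points=points, colors=colors, labels=lab)


# ---------------------------------------------------------------------------
# ground
# ---------------------------------------------------------------------------


def generate_ground(params: SceneParams, rng: Optional[np.random.Generator] = None) -> PointCloud:
    """Grass-like ground: a planar grid over [-extent/2, extent/2]^2.

    The point count is exactly ``round(points_per_unit_area * extent**2)``;
    per-point z is Normal(0, grass_noise_sd) to imitate a grass texture,
    and colours vary around grass green.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng([params.seed, 2])
    area = params.ground_extent**2
    n = int(round(params.points_per_unit_area * area))
    m = int(np.ceil(np.sqrt(n)))
    half = params.ground_extent / 2.0
    coords = (np.arange(m) + 0.5) / m * params.ground_extent - half
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    z = rng.normal(0.0, params.grass_noise_sd, n) if params.grass_noise_sd > 0 else np.zeros(n)
    points = np.column_stack([xy, z])
    base = np.array([60, 150, 40], dtype=np.int64)
    colors = np.clip(base + rng.integers(-25, 26, size=(n, 3)), 0, 255).astype(np.uint8)
    return PointCloud(points=points, colors=colors, labels=np.zeros(n, np.int64))


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

# saturated, mutually distinct target colours (one per cube)
_TARGET_COLORS = np.array(
    [
        (255, 0, 0),
        (0, 0, 255),
        (255, 255, 0),
        (255, 0, 255),
        (0, 255, 255),
        (255, 128, 0),
        (128, 0, 255),
        (0, 255, 0),
    ],
    dtype=np.uint8,
)


def _sample_cube_surface(centre, edge, n_half, rng):
    """Antipodally symmetric surface sample: every point is paired with its
    mirror through the centre, so the sample mean equals the centre to
    floating-point accuracy."""
    face = rng.integers(0, 6, n_half)
    uv = rng.uniform(-0.5, 0.5, (n_half, 2)) * edge
    pts = np.empty((n_half, 3))
    axis = face // 2
    sign = np.where(face % 2 == 0, 1.0, -1.0)
    for a in range(3):
        m = axis == a
        others = [b for b in range(3) if b != a]
        pts[m, a] = sign[m] * edge / 2.0
        pts[np.ix_(m, others)] = uv[m]
    pts = np.vstack([pts, -pts])
    return centre + pts


def place_targets(
    params: SceneParams, rng: Optional[np.random.Generator] = None
) -> tuple[PointCloud, np.ndarray]:
    """Eight cube targets on a circle around the tree.

    Cubes (edge ``target_edge``) sit on the ground at 8 evenly spaced
    azimuths at 70% of the ground half-extent — non-collinear, pairwise
    separations far above ``2 * target_edge``. Each cube has a distinct
    label 10..17 and a distinct saturated colour. Returns the cloud and
    the 8x3 centroid array (equal to the point means to ~1e-9 by the
    antipodal sampling).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng([params.seed, 3])
    radius = 0.7 * params.ground_extent / 2.0
    angles = 2.0 * np.pi * np.arange(8) / 8.0
    # cubes sit slightly sunk into the ground so contact survives coordinate
    # quantisation on write (connectivity of the reference is a contract)
    z_centre = 0.4 * params.target_edge
    centres = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.full(8, z_centre)]
    )
    n_half = 200
    parts, labels, colors = [], [], []
    for k in range(8):
        pts = _sample_cube_surface(centres[k], params.target_edge, n_half, rng)
        parts.append(pts)
        labels.append(np.full(len(pts), TARGET_LABELS[k], np.int64))
        colors.append(np.tile(_TARGET_COLORS[k], (len(pts), 1)))
    cloud = PointCloud(
        points=np.vstack(parts),
        colors=np.vstack(colors).astype(np.uint8),
        labels=np.concatenate(labels),
    )
    return cloud, centres


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_scene(params: SceneParams) -> SceneModel:
    """Compose ground + tree + targets into the reference SceneModel.

    Deterministic in ``params.seed``; parts use independent seeded streams
    so each part equals its standalone generation. ``scene_width`` is the
    larger of the x- and y-extents of the assembled bounding box.
    """
    params.validate()
    ground = generate_ground(params)
    tree = generate_tree(params)
    targets, centroids = place_targets(params)
    reference = PointCloud.concatenate([ground, tree, targets])
    if len(reference) > params.point_budget:
        raise PointBudgetError(
            f"assembled scene has {len(reference)} points, over budget {params.point_budget}"
        )
    lo, hi = reference.bbox()
    scene_width = float(max(hi[0] - lo[0], hi[1] - lo[1]))
    return SceneModel(reference=reference, target_centroids=centroids, scene_width=scene_width)
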