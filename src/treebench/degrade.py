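"""Artefact injection: turn a reference scene into a simulated reconstruction.

Dense photogrammetric reconstructions of vegetation exhibit a recurring
taxonomy of defects: errors of omission (holes, partial trees), floating
artefact clusters (typically reconstructed sky), attached artefacts
(spurious structure touching the crown), ghosts (duplicated object parts
from mis-estimated camera poses), plus coordinate noise, density loss and
an arbitrary similarity-transformed frame.  This module is the
constructive inverse of that taxonomy: each operator injects one defect
class with known ground-truth parameters, and :func:`degrade` composes
them in a fixed order while recording a manifest, so every downstream
evaluator can be scored against exact truth.

Operator order is fixed as omission -> thinning -> jitter -> ghost ->
attached ring -> floating clusters -> pose perturbation: jitter never
blurs injected artefact geometry, and the pose perturbation is outermost
(misalignment affects the whole reconstruction, as in reality).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .align import SimilarityTransform, apply_transform
from .cloud import ARTEFACT_LABEL_START, TREE_LABELS, PointCloud

__all__ = [
    "DegradeSpec",
    "PlacementError",
    "apply_omission",
    "add_floating_clusters",
    "add_attached_ring",
    "add_ghost",
    "add_jitter",
    "thin",
    "perturb_pose",
    "degrade",
]


class PlacementError(RuntimeError):
    """The floating-cluster region cannot host the requested clusters disjointly."""


@dataclasses.dataclass
class DegradeSpec:
    """Parameterised artefact profile for one simulated reconstruction.

    The all-default spec is the identity: ``degrade(scene, DegradeSpec())``
    returns the reference unchanged. ``seed`` fixes every random choice.

    Notes on fields:

    * ``omission_*`` removes vegetation: first ``omission_hole_count``
      spheres of radius ``omission_hole_radius`` centred on random tree
      points (spatially coherent holes), then random tree points until at
      least ``omission_fraction`` of the original tree points are gone.
    * ``floating_*`` appends Gaussian blobs in ``floating_region`` (default:
      a "sky" box above the crown), each with a fresh artefact label.
      Cluster diameter is taken as ``6 * floating_cluster_sd``.
    * ``attached_ring`` appends a horizontal torus hugging the upper crown
      (the classic sky-ring artefact attached to the tree).
    * ``ghost_component`` duplicates one labelled component at
      ``ghost_offset``.
    """

    omission_fraction: float = 0.0
    omission_hole_count: int = 0
    omission_hole_radius: float = 1.5
    floating_cluster_count: int = 0
    floating_cluster_points: int = 200
    floating_cluster_sd: float = 0.12
    floating_region: Optional[np.ndarray] = None  # (2, 3) [min; max], default sky box
    attached_ring: bool = False
    ring_radius: Optional[float] = None  # default: hug the crown surface
    ring_gap: float = 0.0  # >0: hover this far off the crown instead of touching
    ring_thickness: float = 0.35
    ring_points: int = 4000
    ghost_component: Optional[int] = None
    ghost_offset: Sequence[float] = (5.0, 0.0, 0.0)
    jitter_sd: float = 0.0
    thinning_keep: float = 1.0
    pose_perturbation: Optional[SimilarityTransform] = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.omission_fraction <= 1.0:
            raise ValueError("omission_fraction must be in [0, 1]")
        if not 0.0 < self.thinning_keep <= 1.0:
            raise ValueError("thinning_keep must be in (0, 1]")
        for name in ("omission_hole_count", "floating_cluster_count",
                     "floating_cluster_points", "ring_points"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.jitter_sd < 0 or self.floating_cluster_sd <= 0:
            raise ValueError("noise scales must be non-negative (cluster sd positive)")


def _next_artefact_label(cloud: PointCloud) -> int:
    if cloud.labels is None:
        return ARTEFACT_LABEL_START
    existing = cloud.labels[cloud.labels >= ARTEFACT_LABEL_START]
    return ARTEFACT_LABEL_START if existing.size == 0 else int(existing.max()) + 1


def _tree_mask(cloud: PointCloud) -> np.ndarray:
    if cloud.labels is None:
        raise ValueError("cloud must be labelled to identify vegetation points")
    return np.isin(cloud.labels, TREE_LABELS)


# ---------------------------------------------------------------------------
# omission
# ---------------------------------------------------------------------------


def apply_omission(
    cloud: PointCloud,
    spec: DegradeSpec,
    rng: Optional[np.random.Generator] = None,
    manifest: Optional[dict] = None,
) -> PointCloud:
    """Remove vegetation points: seeded spherical holes, then random removal.

    Holes delete *all* points they contain (any label); the fraction rule
    then removes random surviving tree points until at least
    ``omission_fraction`` of the original tree points are gone. Non-tree
    labels are never touched by the fraction rule.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng([spec.seed, 10])
    if spec.omission_hole_count == 0 and spec.omission_fraction == 0.0:
        if manifest is not None:
            manifest["omission"] = {"holes": [], "requested_fraction": 0.0,
                                    "achieved_fraction": 0.0, "hole_fraction": 0.0}
        return cloud
    tree = _tree_mask(cloud)
    n_tree0 = int(tree.sum())
    keep = np.ones(len(cloud), dtype=bool)
    holes = []
    if spec.omission_hole_count > 0 and n_tree0 > 0:
        tree_idx = np.flatnonzero(tree)
        centres_idx = rng.choice(tree_idx, size=spec.omission_hole_count, replace=True)
        tree_kd = cKDTree(cloud.points)
        for ci in centres_idx:
            centre = cloud.points[ci]
            inside = tree_kd.query_ball_point(centre, spec.omission_hole_radius)
            keep[inside] = False
            holes.append({"centre": centre.tolist(), "radius": spec.omission_hole_radius})
    removed_tree = int((tree & ~keep).sum())
    hole_fraction = removed_tree / n_tree0 if n_tree0 else 0.0
    target_removed = int(np.ceil(spec.omission_fraction * n_tree0))
    if removed_tree < target_removed:
        candidates = np.flatnonzero(tree & keep)
        extra = rng.choice(candidates, size=target_removed - removed_tree, replace=False)
        keep[extra] = False
        removed_tree = target_removed
    if manifest is not None:
        manifest["omission"] = {
            "holes": holes,
            "requested_fraction": spec.omission_fraction,
            "hole_fraction": hole_fraction,
            "achieved_fraction": removed_tree / n_tree0 if n_tree0 else 0.0,
        }
    return cloud.subset(keep)


# ---------------------------------------------------------------------------
# floating clusters
# ---------------------------------------------------------------------------


def _default_sky_region(cloud: PointCloud, margin: float) -> np.ndarray:
    """A "sky" box above the crown, clearing the scene top by ``margin``."""
    lo, hi = cloud.bbox()
    cx = 0.5 * (lo[:2] + hi[:2])
    half = 0.375 * (hi[:2] - lo[:2])
    z0 = hi[2] + margin
    return np.array(
        [
            [cx[0] - half[0], cx[1] - half[1], z0],
            [cx[0] + half[0], cx[1] + half[1], z0 + 2.0],
        ]
    )


def add_floating_clusters(
    cloud: PointCloud,
    spec: DegradeSpec,
    rng: Optional[np.random.Generator] = None,
    manifest: Optional[dict] = None,
) -> PointCloud:
    """Append disconnected Gaussian blobs ("sky" artefacts) with fresh labels.

    Cluster centres are rejection-sampled inside ``floating_region`` with
    pairwise separation of at least twice the cluster diameter
    (``6 * floating_cluster_sd``); the region itself must clear the scene
    bounding box by the same margin, which keeps every blob disconnected
    from the scene at any segmentation gap threshold below that margin.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng([spec.seed, 11])
    if spec.floating_cluster_count == 0:
        if manifest is not None:
            manifest.setdefault("artefacts", [])
        return cloud
    diameter = 6.0 * spec.floating_cluster_sd
    min_sep = 2.0 * diameter
    region = spec.floating_region
    if region is None:
        region = _default_sky_region(cloud, margin=min_sep * 1.05)
    region = np.asarray(region, dtype=np.float64).reshape(2, 3)
    lo, hi = cloud.bbox()
    # region must clear the scene by the separation margin (here: vertically
    # or laterally outside the inflated scene box)
    inflated_lo, inflated_hi = lo - min_sep, hi + min_sep
    overlaps = np.all(region[0] < inflated_hi) and np.all(region[1] > inflated_lo)
    if overlaps:
        raise PlacementError(
            "floating_region intersects the scene bounding box inflated by "
            f"{min_sep:g}; floating clusters would not be guaranteed disconnected"
        )
    span = region[1] - region[0]
    if np.any(span <= 0):
        raise PlacementError("floating_region is degenerate")
    centres: list[np.ndarray] = []
    max_tries = 200 * spec.floating_cluster_count + 1000
    tries = 0
    while len(centres) < spec.floating_cluster_count:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.floating_cluster_count} clusters with "
                f"separation {min_sep:g} in the given region after {max_tries} tries"
            )
        tries += 1
        cand = region[0] + rng.uniform(size=3) * span
        if all(np.linalg.norm(cand - c) >= min_sep for c in centres):
            centres.append(cand)

    label0 = _next_artefact_label(cloud)
    parts, labels = [], []
    records = manifest.setdefault("artefacts", []) if manifest is not None else None
    for k, c in enumerate(centres):
        pts = c + rng.normal(0.0, spec.floating_cluster_sd, (spec.floating_cluster_points, 3))
        parts.append(pts)
        labels.append(np.full(len(pts), label0 + k, np.int64))
        if records is not None:
            records.append(
                {"kind": "floating", "label": label0 + k, "centre": c.tolist(),
                 "sd": spec.floating_cluster_sd, "points": spec.floating_cluster_points}
            )
    blob = PointCloud(
        points=np.vstack(parts),
        colors=np.full((sum(map(len, parts)), 3), 200, np.uint8),
        labels=np.concatenate(labels),
    )
    return PointCloud.concatenate([cloud, blob])


# ---------------------------------------------------------------------------
# attached ring
# ---------------------------------------------------------------------------


def add_attached_ring(
    cloud: PointCloud,
    spec: DegradeSpec,
    rng: Optional[np.random.Generator] = None,
    manifest: Optional[dict] = None,
) -> PointCloud:
    """Append a horizontal torus enveloping the upper crown, touching it.

    Mimics the "sky ring" attached artefact: a dense horizontal band of
    points around the upper half of the crown. The default major radius is
    chosen from the crown's own radial extent at ring height so the torus
    interpenetrates the foliage surface (and therefore merges with the
    main component under connected-component segmentation).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng([spec.seed, 12])
    if not spec.attached_ring:
        return cloud
    if cloud.labels is None or not np.any(cloud.labels == 3):
        raise ValueError("attached ring needs foliage points (label 3) to attach to")
    fol = cloud.points[cloud.labels == 3]
    axis_xy = fol[:, :2].mean(axis=0)
    z_ring = float(np.quantile(fol[:, 2], 0.75))
    band_half = spec.ring_thickness + 0.25
    band = fol[np.abs(fol[:, 2] - z_ring) < band_half]
    if len(band) == 0:
        band = fol
    radial = np.linalg.norm(band[:, :2] - axis_xy, axis=1)
    if spec.ring_radius is not None:
        major = spec.ring_radius
    elif spec.ring_gap > 0:
        major = float(radial.max()) + spec.ring_thickness + spec.ring_gap
    else:
        major = float(np.quantile(radial, 0.85))
    n = spec.ring_points
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    # minor-disc offsets
    rr = spec.ring_thickness * np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    radial_off = rr * np.cos(phi)
    z_off = rr * np.sin(phi)
    ring = np.column_stack(
        [
            axis_xy[0] + (major + radial_off) * np.cos(theta),
            axis_xy[1] + (major + radial_off) * np.sin(theta),
            z_ring + z_off,
        ]
    )
    label = _next_artefact_label(cloud)
    ring_cloud = PointCloud(
        points=ring,
        colors=np.tile(np.array([180, 200, 255], np.uint8), (n, 1)),
        labels=np.full(n, label, np.int64),
    )
    if manifest is not None:
        manifest.setdefault("artefacts", []).append(
            {"kind": "attached_ring", "label": label, "centre_xy": axis_xy.tolist(),
             "z": z_ring, "major_radius": major, "thickness": spec.ring_thickness,
             "points": n}
        )
    return PointCloud.concatenate([cloud, ring_cloud])


# ---------------------------------------------------------------------------
# ghost / jitter / thinning / pose
# ---------------------------------------------------------------------------


def add_ghost(
    cloud: PointCloud,
    spec: DegradeSpec,
    manifest: Optional[dict] = None,
) -> PointCloud:
    """Duplicate one labelled component at a rigid offset (a "ghost")."""
    spec.validate()
    if spec.ghost_component is None:
        return cloud
    if cloud.labels is None or not np.any(cloud.labels == spec.ghost_component):
        raise ValueError(f"ghost component label {spec.ghost_component} not present")
    mask = cloud.labels == spec.ghost_component
    offset = np.asarray(spec.ghost_offset, dtype=np.float64).reshape(3)
    label = _next_artefact_label(cloud)
    ghost = PointCloud(
        points=cloud.points[mask] + offset,
        colors=None if cloud.colors is None else cloud.colors[mask].copy(),
        labels=np.full(int(mask.sum()), label, np.int64),
    )
    if manifest is not None:
        manifest.setdefault("artefacts", []).append(
            {"kind": "ghost", "label": label, "source_label": int(spec.ghost_component),
             "offset": offset.tolist(), "points": int(mask.sum())}
        )
    return PointCloud.concatenate([cloud, ghost])


def add_jitter(
    cloud: PointCloud, spec: DegradeSpec, rng: Optional[np.random.Generator] = None
) -> PointCloud:
    """Add iid Normal(0, jitter_sd) noise to every coordinate."""
    spec.validate()
    if spec.jitter_sd == 0.0:
        return cloud
    if rng is None:
        rng = np.random.default_rng([spec.seed, 13])
    out = cloud.copy()
    out.points = out.points + rng.normal(0.0, spec.jitter_sd, out.points.shape)
    return out


def thin(
    cloud: PointCloud, spec: DegradeSpec, rng: Optional[np.random.Generator] = None
) -> PointCloud:
    """Keep a seeded Bernoulli(thinning_keep) subset of the points."""
    spec.validate()
    if spec.thinning_keep == 1.0:
        return cloud
    if rng is None:
        rng = np.random.default_rng([spec.seed, 14])
    keep = rng.uniform(size=len(cloud)) < spec.thinning_keep
    return cloud.subset(keep)


def perturb_pose(cloud: PointCloud, spec: DegradeSpec) -> PointCloud:
    """Apply the spec's similarity transform (simulating an unaligned frame)."""
    spec.validate()
    if spec.pose_perturbation is None:
        return cloud
    return apply_transform(cloud, spec.pose_perturbation)


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------


def degrade(scene_or_cloud, spec: DegradeSpec) -> tuple[PointCloud, dict]:
    """Apply the full artefact profile in fixed order; return cloud + manifest.

    Order: omission -> thinning -> jitter -> ghost -> attached ring ->
    floating clusters -> pose perturbation. The manifest records every
    injected artefact with its ground-truth parameters (label, geometry,
    point counts) and the achieved omission fractions. An all-default spec
    returns the input unchanged (byte-exact) with an empty manifest.
    """
    spec.validate()
    cloud = getattr(scene_or_cloud, "reference", scene_or_cloud)
    manifest: dict = {"seed": spec.seed, "artefacts": []}
    rng = np.random.default_rng([spec.seed, 20])
    out = apply_omission(cloud, spec, rng=rng, manifest=manifest)
    out = thin(out, spec, rng=rng)
    out = add_jitter(out, spec, rng=rng)
    out = add_ghost(out, spec, manifest=manifest)
    out = add_attached_ring(out, spec, rng=rng, manifest=manifest)
    out = add_floating_clusters(out, spec, rng=rng, manifest=manifest)
    out = perturb_pose(out, spec)
    manifest["artefact_count"] = len(manifest["artefacts"])
    manifest["floating_cluster_count"] = sum(
        1 for a in manifest["artefacts"] if a["kind"] == "floating"
    )
    manifest["point_count"] = len(out)
    if spec.pose_perturbation is not None:
        manifest["pose_perturbation"] = spec.pose_perturbation.to_dict()
    return out, manifest
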