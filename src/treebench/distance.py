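"""One-sided nearest-neighbour distance fields and distance-class maps.

The cloud-to-cloud nearest-neighbour distance — computed at every point of
the query cloud against the target cloud — is the standard spatially
explicit error map for reconstruction quality. It is one-sided: the
model-to-reference direction exposes commission errors (artefact points
far from any true structure) but cannot see omission; the
reference-to-model direction exposes omission. Both directions are first
class here.

For visual maps, distances are normalised by scene width and binned into
five classes with the conventional palette blue / green / yellow / red /
purple(outlier); class edges default to 0.0075, 0.015 and 0.0225 of unit
scene width with half-open [lower, upper) intervals, a fourth class up to
twice the last edge and outliers beyond.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, write_ply

__all__ = [
    "DistanceField",
    "DistanceClassScheme",
    "CLASS_PALETTE",
    "nn_distances",
    "classify_distances",
    "summary_stats",
    "write_colored_cloud",
]

# class id -> RGB: blue, green, yellow, red, purple
CLASS_PALETTE = np.array(
    [(0, 0, 255), (0, 255, 0), (255, 255, 0), (255, 0, 0), (160, 32, 240)],
    dtype=np.uint8,
)


@dataclasses.dataclass
class DistanceField:
    """Per-point nearest-neighbour distances of one query cloud.

    ``direction`` is ``"model_to_reference"`` or ``"reference_to_model"``;
    ``scene_width`` is carried so classes can be computed in normalised
    units later.
    """

    distances: np.ndarray
    direction: str
    scene_width: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64).reshape(-1)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if self.direction not in ("model_to_reference", "reference_to_model"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.scene_width > 0:
            raise ValueError("scene_width must be positive")

    def normalized(self) -> np.ndarray:
        return self.distances / self.scene_width

    def __len__(self) -> int:
        return len(self.distances)


@dataclasses.dataclass
class DistanceClassScheme:
    """Strictly increasing normalised class edges plus an outlier cutoff.

    Classes: 0 for [0, t1), 1 for [t1, t2), 2 for [t2, t3),
    3 for [t3, outlier_factor*t3), 4 (outlier) beyond.
    """

    thresholds: Sequence[float] = (0.0075, 0.015, 0.0225)
    outlier_factor: float = 2.0

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        if len(t) != 3 or any(v <= 0 for v in t) or not (t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be 3 strictly increasing positive values")
        if self.outlier_factor <= 1.0:
            raise ValueError("outlier_factor must exceed 1")
        self.thresholds = t

    @property
    def edges(self) -> np.ndarray:
        t = self.thresholds
        return np.array([t[0], t[1], t[2], self.outlier_factor * t[2]])


def nn_distances(query: PointCloud, target: PointCloud, direction: str,
                 scene_width: float) -> DistanceField:
    """Exact nearest-neighbour distance from every query point to the target.

    Uses a k-d tree; results are exact (no approximation) and bit-stable
    across runs. An empty target cloud is a precondition violation.
    """
    if len(target) == 0:
        raise ValueError("target cloud is empty; nearest-neighbour distance undefined")
    if len(query) == 0:
        return DistanceField(np.empty(0), direction, scene_width)
    d, _ = cKDTree(target.points).query(query.points)
    return DistanceField(d, direction, scene_width)


def classify_distances(
    field: DistanceField, scheme: Optional[DistanceClassScheme] = None
) -> tuple[np.ndarray, dict[int, int]]:
    """Bin normalised distances into class ids 0..4.

    Returns the per-point class array and a {class id: count} dict whose
    counts always sum to ``len(field)``. Boundaries follow the half-open
    convention: a normalised distance exactly equal to an edge falls in
    the higher class.
    """
    if scheme is None:
        scheme = DistanceClassScheme()
    classes = np.digitize(field.normalized(), scheme.edges, right=False)
    counts = {c: int((classes == c).sum()) for c in range(5)}
    return classes.astype(np.int64), counts


def summary_stats(field: DistanceField, beyond: Sequence[float] = ()) -> dict:
    """Standard scalar summaries of a distance field.

    Reports mean, RMS, median, 95th percentile and max in scene units plus
    the same values normalised by scene width; ``beyond`` adds
    ``fraction_beyond(t)`` entries (t in scene units).
    """
    d = field.distances
    if len(d) == 0:
        raise ValueError("summary of empty distance field")
    stats = {
        "n": int(len(d)),
        "mean": float(d.mean()),
        "rms": float(np.sqrt((d**2).mean())),
        "median": float(np.median(d)),
        "p95": float(np.quantile(d, 0.95)),
        "max": float(d.max()),
    }
    sw = field.scene_width
    stats["normalized"] = {
        k: stats[k] / sw for k in ("mean", "rms", "median", "p95", "max")
    }
    for t in beyond:
        stats[f"fraction_beyond_{t:g}"] = float((d > t).mean())
    return stats


def write_colored_cloud(
    query: PointCloud, classes: np.ndarray, path: Union[str, "os.PathLike"]
) -> None:
    """Write the query cloud as PLY coloured by distance class (fixed palette)."""
    classes = np.asarray(classes)
    if classes.shape != (len(query),):
        raise ValueError("classes must have one entry per query point")
    colored = PointCloud(
        points=query.points.copy(),
        colors=CLASS_PALETTE[classes],
        labels=None if query.labels is None else query.labels.copy(),
    )
    write_ply(colored, path)
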