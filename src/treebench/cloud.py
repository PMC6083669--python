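"""Point-cloud container and ASCII PLY / XYZ text input-output.

The :class:`PointCloud` is the package's universal currency: an ``(N, 3)``
array of coordinates in "scene units" (whatever unit the reference scene
uses; every distance threshold downstream is normalisable by scene width),
with optional per-point 8-bit RGB colours and optional integer component
labels.

Label vocabulary
----------------
``0``       ground
``1``       trunk
``2``       branch
``3``       foliage
``10..17``  reference target cube index
``>= 100``  injected artefact id

Reading with ``strict=True`` rejects any label outside this closed set.

Only the ASCII 1.0 PLY dialect is supported; binary PLY is rejected
explicitly rather than mis-read, keeping every file diffable and
inspectable with a text editor (the interchange formats CloudCompare and
Meshlab both accept).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "PointCloud",
    "CloudFormatError",
    "UnsupportedDialectError",
    "LABEL_GROUND",
    "LABEL_TRUNK",
    "LABEL_BRANCH",
    "LABEL_FOLIAGE",
    "TARGET_LABELS",
    "ARTEFACT_LABEL_START",
    "is_valid_label",
    "read_ply",
    "write_ply",
    "read_xyz",
    "write_xyz",
]

LABEL_GROUND = 0
LABEL_TRUNK = 1
LABEL_BRANCH = 2
LABEL_FOLIAGE = 3
TARGET_LABELS = tuple(range(10, 18))
ARTEFACT_LABEL_START = 100

TREE_LABELS = (LABEL_TRUNK, LABEL_BRANCH, LABEL_FOLIAGE)


class CloudFormatError(ValueError):
    """A file violates the expected text point-cloud format."""


class UnsupportedDialectError(CloudFormatError):
    """A PLY file uses a dialect (e.g. binary) this package does not read."""


def is_valid_label(label: int) -> bool:
    """True if ``label`` belongs to the closed component-label vocabulary."""
    return (
        label in (LABEL_GROUND, LABEL_TRUNK, LABEL_BRANCH, LABEL_FOLIAGE)
        or label in TARGET_LABELS
        or label >= ARTEFACT_LABEL_START
    )


@dataclasses.dataclass
class PointCloud:
    """N 3-D points with optional colour and component-label attributes.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of coordinates; all values must be finite.
    colors
        Optional ``(N, 3)`` uint8 array of RGB values.
    labels
        Optional ``(N,)`` integer array of component labels.
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        n = len(pts)
        if self.colors is not None:
            col = np.asarray(self.colors)
            if col.shape != (n, 3):
                raise ValueError(f"colors must be ({n}, 3), got {col.shape}")
            if col.dtype != np.uint8:
                if np.any((col < 0) | (col > 255)):
                    raise ValueError("colors must lie in 0..255")
                col = col.astype(np.uint8)
            self.colors = col
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != (n,):
                raise ValueError(f"labels must be ({n},), got {lab.shape}")
            self.labels = lab.astype(np.int64)

    def __len__(self) -> int:
        return len(self.points)

    # -- structural helpers -------------------------------------------------

    def subset(self, index: Union[np.ndarray, Sequence[int]]) -> "PointCloud":
        """Row-select points (boolean mask or integer index), keeping attributes."""
        idx = np.asarray(index)
        return PointCloud(
            points=self.points[idx],
            colors=None if self.colors is None else self.colors[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box as ``(min, max)`` 3-vectors."""
        if len(self) == 0:
            raise ValueError("bounding box of empty cloud is undefined")
        return self.points.min(axis=0), self.points.max(axis=0)

    def copy(self) -> "PointCloud":
        return PointCloud(
            points=self.points.copy(),
            colors=None if self.colors is None else self.colors.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    @staticmethod
    def concatenate(clouds: Iterable["PointCloud"]) -> "PointCloud":
        """Stack clouds in order; attributes are kept only if all parts have them.

        A missing colour array in any part is filled with mid-grey if at
        least one part carries colours; a missing label array raises, since
        silently inventing component labels would corrupt ground truth.
        """
        clouds = list(clouds)
        if not clouds:
            return PointCloud(np.empty((0, 3)))
        pts = np.vstack([c.points for c in clouds])
        colors = None
        if any(c.colors is not None for c in clouds):
            parts = []
            for c in clouds:
                if c.colors is None:
                    parts.append(np.full((len(c), 3), 128, dtype=np.uint8))
                else:
                    parts.append(c.colors)
            colors = np.vstack(parts)
        labels = None
        if any(c.labels is not None for c in clouds):
            if not all(c.labels is not None or len(c) == 0 for c in clouds):
                raise ValueError("cannot concatenate labelled and unlabelled clouds")
            labels = np.concatenate(
                [c.labels if c.labels is not None else np.empty(0, np.int64) for c in clouds]
            )
        return PointCloud(points=pts, colors=colors, labels=labels)


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_FLOAT_TYPES = {"float", "float32", "double", "float64"}
_PLY_UCHAR_TYPES = {"uchar", "uint8"}
_PLY_INT_TYPES = {"char", "int8", "short", "int16", "int", "int32", "uint", "uint32", "ushort", "uint16"}


def _check_labels_strict(labels: np.ndarray, where: str) -> None:
    bad = [int(v) for v in np.unique(labels) if not is_valid_label(int(v))]
    if bad:
        raise CloudFormatError(f"{where}: labels outside the closed vocabulary: {bad}")


def read_ply(path: Union[str, Path], strict: bool = False) -> PointCloud:
    """Read an ASCII PLY file with at least float x, y, z vertex properties.

    Recognised optional properties: ``red``, ``green``, ``blue`` (uchar)
    mapped to colours, and an integer ``label``. Unknown scalar properties
    are skipped. Point order is preserved exactly as stored.

    Parameters
    ----------
    path
        File to read.
    strict
        If true, reject component labels outside the closed vocabulary.

    Raises
    ------
    CloudFormatError
        Malformed header or body; the message names the offending line.
    UnsupportedDialectError
        Binary PLY files.
    """
    path = Path(path)
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        magic = fh.readline().strip()
        if magic != "ply":
            raise CloudFormatError(f"{path}: line 1: not a PLY file (got {magic!r})")
        n_vertex = None
        properties: list[tuple[str, str]] = []  # (type, name) of the vertex element
        in_vertex_element = False
        lineno = 1
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: unexpected end of header")
            lineno += 1
            tokens = line.split()
            if not tokens or tokens[0] == "comment":
                continue
            key = tokens[0]
            if key == "format":
                if len(tokens) >= 2 and tokens[1].startswith("binary"):
                    raise UnsupportedDialectError(
                        f"{path}: line {lineno}: binary PLY is not supported ({line.strip()!r})"
                    )
                if len(tokens) < 2 or tokens[1] != "ascii":
                    raise CloudFormatError(
                        f"{path}: line {lineno}: only 'format ascii 1.0' is supported "
                        f"(got {line.strip()!r})"
                    )
            elif key == "element":
                if len(tokens) != 3:
                    raise CloudFormatError(f"{path}: line {lineno}: malformed element line {line.strip()!r}")
                in_vertex_element = tokens[1] == "vertex"
                if in_vertex_element:
                    try:
                        n_vertex = int(tokens[2])
                    except ValueError:
                        raise CloudFormatError(
                            f"{path}: line {lineno}: bad vertex count {tokens[2]!r}"
                        ) from None
            elif key == "property":
                if in_vertex_element:
                    if len(tokens) != 3 or tokens[1] == "list":
                        raise CloudFormatError(
                            f"{path}: line {lineno}: unsupported vertex property {line.strip()!r}"
                        )
                    properties.append((tokens[1], tokens[2]))
            elif key == "end_header":
                break
            else:
                raise CloudFormatError(f"{path}: line {lineno}: unknown header keyword {line.strip()!r}")
        if n_vertex is None:
            raise CloudFormatError(f"{path}: header has no vertex element")
        names = [name for _, name in properties]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudFormatError(f"{path}: vertex element lacks property {axis!r}")
            ptype = properties[names.index(axis)][0]
            if ptype not in _PLY_FLOAT_TYPES:
                raise CloudFormatError(f"{path}: property {axis!r} must be float, got {ptype!r}")

        ncols = len(properties)
        rows = np.empty((n_vertex, ncols), dtype=np.float64)
        for i in range(n_vertex):
            line = fh.readline()
            if not line:
                raise CloudFormatError(
                    f"{path}: line {lineno + i + 1}: expected {n_vertex} vertices, file ends after {i}"
                )
            vals = line.split()
            if len(vals) != ncols:
                raise CloudFormatError(
                    f"{path}: line {lineno + i + 1}: expected {ncols} values, got {len(vals)}"
                )
            try:
                rows[i] = [float(v) for v in vals]
            except ValueError:
                raise CloudFormatError(
                    f"{path}: line {lineno + i + 1}: non-numeric value in {line.strip()!r}"
                ) from None

    cols = {name: rows[:, j] for j, (_, name) in enumerate(properties)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    colors = None
    if all(c in cols for c in ("red", "green", "blue")):
        colors = np.column_stack([cols["red"], cols["green"], cols["blue"]])
        if np.any((colors < 0) | (colors > 255)):
            raise CloudFormatError(f"{path}: colour values outside 0..255")
        colors = colors.astype(np.uint8)
    labels = None
    if "label" in cols:
        labels = np.round(cols["label"]).astype(np.int64)
        if strict:
            _check_labels_strict(labels, str(path))
    return PointCloud(points=points, colors=colors, labels=labels)


def write_ply(cloud: PointCloud, path: Union[str, Path], precision: int = 6) -> None:
    """Write a cloud as ASCII PLY with one vertex element.

    Colour and label properties are emitted iff present on the cloud.
    Coordinates are written with ``precision`` significant digits
    (default 6); the header vertex count always equals ``len(cloud)``.
    """
    path = Path(path)
    header = ["ply", "format ascii 1.0", f"element vertex {len(cloud)}"]
    header += [f"property float {axis}" for axis in "xyz"]
    if cloud.colors is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    if cloud.labels is not None:
        header.append("property int label")
    header.append("end_header")

    fmt = f"{{:.{precision}g}}"
    lines = [*header]
    for i in range(len(cloud)):
        parts = [fmt.format(v) for v in cloud.points[i]]
        if cloud.colors is not None:
            parts += [str(int(v)) for v in cloud.colors[i]]
        if cloud.labels is not None:
            parts.append(str(int(cloud.labels[i])))
        lines.append(" ".join(parts))
    path.write_text("\n".join(lines) + "\n", encoding="ascii")


# ---------------------------------------------------------------------------
# XYZ text
# ---------------------------------------------------------------------------


def read_xyz(path: Union[str, Path]) -> PointCloud:
    """Read whitespace-delimited rows of ``x y z`` or ``x y z r g b``.

    All rows must have the same column count (3 or 6); a ragged row raises
    :class:`CloudFormatError` naming the row number. Row order is preserved.
    """
    path = Path(path)
    values: list[list[float]] = []
    width = None
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for rowno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if width is None:
                width = len(tokens)
                if width not in (3, 6):
                    raise CloudFormatError(
                        f"{path}: row {rowno}: expected 3 or 6 columns, got {width}"
                    )
            elif len(tokens) != width:
                raise CloudFormatError(
                    f"{path}: row {rowno}: expected {width} columns, got {len(tokens)}"
                )
            try:
                values.append([float(t) for t in tokens])
            except ValueError:
                raise CloudFormatError(
                    f"{path}: row {rowno}: non-numeric value in {line.strip()!r}"
                ) from None
    if not values:
        return PointCloud(np.empty((0, 3)))
    arr = np.asarray(values, dtype=np.float64)
    colors = None
    if arr.shape[1] == 6:
        rgb = arr[:, 3:6]
        if np.any((rgb < 0) | (rgb > 255)):
            raise CloudFormatError(f"{path}: colour values outside 0..255")
        colors = rgb.astype(np.uint8)
    return PointCloud(points=arr[:, :3], colors=colors)


def write_xyz(cloud: PointCloud, path: Union[str, Path], precision: int = 6) -> None:
    """Write ``x y z`` (plus ``r g b`` when colours are present) text rows."""
    path = Path(path)
    fmt = f"{{:.{precision}g}}"
    lines = []
    for i in range(len(cloud)):
        parts = [fmt.format(v) for v in cloud.points[i]]
        if cloud.colors is not None:
            parts += [str(int(v)) for v in cloud.colors[i]]
        lines.append(" ".join(parts))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="ascii")
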